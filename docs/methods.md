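# Methods

## Model

`fpfinder` treats a cohort of genotyped samples as a document collection
and genomic sites as terms.  A site is "present" in a sample iff the
genotype carries at least one ALT allele; the data structure everything
operates on is the boolean site x sample presence/absence matrix.  For a
target sub-population *T* inside (or beside) a background cohort *B*, the
fingerprint score of site *s* is

    score(s) = tf(s) * idf(s)
    tf(s)    = df_T(s) / |T|
    idf(s)   = log10((|B| + 1) / (df_B(s) + 1))

`df_T`, `df_B` are presence counts.  The score is 0 when the site is
absent from the target (enforced explicitly so that an infinite idf under
unsmoothed variants cannot produce NaN), and bounded by `log10(|B| + 1)`.

### Formula variants

TF-IDF has several textbook variants and the choice matters only at the
margins.  The package's default — base-10 log, add-one smoothing of both
the numerator and denominator of the idf ratio — was chosen because (a)
smoothing keeps every score finite, with a ubiquitous background site
scoring exactly 0, and (b) under the 20-vs-410 permutation null the
default's top-5% boundary sits at 0.779 (exact) with 1000-draw
realizations spanning roughly 0.70-0.92, which is the operating range in
which the workflow's canonical threshold (0.817-class values) lives.
Natural log and unsmoothed/denominator-only smoothing remain selectable in
`ScoringConfig` for sensitivity analysis; "add-one-denominator" idf values
are floored at 0 so the score bound stays non-negative.

### Background semantics

Two modes, never inferred silently:

* `disjoint` (pedigree mode): *B* is the set of samples with the
  background role; *T* and *B* are different samples.
* `full-cohort` (region mode): *B* is the whole manifest, so a
  sub-population's own members count toward the background frequency.
  This is the mode used by the region scan, where every region is scored
  against the entire variome and consequently a site fixed in the whole
  cohort scores 0 in every region.

## Permutation threshold

The null hypothesis is no association between a site and the target: the
target presence count is uniform on the integers {0..|T|} and the
background count independently uniform on {0..|B|}.  "A number ranging
from 0 to N" is read as a uniform *integer* — presence counts in finite
cohorts are integers.  Each simulated score is tf(k) * idf(m); the
threshold is the nearest-rank-from-above (1 - f) quantile: the smallest
simulated score with at least `ceil(f * n_sims)` scores at or above it, so
with 1000 draws and f = 0.05 exactly the 50 largest define the boundary.

Because the null lives on a finite (|T|+1) x (|B|+1) grid,
`exact_null_quantile` computes the same quantile by exhaustive
enumeration.  Tests use it as the stable reference: the simulated
threshold converges to it as `n_sims` grows, and the 1000-draw estimator
is centred on it with sd ~ 0.04 at the 20-vs-410 design.  Any single
published realization of the 1000-draw procedure is one draw from that
spread; seeds are therefore mandatory (no wall-clock seeding anywhere).

## Region scan

`score_by_region` computes score[s, r] = tf over region r's samples x idf
over the full cohort.  The *enriched region* of a site is the argmax over
regions; exact ties are broken lexicographically by region label and
flagged rather than hidden.  `trim_low_specificity` drops sites whose row
maximum is below a cutoff (default 0.1, boundary inclusive).
`select_region_specific` applies the top-fraction rule (default 0.1%) to
each region's score column *independently* — the reading consistent with
selecting sites "for each sub-population" — using the same nearest-rank
quantile rule, with boundary ties included (counts can exceed the nominal
fraction but never fall below `ceil(f * n_sites)`); the per-region sets
and their union are both reported.  `compare_enriched_groups` partitions
an externally supplied functional-site list (e.g. GWAS hits with signed
effects) by enriched region and compares two groups' effects with Welch's
t-test; restricting to positive effects is an explicit flag, never
inferred from the data.

## Genic annotation

Gene models come from GFF3 (gene/mRNA/exon/five_prime_UTR/three_prime_UTR
via `gffutils`; the first mRNA per gene is used, with a warning on
multi-isoform genes).  Categories and precedence:

    splicing > UTR5 > UTR3 > exonic > intronic > upstream1kb > downstream1kb > intergenic

* splicing: within 2 bp of an exon-intron junction on the intron side —
  the common annotator default, since only the category name is standard.
* UTR refinement: an exonic position inside a UTR span reports UTR5/UTR3,
  not exonic, because the two are tabulated separately.
* Flanks: 1000 bp, strand-aware (upstream of a minus-strand gene is past
  its 3'-most coordinate).
* Multi-gene hits: the single reported category is the highest-precedence
  one across genes; all (gene, category) overlaps are retained in
  `all_overlaps`.  Gene IDs break residual ties deterministically.

A site is *gene-related* iff its category is not intergenic.  The SNP
spectrum counts the 12 ordered ref->alt pairs with no complementary-strand
collapsing (G->A and C->T are distinct signals).  The down-sampling test
draws `n_sets` same-size subsets of a non-fingerprint pool without
replacement (independently per set) and reports the one-sided empirical
p-value `(1 + #{count <= observed}) / (n_sets + 1)`; on small pools the
per-set counts follow the hypergeometric law, which the tests verify
against `scipy.stats.hypergeom`.

## Synthetic cohorts

The generator emulates the study design directly at the presence level: an
independent Bernoulli draw per site and sample.  It deliberately skips
linkage, diploid dosage and Hardy-Weinberg structure — the scoring model
consumes only presence, so planting the contrast there is sufficient to
validate the scorer, and nothing downstream depends on haplotypes.
Passing tests therefore demonstrate correctness of the scoring and
selection machinery, not robustness to LD or call-rate artefacts of real
resequencing data.

Defaults mirror the design the scorer targets: 20 target samples, a
410-sample background split into six regions (68-69 each, labelled N, NW,
S, USA, YR, YZ), planted sites at presence probability 0.95 inside their
population and 0.002 outside, and unplanted sites with a per-site presence
probability uniform on (0.01, 0.99) shared by all samples (no structure).
With that contrast a planted pedigree site scores about 0.95 x
log10(411/2) ~ 2.2, far above the ~0.78 threshold, while unstructured
sites peak near p * log10(411/(410 p + 1)) <~ 0.16 — which is why clean
recovery tests demand recall 1.0.  Genotypes are emitted as 0/0 vs 0/1
with QUAL drawn on [30, 100]; an extra 5% of low-QUAL (< 30) decoy records
exercise the ingestion filter end to end.  All outputs (VCF 4.2, manifest
TSV, GFF3, truth TSV) are byte-reproducible from the seed.

## Numerical and degenerate-input choices

* Row order is (chrom, pos) lexicographic everywhere; ranked reports sort
  by score descending with (chrom, pos) as tie-break.
* Boundary rules are inclusive throughout (score >= threshold,
  max_score >= cutoff, ties at a quantile boundary all included).
* Missing genotypes count as absent and are tallied per site; this is
  conservative for both tf and df.  Multi-allelic records are dropped, not
  split, and counted.
* Empty post-filter inputs warn explicitly instead of failing or passing
  silently; empty target/background sets are configuration errors.
* Monomorphic rows are retained (they score 0) and countable, keeping
  ingestion counts auditable.

## Problem sizes

Tests and the acceptance script run at desk scale: cohorts of 400-10,000
sites and up to 430 samples, 1000-draw thresholds replicated over 20-100
seeds, 10^5-set down-sampling on a 10-site pool, and 2 x 10^5-draw
convergence checks against the enumerated null.  These sizes give the
comparisons sub-percent Monte-Carlo error while the full suite completes
in well under a minute.

## Known limitations

* The exact TF-IDF variant used by any particular external implementation
  is not recoverable from a single printed threshold; the default here is
  one defensible choice, and `ScoringConfig` exposes the alternatives.
* The annotator is a transparent rule set, not a re-implementation of any
  specific annotation tool; category counts on real data will differ
  slightly wherever splicing-window or isoform conventions differ.
* Per-region top-fraction selection treats region columns independently;
  a pooled-matrix reading of "top 0.1%" would give different counts.  The
  union is reported so both views are auditable.
* Presence simulation without LD means planted-site recovery results say
  nothing about correlated-marker redundancy in real panels.
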