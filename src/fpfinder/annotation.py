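"""Genic-context classification of sites and related summaries.

Each site is placed in exactly one category relative to a set of gene
models: splicing (within 2 bp of an exon-intron junction, on the intron
side), UTR5, UTR3, exonic, intronic, upstream 1 kb, downstream 1 kb
(flanks are strand-aware), or intergenic.  When a site touches several
features or genes the single reported category follows the precedence

    splicing > UTR5 > UTR3 > exonic > intronic > upstream1kb > downstream1kb

with every overlap still recorded.  A site is *gene-related* iff its
category is not intergenic.

Also here: the 12-type SNP substitution spectrum (ordered ref->alt pairs;
complementary types such as G->A and C->T are kept distinct), and a
down-sampling test asking whether fingerprint sites are depleted of
gene-related contexts relative to random same-size draws from the
non-fingerprint pool.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigError, GeneModelError
from .matrix import SITE_COLUMNS

logger = logging.getLogger(__name__)

CATEGORIES = ["splicing", "UTR5", "UTR3", "exonic", "intronic",
              "upstream1kb", "downstream1kb", "intergenic"]
_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}

SNP_TYPES = [f"{r}->{a}" for r, a in itertools.permutations("ACGT", 2)]

FLANK_BP = 1000
SPLICE_WINDOW_BP = 2


@dataclass
class GeneModel:
    """One gene: span, strand and exon/UTR structure (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s, e) in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise GeneModelError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
        for name, spans in (("UTR5", self.utr5), ("UTR3", self.utr3)):
            for (s, e) in spans:
                if not any(xs <= s and e <= xe for xs, xe in self.exons):
                    raise GeneModelError(f"{self.gene_id}: {name} span ({s},{e}) not inside an exon")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
                if s2 - e1 > 1]

    def classify(self, pos: int) -> str | None:
        """Category of a position relative to this gene, or None if unrelated."""
        if self.start <= pos <= self.end:
            for (s, e) in self.introns:
                if s <= pos <= e:
                    near_left = pos - s < SPLICE_WINDOW_BP
                    near_right = e - pos < SPLICE_WINDOW_BP
                    return "splicing" if (near_left or near_right) else "intronic"
            for (s, e) in self.utr5:
                if s <= pos <= e:
                    return "UTR5"
            for (s, e) in self.utr3:
                if s <= pos <= e:
                    return "UTR3"
            for (s, e) in self.exons:
                if s <= pos <= e:
                    return "exonic"
            return "intronic"  # inside span, outside exons/introns list (edge gaps)
        upstream = (self.start - FLANK_BP <= pos < self.start) if self.strand == "+" \
            else (self.end < pos <= self.end + FLANK_BP)
        if upstream:
            return "upstream1kb"
        downstream = (self.end < pos <= self.end + FLANK_BP) if self.strand == "+" \
            else (self.start - FLANK_BP <= pos < self.start)
        if downstream:
            return "downstream1kb"
        return None


class GeneIndex:
    """Chromosome-indexed interval lookup over gene models (span + 1 kb flanks)."""

    def __init__(self, models: list[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        for gm in self.models:
            tree = self._trees.setdefault(gm.chrom, IntervalTree())
            # interval end is exclusive in intervaltree
            tree[gm.start - FLANK_BP: gm.end + FLANK_BP + 1] = gm

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]), key=lambda g: g.gene_id)


@dataclass
class SiteContext:
    """Single-category genic context of one site, with all gene overlaps kept."""

    chrom: str
    pos: int
    category: str
    gene_id: str
    all_overlaps: list[tuple[str, str]]

    @property
    def gene_related(self) -> bool:
        return self.category != "intergenic"


def classify_site(chrom: str, pos: int, index: GeneIndex) -> SiteContext:
    """Classify one position against all overlapping genes by precedence."""
    overlaps = []
    for gm in index.overlapping(chrom, pos):
        cat = gm.classify(pos)
        if cat is not None:
            overlaps.append((gm.gene_id, cat))
    if not overlaps:
        return SiteContext(chrom, pos, "intergenic", "", [])
    gene_id, category = min(overlaps, key=lambda gc: (_PRECEDENCE[gc[1]], gc[0]))
    return SiteContext(chrom, pos, category, gene_id, overlaps)


def classify_sites(sites: pd.DataFrame, index: GeneIndex) -> pd.DataFrame:
    """Classify a table of sites; returns site columns + category/gene_id/gene_related."""
    records = []
    for row in sites.itertuples(index=False):
        ctx = classify_site(row.chrom, row.pos, index)
        records.append((ctx.category, ctx.gene_id, ctx.gene_related))
    out = sites[[c for c in SITE_COLUMNS if c in sites.columns]].copy()
    cats, gids, rels = zip(*records) if records else ((), (), ())
    out["category"] = list(cats)
    out["gene_id"] = list(gids)
    out["gene_related"] = list(rels)
    return out


def load_gene_models(gff_path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/UTR features).

    Only the first mRNA per gene (by start, then ID) is used; multi-isoform
    genes trigger a log warning.  Structural violations (UTR outside exons,
    overlapping exons) raise at load time.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = sorted(db.children(gene, featuretype="mRNA"),
                       key=lambda f: (f.start, f.id))
        if len(mrnas) > 1:
            logger.warning("gene %s has %d isoforms; using %s",
                           gene.id, len(mrnas), mrnas[0].id)
        parent = mrnas[0] if mrnas else gene
        exons = [(f.start, f.end) for f in db.children(parent, featuretype="exon")]
        utr5 = [(f.start, f.end) for f in db.children(parent, featuretype="five_prime_UTR")]
        utr3 = [(f.start, f.end) for f in db.children(parent, featuretype="three_prime_UTR")]
        if not exons:
            exons = [(gene.start, gene.end)]
        models.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons, utr5=utr5, utr3=utr3,
        ))
    return models


def snp_spectrum(sites: pd.DataFrame) -> pd.Series:
    """Counts over the 12 ordered substitution types (ref->alt).

    No complementary-strand collapsing: G->A and C->T stay distinct.
    """
    ref = sites["ref"].to_numpy(dtype=str)
    alt = sites["alt"].to_numpy(dtype=str)
    ok = np.array([r in "ACGT" and a in "ACGT" and len(r) == 1 and len(a) == 1 and r != a
                   for r, a in zip(ref, alt)])
    if not ok.all():
        bad = sites[~ok].head(3)
        raise ConfigError(f"non-SNP rows in spectrum input, e.g.\n{bad}")
    labels = pd.Series([f"{r}->{a}" for r, a in zip(ref, alt)])
    counts = labels.value_counts()
    return counts.reindex(SNP_TYPES, fill_value=0).astype(int)


@dataclass
class DownsampleResult:
    """Random same-size draws from the non-fingerprint pool vs the observed count."""

    observed: int
    set_counts: np.ndarray
    n_sets: int
    set_size: int
    pvalue: float  # one-sided: fraction of sets with count <= observed


def gene_related_downsample_test(fingerprint_gene_related, pool_gene_related,
                                 set_size: int | None = None, n_sets: int = 1000,
                                 seed: int = 0) -> DownsampleResult:
    """Is the fingerprint set depleted of gene-related sites?

    Draws ``n_sets`` subsets of ``set_size`` sites (without replacement,
    independently per set) from the non-fingerprint pool, counts gene-related
    sites per set, and reports the one-sided empirical p-value
    ``(1 + #{sets with count <= observed}) / (n_sets + 1)``.

    Both inputs are boolean arrays (gene-related flags per site, as produced
    by :func:`classify_sites`).
    """
    fp = np.asarray(fingerprint_gene_related, dtype=bool)
    pool = np.asarray(pool_gene_related, dtype=bool)
    if set_size is None:
        set_size = fp.size
    if set_size < 1:
        raise ConfigError("set_size must be >= 1")
    if pool.size < set_size:
        raise ConfigError(f"pool of {pool.size} sites is smaller than set_size={set_size}")
    rng = np.random.default_rng(seed)
    observed = int(fp.sum())

    # vectorised sampling without replacement: argpartition of random keys
    if n_sets * pool.size <= 50_000_000:
        keys = rng.random((n_sets, pool.size))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        set_counts = pool[idx].sum(axis=1)
    else:
        set_counts = np.fromiter(
            (pool[rng.choice(pool.size, size=set_size, replace=False)].sum()
             for _ in range(n_sets)),
            dtype=int, count=n_sets,
        )
    pvalue = (1 + int((set_counts <= observed).sum())) / (n_sets + 1)
    return DownsampleResult(observed=observed, set_counts=np.asarray(set_counts),
                            n_sets=n_sets, set_size=set_size, pvalue=pvalue)
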