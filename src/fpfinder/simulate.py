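"""Synthetic cohorts with planted fingerprint and region-specific sites.

The generator emulates the study design the scoring model targets: a small
target set (a pedigree) nested beside a larger background cohort split into
geographic regions.  Presence is simulated directly — an independent
Bernoulli draw per site and sample — because the scoring model consumes only
presence; linkage and diploid dosage are deliberately not modelled.

Three site classes are emitted:

* *background* sites: per-site presence probability drawn uniformly on
  (0.01, 0.99), shared by every sample — no population structure;
* *pedigree-planted* sites: present with high probability (default 0.95) in
  target samples and very low probability (default 0.002) in the background;
* *region-planted* sites: the same contrast, but between one region's
  samples and everyone else.

Outputs are a standard VCF 4.2 (genotypes 0/0 vs 0/1, QUAL >= 30, plus an
optional fraction of low-QUAL decoy records to exercise the quality filter),
a manifest TSV, a GFF3 of toy gene models, and a truth table labelling every
planted site.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import SITE_COLUMNS, PresenceMatrix, SampleManifest
from .annotation import GeneModel

_NUC = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic cohort.

    ``region_sizes`` defines the background cohort (union of regions); the
    ``n_target`` pedigree samples are disjoint from it.
    """

    n_target: int = 20
    region_sizes: dict[str, int] = field(
        default_factory=lambda: {"N": 68, "NW": 68, "S": 68, "USA": 68, "YR": 69, "YZ": 69}
    )
    n_sites: int = 10_000
    n_planted_pedigree: int = 20
    n_planted_per_region: int = 0
    p_target_present: float = 0.95
    p_background_present: float = 0.002
    background_freq_range: tuple[float, float] = (0.01, 0.99)
    genome: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    n_genes: int = 20
    low_qual_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        n_planted = self.n_planted_pedigree + self.n_planted_per_region * len(self.region_sizes)
        if n_planted > self.n_sites:
            raise ConfigError("more planted sites than total sites")
        for p in (self.p_target_present, self.p_background_present):
            if not 0 <= p <= 1:
                raise ConfigError("presence probabilities must be in [0, 1]")
        if self.n_target < 1 or any(v < 1 for v in self.region_sizes.values()):
            raise ConfigError("all population sizes must be >= 1")

    @property
    def n_background(self) -> int:
        return sum(self.region_sizes.values())


@dataclass
class Cohort:
    """In-memory synthetic cohort plus ground truth."""

    spec: CohortSpec
    sites: pd.DataFrame          # chrom, pos, ref, alt, qual (planted + background)
    presence: np.ndarray         # bool, n_sites x n_samples
    manifest: SampleManifest
    truth: pd.DataFrame          # chrom, pos, planted_class, planted_region
    genes: list[GeneModel]
    decoys: pd.DataFrame         # low-QUAL records (chrom, pos, ref, alt, qual)
    decoy_presence: np.ndarray

    @property
    def matrix(self) -> PresenceMatrix:
        return PresenceMatrix(sites=self.sites[SITE_COLUMNS].copy(),
                              samples=list(self.manifest.samples),
                              values=self.presence)

    def write(self, outdir) -> dict[str, Path]:
        """Emit cohort.vcf, manifest.tsv, genes.gff3 and truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "manifest": outdir / "manifest.tsv",
            "gff3": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
        }
        write_vcf(paths["vcf"], self.all_records(), self.all_presence(),
                  self.manifest.samples, self.spec.genome)
        self.manifest.write(paths["manifest"])
        write_gff3(paths["gff3"], self.genes)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths

    def all_records(self) -> pd.DataFrame:
        both = pd.concat([self.sites, self.decoys], ignore_index=True)
        return both.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def all_presence(self) -> np.ndarray:
        both = pd.concat([self.sites, self.decoys], ignore_index=True)
        order = both.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        stacked = np.vstack([self.presence, self.decoy_presence]) \
            if len(self.decoys) else self.presence
        return stacked[order]


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort per ``spec``; byte-identical for identical seeds."""
    rng = np.random.default_rng(spec.seed)
    regions = sorted(spec.region_sizes)
    samples = [f"T{i + 1:03d}" for i in range(spec.n_target)]
    roles = {s: "target" for s in samples}
    region_of: dict[str, str] = {}
    for lab in regions:
        for i in range(spec.region_sizes[lab]):
            name = f"{lab}{i + 1:03d}"
            samples.append(name)
            roles[name] = "background"
            region_of[name] = lab
    manifest = SampleManifest(samples=samples, roles=roles, regions=region_of)
    n_samples = len(samples)
    is_target = np.array([roles[s] == "target" for s in samples])

    n_decoys = int(round(spec.low_qual_fraction * spec.n_sites))
    n_total = spec.n_sites + n_decoys
    chroms, positions = _draw_positions(rng, spec.genome, n_total)
    ref_idx = rng.integers(0, 4, n_total)
    alt_idx = (ref_idx + rng.integers(1, 4, n_total)) % 4

    sites = pd.DataFrame({
        "chrom": chroms[:spec.n_sites],
        "pos": positions[:spec.n_sites],
        "ref": _NUC[ref_idx[:spec.n_sites]],
        "alt": _NUC[alt_idx[:spec.n_sites]],
        "qual": np.round(rng.uniform(30, 100, spec.n_sites), 1),
    })
    decoys = pd.DataFrame({
        "chrom": chroms[spec.n_sites:],
        "pos": positions[spec.n_sites:],
        "ref": _NUC[ref_idx[spec.n_sites:]],
        "alt": _NUC[alt_idx[spec.n_sites:]],
        "qual": np.round(rng.uniform(0, 29.9, n_decoys), 1),
    })

    # per-sample presence probabilities, one row per site
    probs = np.empty((spec.n_sites, n_samples))
    bg_freq = rng.uniform(*spec.background_freq_range, spec.n_sites)
    probs[:] = bg_freq[:, None]

    classes = np.full(spec.n_sites, "background", dtype=object)
    planted_region = np.full(spec.n_sites, "", dtype=object)
    cursor = 0
    for i in range(spec.n_planted_pedigree):
        probs[cursor, is_target] = spec.p_target_present
        probs[cursor, ~is_target] = spec.p_background_present
        classes[cursor] = "pedigree"
        cursor += 1
    for lab in regions:
        in_region = np.array([region_of.get(s, "") == lab for s in samples])
        for i in range(spec.n_planted_per_region):
            probs[cursor, in_region] = spec.p_target_present
            probs[cursor, ~in_region] = spec.p_background_present
            classes[cursor] = "region"
            planted_region[cursor] = lab
            cursor += 1

    presence = rng.random((spec.n_sites, n_samples)) < probs
    decoy_presence = rng.random((n_decoys, n_samples)) < 0.5

    truth = pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"],
        "planted_class": classes, "planted_region": planted_region,
    })
    truth = truth[truth["planted_class"] != "background"].reset_index(drop=True)

    # canonical (chrom, pos) order for the non-decoy block
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    presence = presence[order]

    genes = _draw_genes(rng, spec.genome, spec.n_genes)
    return Cohort(spec=spec, sites=sites, presence=presence, manifest=manifest,
                  truth=truth.sort_values(["chrom", "pos"]).reset_index(drop=True),
                  genes=genes, decoys=decoys, decoy_presence=decoy_presence)


def _draw_positions(rng, genome, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unique (chrom, pos) pairs spread over the genome proportionally to length."""
    total = sum(length for _, length in genome)
    if n > total:
        raise ConfigError(f"requested {n} sites but genome has only {total} positions")
    flat = rng.choice(total, size=n, replace=False) + 1
    flat.sort()
    chroms = np.empty(n, dtype=object)
    positions = np.empty(n, dtype=int)
    offset = 0
    for name, length in genome:
        mask = (flat > offset) & (flat <= offset + length)
        chroms[mask] = name
        positions[mask] = flat[mask] - offset
        offset += length
    perm = rng.permutation(n)  # decouple site class from genomic position
    return chroms[perm], positions[perm]


def _draw_genes(rng, genome, n_genes: int) -> list[GeneModel]:
    """Toy two-exon genes with UTRs, non-overlapping, random strand."""
    genes: list[GeneModel] = []
    per_chrom = np.array_split(np.arange(n_genes), len(genome))
    for (chrom, length), idxs in zip(genome, per_chrom):
        k = len(idxs)
        if k == 0:
            continue
        slot = length // (k + 1)
        for j, gi in enumerate(idxs):
            start = (j + 1) * slot - slot // 4
            span = int(rng.integers(2000, min(6000, max(2001, slot // 2))))
            end = start + span
            exon1_end = start + span // 3
            exon2_start = end - span // 3
            utr_len = max(50, span // 20)
            strand = "+" if rng.random() < 0.5 else "-"
            utr5 = [(start, start + utr_len)] if strand == "+" else [(end - utr_len, end)]
            utr3 = [(end - utr_len, end)] if strand == "+" else [(start, start + utr_len)]
            genes.append(GeneModel(
                gene_id=f"G{gi + 1:04d}", chrom=chrom, strand=strand,
                start=start, end=end,
                exons=[(start, exon1_end), (exon2_start, end)],
                utr5=utr5, utr3=utr3,
            ))
    return genes


def write_vcf(path, records: pd.DataFrame, presence: np.ndarray,
              samples: list[str], genome) -> None:
    """Write records as minimal VCF 4.2 with GT-only FORMAT (0/0 vs 0/1)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fpfinder-simulate\n")
        for name, length in genome:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, row in enumerate(records.itertuples(index=False)):
            gts = "\t".join("0/1" if p else "0/0" for p in presence[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:g}\t.\t.\tGT\t{gts}\n")


def write_gff3(path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in genes:
            base = f"{gm.chrom}\tfpfinder\t"
            tail = f"\t.\t{gm.strand}\t."
            fh.write(f"{base}gene\t{gm.start}\t{gm.end}{tail}\tID={gm.gene_id}\n")
            mid = f"{gm.gene_id}.1"
            fh.write(f"{base}mRNA\t{gm.start}\t{gm.end}{tail}\tID={mid};Parent={gm.gene_id}\n")
            for k, (s, e) in enumerate(gm.exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}\tID={mid}.exon{k};Parent={mid}\n")
            for k, (s, e) in enumerate(gm.utr5, 1):
                fh.write(f"{base}five_prime_UTR\t{s}\t{e}{tail}\tID={mid}.utr5.{k};Parent={mid}\n")
            for k, (s, e) in enumerate(gm.utr3, 1):
                fh.write(f"{base}three_prime_UTR\t{s}\t{e}{tail}\tID={mid}.utr3.{k};Parent={mid}\n")


@dataclass
class RecoveryReport:
    """Precision/recall of planted-site recovery at a score threshold."""

    n_planted: int
    n_selected: int
    n_true_positive: int
    precision: float | None   # None when nothing selected
    recall: float | None      # None when nothing planted
    planted_ranks: pd.DataFrame  # chrom, pos, score, rank (1 = best)


def recovery_report(truth: pd.DataFrame, results: pd.DataFrame,
                    threshold: float, planted_class: str = "pedigree") -> RecoveryReport:
    """Score the recovery of planted sites among threshold-passing results.

    ``results`` is a score table (from :func:`fpfinder.scoring.score_sites`)
    on the same cohort; ``truth`` the generator's truth table.
    """
    planted = truth[truth["planted_class"] == planted_class][["chrom", "pos"]]
    res = results.copy()
    res_keys = set(zip(res["chrom"], res["pos"]))
    missing = [k for k in zip(planted["chrom"], planted["pos"]) if k not in res_keys]
    if missing:
        raise ConfigError(f"planted sites absent from results: {missing[:5]}")

    res = res.sort_values(["score", "chrom", "pos"],
                          ascending=[False, True, True]).reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    planted_keys = set(zip(planted["chrom"], planted["pos"]))
    res["is_planted"] = [(c, p) in planted_keys for c, p in zip(res["chrom"], res["pos"])]
    selected = res[res["score"] >= threshold]
    tp = int(selected["is_planted"].sum())
    n_sel, n_pl = len(selected), len(planted)
    return RecoveryReport(
        n_planted=n_pl,
        n_selected=n_sel,
        n_true_positive=tp,
        precision=(tp / n_sel) if n_sel else None,
        recall=(tp / n_pl) if n_pl else None,
        planted_ranks=res[res["is_planted"]][["chrom", "pos", "score", "rank"]]
        .reset_index(drop=True),
    )
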