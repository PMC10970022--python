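"""VCF ingestion and the site x sample presence/absence matrix.

The fingerprint workflow starts by transforming a multi-sample VCF into a
boolean "present | absent" table: one row per biallelic SNP, one column per
sample, a cell being true iff that sample's genotype carries at least one
ALT allele.  Variants with QUAL below a cutoff (default 30) are trimmed at
ingestion, as are multi-allelic and non-SNP records unless asked otherwise.

Missing genotypes (``./.``) are treated as *absent* under the default
policy; per-site missingness is recorded so callers can audit or filter.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ManifestError, MatrixFormatError, VcfFormatError

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]
_NUCLEOTIDES = frozenset("ACGT")

_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))?")


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP: chromosome, 1-based position, REF/ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _NUCLEOTIDES or self.alt not in _NUCLEOTIDES:
            raise ValueError(f"ref/alt must be single nucleotides, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleManifest:
    """Maps each sample to a target/background role and an optional region.

    Target and background sets may be disjoint (pedigree mode: a breeding
    family scored against an unrelated cohort) or the targets may be nested
    inside the cohort (region mode: each geographic sub-population scored
    against the full variome).
    """

    samples: list[str]
    roles: dict[str, str]
    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ManifestError(f"duplicate sample IDs in manifest: {dupes}")
        bad_roles = {r for r in self.roles.values() if r not in ("target", "background")}
        if bad_roles:
            raise ManifestError(f"roles must be 'target' or 'background', got {sorted(bad_roles)}")
        missing = [s for s in self.samples if s not in self.roles]
        if missing:
            raise ManifestError(f"samples without a role: {missing}")

    @property
    def target_samples(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == "target"]

    @property
    def background_samples(self) -> list[str]:
        return [s for s in self.samples if self.roles[s] == "background"]

    @property
    def region_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            r = self.regions.get(s, "")
            if r:
                seen.setdefault(r)
        return sorted(seen)

    def region_members(self, label: str) -> list[str]:
        return [s for s in self.samples if self.regions.get(s, "") == label]

    @classmethod
    def read(cls, path) -> "SampleManifest":
        """Read a manifest TSV with header columns sample, role[, region]."""
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        required = {"sample", "role"}
        if not required.issubset(df.columns):
            raise ManifestError(
                f"manifest {path} must have columns 'sample' and 'role'; found {list(df.columns)}"
            )
        samples = df["sample"].tolist()
        roles = dict(zip(df["sample"], df["role"]))
        regions = (
            {s: r for s, r in zip(df["sample"], df["region"]) if r}
            if "region" in df.columns
            else {}
        )
        return cls(samples=samples, roles=roles, regions=regions)

    def write(self, path) -> None:
        df = pd.DataFrame(
            {
                "sample": self.samples,
                "role": [self.roles[s] for s in self.samples],
                "region": [self.regions.get(s, "") for s in self.samples],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def genotype_to_presence(gt: str, *, missing_as_absent: bool = True) -> tuple[bool, bool]:
    """Decode a diploid GT string into (present, is_missing).

    A site is *present* in a sample iff the call carries at least one ALT
    allele (het or hom-alt), regardless of phasing.  ``./.`` is missing and
    counts as absent under the default policy.
    """
    m = _GT_RE.match(gt)
    if m is None or not gt:
        raise VcfFormatError(f"malformed GT string: {gt!r}")
    alleles = [a for a in re.split(r"[/|]", gt.split(":")[0])]
    present = False
    missing = False
    for a in alleles:
        if a == ".":
            missing = True
        elif a.isdigit():
            if int(a) > 0:
                present = True
        else:
            raise VcfFormatError(f"malformed GT string: {gt!r}")
    if missing and not present and not missing_as_absent:
        raise VcfFormatError(f"missing genotype {gt!r} with missing_as_absent disabled")
    return present, missing and not present


@dataclass
class VcfRecords:
    """Filtered VCF content: site metadata plus per-sample presence calls."""

    sites: pd.DataFrame  # columns chrom, pos, ref, alt, qual
    presence: np.ndarray  # bool, n_sites x n_samples, sample order = header order
    missing: np.ndarray  # bool, same shape, true where GT was ./.
    samples: list[str]
    dropped: dict[str, int]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def read_vcf(path, min_qual: float = 30.0, biallelic_snps_only: bool = True) -> VcfRecords:
    """Read a multi-sample VCF, applying the QUAL >= ``min_qual`` trim.

    Records with missing QUAL are dropped (counted under ``no_qual``); with
    ``biallelic_snps_only`` multi-allelic and non-SNP records are dropped and
    counted too.  Sample order follows the VCF header.
    """
    try:
        from cyvcf2 import VCF
        vcf = VCF(str(path))
    except Exception as exc:  # unreadable file or not VCF
        raise VcfFormatError(f"cannot read VCF at {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"VCF {path} has no sample columns (GT data required)")

    rows: list[tuple] = []
    presence_rows: list[np.ndarray] = []
    missing_rows: list[np.ndarray] = []
    dropped = {"low_qual": 0, "no_qual": 0, "multiallelic": 0, "non_snp": 0}

    for var in vcf:
        if var.QUAL is None:
            dropped["no_qual"] += 1
            continue
        if var.QUAL < min_qual:
            dropped["low_qual"] += 1
            continue
        if biallelic_snps_only:
            if len(var.ALT) != 1:
                dropped["multiallelic"] += 1
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1 or var.REF not in _NUCLEOTIDES or var.ALT[0] not in _NUCLEOTIDES:
                dropped["non_snp"] += 1
                continue
        alt = var.ALT[0] if var.ALT else "."
        # gt_types: 0=hom-ref, 1=het, 2=missing, 3=hom-alt
        gt = np.asarray(var.gt_types)
        presence_rows.append((gt == 1) | (gt == 3))
        missing_rows.append(gt == 2)
        rows.append((var.CHROM, var.POS, var.REF, alt, var.QUAL))
    vcf.close()

    if not rows:
        warnings.warn(
            f"no records in {path} survived filtering (min_qual={min_qual}); "
            f"dropped: {dropped}",
            stacklevel=2,
        )
        sites = pd.DataFrame(columns=SITE_COLUMNS + ["qual"])
        return VcfRecords(
            sites=sites,
            presence=np.zeros((0, len(samples)), dtype=bool),
            missing=np.zeros((0, len(samples)), dtype=bool),
            samples=samples,
            dropped=dropped,
        )

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS + ["qual"])
    presence = np.vstack(presence_rows)
    missing = np.vstack(missing_rows)
    # (chrom, pos) sort is the canonical row order everywhere downstream
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    logger.info("read %d sites from %s (dropped %s)", len(sites), path, dropped)
    return VcfRecords(
        sites=sites,
        presence=presence[order],
        missing=missing[order],
        samples=samples,
        dropped=dropped,
    )


@dataclass
class PresenceMatrix:
    """Boolean site x sample table; rows (chrom, pos)-sorted, columns in manifest order."""

    sites: pd.DataFrame  # columns chrom, pos, ref, alt
    samples: list[str]
    values: np.ndarray  # bool, n_sites x n_samples
    missing_counts: np.ndarray | None = None  # per-site count of ./. calls

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise MatrixFormatError(
                f"presence table shape {self.values.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        keys = list(zip(self.sites["chrom"], self.sites["pos"], self.sites["ref"], self.sites["alt"]))
        if len(set(keys)) != len(keys):
            raise MatrixFormatError("duplicate (chrom, pos, ref, alt) rows in matrix")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def presence_counts(self, sample_subset: list[str] | None = None) -> np.ndarray:
        """Number of samples (optionally a subset) carrying each site."""
        if sample_subset is None:
            return self.values.sum(axis=1)
        idx = self.sample_indices(sample_subset)
        return self.values[:, idx].sum(axis=1)

    def sample_indices(self, names: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in names if s not in pos]
        if missing:
            raise ManifestError(f"samples not in matrix: {missing}")
        return np.array([pos[s] for s in names], dtype=int)

    def monomorphic_report(self) -> dict[str, int]:
        """Counts of all-absent and all-present rows (kept, but auditable)."""
        counts = self.values.sum(axis=1)
        return {
            "all_absent": int((counts == 0).sum()),
            "all_present": int((counts == len(self.samples)).sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        df = self.sites.copy()
        for j, s in enumerate(self.samples):
            df[s] = self.values[:, j].astype(int)
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "PresenceMatrix":
        """Read a presence table written by :meth:`write` (round-trip identity)."""
        try:
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        except Exception as exc:
            raise MatrixFormatError(f"cannot parse presence table {path}: {exc}") from exc
        if list(df.columns[:4]) != SITE_COLUMNS:
            raise MatrixFormatError(
                f"presence table {path} must start with columns {SITE_COLUMNS}, "
                f"found {list(df.columns[:4])}"
            )
        samples = list(df.columns[4:])
        cells = df[samples].to_numpy() if samples else np.zeros((len(df), 0))
        bad = ~np.isin(cells, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"presence table {path}: cell at data line {i + 1}, column "
                f"{samples[j]!r} is not 0/1"
            )
        sites = df[SITE_COLUMNS].copy()
        sites["pos"] = sites["pos"].astype(int)
        return cls(sites=sites, samples=samples, values=cells.astype(bool))


def build_matrix(records: VcfRecords, manifest: SampleManifest) -> PresenceMatrix:
    """Restrict VCF presence calls to manifest samples, in manifest order.

    Every manifest sample must appear in the VCF header; extra VCF samples
    are dropped with a log message.  Monomorphic rows are retained (they
    score zero downstream) and countable via ``monomorphic_report``.
    """
    vcf_pos = {s: i for i, s in enumerate(records.samples)}
    missing = [s for s in manifest.samples if s not in vcf_pos]
    if missing:
        raise ManifestError(f"manifest samples missing from VCF: {missing}")
    extra = [s for s in records.samples if s not in set(manifest.samples)]
    if extra:
        logger.warning("dropping %d VCF samples not in manifest: %s", len(extra), extra[:10])
    idx = np.array([vcf_pos[s] for s in manifest.samples], dtype=int)
    cols = idx if len(idx) else slice(0, 0)
    return PresenceMatrix(
        sites=records.sites[SITE_COLUMNS].copy(),
        samples=list(manifest.samples),
        values=records.presence[:, cols],
        missing_counts=records.missing[:, cols].sum(axis=1),
    )


# Spec-facing aliases matching the operation names of the workflow.
write_matrix = PresenceMatrix.write
read_matrix = PresenceMatrix.read
read_manifest = SampleManifest.read
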