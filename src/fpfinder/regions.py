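"""Region-wise fingerprint scanning of a cohort.

Every site is scored once per geographic sub-population: term frequency over
that region's samples, inverse document frequency over the *whole* cohort
(full-cohort background).  The region where a site scores highest is its
*enriched region*; sites whose best score is low everywhere carry no
geographic signal and can be trimmed; the top fraction of each region's
score column defines that region's region-specific sites.

A functional-site list (e.g. GWAS hits with signed phenotypic effects) can
be partitioned by enriched region and the groups' effects compared with a
two-sample test, to ask whether trait-relevant alleles are geographically
biased.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .matrix import SITE_COLUMNS, PresenceMatrix, SampleManifest
from .null import threshold_from_null
from .scoring import DEFAULT_CONFIG, ScoringConfig, inverse_document_frequency, term_frequency

logger = logging.getLogger(__name__)


@dataclass
class RegionScoreTable:
    """Per-site, per-region fingerprint scores with argmax assignment."""

    sites: pd.DataFrame            # chrom, pos, ref, alt
    scores: pd.DataFrame           # one column per region label, same row order
    enriched_region: pd.Series = field(init=False)
    max_score: pd.Series = field(init=False)
    tied: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.scores):
            raise ConfigError("sites and scores row counts differ")
        self._assign()

    def _assign(self) -> None:
        cols = sorted(self.scores.columns)  # lexicographic tie-break
        vals = self.scores[cols].to_numpy(dtype=float)
        if vals.size:
            arg = vals.argmax(axis=1)
            mx = vals[np.arange(len(vals)), arg]
            n_at_max = (vals == mx[:, None]).sum(axis=1)
        else:
            arg = np.zeros(0, dtype=int)
            mx = np.zeros(0)
            n_at_max = np.zeros(0, dtype=int)
        self.enriched_region = pd.Series([cols[i] for i in arg], index=self.sites.index, dtype=object)
        self.max_score = pd.Series(mx, index=self.sites.index)
        self.tied = pd.Series(n_at_max > 1, index=self.sites.index)

    @property
    def regions(self) -> list[str]:
        return list(self.scores.columns)

    def to_frame(self) -> pd.DataFrame:
        df = pd.concat([self.sites.reset_index(drop=True),
                        self.scores.reset_index(drop=True)], axis=1)
        df["enriched_region"] = self.enriched_region.to_numpy()
        df["max_score"] = self.max_score.to_numpy()
        df["tied"] = self.tied.to_numpy()
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def score_by_region(matrix: PresenceMatrix, manifest: SampleManifest,
                    config: ScoringConfig = DEFAULT_CONFIG) -> RegionScoreTable:
    """Score each site per region against the full cohort.

    ``score[s, r] = tf(region r) * idf(whole cohort)``; a site fixed in the
    whole cohort scores zero in every region under the default smoothing.
    """
    labels = manifest.region_labels
    if len(labels) < 2:
        raise ConfigError(f"region scan needs >= 2 labelled regions, found {labels}")
    for lab in labels:
        if not manifest.region_members(lab):
            raise ConfigError(f"region {lab!r} has no samples")

    n_cohort = len(manifest.samples)
    df_cohort = matrix.presence_counts(list(manifest.samples))
    idf = np.asarray(inverse_document_frequency(df_cohort, n_cohort, config), dtype=float)

    cols = {}
    for lab in labels:
        members = manifest.region_members(lab)
        tf = np.asarray(term_frequency(matrix.presence_counts(members), len(members)))
        cols[lab] = np.where(tf == 0.0, 0.0, tf * idf)
    scores = pd.DataFrame(cols, index=matrix.sites.index)
    return RegionScoreTable(sites=matrix.sites[SITE_COLUMNS].copy(), scores=scores)


def assign_enriched_region(table: RegionScoreTable) -> pd.DataFrame:
    """Per-site enriched region (argmax over regions) with exact-tie flag.

    Ties are broken lexicographically by region label and flagged.
    """
    return pd.DataFrame(
        {
            "enriched_region": table.enriched_region,
            "max_score": table.max_score,
            "tied": table.tied,
        }
    )


def trim_low_specificity(table: RegionScoreTable, min_max_score: float = 0.1) -> RegionScoreTable:
    """Drop sites whose best score across regions is below ``min_max_score``."""
    if min_max_score < 0:
        raise ConfigError("min_max_score must be >= 0")
    keep = (table.max_score >= min_max_score).to_numpy()
    if not keep.any():
        warnings.warn(
            f"min_max_score={min_max_score} removed every site", stacklevel=2
        )
    return RegionScoreTable(
        sites=table.sites[keep].reset_index(drop=True),
        scores=table.scores[keep].reset_index(drop=True),
    )


def select_region_specific(table: RegionScoreTable,
                           top_fraction: float = 0.001) -> dict[str, pd.DataFrame]:
    """Top-fraction sites of each region's score column (boundary ties included).

    The quantile is nearest-rank-from-above per region, applied to each
    region column independently; the returned mapping also carries the union
    under the key ``"union"``.
    """
    if not 0 < top_fraction < 1:
        raise ConfigError("top_fraction must be in (0, 1)")
    out: dict[str, pd.DataFrame] = {}
    union_mask = np.zeros(len(table.sites), dtype=bool)
    for lab in table.regions:
        col = table.scores[lab].to_numpy(dtype=float)
        cut = threshold_from_null(col, top_fraction)  # same nearest-rank rule
        mask = col >= cut
        union_mask |= mask
        sel = table.sites[mask].copy()
        sel["score"] = col[mask]
        out[lab] = sel.reset_index(drop=True)
    union = table.sites[union_mask].copy()
    union["max_score"] = table.max_score.to_numpy()[union_mask]
    out["union"] = union.reset_index(drop=True)
    logger.info(
        "region-specific selection at top %.4g%%: %s (union %d)",
        100 * top_fraction,
        {k: len(v) for k, v in out.items() if k != "union"},
        len(union),
    )
    return out


def read_functional_sites(path) -> pd.DataFrame:
    """Read a functional-site list TSV: chrom, pos, ref, alt, effect[, trait]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = SITE_COLUMNS + ["effect"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"functional-site list {path} lacks columns {missing}")
    df["pos"] = df["pos"].astype(int)
    return df


@dataclass
class GroupComparison:
    """Enriched-region partition of functional sites, with a two-group test."""

    summary: pd.DataFrame           # per region: n, mean/median effect and score
    unresolved: pd.DataFrame        # functional sites absent from the cohort table
    pair: tuple[str, str] | None
    statistic: float | None
    pvalue: float | None


def compare_enriched_groups(functional: pd.DataFrame, table: RegionScoreTable,
                            pair: tuple[str, str] | None = None,
                            positive_effects_only: bool = False) -> GroupComparison:
    """Partition functional sites by enriched region and compare two groups.

    ``pair`` names two regions whose effect distributions are compared with
    Welch's t-test.  ``positive_effects_only`` restricts the partition to
    sites with effect > 0 before grouping (an explicit filter, never
    inferred).
    """
    annot = table.to_frame()
    merged = functional.merge(annot, on=SITE_COLUMNS, how="left", indicator=True)
    unresolved = merged[merged["_merge"] == "left_only"][functional.columns].copy()
    resolved = merged[merged["_merge"] == "both"].copy()
    if len(unresolved):
        logger.warning("%d functional sites not found in cohort table", len(unresolved))
    if positive_effects_only:
        resolved = resolved[resolved["effect"] > 0]

    rows = []
    for lab, grp in resolved.groupby("enriched_region", sort=True):
        rows.append(
            {
                "region": lab,
                "n": len(grp),
                "mean_effect": grp["effect"].mean(),
                "median_effect": grp["effect"].median(),
                "mean_score": grp["max_score"].mean(),
                "median_score": grp["max_score"].median(),
            }
        )
    summary = pd.DataFrame(rows, columns=["region", "n", "mean_effect", "median_effect",
                                          "mean_score", "median_score"])

    statistic = pvalue = None
    if pair is not None:
        for lab in pair:
            if lab not in table.regions:
                raise ConfigError(f"region {lab!r} not in table regions {table.regions}")
        a = resolved.loc[resolved["enriched_region"] == pair[0], "effect"]
        b = resolved.loc[resolved["enriched_region"] == pair[1], "effect"]
        if len(a) >= 2 and len(b) >= 2:
            res = stats.ttest_ind(a, b, equal_var=False)
            statistic, pvalue = float(res.statistic), float(res.pvalue)
    return GroupComparison(summary=summary, unresolved=unresolved, pair=pair,
                           statistic=statistic, pvalue=pvalue)
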