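"""TF-IDF fingerprint scoring of genomic sites.

A site's fingerprint score for a target sub-population is the product of

* its *term frequency* — the fraction of target samples carrying the site,
  ``tf = df_target / n_target``, and
* its *inverse document frequency* — the log-scaled rarity of the site in a
  background cohort, by default ``idf = log10((n_background + 1) /
  (df_background + 1))`` (add-one smoothing on both counts).

High scores mark sites conserved within the target set yet rare in the
background — the "fingerprint" of a pedigree or a geographic sub-population.
The smoothing and log-base variants are selectable for sensitivity analysis
but the default is what the permutation threshold is calibrated on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .matrix import PresenceMatrix, SampleManifest

SCORE_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "df_target", "n_target", "df_background", "n_background",
    "tf", "idf", "score",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Formula variant and background semantics for fingerprint scoring.

    Parameters
    ----------
    log_base:
        ``10`` (default) or ``"e"``.
    smoothing:
        ``"add-one-both"`` (default): idf = log((n+1)/(df+1));
        ``"add-one-denominator"``: idf = log(n/(df+1));
        ``"none"``: idf = log(n/df), infinite when df = 0.
    background_mode:
        ``"disjoint"`` (default): df_background counts only samples with the
        background role — pedigree mode, target excluded.
        ``"full-cohort"``: df_background counts every manifest sample —
        region mode, each sub-population scored against the whole variome.
    """

    log_base: int | str = 10
    smoothing: str = "add-one-both"
    background_mode: str = "disjoint"

    def __post_init__(self) -> None:
        if self.log_base not in (10, "e"):
            raise ConfigError(f"log_base must be 10 or 'e', got {self.log_base!r}")
        if self.smoothing not in ("add-one-both", "add-one-denominator", "none"):
            raise ConfigError(f"unknown smoothing {self.smoothing!r}")
        if self.background_mode not in ("disjoint", "full-cohort"):
            raise ConfigError(f"unknown background_mode {self.background_mode!r}")

    def _log(self, x):
        return np.log10(x) if self.log_base == 10 else np.log(x)

    def max_idf(self, n_background: int) -> float:
        """Upper bound of the idf term (attained at df_background = 0)."""
        if self.smoothing == "add-one-both":
            return float(self._log(n_background + 1))
        if self.smoothing == "add-one-denominator":
            return float(self._log(n_background))
        return float("inf")


DEFAULT_CONFIG = ScoringConfig()


def term_frequency(df_target, n_target: int):
    """Presence fraction of a site in the target population."""
    if n_target < 1:
        raise ConfigError("n_target must be >= 1")
    df_target = np.asarray(df_target)
    if np.any((df_target < 0) | (df_target > n_target)):
        raise ConfigError(f"df_target out of range [0, {n_target}]")
    out = df_target / n_target
    return float(out) if out.ndim == 0 else out


def inverse_document_frequency(df_background, n_background: int,
                               config: ScoringConfig = DEFAULT_CONFIG):
    """Log-scaled rarity of a site in the background population."""
    if n_background < 1:
        raise ConfigError("n_background must be >= 1")
    df = np.asarray(df_background, dtype=float)
    if np.any((df < 0) | (df > n_background)):
        raise ConfigError(f"df_background out of range [0, {n_background}]")
    if config.smoothing == "add-one-both":
        out = config._log((n_background + 1) / (df + 1))
    elif config.smoothing == "add-one-denominator":
        out = config._log(n_background / (df + 1))
    else:
        with np.errstate(divide="ignore"):
            out = config._log(n_background / df)
    out = np.maximum(out, 0.0) if config.smoothing == "add-one-denominator" else out
    return float(out) if out.ndim == 0 else out


def fingerprint_score(df_target, n_target, df_background, n_background,
                      config: ScoringConfig = DEFAULT_CONFIG):
    """score = tf * idf, with score = 0 whenever the site is absent from the target."""
    tf = term_frequency(df_target, n_target)
    idf = inverse_document_frequency(df_background, n_background, config)
    tf_a, idf_a = np.asarray(tf, dtype=float), np.asarray(idf, dtype=float)
    score = np.where(tf_a == 0.0, 0.0, tf_a * idf_a)
    return float(score) if score.ndim == 0 else score


def score_sites(matrix: PresenceMatrix, manifest: SampleManifest,
                config: ScoringConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Score every matrix row for the manifest's target set.

    Returns one row per site with columns ``chrom, pos, ref, alt, df_target,
    n_target, df_background, n_background, tf, idf, score``, in the matrix's
    (chrom, pos) row order.
    """
    target = manifest.target_samples
    if config.background_mode == "full-cohort":
        background = list(manifest.samples)
    else:
        background = manifest.background_samples
    if not target:
        raise ConfigError("manifest defines no target samples")
    if not background:
        raise ConfigError("manifest defines no background samples")

    df_t = matrix.presence_counts(target)
    df_b = matrix.presence_counts(background)
    out = matrix.sites.copy()
    out["df_target"] = df_t
    out["n_target"] = len(target)
    out["df_background"] = df_b
    out["n_background"] = len(background)
    out["tf"] = term_frequency(df_t, len(target))
    out["idf"] = inverse_document_frequency(df_b, len(background), config)
    out["score"] = np.where(out["tf"] == 0.0, 0.0, out["tf"] * out["idf"])
    return out[SCORE_COLUMNS]


def rank_results(results: pd.DataFrame) -> pd.DataFrame:
    """Sort score descending with (chrom, pos) as the deterministic tie-break."""
    return results.sort_values(
        ["score", "chrom", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)


def select_fingerprint_sites(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Sites with score >= threshold (boundary inclusive), input order preserved."""
    if not np.isfinite(threshold):
        raise ConfigError(f"threshold must be finite, got {threshold}")
    return results[results["score"] >= threshold].copy()
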