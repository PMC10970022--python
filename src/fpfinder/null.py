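"""Permutation null distribution of fingerprint scores and the selection threshold.

The null assumes no association between a site and the target set: the
presence count in the target is uniform on the integers {0, ..., n_target}
and the background count is independently uniform on {0, ..., n_background}.
Each simulated score multiplies the resulting term frequency and inverse
document frequency.  The selection threshold is the top-``top_fraction``
boundary of the simulated scores (nearest-rank-from-above), e.g. with 1000
simulations and the default 5%, the 50th-largest simulated score.

Because the null is a finite discrete distribution over
(n_target + 1) x (n_background + 1) equally likely pairs, its exact quantile
is computable by exhaustive enumeration — ``exact_null_quantile`` — and the
simulated threshold converges to it as the number of simulations grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .scoring import DEFAULT_CONFIG, ScoringConfig, fingerprint_score


@dataclass(frozen=True)
class NullSimulationSpec:
    """Sizes, simulation count, tail fraction and seed for the null."""

    n_target: int = 20
    n_background: int = 410
    n_sims: int = 1000
    top_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ConfigError("n_sims must be >= 1")
        if not 0 < self.top_fraction < 1:
            raise ConfigError("top_fraction must be in (0, 1)")
        if self.n_target < 1 or self.n_background < 1:
            raise ConfigError("population sizes must be >= 1")


def simulate_null_scores(spec: NullSimulationSpec,
                         config: ScoringConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Draw ``n_sims`` independent null fingerprint scores (reproducible by seed)."""
    rng = np.random.default_rng(spec.seed)
    k = rng.integers(0, spec.n_target + 1, size=spec.n_sims)
    m = rng.integers(0, spec.n_background + 1, size=spec.n_sims)
    return np.asarray(
        fingerprint_score(k, spec.n_target, m, spec.n_background, config), dtype=float
    )


def threshold_from_null(scores, top_fraction: float) -> float:
    """Nearest-rank-from-above upper quantile of the simulated scores.

    Returns the smallest score s such that at least
    ``ceil(top_fraction * len(scores))`` scores are >= s — i.e. with 1000
    scores and 5%, the 50th largest.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ConfigError("cannot take a quantile of an empty score set")
    if not 0 < top_fraction < 1:
        raise ConfigError("top_fraction must be in (0, 1)")
    r = math.ceil(top_fraction * scores.size)
    return float(np.sort(scores)[scores.size - r])


def pedigree_threshold(spec: NullSimulationSpec,
                       config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Simulate the null and return the top-fraction score threshold."""
    return threshold_from_null(simulate_null_scores(spec, config), spec.top_fraction)


def enumerate_null(n_target: int, n_background: int,
                   config: ScoringConfig = DEFAULT_CONFIG) -> np.ndarray:
    """All (n_target+1) x (n_background+1) equally likely null scores."""
    k = np.arange(n_target + 1)
    m = np.arange(n_background + 1)
    grid = fingerprint_score(
        k[:, None], n_target, np.broadcast_to(m[None, :], (k.size, m.size)),
        n_background, config,
    )
    return np.asarray(grid, dtype=float).ravel()


def exact_null_quantile(n_target: int, n_background: int, top_fraction: float,
                        config: ScoringConfig = DEFAULT_CONFIG) -> float:
    """Exact upper quantile of the discrete null, by exhaustive enumeration."""
    return threshold_from_null(enumerate_null(n_target, n_background, config), top_fraction)
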