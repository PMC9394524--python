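"""Inference procedures for registered-profile cohorts and phenotype counts.

* positional comparison of >=2 strains: a sliding one-way ANOVA across
  boundary positions, Tukey's honestly significant difference test for the
  pairwise contrasts, and Benjamini-Hochberg FDR adjustment across
  positions;
* two-sample Kolmogorov-Smirnov tests for extremum-distance distributions;
* percentile-bootstrap confidence intervals (10,000 resamplings by
  default), a bootstrap difference-in-means test (significant when 0 falls
  outside the CI), and bootstrapped phenotype-frequency CIs;
* the cosine-of-orientation gradient-tracking metric.

All stochastic procedures are reproducible given a seed.  The sampling unit
for profile statistics is the cell: per-cell values should be time-averaged
before entering the sliding ANOVA, which avoids pseudo-replication across
frames of the same cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError, UndefinedOrientationError

__all__ = [
    "PositionalStatsResult",
    "BootstrapCI",
    "OrientationRecord",
    "sliding_anova",
    "fdr_adjust",
    "ks_two_sample",
    "bootstrap_ci",
    "diff_means_bootstrap",
    "phenotype_frequency",
    "cosine_of_orientation",
]


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    NaN entries (e.g. positions with zero within-group variance) are passed
    through as NaN and excluded from the adjustment.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    if pv.size:
        out[valid] = multipletests(pv, method="fdr_bh")[1]
    return out


@dataclass
class PositionalStatsResult:
    """Per-position omnibus and pairwise statistics for >=2 groups."""

    positions_um: np.ndarray
    f_stat: np.ndarray
    p_raw: np.ndarray
    q: np.ndarray  # BH across positions (omnibus)
    pair_names: list[tuple[int, int]]
    tukey_p: np.ndarray | None  # (n_pairs, n_positions)
    tukey_q: np.ndarray | None
    alpha: float
    undefined: np.ndarray  # positions where the test was undefined

    @property
    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.q < self.alpha


def sliding_anova(
    groups: Sequence[np.ndarray],
    positions_um: np.ndarray | None = None,
    alpha: float = 0.05,
    tukey: bool = True,
) -> PositionalStatsResult:
    """One-way ANOVA at every boundary position, with optional Tukey HSD
    pairwise comparisons, followed by BH-FDR across positions.

    ``groups`` holds one (n_cells, n_positions) array per strain, each row a
    cell's time-averaged fraction profile.  Positions where all groups are
    constant (zero within-group variance) are flagged as undefined rather
    than assigned a p-value.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise InvalidInputError("need at least two groups")
    n_pos = arrs[0].shape[1]
    for a in arrs:
        if a.ndim != 2 or a.shape[1] != n_pos:
            raise InvalidInputError("groups must be 2-D with a common position axis")
        if a.shape[0] < 2:
            raise InvalidInputError("each group needs at least two cells")
    if positions_um is None:
        positions_um = np.arange(n_pos, dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        f_stat, p_raw = sps.f_oneway(*arrs, axis=0)
    undefined = ~np.isfinite(p_raw)
    p_raw = np.where(undefined, np.nan, p_raw)
    q = fdr_adjust(p_raw)

    pair_names = list(combinations(range(len(arrs)), 2))
    tukey_p = tukey_q = None
    if tukey:
        tukey_p = np.full((len(pair_names), n_pos), np.nan)
        for j in range(n_pos):
            if undefined[j]:
                continue
            res = sps.tukey_hsd(*[a[:, j] for a in arrs])
            for k, (g1, g2) in enumerate(pair_names):
                tukey_p[k, j] = res.pvalue[g1, g2]
        tukey_q = np.vstack([fdr_adjust(row) for row in tukey_p])

    return PositionalStatsResult(
        positions_um=np.asarray(positions_um, dtype=float),
        f_stat=np.asarray(f_stat, dtype=float),
        p_raw=p_raw,
        q=q,
        pair_names=pair_names,
        tukey_p=tukey_p,
        tukey_q=tukey_q,
        alpha=alpha,
        undefined=undefined,
    )


def ks_two_sample(
    a: np.ndarray, b: np.ndarray, method: str = "asymp"
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of the absolute ECDF difference; the p-value is
    two-sided asymptotic by default (``method="exact"`` or ``"auto"`` for
    small samples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("samples must be non-empty")
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BootstrapCI:
    estimate: float
    lower: float
    upper: float
    level: float
    n_boot: int
    seed: int | None


def bootstrap_ci(
    sample: np.ndarray,
    statistic: Callable[..., np.ndarray] = np.mean,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI of ``statistic`` over ``n_boot`` resamples.

    ``statistic`` must accept an ``axis`` keyword (np.mean, np.median, ...);
    otherwise it is applied row-by-row.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least two observations")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    try:
        boots = statistic(x[idx], axis=1)
    except TypeError:
        boots = np.array([statistic(x[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    try:
        est = float(statistic(x, axis=0))
    except TypeError:
        est = float(statistic(x))
    return BootstrapCI(est, float(min(lo, est)), float(max(hi, est)), level, n_boot, seed)


def diff_means_bootstrap(
    a: np.ndarray,
    b: np.ndarray,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[BootstrapCI, bool]:
    """Bootstrap CI of mean(a) - mean(b) from independent resampling of the
    two samples; significant when 0 falls strictly outside the CI (a
    degenerate [0, 0] interval contains 0 and is not significant)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("both samples need at least two observations")
    rng = np.random.default_rng(seed)
    boots_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boots_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    diffs = boots_a - boots_b
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    est = float(a.mean() - b.mean())
    ci = BootstrapCI(est, float(min(lo, est)), float(max(hi, est)), level, n_boot, seed)
    significant = not (ci.lower <= 0.0 <= ci.upper)
    return ci, significant


def phenotype_frequency(
    k: int,
    n: int,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = 0,
) -> BootstrapCI:
    """Frequency k/n of a scored phenotype with a bootstrapped CI.

    Resampling n Bernoulli outcomes with replacement is distributionally a
    Binomial(n, k/n) draw, which is how the resampling is implemented.
    """
    if n < 1 or not 0 <= k <= n:
        raise InvalidInputError("require 0 <= k <= n and n >= 1")
    p_hat = k / n
    rng = np.random.default_rng(seed)
    boots = rng.binomial(n, p_hat, size=n_boot) / n
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return BootstrapCI(p_hat, float(min(lo, p_hat)), float(max(hi, p_hat)), level, n_boot, seed)


@dataclass
class OrientationRecord:
    cell_id: str
    growth_vector_um: np.ndarray
    gradient_axis: np.ndarray
    cosine: float


def cosine_of_orientation(
    growth_vector_um: np.ndarray, gradient_axis: np.ndarray, cell_id: str = "cell"
) -> OrientationRecord:
    """Cosine of the angle between a cell's net growth displacement and the
    increasing-pheromone axis: 1 = growing straight up-gradient, -1 = down.

    The growth vector is the displacement of the polarized-growth tip (e.g.
    final minus initial polar-cap centroid); a zero displacement has no
    orientation and raises.
    """
    g = np.asarray(growth_vector_um, dtype=float)
    ax = np.asarray(gradient_axis, dtype=float)
    ng, na = np.linalg.norm(g), np.linalg.norm(ax)
    if ng == 0:
        raise UndefinedOrientationError("zero growth displacement")
    if na == 0:
        raise InvalidInputError("gradient axis must be non-zero")
    cos = float(np.dot(g, ax) / (ng * na))
    return OrientationRecord(cell_id, g, ax / na, float(np.clip(cos, -1.0, 1.0)))
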