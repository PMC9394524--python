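"""Polar-cap registration and fraction-of-protein normalization.

Each signal-channel periphery profile is circularly shifted so the
reference-channel (polar-cap marker) peak sits at the central index, then
min-subtracted and normalized to sum to one.  The resulting values are the
fraction of the protein found at each position relative to the center of the
polar cap.  Profiles from cells of different perimeter are pooled by
resampling onto a common µm grid centered on the cap; cohort averages carry
percentile-bootstrap confidence bands obtained by resampling cells (cluster
bootstrap), which respects within-cell correlation across frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateProfileError,
    EmptySelectionError,
    InconsistentInputError,
    ResolutionError,
)
from .periphery import PeripheryProfile

__all__ = [
    "RegisteredFractionProfile",
    "AverageDistribution",
    "peak_index",
    "register_to_reference",
    "normalize_fraction",
    "register_and_normalize",
    "resample_to_grid",
    "align_to_common_grid",
    "average_distribution",
    "population_kymograph",
]

_SUM_TOL = 1e-9


@dataclass
class RegisteredFractionProfile:
    """Fraction-of-protein profile registered to the polar cap.

    ``positions_um`` are signed distances from the cap center (0 at the
    central index, negative on one side, positive on the other, following
    the contour orientation).  ``values`` are non-negative and sum to one.
    """

    values: np.ndarray
    positions_um: np.ndarray
    cell_id: str = "cell"
    frame_index: int = 0
    perimeter_um: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.values.shape != self.positions_um.shape:
            raise InconsistentInputError("values and positions differ in length")
        if np.any(self.values < -_SUM_TOL):
            raise InconsistentInputError("fraction values must be non-negative")
        if abs(self.values.sum() - 1.0) > _SUM_TOL:
            raise InconsistentInputError("fraction values must sum to 1")
        if np.any(np.diff(self.positions_um) <= 0):
            raise InconsistentInputError("positions must be strictly increasing")
        center = self.center_index
        if abs(self.positions_um[center]) > 1e-9:
            raise InconsistentInputError("central index must sit at position 0")

    @property
    def center_index(self) -> int:
        return int(np.argmin(np.abs(self.positions_um)))

    def __len__(self) -> int:
        return len(self.values)


def peak_index(profile: PeripheryProfile | np.ndarray) -> int:
    """Index of the maximum intensity; ties resolve to the smallest index.

    An all-equal profile has no usable peak and raises
    :class:`DegenerateProfileError` so the caller can decide how to proceed.
    """
    v = profile.intensities if isinstance(profile, PeripheryProfile) else np.asarray(profile)
    if v.size == 0:
        raise DegenerateProfileError("empty profile")
    if np.all(v == v.flat[0]):
        raise DegenerateProfileError("constant profile has no peak")
    return int(np.argmax(v))


def register_to_reference(signal: np.ndarray, reference_peak: int, n_reference: int | None = None) -> np.ndarray:
    """Circularly shift ``signal`` so ``reference_peak`` lands at the center.

    The central index is ``len(signal) // 2``.  A pure circular permutation:
    the spatial relationship of the signal to the reference is preserved
    exactly and the multiset of values is conserved.
    """
    v = np.asarray(signal)
    n = len(v)
    if n_reference is not None and n_reference != n:
        raise InconsistentInputError(
            f"signal ({n}) and reference ({n_reference}) profile lengths differ"
        )
    if not 0 <= reference_peak < n:
        raise InconsistentInputError("reference peak index out of range")
    return np.roll(v, n // 2 - reference_peak)


def normalize_fraction(values: np.ndarray) -> np.ndarray:
    """Min-subtract then divide by the total so the result sums to one."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateProfileError("need at least 2 values")
    shifted = v - v.min()
    total = shifted.sum()
    if total == 0:
        raise DegenerateProfileError("constant profile cannot be normalized")
    return shifted / total


def register_and_normalize(
    signal: PeripheryProfile,
    reference: PeripheryProfile,
    pixel_size_um: float,
) -> RegisteredFractionProfile:
    """Full registration step for one frame: locate the reference peak,
    shift the signal to center it, and convert to a fraction profile with
    signed µm positions."""
    if len(signal) != len(reference):
        raise InconsistentInputError("signal and reference sampled on different contours")
    peak = peak_index(reference)
    shifted = register_to_reference(signal.intensities, peak)
    values = normalize_fraction(shifted)
    n = len(values)
    step_um = signal.arc_step_px * pixel_size_um
    positions = (np.arange(n) - n // 2) * step_um
    return RegisteredFractionProfile(
        values=values,
        positions_um=positions,
        cell_id=signal.cell_id,
        frame_index=signal.frame_index,
        perimeter_um=n * step_um,
    )


def resample_to_grid(
    profile: RegisteredFractionProfile, grid_spacing_um: float
) -> RegisteredFractionProfile:
    """Resample onto a symmetric grid about 0 with the given spacing.

    Linear circular interpolation (period = perimeter), renormalized to sum
    to one.  The grid spans the largest symmetric range the profile covers.
    """
    if grid_spacing_um <= 0:
        raise ResolutionError("grid spacing must be positive")
    pos, val = profile.positions_um, profile.values
    half_span = min(-pos[0], pos[-1])
    if grid_spacing_um > half_span:
        raise ResolutionError("grid spacing coarser than half the profile span")
    k = int(np.floor(half_span / grid_spacing_um))
    grid = np.arange(-k, k + 1) * grid_spacing_um
    period = profile.perimeter_um if profile.perimeter_um is not None else pos[-1] - pos[0]
    interp = np.interp(grid, pos, val, period=period)
    interp = np.clip(interp, 0.0, None)
    total = interp.sum()
    if total == 0:
        raise DegenerateProfileError("profile vanished under resampling")
    return RegisteredFractionProfile(
        values=interp / total,
        positions_um=grid,
        cell_id=profile.cell_id,
        frame_index=profile.frame_index,
        perimeter_um=profile.perimeter_um,
    )


def align_to_common_grid(
    profiles: list[RegisteredFractionProfile], grid_spacing_um: float
) -> list[RegisteredFractionProfile]:
    """Resample all profiles to one spacing and crop to the shortest
    symmetric half-span present, renormalizing each to sum to one."""
    if not profiles:
        raise EmptySelectionError("no profiles to align")
    resampled = [resample_to_grid(p, grid_spacing_um) for p in profiles]
    k_min = min((len(p) - 1) // 2 for p in resampled)
    out = []
    for p in resampled:
        c = p.center_index
        vals = p.values[c - k_min : c + k_min + 1]
        out.append(
            RegisteredFractionProfile(
                values=vals / vals.sum(),
                positions_um=p.positions_um[c - k_min : c + k_min + 1],
                cell_id=p.cell_id,
                frame_index=p.frame_index,
                perimeter_um=p.perimeter_um,
            )
        )
    return out


def _check_common_grid(profiles: list[RegisteredFractionProfile]) -> np.ndarray:
    grid = profiles[0].positions_um
    for p in profiles[1:]:
        if len(p.positions_um) != len(grid) or not np.allclose(p.positions_um, grid):
            raise InconsistentInputError("profiles are not on a common grid")
    return grid


@dataclass
class AverageDistribution:
    """Cohort-average fraction profile with a bootstrap confidence band."""

    positions_um: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_cells: int
    n_profiles: int
    level: float = 0.95
    n_boot: int = 10000


def average_distribution(
    profiles: list[RegisteredFractionProfile],
    start_frame: int = 9,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | None = 0,
) -> AverageDistribution:
    """Pointwise mean over all cell x frame profiles with frame >= start_frame.

    Early frames often contain cells still completing cytokinesis, so the
    default skips the first nine.  The confidence band is a percentile
    bootstrap over cells: a resample draws whole cells with replacement and
    pools all their retained frames.
    """
    kept = [p for p in profiles if p.frame_index >= start_frame]
    if not kept:
        raise EmptySelectionError(f"no profiles at frame >= {start_frame}")
    grid = _check_common_grid(kept)
    cell_ids = sorted({p.cell_id for p in kept})
    per_cell_sum = np.zeros((len(cell_ids), len(grid)))
    per_cell_n = np.zeros(len(cell_ids))
    index = {c: i for i, c in enumerate(cell_ids)}
    for p in kept:
        i = index[p.cell_id]
        per_cell_sum[i] += p.values
        per_cell_n[i] += 1
    mean = per_cell_sum.sum(axis=0) / per_cell_n.sum()

    n_cells = len(cell_ids)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    boot_means = np.empty((n_boot, len(grid)))
    chunk = max(1, min(n_boot, int(2e7 // max(1, n_cells * len(grid)))))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n_cells, size=(b, n_cells))
        sums = per_cell_sum[idx].sum(axis=1)
        counts = per_cell_n[idx].sum(axis=1)
        boot_means[done : done + b] = sums / counts[:, None]
        done += b
    lower = np.quantile(boot_means, alpha, axis=0)
    upper = np.quantile(boot_means, 1.0 - alpha, axis=0)
    # the percentile band always brackets the point estimate by construction
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    return AverageDistribution(
        positions_um=grid,
        mean=mean,
        lower=lower,
        upper=upper,
        n_cells=n_cells,
        n_profiles=len(kept),
        level=level,
        n_boot=n_boot,
    )


def population_kymograph(
    profiles: list[RegisteredFractionProfile],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Across-cell mean registered profile per frame.

    Returns ``(matrix, positions_um, frames)`` with matrix of shape
    (n_positions, n_frames); frames with no cells appear as NaN columns.
    """
    if not profiles:
        raise EmptySelectionError("no profiles")
    grid = _check_common_grid(profiles)
    frames = np.arange(max(p.frame_index for p in profiles) + 1)
    matrix = np.full((len(grid), len(frames)), np.nan)
    for f in frames:
        vals = [p.values for p in profiles if p.frame_index == f]
        if vals:
            matrix[:, f] = np.mean(vals, axis=0)
    return matrix, grid, frames
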