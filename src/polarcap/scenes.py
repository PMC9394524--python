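"""Synthetic two-channel time-lapse scenes of single polarized yeast cells.

The generator emulates the imaging geometry of a pheromone-treated budding
yeast cell watched in a microfluidic chamber: a roughly circular cell whose
membrane carries

* channel 1 ("reference"): a polarity-reference marker (Bem1-like) with a
  single angular intensity peak, the polar cap;
* channel 2 ("signal"): a protein of interest (RGS- or MAPK-like) whose
  membrane peak sits at a planted arc-length offset from the cap, optionally
  flanked by symmetric local minima, plus a bright intranuclear blob and
  diffuse cytoplasmic background.

All planted parameters (cap direction, inter-channel offset, nucleus mask)
are recorded as ground truth so downstream stages can be tested for exact
recovery.  Frames share the cell geometry; photon noise is re-drawn per
frame, which is the dominant frame-to-frame variation in the real data this
emulates (cells imaged at 20-min intervals over many hours).

Angular profiles are wrapped Gaussians in arc length; intensities are in
arbitrary camera units.  Noise is additive Gaussian clipped at zero.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "membrane_profile",
    "render_scene",
    "make_population",
]

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic cell scene.

    Defaults describe the study conditions emulated throughout the test
    suite: 0.18 µm pixels (60x objective on an sCMOS camera), 29 frames at
    20-min spacing, a ~3.6 µm-radius cell, membrane peak-to-noise ratio 5.
    """

    image_size: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.18
    n_frames: int = 29
    frame_interval_min: float = 20.0
    cell_center: tuple[float, float] = (64.0, 64.0)  # (row, col), pixels
    cell_radius_px: float = 20.0
    cap_angle_rad: float = 0.0
    offset_um: float = 0.0
    cap_width_um: float = 0.5
    signal_baseline_frac: float = 0.25
    minima_depth: float = 0.2
    minima_flank_um: float = 1.0
    minima_width_um: float = 0.4
    membrane_amp: float = 100.0
    membrane_radial_sigma_px: float = 1.2
    cytoplasm_amp: float = 30.0
    nucleus_amp: float = 200.0
    nucleus_center: tuple[float, float] | None = None  # defaults to cell center
    nucleus_radius_px: float = 6.0
    noise_sigma: float = 20.0
    seed: int = 0

    @property
    def perimeter_um(self) -> float:
        return _TWO_PI * self.cell_radius_px * self.pixel_size_um

    @property
    def nucleus_center_px(self) -> tuple[float, float]:
        return self.nucleus_center if self.nucleus_center is not None else self.cell_center

    def validate(self) -> None:
        h, w = self.image_size
        cy, cx = self.cell_center
        r = self.cell_radius_px
        if r <= 0 or self.perimeter_um <= 0:
            raise InvalidConfigError("cell radius/perimeter must be positive")
        if not (cy - r >= 2 and cx - r >= 2 and cy + r <= h - 3 and cx + r <= w - 3):
            raise InvalidConfigError("cell must fit inside the image with a >=2 px margin")
        if self.offset_um < 0:
            raise InvalidConfigError("offset_um must be >= 0")
        if self.noise_sigma < 0:
            raise InvalidConfigError("noise_sigma must be >= 0")
        for name in ("membrane_amp", "cytoplasm_amp", "nucleus_amp"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        ny, nx = self.nucleus_center_px
        if np.hypot(ny - cy, nx - cx) + self.nucleus_radius_px > r:
            raise InvalidConfigError("nucleus must lie entirely inside the cell")
        if self.n_frames < 1:
            raise InvalidConfigError("n_frames must be >= 1")
        if not 0.0 <= self.signal_baseline_frac < 1.0:
            raise InvalidConfigError("signal_baseline_frac must be in [0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted truth for one rendered scene.

    ``cap_arc_um``/``signal_arc_um`` are continuous arc-length coordinates
    (µm, measured along the ideal circular perimeter from angle 0); the
    ``*_index`` fields are the nearest sample indices on the traced boundary
    of the frame-0 cell mask, so they are directly comparable to profile
    argmax indices.
    """

    cell_masks: np.ndarray  # (T, H, W) integer labels (all 1 for one cell)
    nucleus_masks: np.ndarray  # (T, H, W) bool
    cap_arc_um: float
    signal_arc_um: float
    cap_arc_index: int
    signal_arc_index: int
    n_boundary_samples: int
    offset_um: float

    def to_json_dict(self) -> dict:
        return {
            "cap_arc_um": self.cap_arc_um,
            "signal_arc_um": self.signal_arc_um,
            "cap_arc_index": self.cap_arc_index,
            "signal_arc_index": self.signal_arc_index,
            "n_boundary_samples": self.n_boundary_samples,
            "offset_um": self.offset_um,
        }


def _wrapped_gaussian(d_um: np.ndarray, sigma_um: float, period_um: float) -> np.ndarray:
    """Wrapped (circular) Gaussian bump with unit peak, periodic in ``period_um``."""
    d = np.atleast_1d(np.asarray(d_um, dtype=float))
    k = np.arange(-3, 4)
    dd = d[..., None] + k * period_um
    out = np.exp(-0.5 * (dd / sigma_um) ** 2).sum(axis=-1)
    # normalize so the value exactly at the center is 1 (wrap tails add a hair)
    peak = np.exp(-0.5 * (k * period_um / sigma_um) ** 2).sum()
    return out / peak


def membrane_profile(
    arc_position_um: np.ndarray | float,
    cfg: SceneConfig,
    channel: str = "reference",
) -> np.ndarray | float:
    """Closed-form membrane intensity at an arc-length position (µm).

    The reference channel is a single wrapped-Gaussian bump centered on the
    cap.  The signal channel adds a uniform membrane baseline and, when
    ``minima_depth > 0``, symmetric flanking dips at ``minima_flank_um`` on
    either side of its peak (which sits at cap + offset).  Strictly periodic
    in the perimeter length; clipped at zero.
    """
    L = cfg.perimeter_um
    if L <= 0:
        raise InvalidConfigError("non-positive perimeter")
    cap_arc = (cfg.cap_angle_rad % _TWO_PI) * cfg.cell_radius_px * cfg.pixel_size_um
    s = np.asarray(arc_position_um, dtype=float)
    if channel == "reference":
        v = _wrapped_gaussian(s - cap_arc, cfg.cap_width_um, L)
    elif channel == "signal":
        peak = cap_arc + cfg.offset_um
        b = cfg.signal_baseline_frac
        v = b + (1.0 - b) * _wrapped_gaussian(s - peak, cfg.cap_width_um, L)
        if cfg.minima_depth > 0:
            v = v - cfg.minima_depth * (
                _wrapped_gaussian(s - peak - cfg.minima_flank_um, cfg.minima_width_um, L)
                + _wrapped_gaussian(s - peak + cfg.minima_flank_um, cfg.minima_width_um, L)
            )
        v = np.clip(v, 0.0, None)
    else:
        raise InvalidConfigError(f"unknown channel {channel!r}")
    out = cfg.membrane_amp * v
    if np.isscalar(arc_position_um):
        return float(np.asarray(out).reshape(-1)[0])
    return out


def _noiseless_frame(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the deterministic part of one frame.

    Returns ``(channels, cell_mask, nucleus_mask)`` with ``channels`` of
    shape (2, H, W).
    """
    h, w = cfg.image_size
    cy, cx = cfg.cell_center
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    rho = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx) % _TWO_PI
    arc_um = theta * cfg.cell_radius_px * cfg.pixel_size_um

    radial = np.exp(-0.5 * ((rho - cfg.cell_radius_px) / cfg.membrane_radial_sigma_px) ** 2)
    cell_mask = rho <= cfg.cell_radius_px
    ny, nx = cfg.nucleus_center_px
    nucleus_mask = np.hypot(yy - ny, xx - nx) <= cfg.nucleus_radius_px

    ref = radial * membrane_profile(arc_um, cfg, "reference")
    sig = radial * membrane_profile(arc_um, cfg, "signal")
    sig = sig + cfg.cytoplasm_amp * cell_mask + cfg.nucleus_amp * nucleus_mask
    return np.stack([ref, sig]), cell_mask, nucleus_mask


def render_scene(cfg: SceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render a (T, 2, H, W) float stack plus its :class:`GroundTruth`.

    Deterministic given ``cfg.seed``; with ``noise_sigma = 0`` the stack
    equals the noiseless model exactly in every frame.
    """
    cfg.validate()
    model, cell_mask, nucleus_mask = _noiseless_frame(cfg)
    T = cfg.n_frames
    stack = np.broadcast_to(model, (T,) + model.shape).copy()
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        stack += rng.normal(0.0, cfg.noise_sigma, size=stack.shape)
        np.clip(stack, 0.0, None, out=stack)

    # ground-truth arc coordinates on the ideal circle, plus nearest indices
    # on the traced frame-0 boundary so they can be compared to profile argmax
    from .periphery import trace_boundary  # deferred: avoids import cycle

    contour = trace_boundary(cell_mask)
    cy, cx = cfg.cell_center
    ang = np.arctan2(contour.points[:, 0] - cy, contour.points[:, 1] - cx) % _TWO_PI
    L_um = cfg.perimeter_um
    cap_arc = (cfg.cap_angle_rad % _TWO_PI) * cfg.cell_radius_px * cfg.pixel_size_um
    signal_arc = (cap_arc + cfg.offset_um) % L_um

    def nearest_index(target_arc_um: float) -> int:
        target_theta = (target_arc_um / (cfg.cell_radius_px * cfg.pixel_size_um)) % _TWO_PI
        d = np.abs((ang - target_theta + np.pi) % _TWO_PI - np.pi)
        return int(np.argmin(d))

    truth = GroundTruth(
        cell_masks=np.broadcast_to(cell_mask.astype(np.int32), (T,) + cell_mask.shape).copy(),
        nucleus_masks=np.broadcast_to(nucleus_mask, (T,) + nucleus_mask.shape).copy(),
        cap_arc_um=float(cap_arc),
        signal_arc_um=float(signal_arc),
        cap_arc_index=nearest_index(cap_arc),
        signal_arc_index=nearest_index(signal_arc),
        n_boundary_samples=len(contour.points),
        offset_um=float(cfg.offset_um),
    )
    return stack, truth


OffsetSampler = float | tuple[str, float, float] | Callable[[np.random.Generator], float]


def _draw_offset(sampler: OffsetSampler, rng: np.random.Generator) -> float:
    if callable(sampler):
        return float(sampler(rng))
    if isinstance(sampler, (int, float)):
        return float(sampler)
    kind, lo, hi = sampler
    if kind != "uniform":
        raise InvalidConfigError(f"unknown offset sampler {kind!r}")
    return float(rng.uniform(lo, hi))


def make_population(
    n_cells: int,
    offset_sampler: OffsetSampler,
    seed: int,
    base_config: SceneConfig | None = None,
    randomize_cap_angle: bool = True,
) -> list[tuple[np.ndarray, GroundTruth, SceneConfig]]:
    """Render a cohort of independent cells with reproducible per-cell seeds.

    ``offset_sampler`` may be a constant (µm), a ``("uniform", lo, hi)``
    tuple, or a callable taking an ``np.random.Generator``.
    """
    if n_cells < 1:
        raise InvalidConfigError("n_cells must be >= 1")
    base = base_config if base_config is not None else SceneConfig()
    master = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        cell_seed = int(master.integers(0, 2**31 - 1))
        offset = _draw_offset(offset_sampler, master)
        cap = float(master.uniform(0.0, _TWO_PI)) if randomize_cap_angle else base.cap_angle_rad
        cfg = dataclasses.replace(base, seed=cell_seed, offset_um=offset, cap_angle_rad=cap)
        stack, truth = render_scene(cfg)
        cells.append((stack, truth, cfg))
    return cells


def save_scene(outdir: str | Path, stack: np.ndarray, truth: GroundTruth, cfg: SceneConfig,
               cell_id: str = "cell000") -> None:
    """Write a rendered scene as per-channel multi-page TIFFs + truth JSON."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{cell_id}_ch1.tif", stack[:, 0].astype(np.float32), photometric="minisblack")
    tifffile.imwrite(outdir / f"{cell_id}_ch2.tif", stack[:, 1].astype(np.float32), photometric="minisblack")
    tifffile.imwrite(outdir / f"{cell_id}_cellmask.tif", truth.cell_masks.astype(np.uint16), photometric="minisblack")
    tifffile.imwrite(outdir / f"{cell_id}_nucmask.tif", truth.nucleus_masks.astype(np.uint8), photometric="minisblack")
    with open(outdir / f"{cell_id}_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2)
    with open(outdir / f"{cell_id}_config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2)
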