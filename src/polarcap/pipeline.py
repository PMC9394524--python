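"""End-to-end composition of the analysis stages.

``analyze_cell`` turns one two-channel stack + per-frame cell masks into
registered fraction profiles; ``analyze_population`` pools cells onto a
common grid and produces the cohort average, extrema tables, cumulative
distance curves and quantile readouts; ``run_pipeline`` drives everything
from a :class:`~polarcap.config.RunConfig` and writes CSV/JSON results plus
a machine-readable manifest.
"""

from __future__ import annotations

import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import DegenerateProfileError, PolarcapError
from .extrema import ExtremaRecord, distance_cdf, extrema_positions, quantile_distance
from .io import average_to_frame, profiles_to_frame, registered_to_frame, write_json
from .nucleinator import NucleinatorParams, detect_nuclear_mask, replace_with_cell_mean
from .periphery import PeripheryProfile, sample_line_scan, trace_boundary
from .registration import (
    AverageDistribution,
    RegisteredFractionProfile,
    align_to_common_grid,
    average_distribution,
    register_and_normalize,
)
from .scenes import make_population

log = logging.getLogger(__name__)


@dataclass
class CellResult:
    cell_id: str
    registered: list[RegisteredFractionProfile]
    raw_profiles: list[PeripheryProfile] = field(default_factory=list)


def analyze_cell(
    stack: np.ndarray,
    cell_masks: np.ndarray,
    cell_id: str,
    pixel_size_um: float,
    line_width_px: int = 5,
    mask_nuclei: bool = True,
    nucleinator: NucleinatorParams = NucleinatorParams(),
) -> CellResult:
    """Process one cell: nuclear masking (channel 2), periphery line-scans
    of both channels, registration to the channel-1 peak, normalization.

    ``stack`` has shape (T, 2, H, W); ``cell_masks`` (T, H, W).  Frames
    whose reference profile is degenerate (no peak) are skipped with a log
    entry.
    """
    registered: list[RegisteredFractionProfile] = []
    raw: list[PeripheryProfile] = []
    for t in range(stack.shape[0]):
        cm = cell_masks[t] > 0
        try:
            contour = trace_boundary(cm, frame_index=t)
            ch2 = stack[t, 1]
            if mask_nuclei:
                nmask = detect_nuclear_mask(ch2, cm, nucleinator, cell_id, t)
                ch2 = replace_with_cell_mean(ch2, nmask, cm)
            ref = sample_line_scan(stack[t, 0], contour, line_width_px, "reference", cell_id)
            sig = sample_line_scan(ch2, contour, line_width_px, "signal", cell_id)
            raw.extend([ref, sig])
            registered.append(register_and_normalize(sig, ref, pixel_size_um))
        except DegenerateProfileError as exc:
            log.warning("cell %s frame %d skipped: %s", cell_id, t, exc)
        except PolarcapError as exc:
            raise type(exc)(f"cell {cell_id} frame {t}: {exc}") from exc
    return CellResult(cell_id=cell_id, registered=registered, raw_profiles=raw)


@dataclass
class PopulationResult:
    registered: list[RegisteredFractionProfile]  # on the common grid
    average: AverageDistribution
    extrema: list[ExtremaRecord]
    maxima_q50_um: float
    minima_q25_um: float

    def extrema_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell": [r.cell_id for r in self.extrema],
                "frame": [r.frame_index for r in self.extrema],
                "max_pos_um": [r.max_pos_um for r in self.extrema],
                "min_pos_um": [r.min_pos_um for r in self.extrema],
                "max_dist_um": [r.max_dist_um for r in self.extrema],
                "min_dist_um": [r.min_dist_um for r in self.extrema],
            }
        )


def analyze_population(
    cell_results: list[CellResult],
    grid_spacing_um: float = 0.1,
    start_frame: int = 9,
    n_boot: int = 10000,
    seed: int | None = 0,
) -> PopulationResult:
    """Pool registered profiles across cells and summarize the cohort."""
    profiles = [p for cr in cell_results for p in cr.registered]
    common = align_to_common_grid(profiles, grid_spacing_um)
    avg = average_distribution(common, start_frame=start_frame, n_boot=n_boot, seed=seed)
    records = []
    for p in common:
        if p.frame_index < start_frame:
            continue
        try:
            records.append(extrema_positions(p))
        except DegenerateProfileError:
            log.warning("constant profile (cell %s frame %d) skipped", p.cell_id, p.frame_index)
    max_cdf = distance_cdf(np.array([r.max_dist_um for r in records]))
    min_cdf = distance_cdf(np.array([r.min_dist_um for r in records]))
    return PopulationResult(
        registered=common,
        average=avg,
        extrema=records,
        maxima_q50_um=quantile_distance(max_cdf, 0.5),
        minima_q25_um=quantile_distance(min_cdf, 0.25),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis described by ``config`` and write results.

    Returns the manifest dict.  Outputs under ``config.outdir``:
    profiles.csv, registered.csv, average_distribution.csv, extrema.csv,
    cdf_maxima.csv / cdf_minima.csv, quantiles.json, manifest.json.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = config.simulation
        population = make_population(
            sim.n_cells, sim.offset_sampler, seed=config.seed, base_config=sim.scene
        )
        cells = [
            (f"cell{i:03d}", stack, truth.cell_masks)
            for i, (stack, truth, _cfg) in enumerate(population)
        ]
        planted = [truth.offset_um for _stack, truth, _cfg in population]
    else:
        cells = _load_input_cells(Path(config.input_dir))
        planted = None

    results = [
        analyze_cell(
            stack,
            masks,
            cell_id,
            config.pixel_size_um,
            config.line_width_px,
            config.mask_nuclei,
            config.nucleinator,
        )
        for cell_id, stack, masks in cells
    ]
    pop = analyze_population(
        results,
        grid_spacing_um=config.grid_spacing_um,
        start_frame=config.start_frame,
        n_boot=config.n_boot,
        seed=config.seed,
    )

    profiles_to_frame(
        [p for r in results for p in r.raw_profiles], config.pixel_size_um
    ).to_csv(outdir / "profiles.csv", index=False)
    registered_to_frame(pop.registered).to_csv(outdir / "registered.csv", index=False)
    average_to_frame(pop.average).to_csv(outdir / "average_distribution.csv", index=False)
    pop.extrema_frame().to_csv(outdir / "extrema.csv", index=False)
    for name, dists in (
        ("cdf_maxima", [r.max_dist_um for r in pop.extrema]),
        ("cdf_minima", [r.min_dist_um for r in pop.extrema]),
    ):
        cdf = distance_cdf(np.asarray(dists))
        pd.DataFrame(
            {"distance_um": cdf.distances_um, "cumulative_fraction": cdf.fractions}
        ).to_csv(outdir / f"{name}.csv", index=False)

    peak_um = float(pop.average.positions_um[int(np.argmax(pop.average.mean))])
    quantiles = {
        "maxima_distance_q50_um": pop.maxima_q50_um,
        "minima_distance_q25_um": pop.minima_q25_um,
        "average_peak_position_um": peak_um,
        "median_max_dist_um": float(np.median([r.max_dist_um for r in pop.extrema])),
    }
    write_json(outdir / "quantiles.json", quantiles)

    manifest = {
        "polarcap_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.to_dict(),
        "n_cells": len(results),
        "planted_offsets_um": planted,
        "summary": quantiles,
    }
    write_json(outdir / "manifest.json", manifest)
    return manifest


def _load_input_cells(input_dir: Path) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Load per-cell TIFF inputs written by ``polarcap simulate`` (or in the
    same layout): {cell}_ch1.tif, {cell}_ch2.tif, {cell}_cellmask.tif."""
    from .io import read_stack

    cells = []
    for ch1_path in sorted(input_dir.glob("*_ch1.tif")):
        cell_id = ch1_path.name[: -len("_ch1.tif")]
        ch1 = read_stack(ch1_path)
        ch2 = read_stack(input_dir / f"{cell_id}_ch2.tif")
        masks = read_stack(input_dir / f"{cell_id}_cellmask.tif")
        cells.append((cell_id, np.stack([ch1, ch2], axis=1), masks))
    if not cells:
        raise PolarcapError(f"no *_ch1.tif inputs found in {input_dir}")
    return cells
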