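"""TIFF / CSV / JSON helpers shared by the pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidInputError
from .registration import AverageDistribution, RegisteredFractionProfile

__all__ = [
    "read_stack",
    "write_stack",
    "profiles_to_frame",
    "registered_to_frame",
    "frame_to_registered",
    "average_to_frame",
    "write_json",
]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (multi-page) TIFF stack; raises on malformed files."""
    try:
        return tifffile.imread(str(path))
    except (tifffile.TiffFileError, FileNotFoundError, ValueError) as exc:
        raise InvalidInputError(f"cannot read TIFF {path}: {exc}") from exc


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a stack losslessly; integer arrays stay integer (label masks),
    floats are written as-is so round trips are bit-exact."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(stack), photometric="minisblack")


def profiles_to_frame(profiles, pixel_size_um: float) -> pd.DataFrame:
    """Long-format table of raw periphery profiles
    (cell, frame, arc_index, arc_um, channel, intensity)."""
    rows = []
    for p in profiles:
        n = len(p)
        rows.append(
            pd.DataFrame(
                {
                    "cell": p.cell_id,
                    "frame": p.frame_index,
                    "arc_index": np.arange(n),
                    "arc_um": np.arange(n) * p.arc_step_px * pixel_size_um,
                    "channel": p.channel,
                    "intensity": p.intensities,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def registered_to_frame(profiles: list[RegisteredFractionProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            pd.DataFrame(
                {
                    "cell": p.cell_id,
                    "frame": p.frame_index,
                    "position_um": p.positions_um,
                    "fraction": p.values,
                    "perimeter_um": p.perimeter_um,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_registered(df: pd.DataFrame) -> list[RegisteredFractionProfile]:
    out = []
    for (cell, frame), sub in df.groupby(["cell", "frame"], sort=True):
        sub = sub.sort_values("position_um")
        perim = sub["perimeter_um"].iloc[0] if "perimeter_um" in sub else None
        out.append(
            RegisteredFractionProfile(
                values=sub["fraction"].to_numpy(),
                positions_um=sub["position_um"].to_numpy(),
                cell_id=str(cell),
                frame_index=int(frame),
                perimeter_um=None if perim is None or np.isnan(perim) else float(perim),
            )
        )
    return out


def average_to_frame(avg: AverageDistribution) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position_um": avg.positions_um,
            "mean_fraction": avg.mean,
            "ci_lower": avg.lower,
            "ci_upper": avg.upper,
        }
    )


def write_json(path: str | Path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
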