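"""Cell-periphery extraction and line-scan quantification.

The periphery of a cell is defined by sub-pixel iso-contouring of its binary
mask at level 0.5 (marching squares).  Intensity along the boundary is
measured with a band of configurable width (default 5 px) oriented along the
local normal and averaged, producing one intensity per ~1 px of arc; stacking
profiles over frames yields a kymograph (position x time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import AmbiguousMaskError, InconsistentInputError, NoCellError

__all__ = [
    "Contour",
    "PeripheryProfile",
    "Kymograph",
    "trace_boundary",
    "sample_line_scan",
    "build_kymograph",
    "resample_circular",
]

log = logging.getLogger(__name__)


@dataclass
class Contour:
    """Ordered closed boundary of one cell at one frame.

    ``points`` are (row, col) sub-pixel coordinates at ~1 px arc spacing,
    oriented in the direction of increasing ``atan2(row - cy, col - cx)``
    (counter-clockwise in array coordinates).  The first point is the one
    nearest the boundary pixel with the lexicographically smallest
    (row, col).  The path is closed implicitly: the last point connects back
    to the first.
    """

    points: np.ndarray  # (n, 2) float
    perimeter_px: float
    frame_index: int = 0

    def __len__(self) -> int:
        return len(self.points)

    @property
    def arc_step_px(self) -> float:
        return self.perimeter_px / len(self.points)


def _closed_arclength(points: np.ndarray) -> float:
    d = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def trace_boundary(
    cell_mask: np.ndarray, frame_index: int = 0, smoothing_sigma: float = 1.5
) -> Contour:
    """Trace the outer boundary of a single-cell mask.

    Interior holes are filled before contouring, so the result is always the
    outer boundary.  The raw marching-squares path is jagged at the pixel
    scale, which overestimates arc length by several percent; a circular
    Gaussian smoothing of the vertex coordinates (``smoothing_sigma``, in
    samples, skipped for very small contours) removes the pixelation and
    brings the perimeter within ~0.5% of the true outline for both smooth
    and polygonal shapes.  Raises :class:`NoCellError` for an empty mask and
    :class:`AmbiguousMaskError` when the mask has multiple 8-connected
    components.
    """
    m = np.asarray(cell_mask).astype(bool)
    if not m.any():
        raise NoCellError("empty cell mask")
    _, n_comp = measure.label(m, connectivity=2, return_num=True)
    if n_comp > 1:
        raise AmbiguousMaskError(f"mask has {n_comp} connected components")
    filled = ndi.binary_fill_holes(m)

    # pad so masks touching the border still yield one closed contour
    padded = np.pad(filled, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    pts = max(contours, key=len) - 1.0  # undo padding offset
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]

    if smoothing_sigma > 0 and len(pts) >= 12:
        pts = np.column_stack(
            [
                ndi.gaussian_filter1d(pts[:, 0], smoothing_sigma, mode="wrap"),
                ndi.gaussian_filter1d(pts[:, 1], smoothing_sigma, mode="wrap"),
            ]
        )

    # orient counter-clockwise in (row, col) array coordinates:
    # shoelace area with x=col, y=row must be positive
    x, y = pts[:, 1], pts[:, 0]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    if area2 < 0:
        pts = pts[::-1]

    # canonical start: nearest vertex to the smallest-(row, col) boundary pixel
    boundary_px = filled & ~ndi.binary_erosion(filled)
    rows, cols = np.nonzero(boundary_px)
    k = np.lexsort((cols, rows))[0]
    anchor = np.array([rows[k], cols[k]], dtype=float)
    start = int(np.argmin(((pts - anchor) ** 2).sum(axis=1)))
    pts = np.roll(pts, -start, axis=0)

    # resample to uniform ~1 px arc spacing
    perim = _closed_arclength(pts)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(int(round(perim)), 4)
    target = np.linspace(0.0, perim, n, endpoint=False)
    resampled = np.column_stack(
        [np.interp(target, s, closed[:, 0]), np.interp(target, s, closed[:, 1])]
    )
    return Contour(points=resampled, perimeter_px=perim, frame_index=frame_index)


@dataclass
class PeripheryProfile:
    """Intensities sampled along one cell's boundary for one channel/frame."""

    intensities: np.ndarray
    arc_step_px: float
    channel: str
    frame_index: int = 0
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise InconsistentInputError("profile intensities must be finite")

    def __len__(self) -> int:
        return len(self.intensities)


def sample_line_scan(
    image: np.ndarray,
    contour: Contour,
    width_px: int = 5,
    channel: str = "ch",
    cell_id: str = "cell",
) -> PeripheryProfile:
    """Measure intensity along the contour with a ``width_px`` line-scan.

    At each arc sample the intensity is the mean of ``width_px`` points
    spaced 1 px apart along the local normal, centered on the contour point
    (so a width of 5 averages 2 px inward, the point itself, and 2 px
    outward).  Values are bilinearly interpolated; sample coordinates that
    would fall outside the image are clamped to its edge and a warning is
    logged.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise InconsistentInputError("width_px must be odd and >= 1")
    img = np.asarray(image, dtype=float)
    pts = contour.points
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    offsets = np.arange(width_px) - width_px // 2  # symmetric about the contour
    coords = pts[None, :, :] + offsets[:, None, None] * normal[None, :, :]
    rr, cc = coords[..., 0], coords[..., 1]
    h, w = img.shape
    if (rr < 0).any() or (rr > h - 1).any() or (cc < 0).any() or (cc > w - 1).any():
        log.warning("line-scan band extends outside image; clamping to edge")
    rr = np.clip(rr, 0, h - 1)
    cc = np.clip(cc, 0, w - 1)
    samples = ndi.map_coordinates(img, [rr.ravel(), cc.ravel()], order=1, mode="nearest")
    band = samples.reshape(width_px, len(pts))
    return PeripheryProfile(
        intensities=band.mean(axis=0),
        arc_step_px=contour.arc_step_px,
        channel=channel,
        frame_index=contour.frame_index,
        cell_id=cell_id,
    )


def resample_circular(values: np.ndarray, n_out: int) -> np.ndarray:
    """Linear circular resampling of a periodic sequence to ``n_out`` samples."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    src = np.arange(n, dtype=float) / n
    dst = np.arange(n_out, dtype=float) / n_out
    return np.interp(dst, src, values, period=1.0)


@dataclass
class Kymograph:
    """Position x time intensity matrix for one cell and channel."""

    matrix: np.ndarray  # (n_rows, n_frames)
    arc_step_px: float
    frame_times_min: np.ndarray
    channel: str
    cell_id: str = "cell"


def build_kymograph(
    profiles: list[PeripheryProfile],
    n_rows: int,
    frame_interval_min: float = 20.0,
) -> Kymograph:
    """Stack per-frame profiles into a kymograph, resampling each to
    ``n_rows`` rows (linear, circular).  Columns are ordered by frame index."""
    if not profiles:
        raise InconsistentInputError("need at least one profile")
    channels = {p.channel for p in profiles}
    cells = {p.cell_id for p in profiles}
    if len(channels) > 1 or len(cells) > 1:
        raise InconsistentInputError(f"mixed channels/cells: {channels}, {cells}")
    ordered = sorted(profiles, key=lambda p: p.frame_index)
    cols = [resample_circular(p.intensities, n_rows) for p in ordered]
    times = np.array([p.frame_index * frame_interval_min for p in ordered])
    return Kymograph(
        matrix=np.column_stack(cols),
        arc_step_px=ordered[0].arc_step_px * len(ordered[0]) / n_rows,
        frame_times_min=times,
        channel=ordered[0].channel,
        cell_id=ordered[0].cell_id,
    )
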