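"""AFM topography analysis: flattening, RMS roughness, collagen D-period.

Raw AFM height maps carry a sample tilt, per-scan-line offsets and slow
bowing on top of the nanostructure of interest. The standard correction
chain is plane fit -> line (row offset) flattening -> second-order
polynomial background removal -> zero the minimum. Roughness is then the
square root of the second central moment of the heights, and the collagen
D-period is measured as the distance between maximum heights of adjoining
crests in line profiles drawn along fibrils.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.ndimage import map_coordinates

__all__ = [
    "Topography",
    "LineProfile",
    "RoughnessResult",
    "DPeriodResult",
    "plane_flatten",
    "line_flatten",
    "poly2_flatten",
    "zero_min",
    "flatten_chain",
    "rms_roughness",
    "roughness_summary",
    "extract_profile",
    "d_periods",
    "mean_d_period",
    "read_topography",
    "write_topography",
]


@dataclass
class Topography:
    """Height grid in nm with square pixels of side ``pixel_nm``."""

    heights: np.ndarray
    pixel_nm: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights contain non-finite values")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical extent (rows, cols) with pixel centers at integer * pixel_nm."""
        return ((self.shape[0] - 1) * self.pixel_nm, (self.shape[1] - 1) * self.pixel_nm)


@dataclass(frozen=True)
class LineProfile:
    """Heights sampled along a polyline; positions in nm from the start."""

    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        if p.shape != h.shape or p.ndim != 1:
            raise ValueError("positions and heights must be 1-D and equal length")
        if p[0] != 0 or np.any(np.diff(p) <= 0):
            raise ValueError("positions must start at 0 and increase monotonically")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "heights", h)


@dataclass(frozen=True)
class RoughnessResult:
    rms_nm: tuple  # per image
    mean_nm: float
    sd_nm: float


@dataclass(frozen=True)
class DPeriodResult:
    crest_positions_nm: np.ndarray
    unit_lengths_nm: np.ndarray  # adjacent crest distances
    mean_d_nm: float


def _coordinate_grids(t: Topography) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = t.shape
    y, x = np.mgrid[0:rows, 0:cols]
    return x.astype(float), y.astype(float)


def plane_flatten(t: Topography) -> Topography:
    """Subtract the least-squares best-fit plane a*x + b*y + c."""
    rows, cols = t.shape
    if rows * cols < 3 or (rows == 1 and cols == 1):
        raise ValueError("need at least 3 non-collinear pixels for a plane fit")
    x, y = _coordinate_grids(t)
    design = np.column_stack([x.ravel(), y.ravel(), np.ones(x.size)])
    coef, _, rank, _ = np.linalg.lstsq(design, t.heights.ravel(), rcond=None)
    if rank < 3 and rows > 1 and cols > 1:
        raise ValueError("degenerate grid for plane fitting")
    fitted = (design @ coef).reshape(t.shape)
    return Topography(t.heights - fitted, t.pixel_nm, dict(t.metadata))


def line_flatten(t: Topography, statistic: str = "median") -> Topography:
    """Subtract each scan row's median (or mean), removing per-line offsets.

    The median is robust to fibril crests occupying a minority of each row.
    """
    if statistic == "median":
        offsets = np.median(t.heights, axis=1, keepdims=True)
    elif statistic == "mean":
        offsets = t.heights.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return Topography(t.heights - offsets, t.pixel_nm, dict(t.metadata))


def poly2_flatten(t: Topography) -> Topography:
    """Subtract the least-squares 2-D polynomial of total degree <= 2."""
    rows, cols = t.shape
    if rows * cols < 6:
        raise ValueError("need at least 6 pixels for a quadratic surface fit")
    x, y = _coordinate_grids(t)
    xr, yr = x.ravel(), y.ravel()
    design = np.column_stack([np.ones(xr.size), xr, yr, xr**2, xr * yr, yr**2])
    coef, _, rank, _ = np.linalg.lstsq(design, t.heights.ravel(), rcond=None)
    if rank < 6 and rows > 2 and cols > 2:
        raise ValueError("rank-deficient quadratic design")
    fitted = (design @ coef).reshape(t.shape)
    return Topography(t.heights - fitted, t.pixel_nm, dict(t.metadata))


def zero_min(t: Topography) -> Topography:
    """Shift heights so the global minimum is exactly 0."""
    return Topography(t.heights - t.heights.min(), t.pixel_nm, dict(t.metadata))


_FLATTEN_OPS = {
    "plane": plane_flatten,
    "line": line_flatten,
    "poly2": poly2_flatten,
    "zero_min": zero_min,
}


def flatten_chain(t: Topography, steps=("plane", "line", "poly2", "zero_min")) -> Topography:
    """Apply a named sequence of flattening steps; the order used is recorded."""
    for step in steps:
        try:
            t = _FLATTEN_OPS[step](t)
        except KeyError:
            raise ValueError(f"unknown flattening step {step!r}") from None
    t.metadata["flatten_steps"] = list(steps)
    return t


def rms_roughness(t: Topography) -> float:
    """RMS roughness: sqrt of the second central moment of all heights (divisor N)."""
    h = t.heights
    return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def roughness_summary(ts: list[Topography]) -> RoughnessResult:
    """Per-image RMS roughness plus mean and sample sd (divisor n-1) across images."""
    if len(ts) < 2:
        raise ValueError("need >= 2 images for a mean/sd summary")
    rms = tuple(rms_roughness(t) for t in ts)
    arr = np.array(rms)
    return RoughnessResult(rms_nm=rms, mean_nm=float(arr.mean()), sd_nm=float(arr.std(ddof=1)))


def extract_profile(t: Topography, points_nm, spacing_nm: float | None = None) -> LineProfile:
    """Sample heights by bilinear interpolation along a polyline.

    ``points_nm`` is a sequence of (x, y) vertices in nm; pixel centers sit at
    integer multiples of ``pixel_nm``. Samples are spaced ``pixel_nm / 2``
    apart by default (always including both endpoints of the polyline).
    """
    pts = np.asarray(points_nm, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline needs >= 2 (x, y) vertices")
    max_row, max_col = t.extent_nm
    if (
        pts[:, 0].min() < 0
        or pts[:, 1].min() < 0
        or pts[:, 0].max() > max_col + 1e-9
        or pts[:, 1].max() > max_row + 1e-9
    ):
        raise ValueError("polyline extends outside the image")
    spacing = t.pixel_nm / 2 if spacing_nm is None else spacing_nm
    xs, ys, dist = [], [], 0.0
    positions = []
    for a, b in zip(pts[:-1], pts[1:]):
        seg = float(np.hypot(*(b - a)))
        n = max(int(np.ceil(seg / spacing)), 1)
        ts_ = np.linspace(0.0, 1.0, n + 1)
        if xs:  # drop duplicated vertex between segments
            ts_ = ts_[1:]
        xs.append(a[0] + ts_ * (b[0] - a[0]))
        ys.append(a[1] + ts_ * (b[1] - a[1]))
        positions.append(dist + ts_ * seg)
        dist += seg
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    pos = np.concatenate(positions)
    heights = map_coordinates(t.heights, [y / t.pixel_nm, x / t.pixel_nm], order=1, mode="nearest")
    return LineProfile(pos - pos[0], heights)


def d_periods(
    p: LineProfile,
    min_prominence_nm: float | None = None,
    min_separation_nm: float = 30.0,
) -> DPeriodResult:
    """Crest-to-crest D-unit lengths along one profile.

    Crests are local maxima with prominence >= ``min_prominence_nm``
    (default: 10% of the profile's peak-to-peak range) separated by at least
    ``min_separation_nm``. Unit lengths are successive crest distances.
    """
    h = p.heights
    if min_prominence_nm is None:
        min_prominence_nm = 0.1 * float(np.ptp(h))
    spacing = float(np.median(np.diff(p.positions)))
    distance = max(int(np.floor(min_separation_nm / spacing)), 1)
    idx, _ = signal.find_peaks(h, prominence=min_prominence_nm, distance=distance)
    if idx.size < 2:
        raise ValueError(f"found {idx.size} crest(s); need >= 2 to measure a D-unit")
    crest_pos = p.positions[idx]
    units = np.diff(crest_pos)
    return DPeriodResult(
        crest_positions_nm=crest_pos,
        unit_lengths_nm=units,
        mean_d_nm=float(units.mean()),
    )


def mean_d_period(results: list[DPeriodResult]) -> float:
    """Mean D-unit length pooled over all unit lengths of all profiles."""
    if not results:
        raise ValueError("no profile results supplied")
    pooled = np.concatenate([r.unit_lengths_nm for r in results])
    return float(pooled.mean())


def write_topography(t: Topography, path, sidecar_path=None) -> None:
    """Write a height map as a whitespace-delimited text matrix (nm) + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, t.heights, fmt="%.6f")
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    sidecar.write_text(json.dumps({"pixel_nm": t.pixel_nm, **t.metadata}, indent=2, default=float))


def read_topography(path, pixel_nm: float | None = None) -> Topography:
    """Read a plain-text matrix (or CSV) height map; pixel size from the JSON sidecar."""
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else None
    heights = np.loadtxt(path, delimiter=delim)
    meta: dict = {}
    if pixel_nm is None:
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_nm = float(meta.pop("pixel_nm", 1.0))
        else:
            pixel_nm = 1.0
    return Topography(heights, pixel_nm, meta)
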