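"""TPEF/SHG two-channel image analysis.

Glycation produces fluorescent pentosidine crosslinks in collagen, so the
collagen signal migrates from the second-harmonic (SHG) channel into the
two-photon fluorescence (TPEF) channel. The degree of migration is
quantified by the TPEF ratio

    TPEF ratio = I_TPEF / (I_SHG + I_TPEF)

and its complement the SHG ratio, where I_TPEF and I_SHG are channel means
averaged over randomly placed 100 x 100 px regions of interest (ROIs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MultimodalImage",
    "ROI",
    "RatioResult",
    "sample_rois",
    "roi_means",
    "compute_ratios",
    "ratio_series",
    "read_image_pair",
    "write_image_pair",
]


@dataclass
class MultimodalImage:
    """Paired TPEF and SHG intensity grids with physical pixel size (um)."""

    tpef: np.ndarray
    shg: np.ndarray
    pixel_um: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tpef = np.asarray(self.tpef, dtype=float)
        self.shg = np.asarray(self.shg, dtype=float)
        if self.tpef.shape != self.shg.shape or self.tpef.ndim != 2:
            raise ValueError("tpef and shg must be 2-D grids of equal shape")
        if self.tpef.min() < 0 or self.shg.min() < 0:
            raise ValueError("channel intensities must be non-negative")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tpef.shape


@dataclass(frozen=True)
class ROI:
    """A square region of interest, half-open pixel ranges, 0-based top-left corner."""

    row: int
    col: int
    size: int = 100

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.size), slice(self.col, self.col + self.size)


@dataclass(frozen=True)
class RatioResult:
    """Mean channel intensities, the two intensity ratios, and per-ROI diagnostics."""

    i_tpef: float
    i_shg: float
    tpef_ratio: float
    shg_ratio: float
    per_roi: tuple  # ((I_TPEF, I_SHG) per ROI)


def sample_rois(
    img: MultimodalImage,
    n: int = 10,
    size: int = 100,
    seed: int | None = 0,
    no_overlap: bool = False,
) -> list[ROI]:
    """Draw ``n`` ROI corners uniformly over all valid placements (seeded).

    Overlap between ROIs is permitted by default; ``no_overlap`` switches to
    rejection sampling (may fail on crowded images after 10000 attempts).
    """
    rows, cols = img.shape
    if rows < size or cols < size:
        raise ValueError(f"image {img.shape} smaller than ROI size {size}")
    rng = np.random.default_rng(seed)
    rois: list[ROI] = []
    attempts = 0
    while len(rois) < n:
        r = int(rng.integers(0, rows - size + 1))
        c = int(rng.integers(0, cols - size + 1))
        cand = ROI(r, c, size)
        if no_overlap and any(
            abs(cand.row - o.row) < size and abs(cand.col - o.col) < size for o in rois
        ):
            attempts += 1
            if attempts > 10000:
                raise ValueError("could not place non-overlapping ROIs")
            continue
        rois.append(cand)
    return rois


def roi_means(img: MultimodalImage, rois: list[ROI]) -> list[tuple[float, float]]:
    """Arithmetic mean of each channel over each ROI, as (I_TPEF, I_SHG) pairs."""
    out = []
    for roi in rois:
        sr, sc = roi.slices()
        if sr.stop > img.shape[0] or sc.stop > img.shape[1] or roi.row < 0 or roi.col < 0:
            raise ValueError(f"ROI {roi} exceeds image bounds {img.shape}")
        out.append((float(img.tpef[sr, sc].mean()), float(img.shg[sr, sc].mean())))
    return out


def compute_ratios(img: MultimodalImage, rois: list[ROI]) -> RatioResult:
    """TPEF and SHG ratios from ROI-averaged channel means (ratio of means).

    Per-ROI means are averaged across ROIs first; the ratios are then formed
    on the averaged intensities, so tpef_ratio + shg_ratio == 1 exactly.
    """
    per_roi = roi_means(img, rois)
    i_tpef = float(np.mean([p[0] for p in per_roi]))
    i_shg = float(np.mean([p[1] for p in per_roi]))
    total = i_tpef + i_shg
    if total <= 0:
        raise ValueError("zero total intensity over the sampled ROIs")
    tpef_ratio = i_tpef / total
    return RatioResult(
        i_tpef=i_tpef,
        i_shg=i_shg,
        tpef_ratio=tpef_ratio,
        shg_ratio=1.0 - tpef_ratio,  # complement by construction: the two ratios sum to 1 exactly
        per_roi=tuple(per_roi),
    )


def ratio_series(
    entries,
    n_rois: int = 10,
    roi_size: int = 100,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-(day, concentration) mean and sd of the ratios over groups of images.

    ``entries`` is an iterable of (concentration_mM, day, MultimodalImage).
    ROIs are drawn independently per image from one seeded stream. Output is
    ordered by day then concentration; empty groups are skipped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for conc, day, img in entries:
        rois = sample_rois(img, n=n_rois, size=roi_size, seed=int(rng.integers(2**31)))
        res = compute_ratios(img, rois)
        rows.append(
            {
                "concentration_mM": conc,
                "day": day,
                "tpef_ratio": res.tpef_ratio,
                "shg_ratio": res.shg_ratio,
            }
        )
    if not rows:
        raise ValueError("no images supplied")
    table = pd.DataFrame(rows)
    grouped = (
        table.groupby(["day", "concentration_mM"])
        .agg(
            tpef_ratio_mean=("tpef_ratio", "mean"),
            tpef_ratio_sd=("tpef_ratio", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            shg_ratio_mean=("shg_ratio", "mean"),
            shg_ratio_sd=("shg_ratio", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            n_images=("tpef_ratio", "size"),
        )
        .reset_index()
        .sort_values(["day", "concentration_mM"], kind="stable")
        .reset_index(drop=True)
    )
    return grouped


def write_image_pair(img: MultimodalImage, prefix) -> tuple[Path, Path]:
    """Write the two channels as 16-bit TIFFs plus a JSON metadata sidecar.

    Intensities are rounded and clipped to the uint16 range; callers keeping
    sub-integer precision should stay with the in-memory float grids.
    """
    import tifffile

    prefix = Path(prefix)
    tpef_path = prefix.with_name(prefix.name + "_tpef.tif")
    shg_path = prefix.with_name(prefix.name + "_shg.tif")
    for path, chan in ((tpef_path, img.tpef), (shg_path, img.shg)):
        tifffile.imwrite(path, np.clip(np.rint(chan), 0, 65535).astype(np.uint16))
    meta = {"pixel_um": img.pixel_um, **{k: v for k, v in img.metadata.items()}}
    prefix.with_name(prefix.name + "_meta.json").write_text(json.dumps(meta, indent=2, default=float))
    return tpef_path, shg_path


def read_image_pair(tpef_path, shg_path, pixel_um: float | None = None) -> MultimodalImage:
    """Read paired single-channel TIFFs, promoting to float64.

    If ``pixel_um`` is not given, it is taken from a ``*_meta.json`` sidecar
    next to the TPEF file (falling back to 1.0 with the convention that only
    ratios, which are pixel-size free, will be used).
    """
    import tifffile

    tpef = tifffile.imread(tpef_path).astype(float)
    shg = tifffile.imread(shg_path).astype(float)
    meta: dict = {}
    if pixel_um is None:
        sidecar = Path(str(tpef_path).replace("_tpef.tif", "_meta.json"))
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_um = float(meta.get("pixel_um", 1.0))
        else:
            pixel_um = 1.0
    return MultimodalImage(tpef=tpef, shg=shg, pixel_um=pixel_um, metadata=meta)
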