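"""Synthetic data emulating untreated and ribose-glycated pericardium.

Three generators reproduce the statistical structure the downstream
analyses assume, so every stage of the pipeline is testable end to end:

* labelled collagen Raman spectra (Lorentzian band model, glycation-
  dependent band changes, multiplicative gain, linear baseline, noise);
* two-channel TPEF/SHG image fields (wavy collagen + rectilinear elastin
  ridges), where a glycation parameter ``g`` transfers collagen signal
  from the SHG channel into the TPEF channel;
* AFM-style topographies with D-banded fibrils on a tilt plane with
  per-scan-line offsets and Gaussian roughness.

All randomness derives from a single integer seed via
``numpy.random.SeedSequence`` spawning — one sub-stream per generated
object — so equal seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .afm import Topography
from .multiphoton import MultimodalImage
from .spectra import SpectralDataset, Spectrum

__all__ = [
    "BandSpec",
    "GlycationPreset",
    "RamanGenConfig",
    "ImageGenConfig",
    "TopoGenConfig",
    "COLLAGEN_BANDS",
    "GLYCATION_DELTAS",
    "GLYCATION_BAND_FWHM",
    "CONCENTRATIONS_MM",
    "DAYS",
    "make_collagen_bands",
    "apply_glycation",
    "spectrum_from_bands",
    "untreated_reference",
    "generate_raman_dataset",
    "glycation_preset",
    "default_presets",
    "generate_image_pair",
    "noiseless_fields",
    "expected_channel_means",
    "expected_tpef_ratio",
    "fluor_transfer_for_ratio",
    "calibrate_channels",
    "generate_topography",
    "along_fiber_lines",
]

CONCENTRATIONS_MM = (0, 5, 50, 100, 200)
DAYS = (10, 20, 30)

# Collagen fingerprint bands: (center cm-1, FWHM cm-1, amplitude, assignment).
# Relative amplitudes are chosen so the CH2/CH3 band at 1451 and amide I at
# 1666 dominate, with the amide III doublet and the backbone/proline bands at
# intermediate height — the qualitative ordering seen in collagen-rich tissue.
COLLAGEN_BANDS: tuple[tuple[float, float, float, str], ...] = (
    (816.0, 12.0, 0.38, "proline"),
    (856.0, 12.0, 0.48, "hydroxyproline"),
    (873.0, 12.0, 0.42, "hydroxyproline"),
    (922.0, 12.0, 0.45, "C-C_alpha stretch"),
    (938.0, 12.0, 0.52, "C-C_alpha stretch"),
    (1002.0, 8.0, 0.55, "phenylalanine"),
    (1244.0, 14.0, 0.60, "amide III"),
    (1272.0, 14.0, 0.55, "amide III"),
    (1451.0, 16.0, 1.00, "CH2/CH3 collagen and elastin"),
    (1640.0, 20.0, 0.45, "water"),
    (1666.0, 18.0, 0.90, "amide I"),
)

# Amplitude change per unit effect_scale. Positive entries at centers absent
# from COLLAGEN_BANDS are added as new bands (widths below); negative entries
# reduce the nearest modeled band. The 1451 anchor is never touched, so the
# CH2-region decrease reported around 1442 cm-1 has no counterpart in this
# 11-band model; the amide III / amide I region decreases act on the 1272 and
# 1666 bands.
GLYCATION_DELTAS: dict[float, float] = {
    938.0: +0.15,
    1372.0: +0.20,  # broad putative ribose/crosslink band
    1634.0: +0.10,  # amide I secondary-structure shoulder
    1643.0: +0.10,
    922.0: -0.15,
    1272.0: -0.10,
    1666.0: -0.15,
}

# FWHM of bands added by glycation (cm-1); 1372 is deliberately broad.
GLYCATION_BAND_FWHM: dict[float, float] = {1372.0: 30.0, 1634.0: 14.0, 1643.0: 14.0}


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: Lorentzian line with peak ``amplitude`` at ``center``."""

    center: float  # cm-1
    width: float  # FWHM, cm-1
    amplitude: float  # arbitrary intensity units

    def __post_init__(self) -> None:
        if not 800.0 <= self.center <= 1750.0:
            raise ValueError(f"band center {self.center} outside the fingerprint region")
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be non-negative")


@dataclass(frozen=True)
class GlycationPreset:
    """Generator parameters for one (ribose concentration, incubation day) cell."""

    concentration_mM: float
    day: int
    effect_scale: float  # Raman band-change strength, 0..1
    fluor_transfer_g: float  # fraction of collagen signal moved into TPEF, 0..1
    roughness_rms_nm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_scale <= 1.0:
            raise ValueError("effect_scale must be in [0, 1]")
        if not 0.0 <= self.fluor_transfer_g <= 1.0:
            raise ValueError("fluor_transfer_g must be in [0, 1]")
        if self.concentration_mM == 0 and (self.effect_scale != 0 or self.fluor_transfer_g != 0):
            raise ValueError("untreated preset must have zero effect and zero transfer")
        if self.roughness_rms_nm < 0:
            raise ValueError("roughness must be non-negative")


# Calibration constants for the dose/time response (see docs/methods.md):
# response(c, d) = log1p(c / 5 mM) / log1p(200 mM / 5 mM) * (d / 30 days).
G_MAX = 0.26  # fluorescence transfer at 200 mM / 30 d: expected ratio (1+g)/2 = 0.63
ROUGHNESS_UNTREATED_NM = 11.64
ROUGHNESS_GLYCATED_NM = 21.78


def _dose_time_response(concentration_mM: float, day: int) -> float:
    dose = math.log1p(concentration_mM / 5.0) / math.log1p(200.0 / 5.0)
    return dose * (day / 30.0)


def glycation_preset(concentration_mM: float, day: int) -> GlycationPreset:
    """Default preset: effects rise log-like in concentration and linearly in day."""
    r = _dose_time_response(concentration_mM, day)
    return GlycationPreset(
        concentration_mM=concentration_mM,
        day=day,
        effect_scale=min(r, 1.0),
        fluor_transfer_g=min(G_MAX * r, 1.0),
        roughness_rms_nm=ROUGHNESS_UNTREATED_NM
        + (ROUGHNESS_GLYCATED_NM - ROUGHNESS_UNTREATED_NM) * r,
    )


def default_presets(day: int = 30) -> list[GlycationPreset]:
    """The five study concentrations (0, 5, 50, 100, 200 mM) at one time point."""
    return [glycation_preset(c, day) for c in CONCENTRATIONS_MM]


# --------------------------------------------------------------------------
# Raman spectra


@dataclass(frozen=True)
class RamanGenConfig:
    """Raman generator settings.

    ``noise_sd`` is a fraction of the maximum base band amplitude;
    ``effect_jitter_sd`` is the spot-to-spot heterogeneity of the glycation
    effect (absolute, on the 0-1 effect scale) emulating inhomogeneously
    distributed crosslinks; ``gain_sd`` is the sd of the log of the
    per-spectrum multiplicative acquisition gain EMSC is meant to remove.
    """

    axis_lo: float = 400.0
    axis_hi: float = 1800.0
    axis_step: float = 2.0
    baseline_slope_sd: float = 2e-4  # intensity per cm-1
    baseline_offset_sd: float = 0.05
    gain_sd: float = 0.10
    amp_jitter_sd: float = 0.03  # relative, per band
    effect_jitter_sd: float = 0.02
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.axis_lo >= self.axis_hi:
            raise ValueError("axis_lo must be < axis_hi")
        if self.axis_step <= 0:
            raise ValueError("axis_step must be positive")
        for name in ("baseline_slope_sd", "baseline_offset_sd", "gain_sd", "amp_jitter_sd",
                     "effect_jitter_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def axis(self) -> np.ndarray:
        n = int(round((self.axis_hi - self.axis_lo) / self.axis_step)) + 1
        return self.axis_lo + self.axis_step * np.arange(n)


def make_collagen_bands() -> list[BandSpec]:
    """The eleven collagen/elastin fingerprint bands of untreated tissue."""
    return [BandSpec(c, w, a) for c, w, a, _ in COLLAGEN_BANDS]


def apply_glycation(bands: list[BandSpec], effect_scale: float) -> list[BandSpec]:
    """Shift band amplitudes linearly with ``effect_scale`` per the delta table.

    Existing bands listed in :data:`GLYCATION_DELTAS` gain/lose amplitude
    (floored at 0); delta centers with no existing band are appended as new
    bands when the effect is nonzero. The 1451 anchor is left untouched.
    """
    if not 0.0 <= effect_scale <= 1.0:
        raise ValueError("effect_scale must be in [0, 1]")
    existing = {b.center for b in bands}
    out = []
    for b in bands:
        delta = GLYCATION_DELTAS.get(b.center)
        if delta is None or effect_scale == 0.0:
            out.append(b)
        else:
            out.append(replace(b, amplitude=max(b.amplitude + delta * effect_scale, 0.0)))
    if effect_scale > 0.0:
        for center, delta in GLYCATION_DELTAS.items():
            if delta > 0 and center not in existing:
                out.append(BandSpec(center, GLYCATION_BAND_FWHM[center], delta * effect_scale))
    return out


def spectrum_from_bands(bands: list[BandSpec], axis: np.ndarray) -> np.ndarray:
    """Sum of Lorentzian lines, each peaking at its band amplitude."""
    axis = np.asarray(axis, dtype=float)
    y = np.zeros_like(axis)
    for b in bands:
        gamma = b.width / 2.0
        y += b.amplitude * gamma**2 / ((axis - b.center) ** 2 + gamma**2)
    return y


def untreated_reference(cfg: RamanGenConfig) -> Spectrum:
    """Noiseless untreated spectrum (sum of base bands) — the EMSC pure component."""
    axis = cfg.axis
    return Spectrum(axis, spectrum_from_bands(make_collagen_bands(), axis))


def generate_raman_dataset(
    cfg: RamanGenConfig, presets: list[GlycationPreset], n_per_class: int
) -> SpectralDataset:
    """``n_per_class`` labelled spectra per preset on the configured axis.

    Each spectrum is built from the base bands with per-band relative
    amplitude jitter, glycated at ``preset.effect_scale`` plus spot
    heterogeneity (clipped to [0, 1]; untreated spots can thus show small
    native-crosslink-like effects), scaled by a log-normal gain, and summed
    with a random linear baseline and i.i.d. Gaussian noise.
    """
    if not presets:
        raise ValueError("presets must be non-empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    axis = cfg.axis
    base = make_collagen_bands()
    max_amp = max(b.amplitude for b in base)
    streams = np.random.SeedSequence(cfg.seed).spawn(len(presets) * n_per_class)
    X = np.empty((len(streams), axis.size))
    rows = []
    idx = 0
    for preset in presets:
        for j in range(n_per_class):
            rng = np.random.default_rng(streams[idx])
            effect = float(np.clip(preset.effect_scale + rng.normal(0, cfg.effect_jitter_sd), 0, 1))
            factors = np.clip(1.0 + rng.normal(0, cfg.amp_jitter_sd, len(base)), 0, None)
            jittered = [replace(b, amplitude=b.amplitude * f) for b, f in zip(base, factors)]
            bands = apply_glycation(jittered, effect)
            gain = math.exp(rng.normal(0, cfg.gain_sd))
            slope = rng.normal(0, cfg.baseline_slope_sd)
            offset = rng.normal(0, cfg.baseline_offset_sd)
            baseline = offset + slope * (axis - axis.mean())
            noise = rng.normal(0, cfg.noise_sd * max_amp, axis.size)
            X[idx] = gain * spectrum_from_bands(bands, axis) + baseline + noise
            rows.append(
                {
                    "spectrum_id": f"s{idx:04d}",
                    "concentration_mM": preset.concentration_mM,
                    "day": preset.day,
                    "sample_id": f"c{preset.concentration_mM:g}_d{preset.day}_r{j % 3}",
                    "grid_row": j // 10,
                    "grid_col": j % 10,
                }
            )
            idx += 1
    return SpectralDataset(axis, X, pd.DataFrame(rows))


# --------------------------------------------------------------------------
# TPEF/SHG image pairs


@dataclass(frozen=True)
class ImageGenConfig:
    """Two-channel image generator settings (intensities in arbitrary units)."""

    size_px: int = 2048
    pixel_um: float = 225.0 / 2048.0
    n_collagen_fibers: int = 400
    n_elastin_fibers: int = 200
    collagen_amp: float = 100.0
    elastin_amp: float = 100.0
    collagen_width_px: float = 3.0
    elastin_width_px: float = 4.0
    waviness: float = 0.5  # sine perturbation amplitude, units of 25 px
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 100:
            raise ValueError("size_px must be >= 100 to admit 100x100 ROIs")
        for name in ("collagen_amp", "elastin_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")


def _render_ridges(
    rng: np.random.Generator,
    size: int,
    n_fibers: int,
    amp: float,
    width_px: float,
    wave_amp_px: float,
    parallel: bool,
) -> np.ndarray:
    """Render fibers as ridges with Gaussian cross-section, one column at a time.

    Collagen fibers get independent small slopes and a sinusoidal (wavy)
    centerline; elastin fibers share one slope (parallel, rectilinear) and no
    waviness. Both populations use jittered stratified vertical placement, so
    fields are densely and fairly uniformly packed at the 100-px ROI scale —
    the morphology of well-organized unidirectional fiber bundles.
    """
    field = np.zeros((size, size))
    cols = np.arange(size, dtype=float)
    common_slope = rng.uniform(-0.1, 0.1)
    reach = int(np.ceil(4 * width_px))
    offsets = np.arange(-reach, reach + 1)
    spacing = size / max(n_fibers, 1)
    base_rows = (np.arange(n_fibers) + 0.5) * spacing + rng.uniform(0, spacing)
    for i in range(n_fibers):
        if parallel:
            y0 = base_rows[i] + rng.normal(0, 0.5 * spacing)
            slope = common_slope + rng.normal(0, 0.01)
            center = y0 + slope * cols
        else:
            y0 = base_rows[i] + rng.normal(0, 1.5 * spacing)
            slope = rng.uniform(-0.05, 0.05)
            wavelength = rng.uniform(250, 600)
            phase = rng.uniform(0, 2 * np.pi)
            center = y0 + slope * cols + wave_amp_px * np.sin(2 * np.pi * cols / wavelength + phase)
        brightness = amp * rng.uniform(0.8, 1.2)
        rows = np.rint(center)[None, :].astype(int) + offsets[:, None]
        dy = rows - center[None, :]
        vals = brightness * np.exp(-(dy**2) / (2 * width_px**2))
        valid = (rows >= 0) & (rows < size)
        col_idx = np.broadcast_to(cols.astype(int), rows.shape)
        np.add.at(field, (rows[valid], col_idx[valid]), vals[valid])
    return field


@lru_cache(maxsize=4)
def _noiseless_fields_cached(cfg: ImageGenConfig) -> tuple[np.ndarray, np.ndarray]:
    coll_ss, elas_ss, _ = np.random.SeedSequence(cfg.seed).spawn(3)
    collagen = _render_ridges(
        np.random.default_rng(coll_ss),
        cfg.size_px,
        cfg.n_collagen_fibers,
        cfg.collagen_amp,
        cfg.collagen_width_px,
        wave_amp_px=cfg.waviness * 25.0,
        parallel=False,
    )
    elastin = _render_ridges(
        np.random.default_rng(elas_ss),
        cfg.size_px,
        cfg.n_elastin_fibers,
        cfg.elastin_amp,
        cfg.elastin_width_px,
        wave_amp_px=0.0,
        parallel=True,
    )
    return collagen, elastin


def noiseless_fields(cfg: ImageGenConfig) -> tuple[np.ndarray, np.ndarray]:
    """The deterministic (given seed) collagen and elastin fiber fields.

    Fields are linear in the channel amplitudes, so renders are cached at unit
    amplitude and rescaled; callers must not mutate the returned arrays.
    """
    unit = replace(cfg, collagen_amp=1.0, elastin_amp=1.0)
    collagen, elastin = _noiseless_fields_cached(unit)
    return cfg.collagen_amp * collagen, cfg.elastin_amp * elastin


def generate_image_pair(cfg: ImageGenConfig, preset: GlycationPreset) -> MultimodalImage:
    """Two-channel image with collagen signal transfer g = preset.fluor_transfer_g.

        SHG  = (1 - g) * collagen + |N(0, noise_sd)|
        TPEF = elastin + g * collagen + |N(0, noise_sd)|

    Folded-normal noise keeps both channels non-negative without clipping and
    has the exact mean ``noise_sd * sqrt(2/pi)``, so expected channel means —
    and hence the expected TPEF ratio — are available in closed form (see
    :func:`expected_channel_means`). At noise_sd = 0 the channels conserve
    signal exactly: TPEF + SHG = elastin + collagen for any g.
    """
    g = preset.fluor_transfer_g
    collagen, elastin = noiseless_fields(cfg)
    _, _, noise_ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng = np.random.default_rng(noise_ss)
    shape = collagen.shape
    tpef = elastin + g * collagen + np.abs(rng.normal(0, cfg.noise_sd, shape))
    shg = (1.0 - g) * collagen + np.abs(rng.normal(0, cfg.noise_sd, shape))
    meta = {
        "seed": cfg.seed,
        "g": g,
        "concentration_mM": preset.concentration_mM,
        "day": preset.day,
        "collagen_mean": float(collagen.mean()),
        "elastin_mean": float(elastin.mean()),
        "noise_mean": cfg.noise_sd * math.sqrt(2 / math.pi),
        "expected_tpef_ratio": expected_tpef_ratio(cfg, g, fields=(collagen, elastin)),
    }
    return MultimodalImage(tpef=tpef, shg=shg, pixel_um=cfg.pixel_um, metadata=meta)


def expected_channel_means(
    cfg: ImageGenConfig, g: float, fields: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[float, float]:
    """Exact expected (TPEF, SHG) full-image means for transfer fraction ``g``."""
    collagen, elastin = noiseless_fields(cfg) if fields is None else fields
    c = cfg.noise_sd * math.sqrt(2 / math.pi)  # folded-normal mean
    m_coll, m_elas = float(collagen.mean()), float(elastin.mean())
    return m_elas + g * m_coll + c, (1.0 - g) * m_coll + c


def expected_tpef_ratio(
    cfg: ImageGenConfig, g: float, fields: tuple[np.ndarray, np.ndarray] | None = None
) -> float:
    """Closed-form expected TPEF ratio: (mE + g mC + c) / (mE + mC + 2c)."""
    m_tpef, m_shg = expected_channel_means(cfg, g, fields)
    return m_tpef / (m_tpef + m_shg)


def fluor_transfer_for_ratio(cfg: ImageGenConfig, target_ratio: float) -> float:
    """Invert the closed-form expected ratio: the ``g`` that yields ``target_ratio``."""
    collagen, elastin = noiseless_fields(cfg)
    c = cfg.noise_sd * math.sqrt(2 / math.pi)
    m_coll, m_elas = float(collagen.mean()), float(elastin.mean())
    g = (target_ratio * (m_elas + m_coll + 2 * c) - m_elas - c) / m_coll
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"target ratio {target_ratio} needs transfer g={g:.3f} outside [0, 1]")
    return g


def calibrate_channels(cfg: ImageGenConfig) -> ImageGenConfig:
    """Rescale elastin_amp so the expected TPEF and SHG means are equal at g = 0."""
    collagen, elastin = noiseless_fields(cfg)
    if elastin.mean() == 0:
        raise ValueError("elastin field is empty; cannot calibrate")
    scale = float(collagen.mean() / elastin.mean())
    return replace(cfg, elastin_amp=cfg.elastin_amp * scale)


# --------------------------------------------------------------------------
# AFM topographies


@dataclass(frozen=True)
class TopoGenConfig:
    """Topography generator settings (heights in nm, square pixels)."""

    size_px: int = 512
    pixel_nm: float = 2500.0 / 512.0
    d_period_nm: float = 63.8
    band_amp_nm: float = 3.0
    background_rms_nm: float = 0.3
    tilt_coeffs: tuple[float, float, float] = (0.05, 0.05, 0.0)  # nm/px, nm/px, nm
    line_offset_sd_nm: float = 2.0
    fiber_angle_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 2 or self.pixel_nm <= 0:
            raise ValueError("size_px must be >= 2 and pixel_nm positive")
        if self.d_period_nm <= 2 * self.pixel_nm:
            raise ValueError(
                f"d_period_nm {self.d_period_nm} violates Nyquist (<= 2 * {self.pixel_nm:.3f} nm)"
            )
        for name in ("band_amp_nm", "background_rms_nm", "line_offset_sd_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def generate_topography(cfg: TopoGenConfig) -> Topography:
    """D-banded fibril topography: tilt plane + line offsets + banding + roughness.

    Banding is a raised cosine, ``band_amp/2 * (1 + cos(2 pi u / d))`` with
    ``u`` the nm coordinate along the fiber direction, so it is non-negative
    and crest maxima are unambiguous. Seed-deterministic.
    """
    n = cfg.size_px
    y, x = np.mgrid[0:n, 0:n].astype(float)
    a, b, c = cfg.tilt_coeffs
    tilt = a * x + b * y + c
    theta = math.radians(cfg.fiber_angle_deg)
    u = cfg.pixel_nm * (x * math.cos(theta) + y * math.sin(theta))
    banding = cfg.band_amp_nm / 2.0 * (1.0 + np.cos(2 * np.pi * u / cfg.d_period_nm))
    line_ss, noise_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    offsets = np.random.default_rng(line_ss).normal(0, cfg.line_offset_sd_nm, (n, 1))
    noise = np.random.default_rng(noise_ss).normal(0, cfg.background_rms_nm, (n, n))
    heights = tilt + offsets + banding + noise
    meta = {
        "seed": cfg.seed,
        "d_period_nm": cfg.d_period_nm,
        "fiber_angle_deg": cfg.fiber_angle_deg,
        "pixel_nm": cfg.pixel_nm,
    }
    return Topography(heights, cfg.pixel_nm, meta)


def along_fiber_lines(t: Topography, n: int = 6, angle_deg: float | None = None) -> list[np.ndarray]:
    """``n`` straight polylines along the fiber direction, spread across the image.

    Lines are centered on the image, offset perpendicular to the fiber axis,
    and shrunk to stay inside the bounds. Angle defaults to the generator's
    ``fiber_angle_deg`` recorded in the metadata (0 if absent).
    """
    if angle_deg is None:
        angle_deg = float(t.metadata.get("fiber_angle_deg", 0.0))
    theta = math.radians(angle_deg)
    d = np.array([math.cos(theta), math.sin(theta)])
    perp = np.array([-math.sin(theta), math.cos(theta)])
    ext_r, ext_c = t.extent_nm
    center = np.array([ext_c / 2.0, ext_r / 2.0])  # (x, y) in nm
    span = 0.8 * min(ext_r, ext_c)
    offsets = np.linspace(-span / 2, span / 2, n + 2)[1:-1]
    half = 0.49 * min(ext_r, ext_c)
    lines = []
    for off in offsets:
        p0 = center + off * perp - half * d
        p1 = center + off * perp + half * d
        seg = np.vstack([p0, p1])
        np.clip(seg[:, 0], 0, ext_c, out=seg[:, 0])
        np.clip(seg[:, 1], 0, ext_r, out=seg[:, 1])
        lines.append(seg)
    return lines
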