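"""Raman spectrum containers and preprocessing.

The preprocessing chain mirrors standard collagen-tissue Raman workflows:
crop to the 800-1750 cm-1 fingerprint region, extended multiplicative
signal correction (EMSC) against an untreated-tissue reference spectrum,
and normalization to the CH2/CH3 deformation band at 1451 cm-1.

EMSC decomposes a measured spectrum ``s`` into a scaled copy of a pure
reference ``r`` plus a small set of slowly varying background components
``B`` by ordinary least squares::

    s  =  b * r  +  B @ a  +  e

The corrected spectrum is ``(s - B @ a) / b = r + e / b``: background is
removed, the multiplicative acquisition gain is divided out, and the
chemical residual ``e`` (the part carrying class information) is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "EMSCFit",
    "crop_fingerprint",
    "build_emsc_basis",
    "emsc_correct",
    "normalize_at",
    "preprocess_dataset",
    "read_spectra_csv",
    "write_spectra_csv",
]


@dataclass(frozen=True)
class Spectrum:
    """A single Raman spectrum on a strictly increasing wavenumber axis."""

    wavenumbers: np.ndarray  # cm-1
    intensities: np.ndarray  # arbitrary units

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.shape != y.shape:
            raise ValueError("wavenumbers and intensities must be 1-D and equal length")
        if w.size < 2 or np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing with >= 2 points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(y))):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def interpolated_to(self, axis: np.ndarray) -> "Spectrum":
        """Linearly interpolate onto ``axis`` (must lie within the spectrum's range)."""
        axis = np.asarray(axis, dtype=float)
        if axis[0] < self.wavenumbers[0] - 1e-9 or axis[-1] > self.wavenumbers[-1] + 1e-9:
            raise ValueError("target axis extends beyond the spectrum's wavenumber range")
        return Spectrum(axis, np.interp(axis, self.wavenumbers, self.intensities))


@dataclass
class SpectralDataset:
    """Spectra sharing one wavenumber axis, with per-spectrum labels.

    ``intensities`` is (n_spectra, n_wavenumbers); ``labels`` carries at
    least ``spectrum_id``, ``concentration_mM``, ``day`` and ``sample_id``.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ValueError("intensity matrix width must match the wavenumber axis")
        if len(self.labels) == 0:
            self.labels = pd.DataFrame(
                {"spectrum_id": [f"s{i:04d}" for i in range(len(self))]}
            )
        if len(self.labels) != len(self):
            raise ValueError("labels must have one row per spectrum")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavenumbers, self.intensities[i])


@dataclass(frozen=True)
class EMSCFit:
    """Result of fitting one spectrum against the EMSC model."""

    b: float  # multiplicative coefficient on the reference
    a: np.ndarray  # background coefficients, one per basis column
    corrected: Spectrum
    residual_norm: float  # euclidean norm of the least-squares residual


def crop_fingerprint(s: Spectrum, lo: float = 800.0, hi: float = 1750.0) -> Spectrum:
    """Restrict a spectrum to the closed wavenumber interval [lo, hi]."""
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(f"no wavenumbers inside [{lo}, {hi}]")
    return Spectrum(s.wavenumbers[mask], s.intensities[mask])


def build_emsc_basis(reference: Spectrum, n_background: int = 5, kind: str = "hats") -> np.ndarray:
    """Background design matrix over the reference axis, one column per component.

    ``kind='hats'``: piecewise-linear hat functions on ``n_background`` equally
    spaced knots spanning the axis (a linear spline basis — n genuinely linear
    pieces that together span constant and slowly varying backgrounds).
    ``kind='poly'``: monomials of degree 0..n_background-1 in the axis rescaled
    to [-1, 1]. Every column is scaled to unit maximum absolute value.
    """
    if n_background < 1:
        raise ValueError("n_background must be >= 1")
    w = reference.wavenumbers
    if kind == "hats":
        if n_background == 1:
            return np.ones((w.size, 1))
        knots = np.linspace(w[0], w[-1], n_background)
        cols = []
        for i, k in enumerate(knots):
            left = knots[i - 1] if i > 0 else k
            right = knots[i + 1] if i < n_background - 1 else k
            col = np.zeros_like(w)
            if i > 0:
                m = (w >= left) & (w <= k)
                col[m] = (w[m] - left) / (k - left)
            if i < n_background - 1:
                m = (w >= k) & (w <= right)
                col[m] = (right - w[m]) / (right - k)
            if i == 0:
                col[w <= k] = 1.0
            if i == n_background - 1:
                col[w >= k] = 1.0
            cols.append(col)
        basis = np.column_stack(cols)
    elif kind == "poly":
        x = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
        basis = np.column_stack([x**d for d in range(n_background)])
    else:
        raise ValueError(f"unknown basis kind {kind!r}")
    return basis / np.abs(basis).max(axis=0)


def emsc_correct(s: Spectrum, reference: Spectrum, basis: np.ndarray) -> EMSCFit:
    """Fit the EMSC model by ordinary least squares and return the corrected spectrum."""
    if not np.array_equal(s.wavenumbers, reference.wavenumbers):
        raise ValueError("spectrum and reference must share one wavenumber axis")
    basis = np.asarray(basis, dtype=float)
    if basis.shape[0] != len(reference):
        raise ValueError("basis rows must match the axis length")
    design = np.column_stack([reference.intensities, basis])
    coef, _, _, _ = np.linalg.lstsq(design, s.intensities, rcond=None)
    b = float(coef[0])
    a = coef[1:]
    if abs(b) < 1e-8:
        raise ValueError("degenerate EMSC fit: multiplicative coefficient ~ 0")
    corrected = (s.intensities - basis @ a) / b
    residual = s.intensities - design @ coef
    return EMSCFit(
        b=b,
        a=a,
        corrected=Spectrum(s.wavenumbers, corrected),
        residual_norm=float(np.linalg.norm(residual)),
    )


def normalize_at(s: Spectrum, center: float = 1451.0, half_window: float = 5.0) -> Spectrum:
    """Divide a spectrum by its maximum intensity within ``center +/- half_window``.

    The window maximum (rather than a single-point lookup) makes the anchor
    robust to axis discretization.
    """
    mask = np.abs(s.wavenumbers - center) <= half_window
    if not mask.any():
        raise ValueError(f"axis does not cover the anchor window {center} +/- {half_window}")
    anchor = float(s.intensities[mask].max())
    if anchor <= 0:
        raise ValueError(f"non-positive anchor intensity at {center} cm-1")
    return Spectrum(s.wavenumbers, s.intensities / anchor)


def preprocess_dataset(
    ds: SpectralDataset,
    reference: Spectrum,
    lo: float = 800.0,
    hi: float = 1750.0,
    n_background: int = 5,
    basis_kind: str = "hats",
    anchor: float = 1451.0,
    half_window: float = 5.0,
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Crop, EMSC-correct and normalize every spectrum in a dataset.

    Returns the preprocessed dataset (labels preserved) and a per-spectrum
    fit log with the EMSC multiplicative coefficient ``b`` and residual norm.
    Errors are re-raised with the offending spectrum's id.
    """
    ref = crop_fingerprint(reference, lo, hi)
    basis = build_emsc_basis(ref, n_background, kind=basis_kind)
    out = np.empty((len(ds), len(ref)))
    log_rows = []
    ids = ds.labels["spectrum_id"].tolist()
    for i in range(len(ds)):
        try:
            s = crop_fingerprint(ds.spectrum(i), lo, hi)
            if not np.array_equal(s.wavenumbers, ref.wavenumbers):
                s = s.interpolated_to(ref.wavenumbers)
            fit = emsc_correct(s, ref, basis)
            norm = normalize_at(fit.corrected, anchor, half_window)
        except ValueError as exc:
            raise ValueError(f"preprocessing failed for spectrum {ids[i]!r}: {exc}") from exc
        out[i] = norm.intensities
        log_rows.append({"spectrum_id": ids[i], "b": fit.b, "residual_norm": fit.residual_norm})
    return (
        SpectralDataset(ref.wavenumbers, out, ds.labels.reset_index(drop=True)),
        pd.DataFrame(log_rows),
    )


def write_spectra_csv(ds: SpectralDataset, spectra_path, labels_path=None) -> None:
    """Write a dataset as a wide CSV (wavenumber_cm1 + one column per spectrum)."""
    ids = ds.labels["spectrum_id"].tolist()
    table = pd.DataFrame(ds.intensities.T, columns=ids)
    table.insert(0, "wavenumber_cm1", ds.wavenumbers)
    table.to_csv(spectra_path, index=False)
    if labels_path is not None:
        ds.labels.to_csv(labels_path, index=False)


def read_spectra_csv(spectra_path, labels_path=None) -> SpectralDataset:
    """Read the wide CSV spectral format (inverse of :func:`write_spectra_csv`)."""
    table = pd.read_csv(spectra_path)
    if table.columns[0] != "wavenumber_cm1":
        warnings.warn("first column is not 'wavenumber_cm1'; assuming it is the axis")
    w = table.iloc[:, 0].to_numpy(dtype=float)
    X = table.iloc[:, 1:].to_numpy(dtype=float).T
    labels = (
        pd.read_csv(labels_path)
        if labels_path is not None
        else pd.DataFrame({"spectrum_id": list(table.columns[1:])})
    )
    return SpectralDataset(w, X, labels)
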