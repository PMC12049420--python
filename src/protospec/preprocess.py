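"""Deterministic spectral conditioning.

The fixed-grid pipeline used ahead of every model: trim to the informative
wavenumber window (default 600-1640 cm^-1, a closed interval), resample by
piecewise-linear interpolation onto a uniform grid with a fixed number of
points (default 950, endpoints included), then either per-spectrum min-max
normalisation (encoder path) or per-feature standardisation
z = (x - mu) / sigma with population sigma (PCA/LDA path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import LabeledDataset, Spectrum, SpectraValidationError

__all__ = [
    "PreprocessConfig",
    "trim",
    "resample",
    "normalize_spectrum",
    "standardize_features",
    "apply_standardization",
    "preprocess_dataset",
]


@dataclass
class PreprocessConfig:
    """Trim window, target grid length and normalisation switches.

    ``standardize`` is off by default (the encoder path); the PCA/LDA path
    turns it on and fits mu/sigma on training rows only.
    """

    trim_lo: float = 600.0
    trim_hi: float = 1640.0
    n_points: int = 950
    spectrum_norm: str = "minmax"  # or "none"
    standardize: bool = False

    def __post_init__(self):
        if not self.trim_lo < self.trim_hi:
            raise ValueError(f"trim_lo must be < trim_hi, got {self.trim_lo}, {self.trim_hi}")
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")
        if self.spectrum_norm not in ("minmax", "none"):
            raise ValueError(f"unknown spectrum_norm {self.spectrum_norm!r}")

    def grid(self) -> np.ndarray:
        return np.linspace(self.trim_lo, self.trim_hi, self.n_points)


def trim(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep exactly the points with lo <= wavenumber <= hi (closed interval)."""
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if mask.sum() < 2:
        raise SpectraValidationError(
            f"spectrum {spectrum.id!r}: fewer than 2 points survive trimming to [{lo}, {hi}]")
    return Spectrum(spectrum.wavenumbers[mask], spectrum.intensities[mask],
                    dict(spectrum.meta))


def resample(spectrum: Spectrum, n_points: int, lo: float, hi: float) -> Spectrum:
    """Linear interpolation onto the uniform n-point grid from lo to hi inclusive.

    Extrapolation is refused: the spectrum must cover [lo, hi].
    """
    if spectrum.wavenumbers[0] > lo or spectrum.wavenumbers[-1] < hi:
        raise SpectraValidationError(
            f"spectrum {spectrum.id!r} spans "
            f"[{spectrum.wavenumbers[0]:g}, {spectrum.wavenumbers[-1]:g}], "
            f"does not cover [{lo:g}, {hi:g}]; refusing to extrapolate")
    grid = np.linspace(lo, hi, n_points)
    return Spectrum(grid, np.interp(grid, spectrum.wavenumbers, spectrum.intensities),
                    dict(spectrum.meta))


def normalize_spectrum(spectrum: Spectrum, mode: str = "minmax") -> Spectrum:
    if mode == "none":
        return spectrum
    if mode != "minmax":
        raise ValueError(f"unknown normalisation mode {mode!r}")
    y = spectrum.intensities
    span = y.max() - y.min()
    if span == 0:  # constant spectrum: defined to map to all-zeros
        y = np.zeros_like(y)
    else:
        y = (y - y.min()) / span
    return Spectrum(spectrum.wavenumbers, y, dict(spectrum.meta))


def standardize_features(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z = (x - mu) / sigma with population sigma.

    Returns ``(z, mu, sigma, zero_variance_mask)``. Zero-variance columns are
    set to all-zeros (keeping grid alignment) and flagged in the mask; their
    sigma is reported as 0. Requires at least 2 rows.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("standardize_features needs a 2-D matrix with >= 2 rows")
    mu = matrix.mean(axis=0)
    sigma = matrix.std(axis=0)  # population (ddof=0)
    zero_var = sigma == 0
    safe = np.where(zero_var, 1.0, sigma)
    z = (matrix - mu) / safe
    z[:, zero_var] = 0.0
    return z, mu, sigma, zero_var


def apply_standardization(matrix: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
                          zero_var: np.ndarray | None = None) -> np.ndarray:
    """Apply previously fitted mu/sigma (e.g. to a held-out fold)."""
    if zero_var is None:
        zero_var = sigma == 0
    safe = np.where(zero_var, 1.0, sigma)
    z = (np.asarray(matrix, dtype=float) - mu) / safe
    z[:, zero_var] = 0.0
    return z


def preprocess_dataset(dataset: LabeledDataset,
                       cfg: PreprocessConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Trim, resample and per-spectrum-normalise every spectrum.

    Returns ``(matrix, grid)`` where ``matrix`` is (n_spectra, n_points) and
    ``grid`` the shared wavenumber axis in cm^-1. Per-feature standardisation
    is deliberately not part of this step — it must be fitted on training rows
    only (see :func:`standardize_features`).
    """
    cfg = cfg or PreprocessConfig()
    rows = []
    for spec in dataset.spectra:
        # resample interpolates from the full spectrum: the target grid itself
        # enforces the trim window, and interpolation at the window edges needs
        # the neighbouring points that a prior hard trim could discard
        s = resample(spec, cfg.n_points, cfg.trim_lo, cfg.trim_hi)
        s = normalize_spectrum(s, cfg.spectrum_norm)
        rows.append(s.intensities)
    return np.stack(rows), cfg.grid()
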