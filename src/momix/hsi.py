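"""Hyperspectral feature extraction.

The ROI mean spectrum of a 150-band reflectance cube (470-900 nm) is
summarized by per-band statistics, 10-nm binned means (kept on the raw scale
to retain the original value range), a unit-interval normalized spectrum, its
first- and second-order spectral-phasor terms, a fourth-order polynomial fit
and the moduli of the first ten Fourier harmonics.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from numpy.polynomial import polynomial as npoly

from .core import ParameterError, circular_roi_mask, saturation_mask
from .af import spectral_phasor

logger = logging.getLogger("momix")

__all__ = [
    "white_reference_correct",
    "bin_mean_10nm",
    "normalize_unit_interval",
    "polynomial_descriptors",
    "fourier_moduli",
    "extract_hsi_features",
]


def white_reference_correct(cube: np.ndarray, white_cube: np.ndarray) -> np.ndarray:
    """Per-band, per-pixel division by the white-calibration cube.

    Removes the spectral dependence of the illumination; the result is a
    unitless reflectance.  Non-positive white values yield NaN with a warning.
    """
    cube = np.asarray(cube, dtype=float)
    white = np.asarray(white_cube, dtype=float)
    if cube.shape[-1] != white.shape[-1]:
        raise ParameterError("sample and white cubes disagree on band axis")
    bad = white <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive white-reference values masked", stacklevel=2
        )
        white = np.where(bad, np.nan, white)
    return cube / white


def bin_mean_10nm(mean_spectrum, wavelengths, start=470.0, stop=900.0, width=10.0):
    """Means over contiguous half-open wavelength bins tiling [start, stop).

    Bin value = mean of the bands whose centers fall in the interval; empty
    bins are NaN.  With the published 470-900 nm range and 10-nm width this
    tiles the span into 43 intervals.
    """
    spectrum = np.asarray(mean_spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wavelengths) < 0):
        raise ParameterError("wavelengths must be sorted")
    edges = np.arange(start, stop + width / 2, width)
    out = np.full(edges.size - 1, np.nan)
    for i in range(out.size):
        members = (wavelengths >= edges[i]) & (wavelengths < edges[i + 1])
        if members.any():
            out[i] = np.nanmean(spectrum[members])
    return out


def normalize_unit_interval(spectrum) -> np.ndarray:
    """Min-max normalization to [0, 1]; constant input maps to all zeros."""
    s = np.asarray(spectrum, dtype=float)
    if s.size < 2:
        raise ParameterError("need at least 2 points to normalize")
    lo, hi = np.nanmin(s), np.nanmax(s)
    if hi - lo == 0:
        warnings.warn("constant spectrum: unit-interval normalization degenerate", stacklevel=2)
        return np.zeros_like(s)
    return (s - lo) / (hi - lo)


def polynomial_descriptors(normalized_spectrum, wavelengths, degree: int = 4) -> np.ndarray:
    """Least-squares polynomial fit coefficients, lowest order first.

    The fit uses the wavelength coordinate rescaled to [0, 1] for numerical
    conditioning; coefficients are reported in that coordinate.
    """
    y = np.asarray(normalized_spectrum, dtype=float)
    w = np.asarray(wavelengths, dtype=float)
    if y.size < degree + 1:
        raise ParameterError(f"need at least {degree + 1} points for degree {degree}")
    span = w.max() - w.min()
    if span == 0:
        raise ParameterError("degenerate wavelength axis")
    x = (w - w.min()) / span
    keep = np.isfinite(y)
    if keep.sum() < degree + 1:
        raise ParameterError("too few finite points for polynomial fit")
    return npoly.polyfit(x[keep], y[keep], degree)


def fourier_moduli(normalized_spectrum, n_terms: int = 10) -> np.ndarray:
    """|F_k| for k = 1..n_terms of the spectrum's discrete Fourier transform.

    The DC term is excluded (it duplicates the zeroth-order phasor term I).
    """
    s = np.asarray(normalized_spectrum, dtype=float)
    if s.size <= 2 * n_terms:
        raise ParameterError(f"spectrum length {s.size} too short for {n_terms} harmonics")
    return np.abs(np.fft.fft(s)[1 : n_terms + 1])


def extract_hsi_features(cube, roi=None, config=None) -> dict:
    """All HSI features for one specimen, namespaced ``hsi.*``."""
    from .config import StudyConfig

    config = config or StudyConfig()
    data = np.asarray(cube.data, dtype=float)
    wavelengths = cube.wavelengths_nm
    if cube.white_reference is not None:
        data = white_reference_correct(data, cube.white_reference)
    if roi is None:
        shape = data.shape[:2]
        roi = circular_roi_mask(shape, (shape[0] // 2, shape[1] // 2), min(shape) // 2 - 1)

    features: dict[str, float] = {}
    mean_spectrum = np.full(wavelengths.size, np.nan)
    for b, wl in enumerate(wavelengths):
        band = data[..., b]
        valid = roi & saturation_mask(band, cube.detector_capacity) & np.isfinite(band)
        name = f"hsi.w{wl:.0f}"
        if not valid.any():
            logger.warning("HSI band %.0f nm: ROI fully saturated", wl)
            features[f"{name}_mean"] = np.nan
            features[f"{name}_std"] = np.nan
            continue
        vals = band[valid]
        mean_spectrum[b] = vals.mean()
        features[f"{name}_mean"] = float(vals.mean())
        features[f"{name}_std"] = float(vals.std())

    lo, hi = wavelengths.min(), wavelengths.max()
    start = np.floor(lo / config.hsi_bin_nm) * config.hsi_bin_nm
    stop = np.ceil(hi / config.hsi_bin_nm) * config.hsi_bin_nm
    binned = bin_mean_10nm(mean_spectrum, wavelengths, start, stop, config.hsi_bin_nm)
    for i, v in enumerate(binned):
        features[f"hsi.bin{int(start + i * config.hsi_bin_nm)}_mean"] = float(v)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized = normalize_unit_interval(mean_spectrum)
    phasor_input = normalized if config.phasor_on_normalized else mean_spectrum
    finite = np.isfinite(phasor_input)
    if finite.sum() > max(2 * config.hsi_fourier_terms, config.hsi_poly_degree, 4):
        ph = spectral_phasor(phasor_input[finite], orders=(1, 2), normalize=config.normalize_phasor)
        for key, value in ph.items():
            features[f"hsi.{key}"] = value
        coeffs = polynomial_descriptors(
            normalized[finite], wavelengths[finite], config.hsi_poly_degree
        )
        for i, c in enumerate(coeffs):
            features[f"hsi.poly{i}"] = float(c)
        moduli = fourier_moduli(normalized[finite], config.hsi_fourier_terms)
        for k, m in enumerate(moduli, start=1):
            features[f"hsi.fft{k}"] = float(m)
    else:
        for key in ("I", "G1", "S1", "G2", "S2"):
            features[f"hsi.{key}"] = np.nan
        for i in range(config.hsi_poly_degree + 1):
            features[f"hsi.poly{i}"] = np.nan
        for k in range(1, config.hsi_fourier_terms + 1):
            features[f"hsi.fft{k}"] = np.nan
    return features
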