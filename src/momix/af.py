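"""Autofluorescence feature extraction.

Per (excitation, emission cut-on) image the ROI mean and standard deviation
are taken after flat-field correction and saturation masking.  For each
excitation, differences of consecutive long-pass images simulate narrowband
measurements; the narrowband values are interpolated into a pseudo-spectrum
whose low-order discrete Fourier coefficients (the spectral-phasor terms
G, S and the zeroth-order intensity I) summarize spectral shape.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ParameterError, circular_roi_mask, saturation_mask

logger = logging.getLogger("momix")

__all__ = [
    "PseudoSpectrum",
    "flat_field_correct",
    "simulated_narrowband",
    "pseudo_spectrum",
    "spectral_phasor",
    "extract_af_features",
]


@dataclass
class PseudoSpectrum:
    wavelengths_nm: np.ndarray  # uniform, strictly increasing grid
    intensities: np.ndarray
    excitation_nm: float


def flat_field_correct(image, dark=None, flat=None):
    """Flat-field correction: (image - dark) / (flat - dark), gain-normalized.

    The gain normalizer is the mean of (flat - dark) so that a scene equal to
    the flat maps to a constant field at the original intensity scale.
    Pixels where flat - dark <= 0 are returned as NaN (invalid).
    """
    image = np.asarray(image, dtype=float)
    if dark is None:
        dark = np.zeros_like(image)
    if flat is None:
        return image.copy()
    dark = np.asarray(dark, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if dark.shape != image.shape or flat.shape != image.shape:
        raise ParameterError("dark/flat shape must match image shape")
    gain = flat - dark
    valid = gain > 0
    if not valid.any():
        raise ParameterError("flat - dark is nowhere positive")
    out = np.full_like(image, np.nan)
    out[valid] = (image[valid] - dark[valid]) / gain[valid] * gain[valid].mean()
    return out


def admissible_cutons(cutons, excitation_nm):
    """Long-pass cut-ons usable with an excitation line: strictly above it."""
    return sorted(c for c in cutons if c > excitation_nm)


def simulated_narrowband(roi_means: dict, excitation_nm: float):
    """Simulated narrowband values from long-pass ROI means.

    For consecutive admissible cut-ons c_i < c_{i+1}, the band [c_i, c_{i+1})
    gets value mean(c_i) - mean(c_{i+1}): the signal the long-pass at c_i sees
    that the one at c_{i+1} does not.  Returns [] with a warning when fewer
    than two admissible filters exist (e.g. 647-nm excitation with the
    published filter set).
    """
    cutons = admissible_cutons(roi_means, excitation_nm)
    if len(cutons) < 2:
        warnings.warn(
            f"excitation {excitation_nm} nm has {len(cutons)} admissible "
            "long-pass filter(s); no narrowband values",
            stacklevel=2,
        )
        return []
    return [
        ((cutons[i], cutons[i + 1]), roi_means[cutons[i]] - roi_means[cutons[i + 1]])
        for i in range(len(cutons) - 1)
    ]


def pseudo_spectrum(bands, grid_points: int = 32, excitation_nm: float = np.nan) -> PseudoSpectrum:
    """Linearly interpolate narrowband values onto a uniform wavelength grid.

    Each band value is anchored at its interval midpoint; the grid spans the
    first to last midpoint.
    """
    if len(bands) < 2:
        raise ParameterError("pseudo-spectrum needs at least 2 narrowband values")
    mids = np.array([(lo + hi) / 2.0 for (lo, hi), _ in bands], dtype=float)
    vals = np.array([v for _, v in bands], dtype=float)
    order = np.argsort(mids)
    mids, vals = mids[order], vals[order]
    grid = np.linspace(mids[0], mids[-1], int(grid_points))
    return PseudoSpectrum(grid, np.interp(grid, mids, vals), excitation_nm)


def spectral_phasor(spectrum, orders=(1,), normalize: bool = False) -> dict:
    """Spectral-phasor terms: DFT coefficients of an intensity sequence.

    With the forward convention F_k = sum_n x_n exp(-2*pi*i*k*n/N), returns
    ``{"I": F_0, "G<k>": Re F_k, "S<k>": Im F_k}`` for each requested harmonic.
    ``normalize=True`` divides the harmonics by F_0 (classical phasor plot
    coordinates); by default raw coefficients are returned and I is kept as a
    separate feature.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.size == 0:
        raise ParameterError("empty spectrum")
    orders = sorted(int(k) for k in orders)
    if orders and x.size < 2 * max(orders):
        raise ParameterError(
            f"spectrum length {x.size} too short for harmonic {max(orders)}"
        )
    F = np.fft.fft(x)
    out = {"I": float(F[0].real)}
    for k in orders:
        gk, sk = float(F[k].real), float(F[k].imag)
        if normalize:
            if abs(F[0].real) < np.finfo(float).tiny:
                raise ParameterError("cannot normalize phasor: zero total intensity")
            gk, sk = gk / F[0].real, sk / F[0].real
        out[f"G{k}"] = gk
        out[f"S{k}"] = sk
    return out


def _roi_stats(image, roi, capacity):
    valid = roi & saturation_mask(image, capacity) & np.isfinite(image)
    if not valid.any():
        return np.nan, np.nan
    vals = image[valid]
    return float(vals.mean()), float(vals.std())  # population std: ROI is the population


def extract_af_features(stack, roi=None, config=None) -> dict:
    """All AF features for one specimen, namespaced ``af.*``.

    Emits per (excitation, cut-on) image the ROI mean and std; per excitation
    the narrowband values and the pseudo-spectrum phasor terms G, S, I.
    Images whose ROI is fully saturated contribute missing (NaN) features.
    """
    from .config import StudyConfig

    config = config or StudyConfig()
    capacity = stack.detector_capacity
    if roi is None:
        shape = stack.shape
        roi = circular_roi_mask(shape, (shape[0] // 2, shape[1] // 2), min(shape) // 2 - 1)

    features: dict[str, float] = {}
    by_excitation: dict[float, dict] = {}
    for (ex, em), image in sorted(stack.images.items()):
        corrected = flat_field_correct(image, stack.dark, stack.flat)
        mean, std = _roi_stats(corrected, roi, capacity)
        if np.isnan(mean):
            logger.warning("AF image ex=%s em=%s: ROI fully saturated/invalid", ex, em)
        features[f"af.ex{ex}_em{em}_mean"] = mean
        features[f"af.ex{ex}_em{em}_std"] = std
        by_excitation.setdefault(ex, {})[em] = mean

    for ex, means in sorted(by_excitation.items()):
        usable = {c: m for c, m in means.items() if np.isfinite(m)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bands = simulated_narrowband(usable, ex)
        for (lo, hi), value in bands:
            features[f"af.ex{ex}_nb{lo}_{hi}"] = value
        phasor_keys = ("I", "G1", "S1")
        if len(bands) >= 2:
            ps = pseudo_spectrum(bands, config.pseudo_spectrum_points, excitation_nm=ex)
            ph = spectral_phasor(ps.intensities, orders=(1,), normalize=config.normalize_phasor)
            for key in phasor_keys:
                features[f"af.ex{ex}_{key}"] = ph[key]
        elif any(c > ex for c in config.af_emission_cutons_nm) and len(usable) >= 2:
            # admissible filters exist but their means were missing
            for key in phasor_keys:
                features[f"af.ex{ex}_{key}"] = np.nan
    return features
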