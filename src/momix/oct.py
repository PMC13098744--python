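"""OCT feature extraction: texture, spatial-frequency and attenuation.

Texture is characterized by the 13 classical Haralick statistics of the
gray-level co-occurrence matrix (GLCM), averaged over the four principal
offset directions, on XZ (depth) and XY (en-face) ROI slices.  Broader-scale
structure is captured by the mean FFT magnitude over annular frequency bins
of a fixed-size ROI.  Tissue density is summarized by the sample-average
attenuation coefficient mu (mm^-1): per 10x10 lateral tile, the depth profile
of tile means below the detected surface is fit to Beer-law exponential decay
by log-linear least squares.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from skimage.feature import graycomatrix

from .core import ParameterError

logger = logging.getLogger("momix")

__all__ = [
    "quantize_levels",
    "haralick_features",
    "HARALICK_NAMES",
    "annular_frequency_features",
    "attenuation_coefficient",
    "extract_oct_features",
]

HARALICK_NAMES = (
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
)

_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


def quantize_levels(image: np.ndarray, levels: int = 64) -> np.ndarray:
    """Min-max rescale an intensity ROI to integer gray levels 0..levels-1."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi - lo == 0:
        return np.zeros(img.shape, dtype=np.uint16)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.uint16)
    return np.minimum(q, levels - 1)


def _haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """The 13 Haralick statistics of one normalized symmetric GLCM."""
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    # distributions of i+j and |i-j|
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    def xlog2(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(p > 0, p * np.log2(p), 0.0)

    asm = (P**2).sum()
    contrast = ((ii - jj) ** 2 * P).sum()
    if sd_x * sd_y > 0:
        correlation = ((ii - mu_x) * (jj - mu_y) * P).sum() / (sd_x * sd_y)
    else:
        correlation = np.nan  # undefined for a constant region
    variance = ((ii - mu_x) ** 2 * P).sum()
    idm = (P / (1.0 + (ii - jj) ** 2)).sum()
    sum_average = (k_sum * p_sum).sum()
    sum_entropy = -xlog2(p_sum).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * p_sum).sum()
    entropy = -xlog2(P).sum()
    diff_average = (k_diff * p_diff).sum()
    difference_variance = ((k_diff - diff_average) ** 2 * p_diff).sum()
    difference_entropy = -xlog2(p_diff).sum()

    hx = -xlog2(px).sum()
    hy = -xlog2(py).sum()
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = -np.where(pxy > 0, P * np.log2(pxy), 0.0).sum()
        hxy2 = -np.where(pxy > 0, pxy * np.log2(pxy), 0.0).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else np.nan
    arg = 1.0 - np.exp(-2.0 * (hxy2 - entropy))
    imc2 = np.sqrt(arg) if arg >= 0 else 0.0

    return np.array(
        [
            asm,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def haralick_features(roi_slice, levels: int = 64, distance: int = 1) -> np.ndarray:
    """13 Haralick texture statistics, averaged over 0/45/90/135 degrees.

    The slice is min-max quantized to ``levels`` gray values; symmetric
    normalized GLCMs are accumulated at the four unit-distance offsets.  For a
    constant slice, contrast is 0 and angular second moment 1 by the limit;
    correlation is undefined there and reported as NaN.
    """
    img = np.asarray(roi_slice, dtype=float)
    if img.ndim != 2 or min(img.shape) < 2:
        raise ParameterError("texture slice must be at least 2x2")
    q = quantize_levels(img, levels)
    glcm = graycomatrix(
        q.astype(np.uint8) if levels <= 256 else q,
        distances=[distance],
        angles=list(_GLCM_ANGLES),
        levels=levels,
        symmetric=True,
        normed=True,
    )
    per_angle = np.stack(
        [_haralick_from_glcm(glcm[:, :, 0, a]) for a in range(len(_GLCM_ANGLES))]
    )
    # average over the directions where a statistic is defined (correlation
    # can degenerate along a single direction); all-undefined stays NaN
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(per_angle, axis=0)


def annular_frequency_features(roi_slice, n_annuli: int = 10, expected_shape=None) -> np.ndarray:
    """Mean centered-FFT magnitude over equal-width radial frequency bins.

    Bins tile radial frequency 0..Nyquist (0.5 cycles/pixel).  The ROI size
    is a contract: all specimens must use the same grid so that the frequency
    axes are comparable; pass ``expected_shape`` to enforce it.
    """
    img = np.asarray(roi_slice, dtype=float)
    if expected_shape is not None and img.shape != tuple(expected_shape):
        raise ParameterError(
            f"frequency ROI must have fixed shape {tuple(expected_shape)}, got {img.shape}"
        )
    if img.ndim != 2:
        raise ParameterError("frequency ROI must be 2-D")
    mag = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0]))
    fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1]))
    r = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    edges = np.linspace(0.0, 0.5, n_annuli + 1)
    out = np.full(n_annuli, np.nan)
    for k in range(n_annuli):
        sel = (r >= edges[k]) & (r < edges[k + 1]) if k < n_annuli - 1 else (
            (r >= edges[k]) & (r <= edges[k + 1])
        )
        if sel.any():
            out[k] = mag[sel].mean()
    return out


def _linear_fit(z, y):
    """Least-squares line y = a + b z; returns (a, b, r_squared)."""
    A = np.column_stack([np.ones_like(z), z])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= np.finfo(float).eps * max(1.0, float(y @ y)):
        r2 = 1.0 if ss_res <= np.finfo(float).eps * max(1.0, float(y @ y)) else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return coef[0], coef[1], r2


def attenuation_coefficient(
    volume, tile: int = 10, r2_gate: float = 0.5, min_points: int = 5
):
    """Sample-average Beer-law attenuation coefficient in mm^-1.

    Per non-overlapping ``tile`` x ``tile`` lateral tile, the depth profile of
    tile means is assembled; the tissue surface is located at the profile
    argmax; the noise floor is mean + 2 std of the above-surface region; the
    log-intensity is fit linearly from the surface to the first depth where
    the signal drops below the noise floor.  Tiles with fit R^2 below
    ``r2_gate`` are discarded.  Returns (mean mu, per-tile mu array); mean is
    NaN with a logged diagnostic when no tile passes.
    """
    data = np.asarray(volume.data, dtype=float)
    if data.shape[0] < tile or data.shape[1] < tile:
        raise ParameterError(
            f"volume lateral extent {data.shape[:2]} smaller than tile {tile}"
        )
    dz_mm = volume.z_pitch_mm
    mus = []
    for r0 in range(0, data.shape[0] - tile + 1, tile):
        for c0 in range(0, data.shape[1] - tile + 1, tile):
            profile = data[r0 : r0 + tile, c0 : c0 + tile, :].mean(axis=(0, 1))
            surface = int(np.argmax(profile))
            if surface >= 3:
                above = profile[:surface]
                floor = above.mean() + 2.0 * above.std()
            else:
                floor = 0.0
            below = profile[surface:]
            end = below.size
            under = np.nonzero(below < floor)[0]
            if under.size and under[0] > 0:
                end = int(under[0])
            seg = below[:end]
            if seg.size < min_points or np.any(seg <= 0):
                continue
            z_mm = np.arange(surface, surface + seg.size) * dz_mm
            _, slope, r2 = _linear_fit(z_mm, np.log(seg))
            if r2 >= r2_gate:
                mus.append(-slope)
    mus = np.asarray(mus, dtype=float)
    if mus.size == 0:
        logger.warning("attenuation fit: no tile passed the R^2 gate (%g)", r2_gate)
        return np.nan, mus
    return float(mus.mean()), mus


def extract_oct_features(volume, roi_specs=None, config=None) -> dict:
    """All OCT features for one specimen, namespaced ``oct.*``.

    ``roi_specs`` may provide ``xz_row``/``xy_z`` slice indices and per-plane
    ``(row0, col0)`` corner offsets for the fixed-size frequency ROI; defaults
    pick center slices and centered crops.
    """
    from .config import StudyConfig

    config = config or StudyConfig()
    roi_specs = roi_specs or {}
    data = np.asarray(volume.data, dtype=float)
    features: dict[str, float] = {}

    planes = {
        "xz": volume.xz_slice(roi_specs.get("xz_row", data.shape[0] // 2)),
        "xy": volume.xy_slice(roi_specs.get("xy_z", data.shape[2] // 4)),
    }
    size = config.fft_roi_size
    for tag, plane in planes.items():
        if min(plane.shape) < 2:
            for name in HARALICK_NAMES:
                features[f"oct.{tag}_haralick_{name}"] = np.nan
            for k in range(config.n_annuli):
                features[f"oct.{tag}_annulus{k}"] = np.nan
            continue
        hara = haralick_features(plane, config.gray_levels, config.glcm_distance)
        for name, value in zip(HARALICK_NAMES, hara):
            features[f"oct.{tag}_haralick_{name}"] = float(value)
        if min(plane.shape) >= size:
            r0 = roi_specs.get(f"{tag}_fft_corner", (
                (plane.shape[0] - size) // 2,
                (plane.shape[1] - size) // 2,
            ))
            crop = plane[r0[0] : r0[0] + size, r0[1] : r0[1] + size]
            ann = annular_frequency_features(crop, config.n_annuli, expected_shape=(size, size))
        else:
            logger.warning("OCT %s plane smaller than frequency ROI %d", tag, size)
            ann = np.full(config.n_annuli, np.nan)
        for k, value in enumerate(ann):
            features[f"oct.{tag}_annulus{k}"] = float(value)

    mu, _ = attenuation_coefficient(
        volume, tile=config.attenuation_tile, r2_gate=config.attenuation_r2_gate
    )
    features["oct.attenuation_mu"] = mu
    return features
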