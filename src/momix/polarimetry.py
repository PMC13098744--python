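"""Mueller-matrix reconstruction and Lu-Chipman polar decomposition.

A medium's Mueller matrix M maps input to output Stokes vectors.  From a set
of measurements under known generator states, M is recovered per pixel by
least squares.  The Lu-Chipman polar decomposition factorizes
``M = M_dep @ M_ret @ M_dia`` (depolarizer, retarder, diattenuator — the
original ordering) and yields the scalar polarization properties used as
tissue features: diattenuation D, polarizance P, depolarization power Delta,
total retardance R, linear retardance delta with fast-axis orientation theta,
and the circular retardance component psi.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ParameterError, circular_roi_mask

logger = logging.getLogger("momix")

__all__ = [
    "CANONICAL_GENERATOR_STATES",
    "PolarizationProperties",
    "PROPERTY_NAMES",
    "rotator",
    "linear_retarder",
    "depolarizer",
    "diattenuator",
    "mueller_from_stokes_measurements",
    "lu_chipman_decompose",
    "polarization_property_maps",
    "extract_pli_features",
]

# Horizontal, vertical, +45, -45, right- and left-circular: the canonical
# full-rank six-state generator set.
CANONICAL_GENERATOR_STATES = np.array(
    [
        [1.0, 1.0, 0.0, 0.0],
        [1.0, -1.0, 0.0, 0.0],
        [1.0, 0.0, 1.0, 0.0],
        [1.0, 0.0, -1.0, 0.0],
        [1.0, 0.0, 0.0, 1.0],
        [1.0, 0.0, 0.0, -1.0],
    ]
)

PROPERTY_NAMES = (
    "diattenuation",
    "polarizance",
    "depolarization",
    "retardance",
    "linear_retardance",
    "orientation",
    "circular_retardance",
)

_RANGE_TOL = 1e-6


@dataclass
class PolarizationProperties:
    """Scalar polarization properties of one Mueller matrix."""

    diattenuation: float
    polarizance: float
    depolarization: float
    retardance: float
    linear_retardance: float
    orientation: float
    circular_retardance: float
    valid: bool = True
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PROPERTY_NAMES])


def rotator(psi: float) -> np.ndarray:
    """Circular retarder (optical rotator) with circular retardance psi."""
    c, s = np.cos(psi), np.sin(psi)
    return np.array(
        [[1, 0, 0, 0], [0, c, s, 0], [0, -s, c, 0], [0, 0, 0, 1]], dtype=float
    )


def linear_retarder(delta: float, theta: float = 0.0) -> np.ndarray:
    """Linear retarder with retardance delta and fast-axis orientation theta."""
    c2, s2 = np.cos(2 * theta), np.sin(2 * theta)
    cd, sd = np.cos(delta), np.sin(delta)
    return np.array(
        [
            [1, 0, 0, 0],
            [0, c2**2 + s2**2 * cd, c2 * s2 * (1 - cd), -s2 * sd],
            [0, c2 * s2 * (1 - cd), s2**2 + c2**2 * cd, c2 * sd],
            [0, s2 * sd, -c2 * sd, cd],
        ],
        dtype=float,
    )


def depolarizer(power: float) -> np.ndarray:
    """Isotropic depolarizer: diag(1, a, a, a) with a = 1 - power."""
    if not (0.0 <= power <= 1.0):
        raise ParameterError("depolarization power must be in [0, 1]")
    a = 1.0 - power
    return np.diag([1.0, a, a, a])


def diattenuator(d_vec) -> np.ndarray:
    """Pure diattenuator with diattenuation vector d_vec (|d| <= 1)."""
    d = np.asarray(d_vec, dtype=float)
    D = np.linalg.norm(d)
    if D > 1.0 + _RANGE_TOL:
        raise ParameterError("diattenuation magnitude must be <= 1")
    M = np.eye(4)
    M[0, 1:] = d
    M[1:, 0] = d
    if D > 0:
        dhat = np.outer(d / D, d / D)
        M[1:, 1:] = np.sqrt(1 - min(D, 1.0) ** 2) * np.eye(3) + (
            1 - np.sqrt(1 - min(D, 1.0) ** 2)
        ) * dhat
    return M


def mueller_from_stokes_measurements(measurements) -> "MuellerField":
    """Per-pixel least-squares Mueller matrix from a Stokes measurement set.

    With input states stacked column-wise in S (4 x n) and outputs in O,
    solves min ||O - M S|| per pixel; exact for noiseless data when the state
    matrix has rank 4.  Pixels whose solve produces non-finite entries or a
    non-positive m00 are marked invalid.
    """
    from .containers import MuellerField

    S = measurements.input_states.T  # (4, n)
    if S.shape[0] != 4 or np.linalg.matrix_rank(S) < 4:
        raise ParameterError("generator state matrix must be 4 x n with rank 4")
    outputs = np.asarray(measurements.outputs, dtype=float)  # (ny, nx, n, 4)
    O = np.swapaxes(outputs, -1, -2)  # (ny, nx, 4, n)
    pinv = np.linalg.pinv(S)  # (n, 4)
    M = O @ pinv  # (ny, nx, 4, 4)
    valid = np.isfinite(M).all(axis=(-2, -1)) & (M[..., 0, 0] > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning(
            "Mueller reconstruction at %.0f nm: %d invalid pixel(s)",
            measurements.wavelength_nm,
            n_bad,
        )
    return MuellerField(M, measurements.wavelength_nm, valid=valid)


def _invalid_properties() -> PolarizationProperties:
    nan = float("nan")
    return PolarizationProperties(nan, nan, nan, nan, nan, nan, nan, valid=False)


def lu_chipman_decompose(M: np.ndarray) -> PolarizationProperties:
    """Lu-Chipman polar decomposition of a single 4x4 Mueller matrix.

    Factorizes M (after m00 normalization) as depolarizer @ retarder @
    diattenuator.  The diattenuation vector is the first row; the depolarizer
    submatrix comes from the eigenstructure of m' m'^T with its sign from
    det(m'); retardance angles are read off the retarder factor.

    A pure polarizer (|D| = 1) leaves the retarder/depolarizer split
    degenerate: D and polarizance are still reported, the remaining
    properties are NaN and the result is flagged degenerate.  Matrices that
    violate the physicality screen (m00 <= 0 or |m_ij|/m00 > 1 + 1e-6) or
    whose recovered properties fall outside their physical ranges are
    returned invalid — never silently clipped.
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4) or not np.isfinite(M).all():
        return _invalid_properties()
    m00 = M[0, 0]
    if m00 <= 0 or np.max(np.abs(M)) / m00 > 1.0 + _RANGE_TOL:
        return _invalid_properties()
    Mn = M / m00

    d_vec = Mn[0, 1:].copy()
    D = float(np.linalg.norm(d_vec))
    P = float(np.linalg.norm(Mn[1:, 0]))
    if D > 1.0 + _RANGE_TOL or P > 1.0 + _RANGE_TOL:
        return _invalid_properties()
    D = min(D, 1.0)
    P = min(P, 1.0)

    if 1.0 - D < 1e-9:  # pure-polarizer limit: M_D is singular
        nan = float("nan")
        return PolarizationProperties(D, P, nan, nan, nan, nan, nan, degenerate=True)

    M_D = diattenuator(d_vec)
    Mp = Mn @ np.linalg.inv(M_D)
    mp = Mp[1:, 1:]

    mmT = mp @ mp.T
    lam = np.clip(np.linalg.eigvalsh(mmT), 0.0, None)
    sq = np.sqrt(lam)
    c1 = sq.sum()
    c2 = sq[0] * sq[1] + sq[1] * sq[2] + sq[0] * sq[2]
    c3 = sq[0] * sq[1] * sq[2]
    det_mp = np.linalg.det(mp)
    sign = -1.0 if det_mp < 0 else 1.0
    try:
        m_dep = sign * np.linalg.solve(mmT + c2 * np.eye(3), c1 * mmT + c3 * np.eye(3))
    except np.linalg.LinAlgError:
        return _invalid_properties()

    delta_power = 1.0 - abs(np.trace(m_dep)) / 3.0
    if delta_power < -_RANGE_TOL or delta_power > 1.0 + _RANGE_TOL:
        return _invalid_properties()
    delta_power = float(np.clip(delta_power, 0.0, 1.0))

    # near-complete depolarization leaves no retarder information
    if np.linalg.cond(m_dep) > 1e12:
        nan = float("nan")
        return PolarizationProperties(
            D, P, delta_power, nan, nan, nan, nan, degenerate=True
        )
    m_R = np.linalg.solve(m_dep, mp)

    tr = np.trace(m_R)
    R = float(np.arccos(np.clip((1.0 + tr) / 2.0 - 1.0, -1.0, 1.0)))
    lin_arg = np.sqrt((m_R[0, 0] + m_R[1, 1]) ** 2 + (m_R[1, 0] - m_R[0, 1]) ** 2) - 1.0
    delta = float(np.arccos(np.clip(lin_arg, -1.0, 1.0)))
    psi = float(np.arctan2(m_R[0, 1] - m_R[1, 0], m_R[0, 0] + m_R[1, 1]))

    sinR = np.sin(R)
    if sinR > 1e-9 and delta > 1e-9:
        a1 = (m_R[1, 2] - m_R[2, 1]) / (2.0 * sinR)
        a2 = (m_R[2, 0] - m_R[0, 2]) / (2.0 * sinR)
        theta = float(np.arctan2(a2, a1) / 2.0 % np.pi)
        if np.pi - theta < 1e-12:  # branch tie resolved toward 0
            theta = 0.0
    else:
        theta = 0.0

    return PolarizationProperties(D, P, delta_power, R, delta, theta, psi)


def polarization_property_maps(field) -> dict:
    """Per-pixel Lu-Chipman properties of a Mueller field.

    Returns a dict of property-name -> image map plus a ``"valid"`` mask.
    Invalid input pixels propagate; a warning is emitted when more than half
    of the field is invalid.
    """
    matrices = field.matrices
    ny, nx = matrices.shape[:2]
    maps = {name: np.full((ny, nx), np.nan) for name in PROPERTY_NAMES}
    valid = np.zeros((ny, nx), dtype=bool)
    for r in range(ny):
        for c in range(nx):
            if not field.valid[r, c]:
                continue
            props = lu_chipman_decompose(matrices[r, c])
            if not props.valid:
                continue
            valid[r, c] = True
            arr = props.as_array()
            for k, name in enumerate(PROPERTY_NAMES):
                maps[name][r, c] = arr[k]
    frac_bad = 1.0 - valid.mean()
    if frac_bad > 0.5:
        warnings.warn(
            f"{frac_bad:.0%} of pixels invalid in {field.wavelength_nm:.0f} nm field",
            stacklevel=2,
        )
    maps["valid"] = valid
    return maps


def extract_pli_features(fields: dict, roi=None, config=None) -> dict:
    """All PLI features for one specimen, namespaced ``pli.w<wavelength>.*``.

    ``fields`` maps wavelength (nm) to a MuellerField or None (wavelengths
    whose Mueller matrix could not be generated).  Per wavelength: mean and
    std over valid ROI pixels of each polarization property, plus the mean of
    each of the 16 Mueller elements (m00-normalized except m00 itself).
    Missing wavelengths yield missing features, to be imputed downstream.
    """
    from .config import StudyConfig

    config = config or StudyConfig()
    features: dict[str, float] = {}
    wavelengths = sorted(config.pli_wavelengths_nm)
    if not any(fields.get(w) is not None for w in wavelengths):
        logger.warning("no Mueller field available at any wavelength")

    for w in wavelengths:
        prefix = f"pli.w{w}"
        field = fields.get(w)
        element_names = [f"{prefix}.m{i}{j}_mean" for i in range(4) for j in range(4)]
        prop_names = [
            f"{prefix}.{p}_{stat}" for p in PROPERTY_NAMES for stat in ("mean", "std")
        ]
        if field is None:
            for name in element_names + prop_names:
                features[name] = np.nan
            continue
        matrices = field.matrices
        if roi is None:
            shape = matrices.shape[:2]
            roi_mask = circular_roi_mask(
                shape, (shape[0] // 2, shape[1] // 2), min(shape) // 2 - 1
            )
        else:
            roi_mask = roi
        maps = polarization_property_maps(field)
        sel = roi_mask & maps["valid"]
        if not sel.any():
            for name in element_names + prop_names:
                features[name] = np.nan
            continue
        m00 = matrices[..., 0, 0]
        for i in range(4):
            for j in range(4):
                elem = matrices[..., i, j]
                if not (i == 0 and j == 0):
                    elem = elem / m00
                features[f"{prefix}.m{i}{j}_mean"] = float(elem[sel].mean())
        for p in PROPERTY_NAMES:
            vals = maps[p][sel]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                features[f"{prefix}.{p}_mean"] = np.nan
                features[f"{prefix}.{p}_std"] = np.nan
            else:
                features[f"{prefix}.{p}_mean"] = float(vals.mean())
                features[f"{prefix}.{p}_std"] = float(vals.std())
    return features
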