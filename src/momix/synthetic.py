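"""Synthetic multimodal phantom study generator.

Generates a complete phantom study — specimen registry with mixed
paired/unpaired patients, autofluorescence stacks, hyperspectral cubes, OCT
volumes and per-wavelength Stokes measurement sets — with configurable
class-dependent effects, so the entire downstream pipeline is testable
without the real tissue data.

The "paper-cohort" preset reproduces the published study structure exactly:
45 specimens from 26 patients (20 normal, 14 cancer, 11 metaplasia, 6 of
them Barrett's), 10 clinician/pathologist disagreements, 7 specimens the
pathologist could not classify, and 8 patients contributing both normal and
cancer tissue.

Phantoms carry only the statistical structure the analysis assumes (Beer-law
decay with fully developed speckle, smooth two-Gaussian emission spectra,
depolarizer-retarder Mueller media) — no claim of biophysical realism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import AFStack, HSICube, MuellerField, OCTVolume, StokesMeasurementSet
from .core import ParameterError, SpecimenRecord, TissueClass
from .config import (
    AF_EMISSION_CUTONS_NM,
    AF_EXCITATIONS_NM,
    HSI_N_BANDS,
    HSI_RANGE_NM,
    PLI_WAVELENGTHS_NM,
)
from .polarimetry import CANONICAL_GENERATOR_STATES, depolarizer, linear_retarder

logger = logging.getLogger("momix")

__all__ = [
    "ClassEffects",
    "PhantomParams",
    "SyntheticStudy",
    "paper_cohort_records",
    "generate_study",
    "generate_oct_phantom",
    "generate_mueller_phantom",
    "generate_spectral_phantom",
    "generate_feature_study",
]


@dataclass(frozen=True)
class ClassEffects:
    """Ground-truth optical parameters of one tissue class."""

    oct_mu: float = 1.5  # attenuation coefficient, mm^-1
    texture_scale: float = 1.0  # speckle correlation length, pixels
    retardance: float = 0.2  # linear retardance, rad
    depolarization: float = 0.35  # depolarization power, [0, 1]
    spectral_shift_nm: float = 0.0  # emission-spectrum shift, nm

    def __post_init__(self):
        if self.oct_mu <= 0:
            raise ParameterError("attenuation must be positive")
        if not (0.0 <= self.retardance <= np.pi):
            raise ParameterError("retardance must lie in [0, pi]")
        if not (0.0 <= self.depolarization <= 1.0):
            raise ParameterError("depolarization must lie in [0, 1]")


_DEFAULT_EFFECTS = {
    "normal": ClassEffects(),
    "cancer": ClassEffects(
        oct_mu=2.5, texture_scale=2.0, retardance=0.5, depolarization=0.55,
        spectral_shift_nm=20.0,
    ),
    "metaplasia": ClassEffects(
        oct_mu=2.0, texture_scale=1.5, retardance=0.35, depolarization=0.45,
        spectral_shift_nm=10.0,
    ),
}

# Emulates the published missing-Mueller incidence (out of 45 specimens:
# eight at 405 nm, one at 473 nm, six at 632 nm).
_DEFAULT_MISSING_MUELLER = {405: 8 / 45, 442: 0.0, 473: 1 / 45, 543: 0.0, 632: 6 / 45}


@dataclass
class PhantomParams:
    """Generator settings; the defaults are the study conditions."""

    preset: str = "paper-cohort"
    n_patients: int = 26
    class_probs: tuple = (0.6, 0.4, 0.35)  # per-patient P(contribute N / C / M)
    paired_fraction: float = 8 / 26  # patients with both normal and cancer
    class_effects: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    # noise / nuisance structure
    amplitude_jitter: float = 0.05
    mm_noise_sd: float = 0.01
    mm_param_jitter: float = 0.02
    missing_mueller_prob: dict = field(default_factory=lambda: dict(_DEFAULT_MISSING_MUELLER))
    saturated_fraction: float = 0.01
    # image geometry (kept small: the analysis needs statistics, not pixels)
    af_shape: tuple = (32, 32)
    hsi_shape: tuple = (24, 24)
    oct_shape: tuple = (60, 60, 120)
    oct_depth_mm: float = 2.6
    mm_shape: tuple = (24, 24)
    detector_capacity: float = 10.0
    seed: int = 0

    @classmethod
    def null(cls, **kw) -> "PhantomParams":
        """All class effects equal: no real signal anywhere."""
        base = _DEFAULT_EFFECTS["normal"]
        return cls(class_effects={c: base for c in _DEFAULT_EFFECTS}, **kw)

    @classmethod
    def pli_only(cls, **kw) -> "PhantomParams":
        """Class effects confined to the polarization parameters."""
        base = _DEFAULT_EFFECTS["normal"]
        effects = {
            "normal": base,
            "cancer": ClassEffects(retardance=0.5, depolarization=0.55),
            "metaplasia": ClassEffects(retardance=0.35, depolarization=0.45),
        }
        return cls(class_effects=effects, **kw)


@dataclass
class SyntheticStudy:
    records: list  # SpecimenRecord
    data: dict  # specimen_id -> {"af": AFStack, "hsi": HSICube, "oct": OCTVolume,
    #             "pli": {wavelength: StokesMeasurementSet | None}}
    truth_fields: dict  # specimen_id -> {wavelength: MuellerField}
    ground_truth: pd.DataFrame
    params: PhantomParams


def paper_cohort_records() -> tuple[list, dict]:
    """The fixed published cohort: records plus provenance tags.

    Deterministic patient assignment honoring the published structure:
    patients 1-8 contribute a normal and a cancer specimen; 9-14 a cancer and
    a metaplasia; 15-19 a normal and a metaplasia; 15-26 one normal each.
    """
    # (class, subtype, provenance, clinician_class), in fixed order
    inventory = (
        [("normal", "Epithelium", "agree", "normal")] * 14
        + [("normal", "Epithelium", "differ", "cancer")] * 3
        + [("normal", "Epithelium", "na", "normal")] * 3
        + [("cancer", "Adenocarcinoma", "agree", "cancer")] * 7
        + [("cancer", "Squamous cell carcinoma", "agree", "cancer")]
        + [("cancer", "Melanoma", "agree", "cancer")]
        + [("cancer", "Plasmacytoma", "agree", "cancer")]
        + [("cancer", "Not classified", "na", "cancer")] * 4
        + [("metaplasia", "Barretts", "agree", "metaplasia")] * 4
        + [("metaplasia", "Barretts", "differ", "cancer")] * 2
        + [("metaplasia", "Not classified", "differ", "cancer")] * 2
        + [("metaplasia", "Not classified", "differ", "normal")] * 3
    )
    pools = {"normal": [], "cancer": [], "metaplasia": []}
    for item in inventory:
        pools[item[0]].append(item)

    patient_classes = (
        [("normal", "cancer")] * 8
        + [("cancer", "metaplasia")] * 6
        + [("normal", "metaplasia")] * 5
        + [("normal",)] * 7
    )
    records, provenance = [], {}
    n = 0
    for p, classes in enumerate(patient_classes, start=1):
        for cls in classes:
            cls_name, subtype, prov, clinician = pools[cls].pop(0)
            n += 1
            sid = f"S{n:02d}"
            pathologist = (
                TissueClass.UNCLASSIFIED if prov == "na" else TissueClass(cls_name)
            )
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    patient_id=f"P{p:02d}",
                    class_pathologist=pathologist,
                    class_clinician=TissueClass(clinician),
                    tissue_subtype=subtype,
                )
            )
            provenance[sid] = prov
    assert all(not v for v in pools.values())
    return records, provenance


def _sampled_records(params: PhantomParams, rng) -> tuple[list, dict]:
    """Random cohort: per patient, Bernoulli draws decide contributed classes."""
    records, provenance = [], {}
    n = 0
    paired = max(0, round(params.paired_fraction * params.n_patients))
    for p in range(1, params.n_patients + 1):
        classes = []
        if p <= paired:
            classes = ["normal", "cancer"]
        else:
            for cls, prob in zip(("normal", "cancer", "metaplasia"), params.class_probs):
                if rng.random() < prob:
                    classes.append(cls)
            if not classes:
                classes = ["normal"]
        for cls in classes:
            n += 1
            sid = f"S{n:02d}"
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    patient_id=f"P{p:02d}",
                    class_pathologist=TissueClass(cls),
                    class_clinician=TissueClass(cls),
                    tissue_subtype="",
                )
            )
            provenance[sid] = "agree"
    return records, provenance


_BASE_SPECTRA = {
    # (center1, width1, amp1, center2, width2, amp2) of the two-Gaussian
    # latent emission spectrum, nm
    0: (510.0, 40.0, 1.0, 630.0, 60.0, 0.6),
    1: (530.0, 35.0, 0.8, 660.0, 70.0, 0.9),
}


def _latent_spectrum(wavelengths, base_spectrum_id: int, shift_nm: float) -> np.ndarray:
    c1, w1, a1, c2, w2, a2 = _BASE_SPECTRA[base_spectrum_id]
    wl = np.asarray(wavelengths, dtype=float)
    return a1 * np.exp(-0.5 * ((wl - c1 - shift_nm) / w1) ** 2) + a2 * np.exp(
        -0.5 * ((wl - c2 - shift_nm) / w2) ** 2
    )


def generate_spectral_phantom(
    base_spectrum_id: int = 0,
    class_shift_nm: float = 0.0,
    amplitude_jitter: float = 0.05,
    shape=(24, 24),
    seed=None,
    rng=None,
    detector_capacity: float = 10.0,
    saturated_fraction: float = 0.0,
    af_shape=None,
) -> tuple[AFStack, HSICube]:
    """AF stack and HSI cube sharing one latent emission spectrum.

    The HSI cube samples the shifted two-Gaussian base spectrum per band with
    per-pixel amplitude jitter; each AF emission-filter image integrates the
    same latent spectrum above its long-pass cut-on.  A fraction of AF pixels
    is set to the detector capacity to exercise saturation masking.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    wavelengths = np.linspace(HSI_RANGE_NM[0], HSI_RANGE_NM[1], HSI_N_BANDS)
    spectrum = _latent_spectrum(wavelengths, base_spectrum_id, class_shift_nm)

    gain = 1.0 + amplitude_jitter * rng.standard_normal(shape)
    scene = gain[..., None] * spectrum[None, None, :]
    lamp = 1.0 + 0.5 * np.sin(np.linspace(0, np.pi, wavelengths.size))  # smooth lamp spectrum
    cube_data = scene * lamp[None, None, :]
    white = np.broadcast_to(lamp, cube_data.shape).copy()
    cube = HSICube(cube_data, wavelengths, white_reference=white, detector_capacity=detector_capacity)

    af_shape = af_shape or shape
    fine_wl = np.linspace(300.0, 900.0, 1201)
    fine_spec = _latent_spectrum(fine_wl, base_spectrum_id, class_shift_nm)
    images = {}
    ex_gain = {ex: np.exp(-0.5 * ((ex - 460.0) / 120.0) ** 2) for ex in AF_EXCITATIONS_NM}
    for ex in AF_EXCITATIONS_NM:
        for cuton in AF_EMISSION_CUTONS_NM:
            integral = float(np.trapezoid(fine_spec[fine_wl >= cuton], fine_wl[fine_wl >= cuton]))
            img = ex_gain[ex] * integral / 100.0 * (
                1.0 + amplitude_jitter * rng.standard_normal(af_shape)
            )
            if saturated_fraction > 0:
                n_sat = int(round(saturated_fraction * img.size))
                if n_sat:
                    idx = rng.choice(img.size, size=n_sat, replace=False)
                    img.ravel()[idx] = detector_capacity
            images[(ex, cuton)] = img
    stack = AFStack(images, detector_capacity=detector_capacity)
    return stack, cube


def generate_oct_phantom(
    mu: float,
    texture_scale: float = 1.0,
    shape=(60, 60, 120),
    z_spacing_mm: float | None = None,
    depth_mm: float = 2.6,
    seed=None,
    rng=None,
    i0: float = 1.0,
    speckle: bool = True,
    noise_floor: float = 0.005,
    surface_fraction: float = 0.15,
) -> OCTVolume:
    """OCT intensity phantom following Beer's law below a tissue surface.

    Mean intensity at depth z below the surface is i0 * exp(-mu z);
    multiplicative fully developed speckle (unit-mean exponential, optionally
    smoothed to the requested correlation length) is applied below the
    surface and an additive noise floor above it.
    """
    if mu <= 0:
        raise ParameterError("attenuation coefficient must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    ny, nx, nz = shape
    dz = z_spacing_mm if z_spacing_mm is not None else depth_mm / nz
    if dz <= 0:
        raise ParameterError("z spacing must be positive")
    z0 = int(round(surface_fraction * nz))
    z = np.arange(nz)
    decay = np.where(z >= z0, i0 * np.exp(-mu * (z - z0) * dz), 0.0)
    vol = np.broadcast_to(decay, shape).copy()
    if speckle:
        sp = rng.exponential(1.0, size=shape)
        if texture_scale > 0:
            sp = gaussian_filter(sp, sigma=texture_scale)
            sp /= sp.mean()
        vol = vol * sp
    floor = np.abs(noise_floor * rng.standard_normal(shape))
    vol = np.where(np.arange(nz) < z0, floor, np.maximum(vol, 1e-12))
    return OCTVolume(vol, pitch_um=(10.0, 10.0, dz * 1000.0))


def generate_mueller_phantom(
    retardance: float,
    orientation: float = 0.0,
    depolarization: float = 0.0,
    shape=(24, 24),
    noise_sd: float = 0.0,
    seed=None,
    rng=None,
    param_jitter: float = 0.0,
    wavelength_nm: float = 442.0,
) -> tuple[MuellerField, StokesMeasurementSet]:
    """Per-pixel depolarizer-retarder medium plus its Stokes measurements.

    Each pixel's Mueller matrix is depolarizer(Delta) @ linear_retarder(delta,
    theta) with spatial parameter jitter; the measurement set holds, per
    pixel, the output Stokes vectors for the six canonical generator states
    under the forward model plus additive Gaussian noise.
    """
    if not (0.0 <= depolarization <= 1.0):
        raise ParameterError("depolarization must lie in [0, 1]")
    if not (0.0 <= retardance <= np.pi):
        raise ParameterError("retardance must lie in [0, pi]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    ny, nx = shape
    deltas = np.clip(retardance + param_jitter * rng.standard_normal(shape), 0.0, np.pi)
    thetas = orientation + param_jitter * rng.standard_normal(shape)
    depols = np.clip(depolarization + param_jitter * rng.standard_normal(shape), 0.0, 1.0)
    matrices = np.empty((ny, nx, 4, 4))
    for r in range(ny):
        for c in range(nx):
            matrices[r, c] = depolarizer(depols[r, c]) @ linear_retarder(
                deltas[r, c], thetas[r, c]
            )
    states = CANONICAL_GENERATOR_STATES
    outputs = np.einsum("yxij,sj->yxsi", matrices, states)
    if noise_sd > 0:
        outputs = outputs + noise_sd * rng.standard_normal(outputs.shape)
    field = MuellerField(matrices, wavelength_nm)
    measurements = StokesMeasurementSet(states, outputs, wavelength_nm)
    return field, measurements


def generate_study(params: PhantomParams | None = None) -> SyntheticStudy:
    """Generate a full multimodal phantom study.

    Deterministic given ``params.seed``; ground truth (true mu, retardance,
    depolarization, spectral shift, injected missing Mueller wavelengths) is
    recorded per specimen.
    """
    params = params or PhantomParams()
    if params.n_patients <= 0:
        raise ParameterError("need at least one patient")
    root = np.random.default_rng(params.seed)
    if params.preset == "paper-cohort":
        records, provenance = paper_cohort_records()
    else:
        records, provenance = _sampled_records(params, root)

    seeds = np.random.SeedSequence(params.seed).spawn(len(records))
    data, truth_fields, gt_rows = {}, {}, []
    for record, seed_seq in zip(records, seeds):
        rng = np.random.default_rng(seed_seq)
        cls = record.effective_class.value
        eff = params.class_effects[cls]
        af_stack, hsi_cube = generate_spectral_phantom(
            base_spectrum_id=0,
            class_shift_nm=eff.spectral_shift_nm,
            amplitude_jitter=params.amplitude_jitter,
            shape=params.hsi_shape,
            rng=rng,
            detector_capacity=params.detector_capacity,
            saturated_fraction=params.saturated_fraction,
            af_shape=params.af_shape,
        )
        oct_vol = generate_oct_phantom(
            eff.oct_mu,
            texture_scale=eff.texture_scale,
            shape=params.oct_shape,
            depth_mm=params.oct_depth_mm,
            rng=rng,
        )
        pli, fields = {}, {}
        missing = []
        for wl in PLI_WAVELENGTHS_NM:
            if rng.random() < params.missing_mueller_prob.get(wl, 0.0):
                pli[wl] = None
                missing.append(wl)
                continue
            field, meas = generate_mueller_phantom(
                eff.retardance,
                orientation=0.3,
                depolarization=eff.depolarization,
                shape=params.mm_shape,
                noise_sd=params.mm_noise_sd,
                rng=rng,
                param_jitter=params.mm_param_jitter,
                wavelength_nm=wl,
            )
            pli[wl] = meas
            fields[wl] = field
        data[record.specimen_id] = {"af": af_stack, "hsi": hsi_cube, "oct": oct_vol, "pli": pli}
        truth_fields[record.specimen_id] = fields
        gt_rows.append(
            {
                "specimen_id": record.specimen_id,
                "class": cls,
                "mu": eff.oct_mu,
                "texture_scale": eff.texture_scale,
                "retardance": eff.retardance,
                "depolarization": eff.depolarization,
                "spectral_shift_nm": eff.spectral_shift_nm,
                "missing_mueller_nm": tuple(missing),
                "saturated_fraction": params.saturated_fraction,
            }
        )
    ground_truth = pd.DataFrame(gt_rows).set_index("specimen_id")
    logger.info(
        "generated study: %d specimens / %d patients",
        len(records),
        len({r.patient_id for r in records}),
    )
    study = SyntheticStudy(records, data, truth_fields, ground_truth, params)
    study.provenance = provenance
    return study


def generate_feature_study(
    n_per_class: int = 20,
    n_features: int = 50,
    effect: float = 0.0,
    paired_fraction: float = 0.4,
    seed: int = 0,
    classes=("normal", "cancer"),
):
    """Feature-level phantom for statistical calibration experiments.

    Draws standard-normal features per specimen with ``effect`` added to the
    second class, round-robin modality prefixes, and a mixed paired/unpaired
    patient structure.  Returns ``(table, labels, patients)``.
    """
    rng = np.random.default_rng(seed)
    a, b = classes
    n_paired = int(round(paired_fraction * n_per_class))
    rows, labels, patients = [], {}, {}
    sid = 0
    for i in range(n_per_class):
        for cls in (a, b):
            sid += 1
            name = f"S{sid:03d}"
            if i < n_paired:
                pat = f"P{i + 1:03d}"  # paired patient contributes both classes
            else:
                pat = f"P{100 + sid:03d}"
            shift = effect if cls == b else 0.0
            rows.append(pd.Series(rng.standard_normal(n_features) + shift, name=name))
            labels[name] = cls
            patients[name] = pat
    prefixes = ["af", "hsi", "oct", "pli"]
    columns = [f"{prefixes[j % 4]}.synth{j:03d}" for j in range(n_features)]
    table = pd.DataFrame(rows)
    table.columns = columns
    return table, pd.Series(labels), pd.Series(patients)
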