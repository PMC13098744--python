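"""Study configuration: extraction, screening and classifier settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .core import ParameterError

# Published filter sets of the benchtop systems.
AF_EXCITATIONS_NM = (340, 400, 460, 490, 647)
AF_EMISSION_CUTONS_NM = (380, 430, 500, 532, 561, 594, 647)
HSI_RANGE_NM = (470.0, 900.0)
HSI_N_BANDS = 150
PLI_WAVELENGTHS_NM = (405, 442, 473, 543, 632)


@dataclass
class StudyConfig:
    """All tunable parameters of the analysis pipeline.

    Detector capacities are required per system because bit depths differ
    between instruments and are not implied by the data.
    """

    # saturation handling
    detector_capacity: dict = field(
        default_factory=lambda: {"af": 1.0, "hsi": 1.0, "oct": 1.0, "pli": 1.0}
    )
    # AF extraction
    af_excitations_nm: tuple = AF_EXCITATIONS_NM
    af_emission_cutons_nm: tuple = AF_EMISSION_CUTONS_NM
    pseudo_spectrum_points: int = 32
    normalize_phasor: bool = False  # classical F0-normalized phasor if True
    # HSI extraction
    hsi_bin_nm: float = 10.0
    hsi_poly_degree: int = 4
    hsi_fourier_terms: int = 10
    phasor_on_normalized: bool = True
    # OCT extraction
    gray_levels: int = 64
    glcm_distance: int = 1
    n_annuli: int = 10
    fft_roi_size: int = 32
    attenuation_tile: int = 10
    attenuation_r2_gate: float = 0.5
    # PLI extraction
    pli_wavelengths_nm: tuple = PLI_WAVELENGTHS_NM
    # screening
    correlation_threshold: float = 0.85
    fdr_q: float = 0.1
    # classification
    n_trees: int = 100
    top_k: tuple = (3, 10)
    ranking_scope: str = "fold"  # "fold" (leakage-safe) or "global"
    positive_class: str = "cancer"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.correlation_threshold <= 1.0):
            raise ParameterError("correlation threshold must be in (0, 1]")
        if not (0.0 < self.fdr_q < 1.0):
            raise ParameterError("FDR level must be in (0, 1)")
        if not (isinstance(self.seed, (int,)) and self.seed >= 0):
            raise ParameterError("seed must be a non-negative integer")
        for mod, cap in self.detector_capacity.items():
            if cap <= 0:
                raise ParameterError(f"detector capacity for {mod} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("af_excitations_nm", "af_emission_cutons_nm", "pli_wavelengths_nm", "top_k"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        for key, value in raw.items():
            if isinstance(value, tuple):
                raw[key] = list(value)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
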