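"""Shared data model for multimodal tissue studies.

A study is a registry of tissue specimens (each belonging to a patient and
carrying a pathologist and a clinician class label) plus, per specimen, image
data from up to four optical modalities: autofluorescence (AF), hyperspectral
imaging (HSI), optical coherence tomography (OCT) and Mueller-matrix polarized
light imaging (PLI).

Scalar features extracted from the images are collected in a *feature table*:
a :class:`pandas.DataFrame` with specimen ids as the row index and
``"<modality>.<descriptor>"`` feature names as columns.  Missing measurements
(e.g. a wavelength whose Mueller matrix could not be reconstructed) are
``NaN`` and serialize as empty cells, never as sentinel numbers.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("momix")

MODALITIES = ("af", "hsi", "oct", "pli")

__all__ = [
    "MODALITIES",
    "TissueClass",
    "SpecimenRecord",
    "ParameterError",
    "ImputationError",
    "saturation_mask",
    "circular_roi_mask",
    "impute_class_means",
    "write_feature_table",
    "read_feature_table",
    "feature_modality",
    "effective_classes",
    "read_specimen_table",
    "write_specimen_table",
]


class ParameterError(ValueError):
    """An operation was called with out-of-contract parameters."""


class ImputationError(ValueError):
    """A (feature, class) group has no observed value to impute from."""


class TissueClass(str, enum.Enum):
    NORMAL = "normal"
    CANCER = "cancer"
    METAPLASIA = "metaplasia"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SpecimenRecord:
    """One tissue specimen and its study metadata.

    The *effective* class used for analysis is the pathologist's call unless
    the pathologist could not classify the specimen, in which case the
    clinician's initial classification is used.
    """

    specimen_id: str
    patient_id: str
    class_pathologist: TissueClass
    class_clinician: TissueClass
    tissue_subtype: str = ""
    modalities_present: frozenset = field(default_factory=lambda: frozenset(MODALITIES))

    @property
    def effective_class(self) -> TissueClass:
        if self.class_pathologist is TissueClass.UNCLASSIFIED:
            logger.debug(
                "specimen %s unclassified by pathologist; using clinician label %s",
                self.specimen_id,
                self.class_clinician.value,
            )
            return self.class_clinician
        return self.class_pathologist


def saturation_mask(image: np.ndarray, detector_capacity: float) -> np.ndarray:
    """Boolean mask of pixels below the near-saturation threshold.

    A pixel is valid iff its intensity is strictly below 95% of the detector
    capacity; anything within 5% of full scale is treated as saturated.
    Idempotent in the sense that valid pixels stay valid on re-masking.
    """
    if not np.isfinite(detector_capacity) or detector_capacity <= 0:
        raise ParameterError(f"detector capacity must be positive, got {detector_capacity}")
    return np.asarray(image) < 0.95 * detector_capacity


def circular_roi_mask(shape, center, radius: float) -> np.ndarray:
    """Boolean mask of the circular region of interest.

    Pixel (r, c) belongs to the ROI iff its Euclidean distance from *center*
    is <= *radius*.  The circle must fit entirely inside the image grid.
    """
    nrow, ncol = int(shape[0]), int(shape[1])
    cr, cc = float(center[0]), float(center[1])
    if radius < 0:
        raise ParameterError("radius must be non-negative")
    if cr - radius < 0 or cc - radius < 0 or cr + radius > nrow - 1 or cc + radius > ncol - 1:
        raise ParameterError(
            f"circle center={center} radius={radius} exceeds grid bounds {shape}"
        )
    rr, cc_grid = np.ogrid[:nrow, :ncol]
    return (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius**2


def feature_modality(name: str) -> str:
    """Source modality of a namespaced feature name ("af.ex400_mean" -> "af")."""
    return name.split(".", 1)[0]


def effective_classes(records) -> pd.Series:
    """Series mapping specimen_id -> effective class label string."""
    return pd.Series(
        {r.specimen_id: r.effective_class.value for r in records}, name="class"
    )


def impute_class_means(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Replace missing cells with the class-conditional mean of the feature.

    Each NaN in column ``f`` for a specimen of class ``c`` becomes the mean of
    the observed values of ``f`` among the other specimens of class ``c``.
    Observed cells are returned unchanged, so per-class per-feature means are
    preserved exactly.

    Raises
    ------
    ImputationError
        If a (feature, class) group with a missing value has no observed value
        at all to impute from.
    """
    labels = pd.Series(labels).reindex(table.index)
    if labels.isna().any():
        missing = list(table.index[labels.isna()])
        raise ParameterError(f"no class label for specimens {missing}")
    out = table.copy()
    for cls, idx in table.groupby(labels).groups.items():
        block = table.loc[idx]
        col_missing = block.isna().any(axis=0)
        if not col_missing.any():
            continue
        means = block.mean(axis=0)  # skips NaN
        bad = block.columns[col_missing & means.isna()]
        if len(bad):
            raise ImputationError(
                f"feature(s) {list(bad)} have no observed value in class '{cls}'"
            )
        out.loc[idx] = block.fillna(means)
    return out


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV; missing cells serialize as empty fields."""
    table.to_csv(path, index_label="specimen_id", na_rep="")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    try:
        # round_trip parsing keeps 64-bit values bit-exact across a write/read
        table = pd.read_csv(path, index_col="specimen_id", float_precision="round_trip")
    except Exception as exc:  # surface row/column context from pandas
        raise ParameterError(f"malformed feature table {path}: {exc}") from exc
    if table.columns.duplicated().any():
        dup = list(table.columns[table.columns.duplicated()])
        raise ParameterError(f"duplicate feature names in {path}: {dup}")
    return table


_SPECIMEN_COLUMNS = [
    "specimen_id",
    "patient_id",
    "tissue_class",
    "tissue_type",
    "provenance",
    "class_clinician",
]


def write_specimen_table(records, provenance: dict | None = None, path=None) -> pd.DataFrame:
    """Tabulate specimen metadata with the published column set.

    ``provenance`` maps specimen_id to one of {"agree", "differ", "na"}:
    whether pathologist and clinician agreed, differed, or the pathologist
    could not classify the specimen.  When omitted it is derived from the
    two labels of each record.
    """
    rows = []
    for r in records:
        if provenance and r.specimen_id in provenance:
            prov = provenance[r.specimen_id]
        elif r.class_pathologist is TissueClass.UNCLASSIFIED:
            prov = "na"
        else:
            prov = "agree" if r.class_pathologist is r.class_clinician else "differ"
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "patient_id": r.patient_id,
                "tissue_class": r.effective_class.value,
                "tissue_type": r.tissue_subtype,
                "provenance": prov,
                "class_clinician": r.class_clinician.value,
            }
        )
    df = pd.DataFrame(rows, columns=_SPECIMEN_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_specimen_table(path) -> list[SpecimenRecord]:
    """Read specimen metadata CSV back into :class:`SpecimenRecord` objects."""
    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        clinician = TissueClass(row["class_clinician"])
        if row["provenance"] == "na":
            pathologist = TissueClass.UNCLASSIFIED
        else:
            pathologist = TissueClass(row["tissue_class"])
        records.append(
            SpecimenRecord(
                specimen_id=row["specimen_id"],
                patient_id=row["patient_id"],
                class_pathologist=pathologist,
                class_clinician=clinician,
                tissue_subtype=row.get("tissue_type", ""),
            )
        )
    ids = [r.specimen_id for r in records]
    if len(set(ids)) != len(ids):
        raise ParameterError(f"duplicate specimen ids in {path}")
    return records
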