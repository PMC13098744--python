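"""End-to-end orchestration: study -> feature table -> screening -> LOO ROC."""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd

from . import af, classify, hsi, oct as oct_mod, screening
from .config import PLI_WAVELENGTHS_NM, StudyConfig
from .containers import load_af_stack, load_hdf5, save_af_stack, save_hdf5
from .core import effective_classes, read_specimen_table, write_feature_table, write_specimen_table
from .polarimetry import extract_pli_features, mueller_from_stokes_measurements
from .synthetic import SyntheticStudy

logger = logging.getLogger("momix")

__all__ = [
    "extract_specimen_features",
    "extract_study_features",
    "run_screening",
    "run_classification",
    "save_study",
    "load_study",
]


def extract_specimen_features(modality_data: dict, config: StudyConfig) -> dict:
    """Feature map for one specimen from its per-modality data dict."""
    features: dict[str, float] = {}
    if "af" in modality_data:
        features.update(af.extract_af_features(modality_data["af"], config=config))
    if "hsi" in modality_data:
        features.update(hsi.extract_hsi_features(modality_data["hsi"], config=config))
    if "oct" in modality_data:
        features.update(oct_mod.extract_oct_features(modality_data["oct"], config=config))
    if "pli" in modality_data:
        fields = {}
        for wl, meas in modality_data["pli"].items():
            fields[wl] = None if meas is None else mueller_from_stokes_measurements(meas)
        features.update(extract_pli_features(fields, config=config))
    return features


def extract_study_features(study: SyntheticStudy, config: StudyConfig | None = None) -> pd.DataFrame:
    """Feature table (specimens x features) for a whole study."""
    config = config or StudyConfig()
    rows = {}
    t0 = time.perf_counter()
    for record in study.records:
        rows[record.specimen_id] = extract_specimen_features(
            study.data[record.specimen_id], config
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "specimen_id"
    logger.info(
        "extracted %d features x %d specimens in %.1f s",
        table.shape[1],
        table.shape[0],
        time.perf_counter() - t0,
    )
    return table


def run_screening(table, records, config: StudyConfig | None = None):
    config = config or StudyConfig()
    labels = effective_classes(records)
    patients = pd.Series({r.specimen_id: r.patient_id for r in records})
    return screening.screen_features(
        table, labels, patients, threshold=config.correlation_threshold, q=config.fdr_q
    )


def run_classification(table, records, config: StudyConfig | None = None, **kw):
    config = config or StudyConfig()
    labels = effective_classes(records)
    return classify.group_comparisons(table, labels, config=config, **kw)


def save_study(study: SyntheticStudy, outdir) -> None:
    """Write a study to disk in the formats the loaders read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_specimen_table(
        study.records, getattr(study, "provenance", None), outdir / "specimens.csv"
    )
    study.ground_truth.to_csv(outdir / "ground_truth.csv")
    for record in study.records:
        d = outdir / record.specimen_id
        d.mkdir(exist_ok=True)
        payload = study.data[record.specimen_id]
        if "af" in payload:
            save_af_stack(payload["af"], d / "af.tiff")
        if "hsi" in payload:
            save_hdf5(payload["hsi"], d / "hsi.h5")
        if "oct" in payload:
            save_hdf5(payload["oct"], d / "oct.h5")
        for wl, meas in payload.get("pli", {}).items():
            if meas is not None:
                save_hdf5(meas, d / f"pli_{wl}.h5")


def load_study(indir) -> SyntheticStudy:
    """Load a study written by :func:`save_study`."""
    indir = Path(indir)
    records = read_specimen_table(indir / "specimens.csv")
    ground_truth = pd.read_csv(indir / "ground_truth.csv", index_col="specimen_id")
    data = {}
    for record in records:
        d = indir / record.specimen_id
        payload = {}
        if (d / "af.tiff").exists():
            payload["af"] = load_af_stack(d / "af.tiff")
        if (d / "hsi.h5").exists():
            payload["hsi"] = load_hdf5(d / "hsi.h5")
        if (d / "oct.h5").exists():
            payload["oct"] = load_hdf5(d / "oct.h5")
        pli = {}
        for wl in PLI_WAVELENGTHS_NM:
            path = d / f"pli_{wl}.h5"
            pli[wl] = load_hdf5(path) if path.exists() else None
        if any(v is not None for v in pli.values()):
            payload["pli"] = pli
        data[record.specimen_id] = payload
    return SyntheticStudy(records, data, {}, ground_truth, params=None)
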