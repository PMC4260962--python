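"""Readers and writers: ROI images, cohort manifests, feature tables, models.

All on-disk artifacts are plain text (CSV/TSV, JSON) except the images;
feature tables are written with 17 significant digits so a write -> read
round trip reproduces every value exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import MODEL_SCHEMA_VERSION, FittedModel

logger = logging.getLogger("nucmorph")

MANIFEST_COLUMNS = ("patient_id", "label", "dataset_id", "roi_path")
MAX_ROIS_PER_PATIENT = 4


def read_roi_image(path: str | Path) -> np.ndarray:
    """Read a TIFF/PNG ROI as an H x W x 3 uint8 array.

    Raises with the offending path on a missing file, wrong channel count,
    or unsupported bit depth.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"ROI image not found: {p}")
    arr = iio.imread(p)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"{p}: expected a 3-channel RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{p}: unsupported bit depth {arr.dtype}; 8 bits per channel required")
    return arr


@dataclass
class PatientEntry:
    patient_id: str
    label: int
    dataset_id: str
    roi_paths: list[str]


@dataclass
class CohortManifest:
    """Patients with 1-4 ROI paths each and a binary diagnosis label."""

    patients: list[PatientEntry]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patient_id": p.patient_id, "label": p.label,
             "dataset_id": p.dataset_id, "roi_path": rp}
            for p in self.patients for rp in p.roi_paths
        ]
        return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))

    def __len__(self) -> int:
        return len(self.patients)


def manifest_from_frame(df: pd.DataFrame) -> CohortManifest:
    """Validate a one-row-per-ROI table and group it by patient."""
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("manifest is empty")
    bad_labels = set(df["label"].unique()) - {0, 1}
    if bad_labels:
        raise ValueError(f"unknown labels {sorted(bad_labels)}; labels must be 0 or 1")
    dup = df.duplicated(subset=["patient_id", "roi_path"])
    if dup.any():
        raise ValueError(f"duplicate (patient_id, roi_path) rows: "
                         f"{df.loc[dup, 'patient_id'].tolist()}")
    patients: list[PatientEntry] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        if len(grp) > MAX_ROIS_PER_PATIENT:
            raise ValueError(
                f"patient {pid} has {len(grp)} ROIs; each case must have "
                f"1 to {MAX_ROIS_PER_PATIENT} ROIs")
        if grp["label"].nunique() > 1 or grp["dataset_id"].nunique() > 1:
            raise ValueError(f"patient {pid} has inconsistent label or dataset_id")
        patients.append(PatientEntry(
            patient_id=str(pid), label=int(grp["label"].iloc[0]),
            dataset_id=str(grp["dataset_id"].iloc[0]),
            roi_paths=[str(r) for r in grp["roi_path"]]))
    return CohortManifest(patients=patients)


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a CSV/TSV cohort manifest (one row per ROI)."""
    p = Path(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(p, sep=sep)
    except pd.errors.EmptyDataError:
        raise ValueError(f"manifest {p} is empty") from None
    return manifest_from_frame(df)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a nucleus- or patient-level feature table as delimited text."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    p = Path(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    index = table.index.name is not None
    table.to_csv(p, sep=sep, float_format="%.17g", index=index)


def read_feature_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    p = Path(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(p, sep=sep, index_col=index_col, float_precision="round_trip")


def save_model(model: FittedModel, path: str | Path) -> None:
    """Serialize a fitted model (weights, intercept, standardization) to JSON."""
    payload = {
        "schema_version": model.schema_version,
        "lambda": model.lam,
        "intercept": model.intercept,
        "weights": model.weights,
        "feature_names": model.feature_names,
        "standardization": model.standardization,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> FittedModel:
    p = Path(path)
    try:
        payload = json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"corrupted model file {p}: {e}") from None
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"{p}: model schema version {version} unsupported "
                         f"(expected {MODEL_SCHEMA_VERSION})")
    return FittedModel(
        lam=float(payload["lambda"]), intercept=float(payload["intercept"]),
        weights={k: float(v) for k, v in payload["weights"].items()},
        feature_names=list(payload["feature_names"]),
        standardization=payload.get("standardization", {}),
        schema_version=version,
    )
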