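"""Patient-level summarization: 196 per-nucleus features -> 392 per patient.

Nuclei are pooled across a patient's ROIs with equal weight per nucleus;
for every per-nucleus feature the mean and the n-1 sample standard
deviation are reported, named ``Mean_<feature>`` and ``SD_<feature>``.
Patients with fewer than two nuclei are excluded (the SD is undefined)
with a logged reason.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import NUCLEUS_FEATURE_NAMES

logger = logging.getLogger("nucmorph")

#: The 392 summary column names: {Mean, SD} x 196 per-nucleus features.
PATIENT_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{prefix}_{name}" for name in NUCLEUS_FEATURE_NAMES for prefix in ("Mean", "SD")
)

#: Identifier columns of a nucleus feature table.
ID_COLUMNS: tuple[str, ...] = ("patient_id", "roi_id", "nucleus_label")


def summarize_patient(records: pd.DataFrame) -> pd.Series:
    """392 summary values for one patient's pooled nucleus records."""
    feats = records[list(NUCLEUS_FEATURE_NAMES)]
    if len(feats) < 2:
        raise ValueError("patient summarization requires >= 2 nuclei (SD undefined)")
    means = feats.mean(axis=0)
    sds = feats.std(axis=0, ddof=1)
    out = {}
    for name in NUCLEUS_FEATURE_NAMES:
        out[f"Mean_{name}"] = float(means[name])
        out[f"SD_{name}"] = float(sds[name])
    return pd.Series(out, index=list(PATIENT_FEATURE_NAMES))


def summarize_cohort(records: pd.DataFrame, manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """One 392-feature row per patient; patients with < 2 nuclei are dropped.

    ``manifest`` (optional) supplies per-patient ``label`` and
    ``dataset_id`` columns to prepend.
    """
    rows = []
    for patient_id, group in records.groupby("patient_id", sort=True):
        if len(group) < 2:
            logger.warning("patient %s excluded: %d nucleus (SD undefined)", patient_id, len(group))
            continue
        row = summarize_patient(group)
        row["patient_id"] = patient_id
        rows.append(row)
    if not rows:
        raise ValueError("no patient with >= 2 nuclei")
    table = pd.DataFrame(rows).set_index("patient_id")
    table = table[list(PATIENT_FEATURE_NAMES)]
    if manifest is not None:
        meta = manifest.drop_duplicates("patient_id").set_index("patient_id")
        table.insert(0, "label", meta.loc[table.index, "label"].astype(int))
        table.insert(1, "dataset_id", meta.loc[table.index, "dataset_id"])
    return table
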