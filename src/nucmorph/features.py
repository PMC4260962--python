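"""Per-nucleus feature assembly: 12 shape + 40 first-order + 144 texture = 196.

This module glues segmentation and the three feature families into the
canonical 196-value record per nucleus and the per-ROI extraction loop.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .color import ChannelStack, build_channel_stack
from .config import PipelineConfig
from .firstorder import FIRSTORDER_FEATURE_NAMES, compute_firstorder
from .segment import NucleusObject, segment_roi
from .shape import SHAPE_FEATURE_NAMES, compute_shape
from .texture import TEXTURE_FEATURE_NAMES, compute_texture

logger = logging.getLogger("nucmorph")

#: The 196 per-nucleus feature names in canonical column order.
NUCLEUS_FEATURE_NAMES: tuple[str, ...] = (
    SHAPE_FEATURE_NAMES + FIRSTORDER_FEATURE_NAMES + TEXTURE_FEATURE_NAMES
)


def compute_nucleus_features(
    nucleus: NucleusObject, stack: ChannelStack, config: PipelineConfig | None = None
) -> dict[str, float]:
    """All 196 named feature values for one nucleus."""
    cfg = config or PipelineConfig()
    out: dict[str, float] = {}
    out.update(compute_shape(nucleus))
    out.update(compute_firstorder(nucleus, stack))
    out.update(compute_texture(nucleus, stack, cfg.n_grey_levels))
    return out


def extract_roi_features(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    patient_id: str = "",
    roi_id: str = "",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment one ROI and compute the 196 features for each nucleus.

    Returns (records, label map); ``records`` has one row per nucleus with
    id columns followed by the 196 canonical feature columns.
    """
    cfg = config or PipelineConfig()
    labels, objects = segment_roi(img, cfg)
    stack = build_channel_stack(img, cfg.stain_matrix)
    rows = []
    for obj in objects:
        if obj.area_px < 4:
            logger.warning("nucleus %s/%s#%d skipped: %d px (< 4, moments undefined)",
                           patient_id, roi_id, obj.label, obj.area_px)
            continue
        row = {"patient_id": patient_id, "roi_id": roi_id, "nucleus_label": obj.label}
        row.update(compute_nucleus_features(obj, stack, cfg))
        rows.append(row)
    columns = ["patient_id", "roi_id", "nucleus_label", *NUCLEUS_FEATURE_NAMES]
    records = pd.DataFrame(rows, columns=columns)
    logger.info("extract: %s/%s -> %d nuclei x %d features",
                patient_id, roi_id, len(records), len(NUCLEUS_FEATURE_NAMES))
    return records, labels
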