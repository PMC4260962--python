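"""Pipeline configuration.

A single :class:`PipelineConfig` carries every tunable parameter of the
pipeline — segmentation gates, the nucleus size filter, grey-level
quantization, the regularization grid and cross-validation setup — plus the
one random seed from which all randomness (CV folds, synthetic cohorts)
flows.  The config round-trips losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Published optical-density vectors for hematoxylin and eosin in RGB-OD
#: space (rows are stains).  Normalized to unit Euclidean norm on load.
DEFAULT_STAIN_VECTORS: tuple[tuple[float, float, float], ...] = (
    (0.650, 0.704, 0.286),  # hematoxylin
    (0.072, 0.990, 0.105),  # eosin
)


def _normalize_stains(rows) -> tuple[tuple[float, ...], ...]:
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] not in (2, 3):
        raise ValueError("stain matrix must be 2x3 or 3x3")
    norms = np.linalg.norm(arr, axis=1)
    if np.any(norms == 0):
        raise ValueError("stain vector with zero norm")
    arr = arr / norms[:, None]
    if np.linalg.matrix_rank(arr) < arr.shape[0]:
        raise ValueError("stain vectors are linearly dependent")
    return tuple(tuple(float(v) for v in row) for row in arr)


@dataclass
class PipelineConfig:
    """All pipeline parameters with the defaults used throughout.

    Units: lengths in pixels at the nominal acquisition scale of
    ``pixel_size_um`` µm/px (40x magnification); hue in degrees;
    saturation/value in [0, 1].
    """

    # acquisition
    pixel_size_um: float = 0.25

    # segmentation: HSV gate bracketing hematoxylin blue-purple
    hue_range: tuple[float, float] = (180.0, 320.0)
    sat_min: float = 0.15
    val_max: float = 0.85
    closing_radius: int = 2
    marker_min_distance: int = 8
    min_area_px: int = 200
    max_area_px: int = 4000

    # texture quantization
    n_grey_levels: int = 32

    # classifier
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    cv_folds: int = 9

    # randomness
    seed: int = 0

    # color deconvolution (rows re-normalized on construction)
    stain_vectors: tuple[tuple[float, ...], ...] = DEFAULT_STAIN_VECTORS

    def __post_init__(self) -> None:
        self.stain_vectors = _normalize_stains(self.stain_vectors)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (0 <= self.sat_min <= 1 and 0 <= self.val_max <= 1):
            raise ValueError("sat_min and val_max must lie in [0, 1]")
        if self.min_area_px <= 0 or self.max_area_px <= 0:
            raise ValueError("size-filter bounds must be positive")
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px exceeds max_area_px")
        if self.n_grey_levels < 2:
            raise ValueError("n_grey_levels must be >= 2")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_lambda < 2 or not (0 < self.lambda_min_ratio < 1):
            raise ValueError("invalid lambda grid parameters")
        hue = tuple(float(h) for h in self.hue_range)
        if not all(0 <= h < 360 for h in hue):
            raise ValueError("hue_range values must lie in [0, 360)")
        self.hue_range = hue

    @property
    def stain_matrix(self) -> np.ndarray:
        return np.asarray(self.stain_vectors, dtype=float)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        data["hue_range"] = tuple(data["hue_range"])
        data["stain_vectors"] = tuple(tuple(r) for r in data["stain_vectors"])
        return cls(**data)
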