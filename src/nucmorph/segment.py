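"""Nuclei segmentation: HSV gate -> morphological cleanup -> watershed -> size filter.

Coordinates are 0-based row-major; bounding boxes are half-open
``(row0, col0, height, width)``.  Connected components use 4-connectivity;
boundary tracing uses 8-connectivity so contours stay closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.segmentation import watershed as _watershed

from .color import to_hsv
from .config import PipelineConfig

logger = logging.getLogger("nucmorph")

_STRUCT4 = ndi.generate_binary_structure(2, 1)
_STRUCT8 = ndi.generate_binary_structure(2, 2)


@dataclass
class NucleusObject:
    """One segmented nucleus: local mask, bbox, closed contour, area."""

    label: int
    mask: np.ndarray              # bounding-box-local booleans
    bbox: tuple[int, int, int, int]  # (row0, col0, height, width), half-open
    contour: np.ndarray           # (n, 2) float row/col vertices, closed
    area_px: int

    @property
    def global_coords(self) -> tuple[np.ndarray, np.ndarray]:
        rr, cc = np.nonzero(self.mask)
        return rr + self.bbox[0], cc + self.bbox[1]


def hsv_threshold(
    img: np.ndarray,
    hue_range: tuple[float, float] = (180.0, 320.0),
    sat_min: float = 0.15,
    val_max: float = 0.85,
) -> np.ndarray:
    """Gate pixels by hue window (circular), minimum saturation, maximum value.

    A wrap-around window (lo > hi) is handled circularly, e.g. 350° -> 20°.
    """
    lo, hi = float(hue_range[0]), float(hue_range[1])
    if lo == hi:
        raise ValueError("empty hue range")
    hsv = to_hsv(img)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    if lo < hi:
        in_hue = (h >= lo) & (h <= hi)
    else:
        in_hue = (h >= lo) | (h <= hi)
    return in_hue & (s >= sat_min) & (v <= val_max)


def clean_mask(mask: np.ndarray, closing_radius: int = 2) -> np.ndarray:
    """Fill holes and close with a disk element to merge scattered fragments.

    The result is a superset of the hole-filled input (closing is extensive).
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return m.copy()
    filled = ndi.binary_fill_holes(m, structure=_STRUCT4)
    closed = morphology.closing(filled, morphology.disk(closing_radius))
    return ndi.binary_fill_holes(closed | filled, structure=_STRUCT4)


def watershed_split(mask: np.ndarray, marker_min_distance: int = 8) -> np.ndarray:
    """Separate touching nuclei by watershed on the negated distance transform.

    Markers are the regional maxima of the Euclidean distance transform,
    suppressed within a ``(2 h + 1)``-sized window so two markers are at
    least about ``h`` apart; connected maxima plateaus collapse into a
    single marker.  Foreground components left unmarked (entirely dominated
    by a larger neighbour within the window) are appended as their own
    labels, so every foreground pixel receives exactly one label.
    """
    m = np.asarray(mask, dtype=bool)
    labels = np.zeros(m.shape, dtype=np.int32)
    if not m.any():
        return labels
    edt = ndi.distance_transform_edt(m)
    size = 2 * int(marker_min_distance) + 1
    peaks = (edt == ndi.maximum_filter(edt, size=size)) & m
    markers, _ = ndi.label(peaks, structure=_STRUCT8)
    labels = _watershed(-edt, markers, mask=m, connectivity=1).astype(np.int32)
    leftover = m & (labels == 0)
    if leftover.any():
        extra, n_extra = ndi.label(leftover, structure=_STRUCT4)
        labels[leftover] = extra[leftover] + labels.max()
    return _compact_labels(labels)


def _compact_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1..K preserving label order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


def size_filter(labels: np.ndarray, min_px: int = 200, max_px: int = 4000) -> np.ndarray:
    """Keep regions whose area lies in the closed interval [min_px, max_px]."""
    if min_px > max_px:
        raise ValueError("min_px exceeds max_px")
    lab = np.asarray(labels)
    if lab.max() == 0:
        return lab.astype(np.int32)
    areas = np.bincount(lab.ravel())
    keep = (areas >= min_px) & (areas <= max_px)
    keep[0] = False
    out = np.where(keep[lab], lab, 0).astype(np.int32)
    return _compact_labels(out)


def _trace_contour(local_mask: np.ndarray) -> np.ndarray:
    """Closed outer boundary of a region as subpixel iso-contour vertices."""
    padded = np.pad(local_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo padding offset
    if not np.array_equal(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    return contour


def extract_objects(labels: np.ndarray, img: np.ndarray | None = None) -> list[NucleusObject]:
    """Build one :class:`NucleusObject` per label, ordered by label."""
    lab = np.asarray(labels)
    objects: list[NucleusObject] = []
    for region in measure.regionprops(lab):
        r0, c0, r1, c1 = region.bbox
        local = lab[r0:r1, c0:c1] == region.label
        objects.append(
            NucleusObject(
                label=int(region.label),
                mask=local,
                bbox=(int(r0), int(c0), int(r1 - r0), int(c1 - c0)),
                contour=_trace_contour(local) + np.array([r0, c0], dtype=float),
                area_px=int(region.area),
            )
        )
    return objects


def segment_roi(img: np.ndarray, config: PipelineConfig | None = None) -> tuple[np.ndarray, list[NucleusObject]]:
    """Full segmentation of one ROI; returns (label map, nucleus objects)."""
    cfg = config or PipelineConfig()
    raw = hsv_threshold(img, cfg.hue_range, cfg.sat_min, cfg.val_max)
    cleaned = clean_mask(raw, cfg.closing_radius)
    labels = watershed_split(cleaned, cfg.marker_min_distance)
    n_before = int(labels.max())
    filtered = size_filter(labels, cfg.min_area_px, cfg.max_area_px)
    objects = extract_objects(filtered, img)
    logger.info(
        "segment: %d candidate regions, %d pass size filter [%d, %d] px",
        n_before, len(objects), cfg.min_area_px, cfg.max_area_px,
    )
    return filtered, objects
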