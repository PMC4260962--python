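"""Morphological features: the 12 shape descriptors per nucleus.

Conventions (documented once, used everywhere):

* area = pixel count; lengths in pixels (physical units derivable through
  the configured pixel size).
* perimeter = Crofton estimate over 4 directions — a standard unbiased line
  -intercept estimator; it is exactly invariant under 90° rotations and can
  slightly undershoot a smooth outline, so circularity is clipped at 1.
* equivalent spherical perimeter ESP = 2 sqrt(pi * area), the perimeter of
  the circle with the region's area.
* ellipse axes come from the eigenvalues of the second-central-moment
  matrix, rescaled so the ellipse area equals the region area.
* bounding rectangle is axis-aligned; Feret's diameter is the maximum
  pairwise distance between convex-hull vertices of pixel centers.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure, morphology

from .segment import NucleusObject

logger = logging.getLogger("nucmorph")

#: Column names of the 12 shape features, in canonical order.
SHAPE_FEATURE_NAMES: tuple[str, ...] = (
    "Area", "Perim", "ESP", "Width", "Height", "Major", "Minor",
    "Circ", "AR", "Round", "Solidity", "Feret",
)


def fit_ellipse_moments(mask: np.ndarray) -> tuple[float, float, float]:
    """(major, minor, orientation) of the area-matched moment ellipse.

    Axis lengths are full diameters; the ellipse has the same second-moment
    eigen-directions as the region and exactly the region's area.
    Orientation is the angle (radians, in (-pi/2, pi/2]) of the major axis
    measured from the row axis.  Degenerate (collinear) regions have the
    minor axis floored at 1 px.
    """
    rr, cc = np.nonzero(mask)
    n = rr.size
    if n < 2:
        raise ValueError("ellipse fit requires >= 2 pixels")
    r0, c0 = rr.mean(), cc.mean()
    dr, dc = rr - r0, cc - c0
    mu20 = float(np.mean(dr * dr))
    mu02 = float(np.mean(dc * dc))
    mu11 = float(np.mean(dr * dc))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_minor, lam_major = max(evals[0], 0.0), max(evals[1], 0.0)
    vec = evecs[:, 1]
    orientation = float(np.arctan2(vec[1], vec[0]))
    if orientation <= -np.pi / 2:
        orientation += np.pi
    elif orientation > np.pi / 2:
        orientation -= np.pi
    area = float(n)
    if lam_minor <= 0:
        logger.debug("degenerate region (collinear pixels): minor axis floored at 1 px")
        minor = 1.0
        major = 4.0 * area / np.pi  # keep pi/4 * major * minor = area
    else:
        ratio = np.sqrt(lam_major / lam_minor)  # major/minor
        minor = 2.0 * np.sqrt(area / (np.pi * ratio))
        major = ratio * minor
    return major, minor, orientation


def _feret_diameter(mask: np.ndarray) -> float:
    """Max pairwise distance over convex-hull vertices of pixel centers."""
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    if len(pts) == 1:
        return 0.0
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # collinear
        verts = pts
    return float(pdist(verts).max())


def compute_shape(nucleus: NucleusObject) -> dict[str, float]:
    """The 12 morphological features of one nucleus."""
    mask = nucleus.mask
    area = float(mask.sum())
    if area < 1:
        raise ValueError("empty nucleus mask")
    perim = float(measure.perimeter_crofton(mask, directions=4))
    esp = 2.0 * np.sqrt(np.pi * area)
    height, width = float(mask.shape[0]), float(mask.shape[1])
    if area >= 2:
        major, minor, _ = fit_ellipse_moments(mask)
    else:
        major = minor = 1.0
    circ = min(1.0, 4.0 * np.pi * area / perim**2) if perim > 0 else 1.0
    hull_area = float(morphology.convex_hull_image(mask).sum())
    return {
        "Area": area,
        "Perim": perim,
        "ESP": float(esp),
        "Width": width,
        "Height": height,
        "Major": float(major),
        "Minor": float(minor),
        "Circ": float(circ),
        "AR": float(major / minor),
        "Round": float(4.0 * area / (np.pi * major**2)),
        "Solidity": float(area / hull_area),
        "Feret": _feret_diameter(mask),
    }
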