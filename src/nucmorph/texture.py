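"""Second-order texture features: co-occurrence (GLCM) and run-length (GLRLM).

Per nucleus and per channel, masked pixel values are linearly quantized to
grey levels 1..N_g, and two matrices are built over four directions
(horizontal, vertical, the two diagonals) at displacement 1:

* GLCM — symmetric pair counts (both orderings) restricted to pixel pairs
  that lie entirely inside the nucleus mask, normalized to sum 1 per
  direction and averaged over the directions that contain at least one
  pair.  Eight Haralick-style statistics are derived from the average.
* GLRLM — counts of maximal collinear runs of equal level; mask gaps
  terminate runs.  The four per-direction matrices are zero-padded to a
  common maximum run length and averaged entrywise.  Ten run-emphasis
  statistics are derived.

With 8 channels this yields 64 + 80 = 144 texture values per nucleus.
A nucleus whose mask admits no valid pair in any direction receives the
constant-region limits (energy 1, entropy 0, inertia 0, IDM 1, remaining
features 0).
"""

from __future__ import annotations

import numpy as np

from .color import CHANNEL_SUFFIX, ChannelStack
from .segment import NucleusObject

#: The four displacement offsets (row, col) at d = 1.
OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "Correlation", "ClusterShade", "ClusterProminence", "Energy",
    "Entropy", "HaraCorrelation", "IDM", "Inertia",
)
GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "SRE", "LRE", "GLN", "RLN", "LGLRE", "HGLRE",
    "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
)

#: The 144 texture column names, channel-major order following the stack.
TEXTURE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{feat}_{suffix}"
    for suffix in CHANNEL_SUFFIX.values()
    for feat in GLCM_FEATURE_NAMES + GLRLM_FEATURE_NAMES
)

#: Feature values of a constant (or pair-less) region.
CONSTANT_GLCM_FEATURES: dict[str, float] = {
    "Correlation": 0.0, "ClusterShade": 0.0, "ClusterProminence": 0.0,
    "Energy": 1.0, "Entropy": 0.0, "HaraCorrelation": 0.0,
    "IDM": 1.0, "Inertia": 0.0,
}


def quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Linear min-max binning of values into integer levels 1..n_levels.

    A constant input maps entirely to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return np.ones(v.shape, dtype=np.int32)
    levels = 1 + np.floor((v - lo) / (hi - lo) * n_levels).astype(np.int32)
    return np.minimum(levels, n_levels)


def glcm_single_direction(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, offset: tuple[int, int]
) -> np.ndarray:
    """Symmetric pair-count matrix for one displacement (unnormalized)."""
    lv = np.where(mask, levels, 0).astype(np.int64)
    dr, dc = offset
    h, w = lv.shape
    a = lv[max(dr, 0):h + min(dr, 0), max(dc, 0):w + min(dc, 0)]
    b = lv[max(-dr, 0):h + min(-dr, 0), max(-dc, 0):w + min(-dc, 0)]
    valid = (a > 0) & (b > 0)
    ai, bi = a[valid] - 1, b[valid] - 1
    counts = np.bincount(ai * n_levels + bi, minlength=n_levels * n_levels)
    mat = counts.reshape(n_levels, n_levels).astype(np.float64)
    return mat + mat.T


def build_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray | None:
    """Four-direction averaged, normalized, symmetric GLCM.

    Directions with zero valid in-mask pairs are skipped from the average.
    Returns None when no direction has a pair (feature values then fall
    back to the constant-region limits).
    """
    mats = []
    for offset in OFFSETS:
        m = glcm_single_direction(levels, mask, n_levels, offset)
        total = m.sum()
        if total > 0:
            mats.append(m / total)
    if not mats:
        return None
    return np.mean(mats, axis=0)


def glcm_features(p: np.ndarray) -> dict[str, float]:
    """The 8 co-occurrence statistics of a normalized symmetric GLCM."""
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))
    energy = float(np.sum(p**2))
    pos = p[p > 0]
    entropy = float(-np.sum(pos * np.log2(pos)))
    inertia = float(np.sum((ii - jj) ** 2 * p))
    idm = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    corr = float((np.sum(ii * jj * p) - mu * mu) / sigma2) if sigma2 > 0 else 0.0
    shade = float(np.sum((ii + jj - 2 * mu) ** 3 * p))
    prominence = float(np.sum((ii + jj - 2 * mu) ** 4 * p))
    # classic marginal form; equals `corr` for a symmetric normalized matrix
    py = p.sum(axis=0)
    mux, muy = float(np.sum(i * px)), float(np.sum(i * py))
    sx = float(np.sqrt(np.sum((i - mux) ** 2 * px)))
    sy = float(np.sqrt(np.sum((i - muy) ** 2 * py)))
    hara = float((np.sum(ii * jj * p) - mux * muy) / (sx * sy)) if sx > 0 and sy > 0 else 0.0
    return {
        "Correlation": corr, "ClusterShade": shade, "ClusterProminence": prominence,
        "Energy": energy, "Entropy": entropy, "HaraCorrelation": hara,
        "IDM": idm, "Inertia": inertia,
    }


def _direction_lines(levels: np.ndarray, mask: np.ndarray, offset: tuple[int, int]) -> list[np.ndarray]:
    """The collinear in-bbox pixel sequences for one direction (masked-out = 0)."""
    lv = np.where(mask, levels, 0).astype(np.int64)
    dr, dc = offset
    if (dr, dc) == (0, 1):
        return [lv[r] for r in range(lv.shape[0])]
    if (dr, dc) == (1, 0):
        return [lv[:, c] for c in range(lv.shape[1])]
    if (dr, dc) == (1, 1):
        return [np.diagonal(lv, k) for k in range(-lv.shape[0] + 1, lv.shape[1])]
    if (dr, dc) == (1, -1):
        fl = lv[:, ::-1]
        return [np.diagonal(fl, k) for k in range(-fl.shape[0] + 1, fl.shape[1])]
    raise ValueError(f"unsupported offset {offset}")


def glrlm_single_direction(
    levels: np.ndarray, mask: np.ndarray, n_levels: int, offset: tuple[int, int]
) -> np.ndarray:
    """Run-length count matrix (n_levels x R_max) for one direction.

    Row i-1 holds counts of maximal runs of level i by length; pixels
    outside the mask terminate runs and are not counted.
    """
    lines = _direction_lines(levels, mask, offset)
    # concatenate with 0 separators so runs never bridge lines
    seq = np.concatenate([np.concatenate([line, [0]]) for line in lines])
    boundaries = np.flatnonzero(np.diff(seq) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [seq.size]])
    vals = seq[starts]
    lens = ends - starts
    keep = vals > 0
    vals, lens = vals[keep], lens[keep]
    r_max = int(lens.max()) if lens.size else 1
    mat = np.zeros((n_levels, r_max), dtype=np.float64)
    np.add.at(mat, (vals - 1, lens - 1), 1.0)
    return mat


def build_glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Four-direction GLRLM: matrices zero-padded to common R, averaged."""
    mats = [glrlm_single_direction(levels, mask, n_levels, off) for off in OFFSETS]
    r_max = max(m.shape[1] for m in mats)
    out = np.zeros((n_levels, r_max), dtype=np.float64)
    for m in mats:
        out[:, : m.shape[1]] += m
    return out / len(mats)


def glrlm_features(r: np.ndarray) -> dict[str, float]:
    """The 10 run-length statistics of a (possibly averaged) GLRLM."""
    n_r = float(r.sum())
    if n_r <= 0:
        raise ValueError("empty run-length matrix")
    n_levels, r_max = r.shape
    i = np.arange(1, n_levels + 1, dtype=np.float64)[:, None]
    j = np.arange(1, r_max + 1, dtype=np.float64)[None, :]
    return {
        "SRE": float(np.sum(r / j**2) / n_r),
        "LRE": float(np.sum(r * j**2) / n_r),
        "GLN": float(np.sum(r.sum(axis=1) ** 2) / n_r),
        "RLN": float(np.sum(r.sum(axis=0) ** 2) / n_r),
        "LGLRE": float(np.sum(r / i**2) / n_r),
        "HGLRE": float(np.sum(r * i**2) / n_r),
        "SRLGLE": float(np.sum(r / (i**2 * j**2)) / n_r),
        "SRHGLE": float(np.sum(r * i**2 / j**2) / n_r),
        "LRLGLE": float(np.sum(r * j**2 / i**2) / n_r),
        "LRHGLE": float(np.sum(r * i**2 * j**2) / n_r),
    }


def compute_texture(nucleus: NucleusObject, stack: ChannelStack, n_levels: int = 32) -> dict[str, float]:
    """The 144 texture features (18 statistics x 8 channels) of one nucleus."""
    r0, c0, h, w = nucleus.bbox
    mask = nucleus.mask
    out: dict[str, float] = {}
    for name, plane in stack:
        suffix = CHANNEL_SUFFIX[name]
        local = plane[r0:r0 + h, c0:c0 + w]
        levels = np.zeros(mask.shape, dtype=np.int32)
        levels[mask] = quantize(local[mask], n_levels)
        glcm = build_glcm(levels, mask, n_levels)
        feats = CONSTANT_GLCM_FEATURES if glcm is None else glcm_features(glcm)
        for k in GLCM_FEATURE_NAMES:
            out[f"{k}_{suffix}"] = feats[k]
        rlm = build_glrlm(levels, mask, n_levels)
        rfeats = glrlm_features(rlm)
        for k in GLRLM_FEATURE_NAMES:
            out[f"{k}_{suffix}"] = rfeats[k]
    return out
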