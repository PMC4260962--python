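"""First-order intensity statistics per nucleus, on each of the 8 channels.

Five statistics per channel — mean, median, variance, skewness, kurtosis —
giving 40 values per nucleus.  The dispersion column is emitted as
``Variance`` (the square of the n-1 sample standard deviation) to match the
historical feature naming; moment-based (biased) skewness and *excess*
kurtosis are used, with the convention that a constant region has skewness
0 and kurtosis 0.  Statistics are computed on the float channel planes, not
the 8-bit quantized views.
"""

from __future__ import annotations

import numpy as np

from .color import CHANNEL_SUFFIX, ChannelStack
from .segment import NucleusObject

#: Statistic names in canonical order.
FIRSTORDER_STATS: tuple[str, ...] = ("Mean", "Median", "Variance", "Skewness", "Kurtosis")

#: The 40 column names, channel-major order following the stack.
FIRSTORDER_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{suffix}" for suffix in CHANNEL_SUFFIX.values() for stat in FIRSTORDER_STATS
)


def firstorder_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, median, variance (n-1), skewness g1 and excess kurtosis of a sample."""
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    if n < 4:
        raise ValueError("first-order moments require >= 4 pixels")
    mean = float(v.mean())
    centered = v - mean
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        skew, kurt = 0.0, 0.0
    else:
        skew = float(np.mean(centered**3) / m2**1.5)
        kurt = float(np.mean(centered**4) / m2**2 - 3.0)
    return {
        "Mean": mean,
        "Median": float(np.median(v)),
        "Variance": float(v.var(ddof=1)),
        "Skewness": skew,
        "Kurtosis": kurt,
    }


def compute_firstorder(nucleus: NucleusObject, stack: ChannelStack) -> dict[str, float]:
    """The 40 first-order features (5 statistics x 8 channels) of one nucleus."""
    r0, c0, h, w = nucleus.bbox
    out: dict[str, float] = {}
    for name, plane in stack:
        values = plane[r0:r0 + h, c0:c0 + w][nucleus.mask]
        stats = firstorder_stats(values)
        suffix = CHANNEL_SUFFIX[name]
        for stat in FIRSTORDER_STATS:
            out[f"{stat}_{suffix}"] = stats[stat]
    return out
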