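import numpy as np
import pytest

from nucmorph import CohortSpec, PipelineConfig, render_roi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_roi():
    """One rendered ROI of each class with ground truth (session-cached)."""
    spec = CohortSpec(nuclei_per_roi=12, roi_size=200, seed=7)
    img0, truth0 = render_roi(spec, 0, np.random.default_rng(7))
    img1, truth1 = render_roi(spec, 1, np.random.default_rng(8))
    return {"spec": spec, 0: (img0, truth0), 1: (img1, truth1)}


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    size = 2 * (radius + pad) + 1
    c = radius + pad
    rr, cc = np.mgrid[0:size, 0:size]
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


def rect_mask(h: int, w: int, pad: int = 2) -> np.ndarray:
    m = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
    m[pad:pad + h, pad:pad + w] = True
    return m
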