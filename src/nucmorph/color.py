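"""Color transforms: build the 8-channel grey-level stack from an RGB ROI.

The channels, in canonical order, are the red, green and blue planes of the
RGB image, the Value plane of HSV, the CIE L* planes of Lab and Luv (equal
by construction — both are CIE L*; two channels are kept for fidelity to the
original 8-channel schema), the Blue-Ratio transform that accentuates the
hematoxylin dye, and the hematoxylin concentration plane recovered by color
deconvolution of the H&E stains.

Conventions
-----------
* Input images are H x W x 3 uint8 (sRGB assumed, D65 white point).
* Optical density is ``OD = -log10((I + 1) / 256)`` per channel, so a fully
  transmitting pixel (I = 255) has OD exactly 0 and the log is always
  defined (one grey level of regularization).
* Every plane is kept as float; an 8-bit view (per-ROI min-max rescale) is
  attached for consumers that need a bounded grey-level range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

#: Canonical channel names of the stack, in fixed order.
CHANNEL_NAMES: tuple[str, ...] = (
    "Red", "Green", "Blue", "V_HSV", "L_Lab", "L_Luv", "BR", "H_HE",
)

#: Suffix used in feature-column names for each channel.
CHANNEL_SUFFIX: dict[str, str] = {
    "Red": "Red", "Green": "Green", "Blue": "Blue",
    "V_HSV": "HSV", "L_Lab": "Lab", "L_Luv": "Luv",
    "BR": "BR", "H_HE": "HE",
}


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB array, got shape {arr.shape}")
    return arr


@dataclass
class ChannelStack:
    """The 8 grey-level planes derived from one RGB ROI.

    ``planes`` maps canonical channel name to a float H x W array;
    ``quantized`` holds the per-ROI min-max rescaled uint8 views.
    """

    planes: dict[str, np.ndarray]
    quantized: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if tuple(self.planes) != CHANNEL_NAMES:
            raise ValueError("channel stack must contain exactly the 8 canonical channels")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError("all planes must share the same shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def __iter__(self):
        return iter(self.planes.items())


def to_hsv(img: np.ndarray) -> np.ndarray:
    """Hexcone HSV with H in degrees [0, 360), S and V in [0, 1].

    Undefined hue (grey pixels) is reported as 0.
    """
    arr = _validate_rgb(img)
    hsv = skcolor.rgb2hsv(arr.astype(np.float64) / 255.0)
    hsv[..., 0] *= 360.0
    return hsv


def _cie_lightness(img: np.ndarray) -> np.ndarray:
    """CIE L* in [0, 100] from sRGB (D65) via relative luminance Y."""
    arr = _validate_rgb(img)
    y = skcolor.rgb2xyz(arr.astype(np.float64) / 255.0)[..., 1]
    eps = (6.0 / 29.0) ** 3
    f = np.where(y > eps, np.cbrt(y), y / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
    return 116.0 * f - 16.0


def to_lab_l(img: np.ndarray) -> np.ndarray:
    """CIE L* in [0, 100] from sRGB (D65), i.e. the L plane of Lab."""
    return _cie_lightness(img)


def to_luv_l(img: np.ndarray) -> np.ndarray:
    """The L plane of Luv — the same CIE L* as Lab's, by definition.

    Computed through one shared code path so the two planes are bit-equal;
    both channels are retained for fidelity to the 8-channel schema.
    """
    return _cie_lightness(img)


def blue_ratio(img: np.ndarray) -> np.ndarray:
    """Blue-Ratio transform: BR = (100 B / (1 + R + G)) * (256 / (1 + R + G + B)).

    Pixels whose blue component dominates red and green — hematoxylin-stained
    nuclei — receive high values.  Denominators are >= 1 by construction, so
    the transform is total and non-negative.
    """
    arr = _validate_rgb(img).astype(np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    return (100.0 * b / (1.0 + r + g)) * (256.0 / (1.0 + r + g + b))


def rgb_to_od(img: np.ndarray) -> np.ndarray:
    """Per-channel optical density: OD = -log10((I + 1) / 256)."""
    arr = np.asarray(img, dtype=np.float64)
    return -np.log10((arr + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded and clipped to uint8."""
    inten = 256.0 * np.power(10.0, -np.asarray(od, dtype=np.float64)) - 1.0
    return np.clip(np.rint(inten), 0, 255).astype(np.uint8)


def he_deconvolve(img: np.ndarray, stain_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Separate hematoxylin and eosin by color deconvolution.

    ``stain_matrix`` has one unit-norm OD row vector per stain (hematoxylin
    first).  Concentrations are the OD image projected through the
    pseudo-inverse of the stain matrix, clipped at zero.  Returns the
    (hematoxylin, eosin) concentration planes.
    """
    m = np.asarray(stain_matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("stain matrix must have shape (n_stains, 3)")
    if np.linalg.matrix_rank(m) < m.shape[0]:
        raise ValueError("singular stain matrix")
    od = rgb_to_od(np.asarray(img, dtype=np.float64)[..., :3])
    conc = od @ np.linalg.pinv(m)
    conc = np.clip(conc, 0.0, None)
    return conc[..., 0], conc[..., 1]


def quantize_plane(plane: np.ndarray) -> np.ndarray:
    """Per-ROI min-max rescale of a float plane to uint8 (constant -> zeros)."""
    p = np.asarray(plane, dtype=np.float64)
    lo, hi = float(p.min()), float(p.max())
    if hi <= lo:
        return np.zeros(p.shape, dtype=np.uint8)
    return np.clip(np.rint((p - lo) / (hi - lo) * 255.0), 0, 255).astype(np.uint8)


def build_channel_stack(img: np.ndarray, stain_matrix: np.ndarray | None = None) -> ChannelStack:
    """Assemble the 8-channel stack for one ROI."""
    from .config import DEFAULT_STAIN_VECTORS, _normalize_stains

    arr = _validate_rgb(img)
    if stain_matrix is None:
        stain_matrix = np.asarray(_normalize_stains(DEFAULT_STAIN_VECTORS))
    hsv = to_hsv(arr)
    h_plane, _ = he_deconvolve(arr, stain_matrix)
    planes = {
        "Red": arr[..., 0].astype(np.float64),
        "Green": arr[..., 1].astype(np.float64),
        "Blue": arr[..., 2].astype(np.float64),
        "V_HSV": hsv[..., 2],
        "L_Lab": to_lab_l(arr),
        "L_Luv": to_luv_l(arr),
        "BR": blue_ratio(arr),
        "H_HE": h_plane,
    }
    quantized = {name: quantize_plane(p) for name, p in planes.items()}
    return ChannelStack(planes=planes, quantized=quantized)
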