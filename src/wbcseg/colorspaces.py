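"""Pixel-wise conversions among RGB, HSV and CIE L*a*b*.

All conversions assume 8-bit sRGB input with the D65 white point, the
standard assumption for camera images.  Hue is carried in radians in
``[0, 2*pi)`` throughout the package; gray pixels (zero saturation) are
assigned hue 0 by convention so every conversion is a total function.
Out-of-gamut L*a*b* values are clamped channel-wise at the final RGB
mapping, never earlier.
"""

from __future__ import annotations

import numpy as np
from skimage import color

_TWO_PI = 2.0 * np.pi


def _as_float_rgb(img: np.ndarray) -> np.ndarray:
    """8-bit (or float [0,1]) RGB -> float64 in [0,1]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to HSV with hue in radians.

    Parameters
    ----------
    img : (H, W, 3) uint8 or float array
        8-bit channels in [0, 255] or floats in [0, 1].

    Returns
    -------
    (H, W, 3) float64 array
        Channel 0 is hue in radians ``[0, 2*pi)``, channel 1 saturation in
        [0, 1], channel 2 value in [0, 1].  Gray pixels get hue 0.
    """
    hsv = color.rgb2hsv(_as_float_rgb(img))
    hsv[..., 0] = (hsv[..., 0] * _TWO_PI) % _TWO_PI
    return hsv


def hsv_to_rgb(hsv: np.ndarray, as_uint8: bool = True) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsv` (hue in radians)."""
    hsv = np.asarray(hsv, dtype=np.float64)
    out = hsv.copy()
    out[..., 0] = (out[..., 0] / _TWO_PI) % 1.0
    out[..., 1:] = np.clip(out[..., 1:], 0.0, 1.0)
    rgb = color.hsv2rgb(out)
    return _to_uint8(rgb) if as_uint8 else rgb


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert sRGB to CIE L*a*b* (D65): L in [0, 100], a/b opponent axes."""
    return color.rgb2lab(_as_float_rgb(img))


def lab_to_rgb(lab: np.ndarray, as_uint8: bool = True) -> np.ndarray:
    """Convert L*a*b* back to sRGB, clamping out-of-gamut values channel-wise."""
    rgb = color.lab2rgb(np.asarray(lab, dtype=np.float64))
    # skimage clips to [0,1] internally; keep an explicit clip as the contract
    rgb = np.clip(rgb, 0.0, 1.0)
    return _to_uint8(rgb) if as_uint8 else rgb
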