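"""Sunset glow index from color fundus photographs.

Chronic choroidal depigmentation shifts the fundus toward orange-red
("sunset glow fundus").  The sunset glow index quantifies the color balance
of a fundus crop as the mean red-channel luminance divided by the sum of
the mean red, green and blue luminances, each measured on the raw 8-bit
(256-step) scale without colorimetric weighting.  The index is invariant
to overall brightness and rises monotonically with red dominance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SGIResult", "crop_center_square", "sunset_glow_index"]


@dataclass(frozen=True)
class SGIResult:
    """Mean channel luminances and the sunset glow index.

    ``sgi = l_red / (l_red + l_green + l_blue)``; NaN for an all-black
    image, where the denominator vanishes.
    """

    l_red: float
    l_green: float
    l_blue: float
    sgi: float


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if img.size == 0:
        raise ValueError("empty image")
    return img


def crop_center_square(
    img: np.ndarray,
    side: int = 800,
    origin: tuple[int, int] | None = None,
) -> np.ndarray:
    """Square crop, centered by default.

    An explicit ``origin`` (row, column of the crop's top-left corner)
    supports operator-chosen placement, e.g. to keep the optic disc or
    peripapillary atrophy out of the measurement area.
    """
    img = _check_rgb(img)
    h, w = img.shape[:2]
    if side > h or side > w:
        raise ValueError(f"crop side {side} exceeds image size {h}x{w}")
    if origin is None:
        origin = ((h - side) // 2, (w - side) // 2)
    r0, c0 = origin
    if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
        raise ValueError(f"crop origin {origin} with side {side} outside bounds")
    return img[r0 : r0 + side, c0 : c0 + side]


def sunset_glow_index(img: np.ndarray) -> SGIResult:
    """Mean channel luminances of an RGB image and their red fraction."""
    img = _check_rgb(img)
    means = img.reshape(-1, 3).mean(axis=0, dtype=np.float64)
    total = means.sum()
    sgi = float(means[0] / total) if total > 0 else float("nan")
    return SGIResult(
        l_red=float(means[0]),
        l_green=float(means[1]),
        l_blue=float(means[2]),
        sgi=sgi,
    )
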