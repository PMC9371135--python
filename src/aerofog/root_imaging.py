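"""Root-image enhancement.

Roots photographed in the growth chamber hang as dark reddish strands
over a bright greenish background. The enhancement pipeline segments
the background by hue (H inside (35, 140) on the 0–179 hue scale) and
high-intensity pixels by value (V inside (100, 255)), ANDs the value
mask with the negated hue mask, cleans the result with a 2×2
morphological opening, and applies the resulting root mask (and its
complement) to the RGB and HSV representations of the image.

The hue band is interpreted on the 0–179 quantization (a 140 upper
bound exceeds nothing there, while on 0–360 it would cut off typical
green backgrounds); the scale is configurable. Band membership is
inclusive at both ends, and "morphological filtering" is opening by
default (noise removal); closing is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

__all__ = [
    "HsvThresholds",
    "EnhancementResult",
    "enhance_root",
    "morphological_open",
    "morphological_close",
    "dice_score",
]


@dataclass(frozen=True)
class HsvThresholds:
    """Segmentation bands: hue band covering the background, value band
    covering well-lit pixels, and the structuring-element shape."""

    h_band: tuple[float, float] = (35.0, 140.0)
    v_band: tuple[float, float] = (100.0, 255.0)
    kernel: tuple[int, int] = (2, 2)
    hue_scale: float = 180.0  # H quantized to [0, hue_scale)
    value_scale: float = 255.0

    def __post_init__(self) -> None:
        for lo, hi, top, name in (
            (*self.h_band, self.hue_scale, "h_band"),
            (*self.v_band, self.value_scale, "v_band"),
        ):
            if not (0.0 <= lo <= hi <= top):
                raise ValueError(f"{name} must be ordered within [0, {top}]")
        if min(self.kernel) < 1:
            raise ValueError("kernel must be at least 1x1")


@dataclass(frozen=True)
class EnhancementResult:
    """Pipeline outputs: complementary masks and the masked renderings.

    ``hsv_enhanced`` is the HSV-valued array with the background zeroed
    (only root pixels keep their HSV triplet); ``hsv_enhanced_rgb`` is
    the same content rendered back to RGB for viewing.
    """

    root_mask: np.ndarray
    background_mask: np.ndarray
    rgb_enhanced: np.ndarray
    hsv_enhanced: np.ndarray
    hsv_enhanced_rgb: np.ndarray
    mask_h: np.ndarray
    mask_v: np.ndarray


def morphological_open(mask: np.ndarray, kernel: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Binary opening (erosion then dilation) with an all-ones kernel.

    Removes connected structure smaller than the kernel; idempotent.
    """
    structure = np.ones(kernel, dtype=bool)
    return ndimage.binary_opening(np.asarray(mask, dtype=bool), structure=structure)


def morphological_close(mask: np.ndarray, kernel: tuple[int, int] = (2, 2)) -> np.ndarray:
    """Binary closing with an all-ones kernel (fills gaps smaller than
    the kernel); the alternative filter behind the ``close`` flag."""
    structure = np.ones(kernel, dtype=bool)
    return ndimage.binary_closing(np.asarray(mask, dtype=bool), structure=structure)


def enhance_root(
    image: np.ndarray,
    thr: HsvThresholds = HsvThresholds(),
    close: bool = False,
) -> EnhancementResult:
    """Run the root-enhancement pipeline on an 8-bit RGB image.

    Steps: RGB→HSV; hue mask over ``h_band`` (background colors); value
    mask over ``v_band`` (well-lit pixels); raw root = value mask AND
    NOT hue mask; morphological opening (or closing when ``close``)
    with the configured kernel; the filtered mask keeps the root in the
    RGB image and removes the background from the HSV representation.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("input must be an RGB (H x W x 3) image")
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2x2 pixels")
    rgb = image.astype(np.uint8) if image.dtype != np.uint8 else image

    hsv = rgb2hsv(rgb)  # H, S, V all in [0, 1]
    h = hsv[..., 0] * thr.hue_scale
    v = hsv[..., 2] * thr.value_scale

    mask_h = (h >= thr.h_band[0]) & (h <= thr.h_band[1])
    mask_v = (v >= thr.v_band[0]) & (v <= thr.v_band[1])
    raw = mask_v & ~mask_h
    filt = morphological_close(raw, thr.kernel) if close else morphological_open(raw, thr.kernel)

    root_mask = filt
    background_mask = ~filt
    rgb_enhanced = np.where(root_mask[..., None], rgb, 0).astype(np.uint8)
    hsv_scaled = np.stack(
        [h, hsv[..., 1] * thr.value_scale, v], axis=-1
    )
    hsv_enhanced = np.where(root_mask[..., None], hsv_scaled, 0.0)
    hsv_enhanced_rgb = (
        hsv2rgb(np.where(root_mask[..., None], hsv, 0.0)) * 255.0
    ).round().astype(np.uint8)
    return EnhancementResult(
        root_mask=root_mask,
        background_mask=background_mask,
        rgb_enhanced=rgb_enhanced,
        hsv_enhanced=hsv_enhanced,
        hsv_enhanced_rgb=hsv_enhanced_rgb,
        mask_h=mask_h,
        mask_v=mask_v,
    )


def dice_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between binary masks; 1.0 when
    both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
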