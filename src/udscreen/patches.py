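"""Square fixed-resolution lesion patches without aspect-ratio distortion.

Embedding networks need identical input dimensions, but naive resizing of
rectangular crops changes the width:height ratio of the lesion — exactly the
kind of shape distortion that would mislead outlier selection. Rectangular
crops are therefore first padded to square with a constant equal to the mean
frame-ring (surrounding skin) color, then upscaled isotropically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from .geometry import BoundingBox, LesionCrop, LesionId, WideFieldImage, crop_lesion, frame_ring_pixels

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 224


@dataclass
class Patch:
    """S x S x 3 lesion image ready for the embedder."""

    pixels: np.ndarray
    lesion_id: Optional[LesionId] = None
    pad_value: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        s = self.pixels.shape
        if len(s) != 3 or s[0] != s[1] or s[2] != 3:
            raise ValueError(f"patch must be square SxSx3, got {s}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def pad_to_square(crop: LesionCrop) -> LesionCrop:
    """Pad the shorter dimension to the longer one with the frame-ring mean color.

    Padding is split symmetrically; an odd remainder goes to the bottom/right.
    Original pixels are untouched and the operation is idempotent.
    """
    h, w = crop.height, crop.width
    if h == w:
        return crop
    pad_value = frame_ring_pixels(crop).mean(axis=0)
    side = max(h, w)
    out = np.empty((side, side, 3), dtype=np.float64)
    out[:] = pad_value
    pad_h, pad_w = side - h, side - w
    top, left = pad_h // 2, pad_w // 2
    out[top : top + h, left : left + w] = crop.pixels
    padded = LesionCrop(pixels=out, source_box=crop.source_box, frame_width=crop.frame_width)
    return padded


def resize_patch(crop: LesionCrop, size: int = DEFAULT_PATCH_SIZE) -> Patch:
    """Bilinear resize of a square crop to ``size`` x ``size``.

    Lesions are normally smaller than the target resolution, so this is an
    upscale; larger crops are downscaled with a logged warning (anti-aliased).
    """
    h, w = crop.height, crop.width
    if h != w:
        raise ValueError(f"crop must be square before resizing, got {h}x{w}; pad first")
    if h > size:
        logger.warning("crop side %d exceeds patch size %d; downscaling", h, size)
    if h == size:
        pixels = crop.pixels.copy()
    else:
        pixels = resize(
            crop.pixels, (size, size), order=1, mode="edge",
            anti_aliasing=(h > size), preserve_range=True,
        )
    pixels = np.clip(pixels, 0.0, 1.0)
    return Patch(pixels=pixels, lesion_id=crop.lesion_id)


def prepare_patch(
    crop: LesionCrop, size: int = DEFAULT_PATCH_SIZE
) -> Patch:
    """Crop -> square padding -> isotropic resize, with pad value recorded."""
    h, w = crop.height, crop.width
    pad_value = None
    if h != w:
        pad_value = tuple(float(v) for v in frame_ring_pixels(crop).mean(axis=0))
    patch = resize_patch(pad_to_square(crop), size=size)
    patch.pad_value = pad_value
    return patch


def prepare_patches(
    image: WideFieldImage,
    boxes: Sequence[BoundingBox],
    size: int = DEFAULT_PATCH_SIZE,
    frame_width: Optional[int] = None,
) -> list[Patch]:
    """Patch preparation for all of one patient's lesion boxes."""
    return [
        prepare_patch(crop_lesion(image, box, frame_width=frame_width), size=size)
        for box in boxes
    ]
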