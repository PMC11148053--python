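"""Image and bounding-box data model shared by every pipeline stage.

Conventions, fixed package-wide:

* coordinates are 0-based with origin at the top-left; ``x`` indexes columns
  and ``y`` indexes rows;
* boxes are half-open: ``(x_min, y_min, x_max, y_max)`` covers columns
  ``x_min .. x_max - 1`` and rows ``y_min .. y_max - 1``;
* pixel values are floats in ``[0, 1]``; I/O converts 8-bit data on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Union

import numpy as np

LesionId = Union[int, str]

#: Rec. 601 luma weights used wherever a scalar intensity is needed.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned lesion locus in image coordinates (half-open intervals)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: Optional[float] = None
    lesion_id: Optional[LesionId] = None

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise ValueError("box coordinates must be non-negative")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        """Translate by (dx, dy), preserving confidence and identity."""
        return replace(
            self,
            x_min=self.x_min + dx,
            y_min=self.y_min + dy,
            x_max=self.x_max + dx,
            y_max=self.y_max + dy,
        )

    def with_id(self, lesion_id: LesionId) -> "BoundingBox":
        return replace(self, lesion_id=lesion_id)

    def with_confidence(self, confidence: float) -> "BoundingBox":
        return replace(self, confidence=confidence)

    def contains(self, other: "BoundingBox") -> bool:
        return (
            other.x_min >= self.x_min
            and other.y_min >= self.y_min
            and other.x_max <= self.x_max
            and other.y_max <= self.y_max
        )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


@dataclass
class WideFieldImage:
    """High-resolution RGB photograph of a large body region."""

    pixels: np.ndarray
    patient_id: str = "unknown"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 RGB array, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have positive height and width")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def default_frame_width(h: int, w: int) -> int:
    """Default frame-ring width: 10% of the shorter crop side, at least 1 px."""
    return max(1, round(0.1 * min(h, w)))


@dataclass
class LesionCrop:
    """Sub-image around one lesion plus the width of its surrounding-skin ring.

    The frame ring (pixels within ``frame_width`` of the crop border) is assumed
    to show skin around the lesion, because detector boxes always include a
    margin of surrounding skin; its mean intensity is the illumination feature.
    """

    pixels: np.ndarray
    source_box: BoundingBox
    frame_width: int = field(default=0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("crop must be hxwx3")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("crop must be non-empty")
        if self.frame_width <= 0:
            self.frame_width = default_frame_width(*self.pixels.shape[:2])

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def lesion_id(self) -> Optional[LesionId]:
        return self.source_box.lesion_id


def crop_lesion(
    image: WideFieldImage,
    box: BoundingBox,
    frame_width: Optional[int] = None,
    clip: bool = True,
) -> LesionCrop:
    """Extract the sub-image covered by ``box``.

    Boxes partially outside the image are clipped to its extent when
    ``clip=True`` (the default) and rejected otherwise; boxes entirely outside
    the image always raise.
    """
    H, W = image.height, image.width
    x0, y0 = box.x_min, box.y_min
    x1, y1 = box.x_max, box.y_max
    if x0 >= W or y0 >= H or x1 <= 0 or y1 <= 0:
        raise ValueError(f"box {box} lies entirely outside the {H}x{W} image")
    inside = x0 >= 0 and y0 >= 0 and x1 <= W and y1 <= H
    if not inside and not clip:
        raise ValueError(f"box {box} extends beyond the {H}x{W} image")
    xi0, yi0 = int(np.floor(max(x0, 0))), int(np.floor(max(y0, 0)))
    xi1, yi1 = int(np.ceil(min(x1, W))), int(np.ceil(min(y1, H)))
    pixels = image.pixels[yi0:yi1, xi0:xi1].copy()
    clipped = BoundingBox(xi0, yi0, xi1, yi1, box.confidence, box.lesion_id)
    fw = frame_width if frame_width is not None else default_frame_width(
        pixels.shape[0], pixels.shape[1]
    )
    return LesionCrop(pixels=pixels, source_box=clipped, frame_width=fw)


def frame_ring_mask(height: int, width: int, frame_width: int) -> np.ndarray:
    """Boolean mask of pixels whose distance from the crop border is < frame_width."""
    rows = np.arange(height)
    cols = np.arange(width)
    row_edge = np.minimum(rows, height - 1 - rows)[:, None]
    col_edge = np.minimum(cols, width - 1 - cols)[None, :]
    return np.minimum(row_edge, col_edge) < frame_width


def frame_ring_pixels(crop: LesionCrop) -> np.ndarray:
    """The crop's outer ring of pixels as an (n, 3) array; never empty.

    The ring is clipped to the available pixels: a crop smaller than
    ``2 * frame_width`` in either dimension simply returns all its pixels.
    """
    mask = frame_ring_mask(crop.height, crop.width, crop.frame_width)
    return crop.pixels[mask]


def luma(pixels: np.ndarray) -> np.ndarray:
    """Scalar intensity of RGB pixels (Rec. 601 weights)."""
    return np.asarray(pixels) @ LUMA_WEIGHTS


def iter_crops(
    image: WideFieldImage,
    boxes: list[BoundingBox],
    frame_width: Optional[int] = None,
) -> Iterator[LesionCrop]:
    for box in boxes:
        yield crop_lesion(image, box, frame_width=frame_width)
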