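"""Overlapping-tile decomposition of wide-field images and NMS merging.

High-resolution photographs are far larger than the resolution a lesion
detector consumes, so the image is cut into overlapping fixed-size windows,
the detector runs per window, detections are remapped to global coordinates,
and duplicates from the overlap zones are resolved by greedy non-maximum
suppression at a deliberately low IoU threshold (10%): distinct lesions rarely
overlap at all, so even modest overlap indicates a duplicate detection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import BoundingBox, iou


@dataclass(frozen=True)
class TileWindow:
    """Placement of one tile inside the full image."""

    x_off: int
    y_off: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.x_off < 0 or self.y_off < 0:
            raise ValueError(f"invalid tile window {self}")

    def contains_box(self, box: BoundingBox) -> bool:
        return (
            box.x_min >= self.x_off
            and box.y_min >= self.y_off
            and box.x_max <= self.x_off + self.width
            and box.y_max <= self.y_off + self.height
        )


@dataclass
class TilingConfig:
    """Tiling and merge parameters.

    tile_size
        Side length of each (square) tile in pixels; 1280 matches the
        resolution the wide-field lesion detector was designed for.
    overlap_fraction
        Fraction of the tile side shared by adjacent tiles. Lesions smaller
        than ``tile_size * overlap_fraction`` are guaranteed to appear whole
        in at least one tile.
    nms_iou
        IoU above which a lower-confidence detection is suppressed (0.10).
    """

    tile_size: int = 1280
    overlap_fraction: float = 0.2
    nms_iou: float = 0.10

    def __post_init__(self) -> None:
        if self.tile_size < 32:
            raise ValueError("tile_size must be >= 32")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not (0.0 < self.nms_iou < 1.0):
            raise ValueError("nms_iou must be in (0, 1)")


def _axis_offsets(extent: int, tile: int, stride: int) -> list[int]:
    """Tile offsets along one axis: regular stride, last tile shifted inward."""
    if extent <= tile:
        return [0]
    offsets: list[int] = []
    pos = 0
    while pos + tile < extent:
        offsets.append(pos)
        pos += stride
    last = extent - tile
    if not offsets or offsets[-1] != last:
        offsets.append(last)
    return offsets


def make_tiles(image_height: int, image_width: int, config: TilingConfig) -> list[TileWindow]:
    """Overlapping windows covering the whole image.

    Every tile is full-size wherever the image allows it; along an axis shorter
    than the tile size a single image-sized window is used (no padding — the
    detector only ever sees real pixels). Border tiles are shifted inward
    rather than extending past the image.
    """
    if image_height < 1 or image_width < 1:
        raise ValueError("image dimensions must be positive")
    stride = max(1, round(config.tile_size * (1.0 - config.overlap_fraction)))
    tile_w = min(config.tile_size, image_width)
    tile_h = min(config.tile_size, image_height)
    xs = _axis_offsets(image_width, tile_w, stride)
    ys = _axis_offsets(image_height, tile_h, stride)
    return [TileWindow(x, y, tile_w, tile_h) for y in ys for x in xs]


def map_to_global(window: TileWindow, local_box: BoundingBox) -> BoundingBox:
    """Shift a tile-local detection into full-image coordinates."""
    if local_box.x_max > window.width or local_box.y_max > window.height:
        raise ValueError(f"local box {local_box} exceeds window extent {window}")
    return local_box.shifted(window.x_off, window.y_off)


def map_to_local(window: TileWindow, global_box: BoundingBox) -> BoundingBox:
    """Inverse of :func:`map_to_global` for boxes inside the window."""
    if not window.contains_box(global_box):
        raise ValueError(f"box {global_box} not contained in window {window}")
    return global_box.shifted(-window.x_off, -window.y_off)


def _nms_sort_key(box: BoundingBox):
    # descending confidence; deterministic tie-break by position
    return (-box.confidence, box.y_min, box.x_min, box.y_max, box.x_max)


def merge_detections(detections: list[BoundingBox], nms_iou: float = 0.10) -> list[BoundingBox]:
    """Greedy non-maximum suppression over aggregated tile detections.

    Boxes are visited in decreasing confidence order (ties broken by position
    for determinism); a box is kept iff its IoU with every already-kept box is
    <= ``nms_iou``. The result is a subset of the input, sorted by confidence
    descending.
    """
    for det in detections:
        if det.confidence is None:
            raise ValueError(f"detection {det} lacks a confidence value")
    kept: list[BoundingBox] = []
    for box in sorted(detections, key=_nms_sort_key):
        if all(iou(box, k) <= nms_iou for k in kept):
            kept.append(box)
    return kept
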