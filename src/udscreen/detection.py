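"""Lesion detection: a classical multi-threshold blob detector plus an
adapter contract for learned detector backends.

The built-in detector binarizes the grayscale tile at a ladder of intensity
thresholds, keeps connected components that look lesion-like (area and
circularity gates), and groups components that persist across threshold
levels. Persistence across levels serves as the detection confidence: a
clearly darker-than-skin lesion appears at every level, a faint freckle at
few. Learned backends (e.g. a single-class YOLO-family model) plug in through
:class:`DetectorContract` without this package executing any deep model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, runtime_checkable

import numpy as np
from skimage import measure

from .geometry import BoundingBox, WideFieldImage, luma
from .tiling import TileWindow, TilingConfig, make_tiles, map_to_global, merge_detections

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONFIDENCE = 0.20


@dataclass
class BlobDetectorConfig:
    """Parameters of the multi-threshold blob detector.

    Thresholds are grayscale fractions in [0, 1]; a pixel belongs to the
    foreground at level ``t`` when it is darker than ``t``. Components are kept
    when their pixel area lies in ``[area_min, area_max]`` and their
    circularity ``4*pi*A / P**2`` is at least ``circularity_min``. Components
    whose centers are within ``min_center_distance`` across levels are grouped
    into one candidate lesion; the group's tight bounding box is expanded by
    ``box_margin_fraction`` per side so crops include surrounding skin.

    ``min_local_contrast`` rejects candidates that are not darker than their
    immediate surround: a lesion is locally dark even inside a shadow, whereas
    blobs produced by illumination structure (shadow interiors, gradients)
    have no local contrast.
    """

    threshold_min: float = 0.25
    threshold_max: float = 0.75
    threshold_step: float = 0.05
    area_min: int = 20
    area_max: int = 20_000
    circularity_min: float = 0.25
    min_center_distance: float = 12.0
    box_margin_fraction: float = 0.15
    min_local_contrast: float = 0.08

    def __post_init__(self) -> None:
        if not self.threshold_min < self.threshold_max:
            raise ValueError("threshold_min must be < threshold_max")
        if self.threshold_step <= 0:
            raise ValueError("threshold_step must be positive")
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be < area_max")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(
            self.threshold_min, self.threshold_max + 1e-9, self.threshold_step
        )


@runtime_checkable
class DetectorContract(Protocol):
    """Contract every detector backend fulfils.

    ``detect`` receives one RGB tile (h x w x 3 floats in [0, 1]) together
    with its placement in the full image and returns tile-local
    :class:`BoundingBox` objects carrying confidences in [0, 1]. All returned
    boxes must lie inside the tile.
    """

    input_resolution: int

    def detect(self, tile: np.ndarray, window: TileWindow) -> list[BoundingBox]:
        ...


@dataclass
class ExternalDetectorAdapter:
    """Adapter wrapping a learned detector backend.

    The configuration fields record the recipe a single-class wide-field
    lesion backend is expected to honor: one target class, anchor aspect
    ratios derived from the training boxes by KNN clustering, color-channel
    normalization disabled (so shadowed regions are not spuriously boosted),
    a raised per-image box limit for dense lesion fields, and NMS deferred to
    the post-merge stage of this package. The adapter does not run a model
    itself; ``backend`` does.
    """

    backend: Callable[[np.ndarray], list[BoundingBox]]
    input_resolution: int = 1280
    single_class: bool = True
    anchor_aspect_ratios_from_knn: bool = True
    channel_normalization_disabled: bool = True
    max_boxes_per_image: int = 1000
    nms_deferred_to_merge: bool = True

    def detect(self, tile: np.ndarray, window: TileWindow) -> list[BoundingBox]:
        return self.backend(tile)


def _group_boxes(
    candidates: list[tuple[float, float, BoundingBox]],
    min_center_distance: float,
) -> list[list[tuple[float, float, BoundingBox]]]:
    """Greedy grouping of per-level components by center proximity."""
    groups: list[list[tuple[float, float, BoundingBox]]] = []
    centers: list[tuple[float, float]] = []  # running group centroid
    for cy, cx, box in candidates:
        best, best_d = -1, np.inf
        for gi, (gy, gx) in enumerate(centers):
            d = np.hypot(cy - gy, cx - gx)
            if d < best_d:
                best, best_d = gi, d
        if best >= 0 and best_d <= min_center_distance:
            groups[best].append((cy, cx, box))
            ys = [c[0] for c in groups[best]]
            xs = [c[1] for c in groups[best]]
            centers[best] = (float(np.mean(ys)), float(np.mean(xs)))
        else:
            groups.append([(cy, cx, box)])
            centers.append((cy, cx))
    return groups


class BlobDetector:
    """Multi-threshold blob detector fulfilling :class:`DetectorContract`."""

    def __init__(self, config: Optional[BlobDetectorConfig] = None):
        self.config = config or BlobDetectorConfig()
        self.input_resolution = 1280

    def detect(self, tile: np.ndarray, window: Optional[TileWindow] = None) -> list[BoundingBox]:
        return detect_blobs(tile, self.config)


def detect_blobs(tile: np.ndarray, config: Optional[BlobDetectorConfig] = None) -> list[BoundingBox]:
    """Detect dark, roughly round blobs in an RGB tile.

    Returns tile-local boxes with confidence equal to the fraction of
    threshold levels at which the blob appears. Deterministic.
    """
    config = config or BlobDetectorConfig()
    tile = np.asarray(tile, dtype=np.float64)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError(f"expected an RGB tile, got shape {tile.shape}")
    gray = luma(tile)
    h, w = gray.shape
    levels = config.levels
    candidates: list[tuple[float, float, BoundingBox]] = []
    for t in levels:
        mask = gray < t
        if not mask.any():
            continue
        labels = measure.label(mask, connectivity=2)
        for region in measure.regionprops(labels):
            if not (config.area_min <= region.area <= config.area_max):
                continue
            perimeter = region.perimeter
            if perimeter <= 0:
                continue
            circularity = 4.0 * np.pi * region.area / perimeter**2
            if circularity < config.circularity_min:
                continue
            y0, x0, y1, x1 = region.bbox
            cy, cx = region.centroid
            candidates.append((cy, cx, BoundingBox(x0, y0, x1, y1)))

    detections: list[BoundingBox] = []
    n_levels = len(levels)
    for group in _group_boxes(candidates, config.min_center_distance):
        confidence = len(group) / n_levels
        x0 = min(b.x_min for _, _, b in group)
        y0 = min(b.y_min for _, _, b in group)
        x1 = max(b.x_max for _, _, b in group)
        y1 = max(b.y_max for _, _, b in group)
        if config.min_local_contrast > 0:
            gx0, gy0, gx1, gy1 = int(x0), int(y0), int(x1), int(y1)
            pad = max(3, (gx1 - gx0 + gy1 - gy0) // 4)
            ox0, oy0 = max(0, gx0 - pad), max(0, gy0 - pad)
            ox1, oy1 = min(w, gx1 + pad), min(h, gy1 + pad)
            outer = gray[oy0:oy1, ox0:ox1]
            inner = gray[gy0:gy1, gx0:gx1]
            n_ring = outer.size - inner.size
            if n_ring > 0:
                ring_mean = (outer.sum() - inner.sum()) / n_ring
                if ring_mean - inner.mean() < config.min_local_contrast:
                    continue
        mx = config.box_margin_fraction * (x1 - x0)
        my = config.box_margin_fraction * (y1 - y0)
        box = BoundingBox(
            max(0, int(np.floor(x0 - mx))),
            max(0, int(np.floor(y0 - my))),
            min(w, int(np.ceil(x1 + mx))),
            min(h, int(np.ceil(y1 + my))),
            confidence=min(1.0, confidence),
        )
        detections.append(box)
    return detections


def filter_by_confidence(
    detections: list[BoundingBox], min_confidence: float = DEFAULT_MIN_CONFIDENCE
) -> list[BoundingBox]:
    """Keep detections whose confidence is >= ``min_confidence`` (order preserved)."""
    for det in detections:
        if det.confidence is None:
            raise ValueError(f"detection {det} lacks a confidence value")
    return [d for d in detections if d.confidence >= min_confidence]


def run_tiled_detection(
    image: WideFieldImage,
    detector: DetectorContract,
    tiling: Optional[TilingConfig] = None,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[BoundingBox]:
    """Full-image detection: tile, detect per tile, remap, NMS-merge, filter.

    Surviving detections receive sequential lesion ids ("L0001", ...) in final
    confidence order.
    """
    tiling = tiling or TilingConfig()
    windows = make_tiles(image.height, image.width, tiling)
    aggregated: list[BoundingBox] = []
    for window in windows:
        tile = image.pixels[
            window.y_off : window.y_off + window.height,
            window.x_off : window.x_off + window.width,
        ]
        local = detector.detect(tile, window)
        for box in local:
            if box.x_max > window.width + 1e-9 or box.y_max > window.height + 1e-9:
                raise ValueError(
                    f"detector returned out-of-tile box {box} for tile at "
                    f"({window.x_off}, {window.y_off})"
                )
            aggregated.append(map_to_global(window, box))
    merged = merge_detections(aggregated, tiling.nms_iou)
    kept = filter_by_confidence(merged, min_confidence)
    logger.info(
        "patient %s: %d raw, %d after NMS, %d after confidence filter",
        image.patient_id, len(aggregated), len(merged), len(kept),
    )
    return [box.with_id(f"L{i + 1:04d}") for i, box in enumerate(kept)]
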