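"""Seeded wide-field phantoms with ground truth, and synthetic rater behavior.

Clinical total-body photographs cannot be redistributed, so every pipeline
stage is exercised on generated phantoms that reproduce the structural
features the method depends on: a skin-tone background with a smooth
illumination gradient, darkened shadow regions, tens to hundreds of lesions
per patient with a right-tailed (log-normal) pixel-area distribution, a
dominant population of common-appearance lesions, and a few planted
appearance outliers displaced in color, eccentricity and size. Ground truth
(boxes, outlier flags, shadow membership) is recorded exactly, and synthetic
participants with group-specific pick probabilities emulate the multi-rater
selection study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detection import DetectorContract
from .geometry import BoundingBox, WideFieldImage
from .tiling import TileWindow
from .validation import GROUPS, SelectionRecord


@dataclass
class PhantomConfig:
    """Conditions of one synthetic patient.

    Lesion pixel areas are drawn log-normally (right-tailed, as real
    patient-wise lesion-size distributions are); common lesions share a base
    color and near-round shape with small jitter, outliers are displaced by
    ``outlier_effect`` times the base spread in color and elongated in shape.
    """

    image_height: int = 1024
    image_width: int = 2048
    n_common: int = 100
    n_outliers: int = 5
    area_lognormal_mu: float = 5.0  # median lesion area ~ e^5 ≈ 148 px²
    area_lognormal_sigma: float = 0.5
    base_color_mean: tuple[float, float, float] = (0.42, 0.28, 0.22)
    base_color_sd: float = 0.03
    skin_color: tuple[float, float, float] = (0.85, 0.70, 0.60)
    outlier_effect: float = 3.0
    n_shadow_regions: int = 2
    shadow_darkening: float = 0.45
    n_shadow_lesions: int = 0
    min_lesion_gap: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_common + self.n_outliers < 2:
            raise ValueError("need at least 2 lesions in total")
        if self.outlier_effect <= 1.0:
            raise ValueError("outlier_effect must be > 1")
        if not (0.0 < self.shadow_darkening < 1.0):
            raise ValueError("shadow_darkening must be in (0, 1)")
        if self.n_shadow_lesions > 0 and self.n_shadow_regions == 0:
            raise ValueError("cannot place shadow lesions without shadow regions")


@dataclass
class ShadowRegion:
    cy: float
    cx: float
    ry: float
    rx: float

    def contains(self, y: float, x: float) -> bool:
        return ((y - self.cy) / self.ry) ** 2 + ((x - self.cx) / self.rx) ** 2 <= 1.0


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated phantom."""

    boxes: list[BoundingBox]
    is_outlier: list[bool]
    in_shadow: list[bool]
    shadow_regions: list[ShadowRegion] = field(default_factory=list)

    @property
    def outlier_ids(self) -> set:
        return {b.lesion_id for b, o in zip(self.boxes, self.is_outlier) if o}

    @property
    def common_ids(self) -> set:
        return {b.lesion_id for b, o in zip(self.boxes, self.is_outlier) if not o}


def _place_centers(
    config: PhantomConfig,
    shadows: list[ShadowRegion],
    margin: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Rejection-sample lesion centers with a minimum pairwise gap."""
    n_total = config.n_common + config.n_outliers
    centers: list[tuple[float, float]] = []
    H, W = config.image_height, config.image_width

    def try_place(sampler, count: int) -> None:
        placed = 0
        for _ in range(20_000):
            if placed == count:
                return
            y, x = sampler()
            if not (margin <= y <= H - margin and margin <= x <= W - margin):
                continue
            if all(np.hypot(y - cy, x - cx) >= config.min_lesion_gap for cy, cx in centers):
                centers.append((y, x))
                placed += 1
        if placed < count:
            raise RuntimeError(
                f"could not place {count} lesions with gap {config.min_lesion_gap}; "
                "reduce the lesion count or the gap"
            )

    if config.n_shadow_lesions > 0:
        def shadow_sampler():
            s = shadows[rng.integers(len(shadows))]
            ang = rng.uniform(0, 2 * np.pi)
            rad = np.sqrt(rng.uniform(0, 0.8))
            return s.cy + rad * s.ry * np.sin(ang), s.cx + rad * s.rx * np.cos(ang)

        try_place(shadow_sampler, min(config.n_shadow_lesions, n_total))

    def uniform_sampler():
        return rng.uniform(0, H), rng.uniform(0, W)

    try_place(uniform_sampler, n_total - len(centers))
    return centers


def generate_phantom(config: PhantomConfig) -> tuple[WideFieldImage, PhantomTruth]:
    """Render one phantom patient image with exact ground truth.

    Deterministic per seed: the same config yields a bit-identical image and
    truth. Shadows darken everything inside them — lesions included — so
    shadowed lesions carry genuinely darker frame pixels.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.image_height, config.image_width

    # background: skin tone with a smooth large-scale illumination gradient
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    gradient = 1.0 + 0.08 * np.cos(np.pi * xx / W + rng.uniform(0, 1)) * np.cos(
        np.pi * yy / H + rng.uniform(0, 1)
    )
    img = np.empty((H, W, 3))
    skin = np.array(config.skin_color)
    noise = rng.normal(0, 0.01, size=(H, W))
    for c in range(3):
        img[:, :, c] = skin[c] * gradient + noise

    shadows = []
    for _ in range(config.n_shadow_regions):
        shadows.append(
            ShadowRegion(
                cy=rng.uniform(0.15 * H, 0.85 * H),
                cx=rng.uniform(0.1 * W, 0.9 * W),
                ry=rng.uniform(0.08 * H, 0.18 * H),
                rx=rng.uniform(0.05 * W, 0.12 * W),
            )
        )

    max_radius = np.exp(config.area_lognormal_mu + 3 * config.area_lognormal_sigma)
    margin = min(60.0, np.sqrt(max_radius / np.pi) * config.outlier_effect + 12)
    centers = _place_centers(config, shadows, margin, rng)
    n_total = config.n_common + config.n_outliers
    # which placed centers become outliers: keep deterministic but spread over
    # both shadow-forced and free placements
    outlier_idx = set(rng.choice(n_total, size=config.n_outliers, replace=False).tolist())

    boxes: list[BoundingBox] = []
    is_outlier: list[bool] = []
    in_shadow: list[bool] = []
    base = np.array(config.base_color_mean)
    for i, (cy, cx) in enumerate(centers):
        outlier = i in outlier_idx
        area = float(np.exp(rng.normal(config.area_lognormal_mu, config.area_lognormal_sigma)))
        color = base + rng.normal(0, config.base_color_sd, size=3)
        axis_ratio = rng.uniform(0.85, 1.0)
        if outlier:
            # displaced toward dark red/blue, elongated, enlarged
            shift = config.outlier_effect * config.base_color_sd
            color = color + np.array([2.0, -1.5, 1.0]) * shift
            axis_ratio = axis_ratio / config.outlier_effect
            area *= config.outlier_effect
        color = np.clip(color, 0.02, 0.98)
        r = np.sqrt(area / np.pi)
        ry = r / np.sqrt(axis_ratio)
        rx = r * np.sqrt(axis_ratio)
        theta = rng.uniform(0, np.pi)
        # render into a local window
        ext = int(np.ceil(max(ry, rx))) + 3
        y0, y1 = max(0, int(cy) - ext), min(H, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(W, int(cx) + ext + 1)
        ly, lx = np.mgrid[y0:y1, x0:x1].astype(np.float64)
        dy, dx = ly - cy, lx - cx
        ct, st = np.cos(theta), np.sin(theta)
        u = (ct * dx + st * dy) / rx
        v = (-st * dx + ct * dy) / ry
        dist = np.sqrt(u**2 + v**2)
        alpha = np.clip((1.15 - dist) / 0.3, 0.0, 1.0)  # soft edge
        for c in range(3):
            img[y0:y1, x0:x1, c] = (
                alpha * color[c] + (1 - alpha) * img[y0:y1, x0:x1, c]
            )
        # axis-aligned extent of the rotated ellipse
        half_w = np.sqrt((rx * ct) ** 2 + (ry * st) ** 2)
        half_h = np.sqrt((rx * st) ** 2 + (ry * ct) ** 2)
        boxes.append(
            BoundingBox(
                max(0, int(np.floor(cx - half_w - 2))),
                max(0, int(np.floor(cy - half_h - 2))),
                min(W, int(np.ceil(cx + half_w + 2))),
                min(H, int(np.ceil(cy + half_h + 2))),
                lesion_id=f"G{i + 1:04d}",
            )
        )
        is_outlier.append(outlier)
        in_shadow.append(any(s.contains(cy, cx) for s in shadows))

    # shadows multiply the rendered scene so lesion frames darken too
    shade = np.ones((H, W))
    for s in shadows:
        d = np.sqrt(((yy - s.cy) / s.ry) ** 2 + ((xx - s.cx) / s.rx) ** 2)
        inside = np.clip((1.1 - d) / 0.2, 0.0, 1.0)
        shade = np.minimum(shade, 1.0 - config.shadow_darkening * inside)
    img *= shade[:, :, None]

    img = np.clip(img, 0.0, 1.0)
    image = WideFieldImage(pixels=img, patient_id=f"phantom-{config.seed}")
    truth = PhantomTruth(
        boxes=boxes, is_outlier=is_outlier, in_shadow=in_shadow, shadow_regions=shadows
    )
    return image, truth


class OracleDetector:
    """Detector that returns the ground-truth boxes contained in each tile.

    Used to validate the tiling/merge machinery independently of any actual
    detector. Boxes fully contained in a tile are reported in tile-local
    coordinates with a fixed confidence.
    """

    input_resolution = 1280

    def __init__(self, truth: PhantomTruth, confidence: float = 0.9):
        self.truth = truth
        self.confidence = confidence

    def detect(self, tile: np.ndarray, window: TileWindow) -> list[BoundingBox]:
        out = []
        for box in self.truth.boxes:
            if window.contains_box(box):
                local = box.shifted(-window.x_off, -window.y_off)
                out.append(local.with_confidence(self.confidence))
        return out


@dataclass
class GroupBehavior:
    """Pick behavior of one participant group.

    ``p_outlier``/``p_common``: probability of selecting each planted outlier
    or common lesion; ``confidence_probs``: distribution over the 1-5
    confidence scale; ``order_noise``: jitter of the outlier-first ordering.
    """

    p_outlier: float
    p_common: float
    confidence_probs: tuple[float, ...] = (0.05, 0.1, 0.3, 0.35, 0.2)
    order_noise: float = 0.2

    def __post_init__(self) -> None:
        if not (0 <= self.p_outlier <= 1 and 0 <= self.p_common <= 1):
            raise ValueError("pick probabilities must lie in [0, 1]")
        if abs(sum(self.confidence_probs) - 1.0) > 1e-9 or len(self.confidence_probs) != 5:
            raise ValueError("confidence_probs must be 5 values summing to 1")


#: Default study-like behaviors: experts pick planted outliers almost always
#: and are confident; non-clinicians pick more common lesions and are less
#: confident. AI assistance raises outlier pick rates and confidence.
DEFAULT_BEHAVIORS: dict[str, GroupBehavior] = {
    "derm>10y": GroupBehavior(0.90, 0.03, (0.0, 0.03, 0.12, 0.40, 0.45)),
    "derm<=10y": GroupBehavior(0.85, 0.04, (0.0, 0.05, 0.20, 0.45, 0.30)),
    "derm<=5y": GroupBehavior(0.85, 0.05, (0.02, 0.08, 0.30, 0.40, 0.20)),
    "gp": GroupBehavior(0.65, 0.08, (0.05, 0.15, 0.40, 0.30, 0.10)),
    "student": GroupBehavior(0.60, 0.15, (0.10, 0.25, 0.40, 0.20, 0.05)),
}

#: Cohort layout mirroring the study: (participant count, group) pairs.
DEFAULT_COHORT: tuple[tuple[int, str], ...] = (
    (4, "derm<=5y"),
    (2, "derm<=10y"),
    (3, "derm>10y"),
    (2, "gp"),
    (6, "student"),
)


def generate_selections(
    truth: PhantomTruth,
    behaviors: Optional[dict[str, GroupBehavior]] = None,
    cohort: Sequence[tuple[int, str]] = DEFAULT_COHORT,
    patient_id: str = "phantom",
    ai_assisted: bool = False,
    seed: int = 0,
) -> list[SelectionRecord]:
    """Simulate one round of participant selections on a phantom.

    Each participant independently selects outliers with probability
    ``p_outlier`` and common lesions with ``p_common``, orders picks
    outlier-first with noise, and draws a confidence from the group's
    distribution.
    """
    behaviors = behaviors or DEFAULT_BEHAVIORS
    rng = np.random.default_rng(seed)
    records = []
    for count, group in cohort:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        beh = behaviors[group]
        for j in range(count):
            picks = []
            for box, outlier in zip(truth.boxes, truth.is_outlier):
                p = beh.p_outlier if outlier else beh.p_common
                if rng.random() < p:
                    key = -(float(outlier) + rng.normal(0, beh.order_noise))
                    picks.append((key, box.lesion_id))
            picks.sort()
            confidence = int(rng.choice(5, p=beh.confidence_probs)) + 1
            records.append(
                SelectionRecord(
                    participant_id=f"{group}-{j + 1}",
                    group=group,
                    patient_id=patient_id,
                    ordered_lesion_ids=[lid for _, lid in picks],
                    confidence=confidence,
                    ai_assisted=ai_assisted,
                )
            )
    return records


def assisted_behaviors(
    behaviors: Optional[dict[str, GroupBehavior]] = None,
    outlier_boost: float = 0.08,
    confidence_shift: float = 0.5,
) -> dict[str, GroupBehavior]:
    """AI-assisted variant of a behavior set: more outlier picks, more confidence."""
    behaviors = behaviors or DEFAULT_BEHAVIORS
    out = {}
    for group, beh in behaviors.items():
        probs = np.asarray(beh.confidence_probs, dtype=np.float64)
        # shift mass toward higher confidence
        shifted = probs.copy()
        move = confidence_shift * 0.5
        for i in range(4):
            delta = move * shifted[i]
            shifted[i] -= delta
            shifted[i + 1] += delta
        shifted /= shifted.sum()
        out[group] = GroupBehavior(
            p_outlier=min(1.0, beh.p_outlier + outlier_boost),
            p_common=beh.p_common,
            confidence_probs=tuple(shifted),
            order_noise=beh.order_noise,
        )
    return out
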