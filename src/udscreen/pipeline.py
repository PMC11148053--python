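"""End-to-end orchestration: detect -> filter -> prep -> embed -> score.

Each patient is processed in complete isolation — the embedder only ever sees
that patient's lesions — and every stochastic stage derives its seed from the
run's global seed, so a rerun with the same configuration and seed reproduces
every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import io as udio
from .detection import (
    BlobDetector,
    BlobDetectorConfig,
    DetectorContract,
    run_tiled_detection,
)
from .embedding import (
    DESK_SCALE,
    FULL_SCALE,
    PROFILES,
    HandcraftedFeatureEmbedder,
    SelfDistillationEmbedder,
)
from .geometry import BoundingBox, WideFieldImage, crop_lesion
from .illumination import illumination_mask
from .patches import prepare_patch
from .scoring import render_overlay, top_k, ud_scores
from .tiling import TilingConfig
from .validation import EvaluationConfig, SelectionRecord, group_summaries, report_to_frames

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline constants in one place; defaults are the study values."""

    tiling: TilingConfig = field(default_factory=TilingConfig)
    blob: BlobDetectorConfig = field(default_factory=BlobDetectorConfig)
    detector: str = "builtin_blob"
    min_confidence: float = 0.20
    illumination_k_sigma: float = 2.0
    illumination_robust: bool = False
    embedder: str = "ssl"  # "ssl" | "handcrafted"
    embedder_profile: str = "full-scale"
    ud_top_k: int = 10
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    @property
    def patch_size(self) -> int:
        return PROFILES[self.embedder_profile].patch_size

    def make_embedder(self, seed: int):
        if self.embedder == "handcrafted":
            return HandcraftedFeatureEmbedder()
        if self.embedder == "ssl":
            est = PROFILES[self.embedder_profile].estimator()
            est.set_params(random_state=seed)
            return est
        raise ValueError(f"unknown embedder {self.embedder!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "tiling" in kwargs:
            kwargs["tiling"] = TilingConfig(**kwargs["tiling"])
        if "blob" in kwargs:
            kwargs["blob"] = BlobDetectorConfig(**kwargs["blob"])
        if "evaluation" in kwargs:
            kwargs["evaluation"] = EvaluationConfig(**kwargs["evaluation"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PatientResult:
    """Everything produced for one patient."""

    patient_id: str
    detections: list[BoundingBox]
    kept_boxes: list[BoundingBox]
    discarded_ids: list
    score_table: Optional[pd.DataFrame]
    top_k_ids: list
    manifest: dict


def _patient_seed(global_seed: int, patient_id: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{patient_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def screen_patient(
    image: WideFieldImage,
    config: Optional[PipelineConfig] = None,
    detector: Optional[DetectorContract] = None,
    detections: Optional[list[BoundingBox]] = None,
) -> PatientResult:
    """Run the full screening chain on one patient image.

    ``detections`` may be supplied to skip the detection stage (e.g. boxes
    from an external detector already merged and filtered).
    """
    config = config or PipelineConfig()
    if detections is None:
        detector = detector or BlobDetector(config.blob)
        detections = run_tiled_detection(
            image, detector, config.tiling, config.min_confidence
        )
    n_detected = len(detections)
    manifest: dict = {
        "patient_id": image.patient_id,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_detected": n_detected,
    }
    if n_detected == 0:
        logger.warning("patient %s: no lesions detected", image.patient_id)
        manifest.update({"n_discarded": 0, "discard_rate": 0.0, "n_scored": 0})
        return PatientResult(image.patient_id, [], [], [], None, [], manifest)

    crops = [crop_lesion(image, box) for box in detections]
    flags, stats = illumination_mask(
        crops, k_sigma=config.illumination_k_sigma, robust=config.illumination_robust
    )
    kept_boxes = [b for b, f in zip(detections, flags) if not f]
    discarded = [b.lesion_id for b, f in zip(detections, flags) if f]
    manifest.update(
        {
            "n_discarded": len(discarded),
            "discard_rate": len(discarded) / n_detected,
            "illumination_mu": stats.mu,
            "illumination_sigma": stats.sigma,
        }
    )
    kept_crops = [c for c, f in zip(crops, flags) if not f]
    patches = [prepare_patch(c, size=config.patch_size) for c in kept_crops]
    embedder = config.make_embedder(_patient_seed(config.seed, image.patient_id))
    embedder.fit(patches)
    embeddings = embedder.transform(patches)
    manifest["stop_epoch"] = getattr(embedder, "stop_epoch_", None)
    manifest["stop_reason"] = getattr(embedder, "stop_reason_", None)
    lesion_ids = [p.lesion_id if p.lesion_id is not None else i for i, p in enumerate(patches)]
    table = ud_scores(embeddings, lesion_ids=lesion_ids)
    proposed = top_k(table, k=config.ud_top_k)
    manifest["n_scored"] = len(table)
    return PatientResult(
        image.patient_id, detections, kept_boxes, discarded, table, proposed, manifest
    )


def run_screening(
    images: Sequence[Union[WideFieldImage, str, Path]],
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
    detector: Optional[DetectorContract] = None,
    write_overlays: bool = True,
) -> dict[str, PatientResult]:
    """Screen several patients; optionally persist score tables and overlays.

    A failing patient is logged and skipped; the others proceed.
    """
    config = config or PipelineConfig()
    results: dict[str, PatientResult] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for item in images:
        image = item if isinstance(item, WideFieldImage) else udio.read_image(item)
        try:
            result = screen_patient(image, config, detector=detector)
        except Exception:
            logger.exception("patient %s failed; continuing", image.patient_id)
            continue
        results[image.patient_id] = result
        if out is not None:
            if result.score_table is not None:
                udio.write_score_table(
                    result.score_table, out / f"{image.patient_id}_scores.csv"
                )
                if write_overlays:
                    overlay = render_overlay(
                        image.pixels, result.kept_boxes, result.score_table,
                        k=config.ud_top_k,
                    )
                    overlay.save(out / f"{image.patient_id}_overlay.png")
            udio.write_boxes_csv(
                result.detections, out / f"{image.patient_id}_detections.csv",
                image.patient_id,
            )
            with open(out / f"{image.patient_id}_manifest.json", "w") as fh:
                json.dump(result.manifest, fh, indent=1, sort_keys=True)
    return results


def run_evaluation(
    records: Sequence[SelectionRecord],
    ai_rankings: dict,
    config: Optional[PipelineConfig] = None,
    excluded_lesions: Optional[dict] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Compute the study-report statistics, optionally writing JSON + CSVs."""
    config = config or PipelineConfig()
    seen = set()
    for r in records:
        key = (r.participant_id, r.patient_id, r.ai_assisted)
        if key in seen:
            raise ValueError(f"duplicate selection record {key}")
        seen.add(key)
    known = {lid for ranking in ai_rankings.values() for lid in ranking}
    cleaned = []
    for r in records:
        unknown = [lid for lid in r.ordered_lesion_ids if lid not in known]
        if unknown:
            logger.warning(
                "record %s/%s refers to unknown lesions %s; dropped",
                r.participant_id, r.patient_id, unknown,
            )
        cleaned.append(
            SelectionRecord(
                r.participant_id, r.group, r.patient_id,
                [lid for lid in r.ordered_lesion_ids if lid in known],
                r.confidence, r.ai_assisted,
            )
        )
    report = group_summaries(
        cleaned, ai_rankings, config.evaluation, excluded_lesions
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
        for name, frame in report_to_frames(report).items():
            frame.to_csv(out / f"{name}.csv")
    return report
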