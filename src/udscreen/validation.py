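"""Rater-study metrics: sensitivity, expert majority voting, top-u curves.

The clinical reference standard for the ugly-duckling task is the majority
selection of the most experienced dermatologists: a lesion counts as a true
ugly duckling for a patient image when at least 2 of the 3 experts picked it.
Every participant's (and the AI's) selections are evaluated against that
reference with the sensitivity TP / (TP + FN); the AI additionally gets a
top-u sensitivity curve, treating its u highest-scoring lesions as the
selected set. Selections deeper than rank 20 and poorly illuminated lesions
are excluded before any metric is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import BoundingBox, LesionId, iou

logger = logging.getLogger(__name__)

GROUPS = ("derm<=5y", "derm<=10y", "derm>10y", "gp", "student")
EXPERT_GROUP = "derm>10y"


@dataclass
class SelectionRecord:
    """One participant's ordered lesion picks for one patient image."""

    participant_id: str
    group: str
    patient_id: str
    ordered_lesion_ids: list[LesionId]
    confidence: int
    ai_assisted: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if len(set(self.ordered_lesion_ids)) != len(self.ordered_lesion_ids):
            raise ValueError(
                f"duplicate lesion ids in selection of {self.participant_id} "
                f"for {self.patient_id}"
            )
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ValueError(f"confidence must be an integer 1..5, got {self.confidence}")


@dataclass
class EvaluationConfig:
    """Evaluation constants.

    max_rank: selections deeper than this are discarded (rank-20 truncation).
    majority_min: experts required to agree for the majority reference (2 of 3).
    ai_top_k: size of the AI's proposed ugly-duckling set (10; per-patient
    overrides support the occasional image where fewer were highlighted).
    """

    max_rank: int = 20
    expert_group: str = EXPERT_GROUP
    majority_min: int = 2
    ai_top_k: int = 10
    match_iou_min: float = 0.3
    top_u_max: int = 50
    ai_top_k_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_rank < self.ai_top_k:
            raise ValueError("max_rank must be >= ai_top_k")

    def top_k_for(self, patient_id: str) -> int:
        return self.ai_top_k_overrides.get(patient_id, self.ai_top_k)


def match_selections_to_lesions(
    drawn_boxes: Sequence[BoundingBox],
    detected: Sequence[BoundingBox],
    match_iou_min: float = 0.3,
) -> list[LesionId]:
    """Map participant-drawn boxes to detected lesion ids.

    Greedy one-to-one assignment in drawn order: each drawn box takes the
    highest-IoU unmatched detection with IoU >= ``match_iou_min``; drawn boxes
    that match nothing are dropped with a warning.
    """
    for det in detected:
        if det.lesion_id is None:
            raise ValueError("detected boxes must carry lesion ids")
    taken: set[LesionId] = set()
    matched: list[LesionId] = []
    for drawn in drawn_boxes:
        best_id, best_iou = None, match_iou_min
        for det in detected:
            if det.lesion_id in taken:
                continue
            overlap = iou(drawn, det)
            if overlap >= best_iou:
                best_id, best_iou = det.lesion_id, overlap
        if best_id is None:
            logger.warning("drawn box %s matched no detected lesion; dropped", drawn)
        else:
            taken.add(best_id)
            matched.append(best_id)
    return matched


def match_boxes_by_iou(
    source: Sequence[BoundingBox],
    detected: Sequence[BoundingBox],
    match_iou_min: float = 0.3,
) -> dict:
    """Greedy one-to-one source-id -> detected-id mapping by IoU.

    Used to translate ground-truth or externally annotated lesion identities
    into the detector's identities.
    """
    mapping: dict = {}
    taken: set = set()
    for s in source:
        best_id, best_iou = None, match_iou_min
        for d in detected:
            if d.lesion_id in taken:
                continue
            overlap = iou(s, d)
            if overlap >= best_iou:
                best_id, best_iou = d.lesion_id, overlap
        if best_id is not None:
            mapping[s.lesion_id] = best_id
            taken.add(best_id)
    return mapping


def truncate_selection(
    record: SelectionRecord,
    max_rank: int = 20,
    excluded_lesions: Optional[set] = None,
) -> SelectionRecord:
    """Drop excluded lesions, then keep the first ``max_rank`` remaining picks."""
    excluded = excluded_lesions or set()
    kept = [lid for lid in record.ordered_lesion_ids if lid not in excluded][:max_rank]
    return replace(record, ordered_lesion_ids=kept)


def sensitivity(selected: set, reference: set) -> Optional[float]:
    """TP / (TP + FN); None (undefined, to be skipped) when reference is empty."""
    if not reference:
        return None
    tp = len(selected & reference)
    fn = len(reference - selected)
    return tp / (tp + fn)


def majority_selection(
    expert_records: Sequence[SelectionRecord],
    majority_min: int = 2,
    expert_group: str = EXPERT_GROUP,
) -> set:
    """Lesions picked by at least ``majority_min`` of the experts (one patient)."""
    if not expert_records:
        raise ValueError("no expert records given")
    patients = {r.patient_id for r in expert_records}
    if len(patients) != 1:
        raise ValueError(f"records mix patients: {sorted(patients)}")
    for r in expert_records:
        if r.group != expert_group:
            raise ValueError(f"record from non-expert group {r.group!r}")
        if r.ai_assisted:
            raise ValueError("majority reference must use unassisted expert records")
    counts: dict = {}
    for r in expert_records:
        for lid in r.ordered_lesion_ids:
            counts[lid] = counts.get(lid, 0) + 1
    return {lid for lid, c in counts.items() if c >= majority_min}


def top_u_ai_sensitivity(
    ai_ranking: Sequence[LesionId], record: SelectionRecord, u: int
) -> Optional[float]:
    """Sensitivity of the AI's top-u lesions against one participant's picks.

    Participant picks the AI never detected remain in the reference and count
    as false negatives.
    """
    if u < 1:
        raise ValueError("u must be >= 1")
    return sensitivity(set(ai_ranking[:u]), set(record.ordered_lesion_ids))


def _iqr(values: Sequence[float]) -> float:
    if len(values) == 0:
        return float("nan")
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def _mean(values: Sequence[float]) -> float:
    return float(np.mean(values)) if len(values) else float("nan")


def group_summaries(
    records: Sequence[SelectionRecord],
    ai_rankings: Mapping[str, Sequence[LesionId]],
    config: Optional[EvaluationConfig] = None,
    excluded_lesions: Optional[Mapping[str, set]] = None,
) -> dict:
    """Study-report statistics per group and assistance condition.

    For every (group, ai_assisted) cell: mean/IQR of per-image sensitivity
    against the expert majority, mean/IQR of top-k AI sensitivity, the top-u
    AI sensitivity curve (u = 1..top_u_max), mean number of selected lesions,
    mean confidence, and the per-participant-per-image confidence change
    (assisted minus unassisted). The AI's own sensitivity against the expert
    majority is reported as well. Records are truncated (rank cap + excluded
    lesions) before anything is computed; images with an empty reference are
    skipped, never counted as zero.
    """
    config = config or EvaluationConfig()
    excluded_lesions = excluded_lesions or {}

    truncated = [
        truncate_selection(
            r, config.max_rank, set(excluded_lesions.get(r.patient_id, set()))
        )
        for r in records
    ]

    patients = sorted({r.patient_id for r in truncated})
    majorities: dict[str, set] = {}
    for pid in patients:
        experts = [
            r
            for r in truncated
            if r.patient_id == pid and r.group == config.expert_group and not r.ai_assisted
        ]
        if experts:
            majorities[pid] = majority_selection(
                experts, config.majority_min, config.expert_group
            )

    def ai_top(pid: str, u: int) -> list[LesionId]:
        ranking = ai_rankings.get(pid, [])
        return list(ranking[:u])

    by_cell: dict[tuple[str, bool], list[SelectionRecord]] = {}
    for r in truncated:
        by_cell.setdefault((r.group, r.ai_assisted), []).append(r)

    report: dict = {"groups": {}, "ai": {}, "patients": patients}
    for (group, assisted), cell in sorted(by_cell.items()):
        maj_sens = [
            s
            for r in cell
            if r.patient_id in majorities
            and (s := sensitivity(set(r.ordered_lesion_ids), majorities[r.patient_id]))
            is not None
        ]
        topk_sens = [
            s
            for r in cell
            if (
                s := top_u_ai_sensitivity(
                    ai_rankings.get(r.patient_id, []),
                    r,
                    config.top_k_for(r.patient_id),
                )
            )
            is not None
        ]
        top_u_curve = {}
        for u in range(1, config.top_u_max + 1):
            vals = [
                s
                for r in cell
                if (s := top_u_ai_sensitivity(ai_rankings.get(r.patient_id, []), r, u))
                is not None
            ]
            top_u_curve[u] = _mean(vals)
        report["groups"][f"{group}|{'ai' if assisted else 'no_ai'}"] = {
            "n_records": len(cell),
            "majority_sensitivity_mean": _mean(maj_sens),
            "majority_sensitivity_iqr": _iqr(maj_sens),
            "top_k_ai_sensitivity_mean": _mean(topk_sens),
            "top_k_ai_sensitivity_iqr": _iqr(topk_sens),
            "top_u_ai_sensitivity": top_u_curve,
            "mean_selected_per_image": _mean(
                [len(r.ordered_lesion_ids) for r in cell]
            ),
            "mean_confidence": _mean([r.confidence for r in cell]),
        }

    # confidence change: assisted minus unassisted, per participant per image
    paired: dict[tuple[str, str], dict[bool, SelectionRecord]] = {}
    for r in truncated:
        paired.setdefault((r.participant_id, r.patient_id), {})[r.ai_assisted] = r
    deltas_by_group: dict[str, list[float]] = {}
    count_deltas_by_group: dict[str, list[float]] = {}
    for (part, pid), pair in paired.items():
        if True not in pair or False not in pair:
            logger.warning(
                "participant %s image %s lacks a paired record; skipped for deltas",
                part, pid,
            )
            continue
        g = pair[True].group
        deltas_by_group.setdefault(g, []).append(
            pair[True].confidence - pair[False].confidence
        )
        count_deltas_by_group.setdefault(g, []).append(
            len(pair[True].ordered_lesion_ids) - len(pair[False].ordered_lesion_ids)
        )
    for g in deltas_by_group:
        report["groups"].setdefault(f"{g}|delta", {})
        report["groups"][f"{g}|delta"] = {
            "confidence_change_mean": _mean(deltas_by_group[g]),
            "selected_count_change_mean": _mean(count_deltas_by_group[g]),
        }

    # the AI itself against the expert majority
    ai_maj = [
        s
        for pid in patients
        if pid in majorities
        and (
            s := sensitivity(
                set(ai_top(pid, config.top_k_for(pid))), majorities[pid]
            )
        )
        is not None
    ]
    report["ai"] = {
        "top_k_sensitivity_vs_majority_mean": _mean(ai_maj),
        "top_k_sensitivity_vs_majority_iqr": _iqr(ai_maj),
    }
    return report


def report_to_frames(report: dict) -> dict[str, pd.DataFrame]:
    """Flatten a group_summaries report into tidy DataFrames for CSV export."""
    rows, curve_rows = [], []
    for cell, stats in report["groups"].items():
        flat = {k: v for k, v in stats.items() if not isinstance(v, dict)}
        flat["cell"] = cell
        rows.append(flat)
        for u, v in stats.get("top_u_ai_sensitivity", {}).items():
            curve_rows.append({"cell": cell, "u": u, "mean_sensitivity": v})
    return {
        "summary": pd.DataFrame(rows).set_index("cell"),
        "top_u_curves": pd.DataFrame(curve_rows),
    }
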