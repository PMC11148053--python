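"""Readers and writers for the package's on-disk dialects.

Images are 8-bit RGB PNG/TIFF. Boxes travel either as COCO-style JSON
(xywh, converted to the package's half-open xyxy convention on ingest) or as
a flat CSV with columns ``patient_id, lesion_id, x_min, y_min, x_max, y_max,
confidence``. Participant selections use a long CSV with one row per pick.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import BoundingBox, WideFieldImage
from .validation import SelectionRecord

PathLike = Union[str, Path]

BOX_CSV_COLUMNS = ["patient_id", "lesion_id", "x_min", "y_min", "x_max", "y_max", "confidence"]


def read_image(path: PathLike, patient_id: Optional[str] = None) -> WideFieldImage:
    """Load an 8-bit RGB PNG/TIFF into the [0, 1] float convention."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"), dtype=np.float64) / 255.0
    return WideFieldImage(pixels=arr, patient_id=patient_id or Path(path).stem)


def write_image(image: Union[WideFieldImage, np.ndarray], path: PathLike) -> None:
    pixels = image.pixels if isinstance(image, WideFieldImage) else np.asarray(image)
    arr = (np.clip(pixels, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def write_boxes_csv(boxes: Sequence[BoundingBox], path: PathLike, patient_id: str) -> None:
    rows = [
        {
            "patient_id": patient_id,
            "lesion_id": b.lesion_id,
            "x_min": b.x_min,
            "y_min": b.y_min,
            "x_max": b.x_max,
            "y_max": b.y_max,
            "confidence": b.confidence,
        }
        for b in boxes
    ]
    pd.DataFrame(rows, columns=BOX_CSV_COLUMNS).to_csv(path, index=False)


def read_boxes_csv(path: PathLike) -> dict[str, list[BoundingBox]]:
    """Boxes grouped by patient_id."""
    df = pd.read_csv(path)
    out: dict[str, list[BoundingBox]] = {}
    for row in df.itertuples(index=False):
        conf = None if pd.isna(row.confidence) else float(row.confidence)
        out.setdefault(str(row.patient_id), []).append(
            BoundingBox(
                float(row.x_min), float(row.y_min), float(row.x_max), float(row.y_max),
                confidence=conf, lesion_id=row.lesion_id,
            )
        )
    return out


def boxes_to_coco(
    boxes: Sequence[BoundingBox],
    image_height: int,
    image_width: int,
    patient_id: str,
) -> dict:
    """COCO-style dict (xywh) for one image."""
    return {
        "images": [
            {"id": 1, "file_name": f"{patient_id}.png", "height": image_height, "width": image_width}
        ],
        "categories": [{"id": 1, "name": "lesion"}],
        "annotations": [
            {
                "id": i + 1,
                "image_id": 1,
                "category_id": 1,
                "bbox": [b.x_min, b.y_min, b.width, b.height],
                "area": b.area,
                "score": b.confidence,
                "lesion_id": b.lesion_id,
                "iscrowd": 0,
            }
            for i, b in enumerate(boxes)
        ],
    }


def write_coco(boxes: Sequence[BoundingBox], path: PathLike, image_height: int,
               image_width: int, patient_id: str) -> None:
    with open(path, "w") as fh:
        json.dump(boxes_to_coco(boxes, image_height, image_width, patient_id), fh, indent=1)


def read_coco(path: PathLike) -> list[BoundingBox]:
    """Boxes from a COCO-style JSON file (xywh converted to half-open xyxy)."""
    with open(path) as fh:
        data = json.load(fh)
    boxes = []
    for ann in data.get("annotations", []):
        x, y, w, h = ann["bbox"]
        boxes.append(
            BoundingBox(
                x, y, x + w, y + h,
                confidence=ann.get("score"),
                lesion_id=ann.get("lesion_id", ann.get("id")),
            )
        )
    return boxes


SELECTION_CSV_COLUMNS = [
    "participant_id", "group", "patient_id", "rank", "lesion_id", "confidence", "ai_assisted",
]


def write_selections_csv(records: Sequence[SelectionRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        if r.ordered_lesion_ids:
            for rank, lid in enumerate(r.ordered_lesion_ids, start=1):
                rows.append(
                    [r.participant_id, r.group, r.patient_id, rank, lid, r.confidence, r.ai_assisted]
                )
        else:
            rows.append([r.participant_id, r.group, r.patient_id, 0, "", r.confidence, r.ai_assisted])
    pd.DataFrame(rows, columns=SELECTION_CSV_COLUMNS).to_csv(path, index=False)


def read_selections_csv(path: PathLike) -> list[SelectionRecord]:
    df = pd.read_csv(path)
    records = []
    keys = ["participant_id", "patient_id", "ai_assisted"]
    for (part, pid, assisted), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("rank")
        picks = [str(lid) for r, lid in zip(grp["rank"], grp["lesion_id"]) if r > 0]
        records.append(
            SelectionRecord(
                participant_id=str(part),
                group=str(grp["group"].iloc[0]),
                patient_id=str(pid),
                ordered_lesion_ids=picks,
                confidence=int(grp["confidence"].iloc[0]),
                ai_assisted=bool(assisted),
            )
        )
    return records


def write_score_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, index=False, float_format="%.8f")


def read_score_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
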