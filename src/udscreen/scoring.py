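"""Ugly-duckling scoring: cosine distance from the median embedding.

The "ugly duckling" sign is inherently relative: a suspicious lesion is one
that deviates from the patient's own nevus pattern. With all of a patient's
lesions embedded in a common latent space, the patient's typical appearance
is summarized by the coordinate-wise median embedding; each lesion's raw
outlierness is its cosine distance from that median, and min-max
normalization across the patient's lesions yields a UD score in [0, 1]. The
top-k (default 10) scoring lesions are proposed for dermoscopic review.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import BoundingBox, LesionId


def median_embedding(embeddings: np.ndarray) -> np.ndarray:
    """Coordinate-wise median across lesion embeddings (midpoint for even n)."""
    E = np.asarray(embeddings, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] < 1:
        raise ValueError("embedding matrix must be 2-D with at least one row")
    return np.median(E, axis=0)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b), in [0, 2]. Zero vectors are rejected."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for zero vectors")
    # clamp floating-point noise at the boundaries
    return float(np.clip(1.0 - np.dot(a, b) / (na * nb), 0.0, 2.0))


def ud_scores(
    embeddings: np.ndarray, lesion_ids: Optional[Sequence[LesionId]] = None
) -> pd.DataFrame:
    """Per-lesion UD score table.

    Raw distance is the cosine distance of each embedding from the
    coordinate-wise median embedding; scores are min-max normalized per
    patient (all zero when every distance is equal). Ranks are 1-based by
    descending score with lesion_id as the deterministic tie-break.

    Returns a DataFrame with columns ``lesion_id, raw_distance, score, rank``.
    """
    E = np.asarray(embeddings, dtype=np.float64)
    if E.ndim != 2 or E.shape[0] < 2:
        raise ValueError("need at least 2 lesion embeddings to score")
    if not np.all(np.isfinite(E)):
        raise ValueError("embedding matrix contains non-finite entries")
    n = E.shape[0]
    if lesion_ids is None:
        lesion_ids = list(range(n))
    if len(lesion_ids) != n:
        raise ValueError("lesion_ids length must match number of embeddings")
    med = median_embedding(E)
    if np.linalg.norm(med) == 0.0:
        raise ValueError("median embedding is the zero vector; cannot score")
    distances = np.array([cosine_distance(row, med) for row in E])
    d_min, d_max = distances.min(), distances.max()
    if d_max > d_min:
        scores = (distances - d_min) / (d_max - d_min)
    else:
        scores = np.zeros_like(distances)
    table = pd.DataFrame(
        {"lesion_id": list(lesion_ids), "raw_distance": distances, "score": scores}
    )
    order = table.sort_values(
        ["score", "lesion_id"], ascending=[False, True], kind="mergesort"
    ).index
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    table["rank"] = ranks
    return table


def top_k(table: pd.DataFrame, k: int = 10) -> list[LesionId]:
    """The first min(k, n) lesion_ids by rank — the proposed AI ugly ducklings."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = table.sort_values("rank")
    return list(ordered["lesion_id"].iloc[: min(k, len(table))])


class UglyDucklingScorer(BaseEstimator):
    """Median-reference cosine outlier scorer (sklearn-style estimator).

    Parameters
    ----------
    top_k : int
        Number of lesions proposed as ugly ducklings (default 10).
    reference : {"median", "medoid"}
        "median" (default) uses the coordinate-wise median embedding;
        "medoid" uses the row minimizing total cosine distance to all rows.

    Attributes (after ``fit``)
    --------------------------
    reference_embedding_ : the patient's typical-appearance vector
    score_table_ : DataFrame (lesion_id, raw_distance, score, rank)
    ranking_ : all lesion_ids ordered by rank
    top_k_ids_ : the proposed ugly ducklings
    """

    def __init__(self, top_k: int = 10, reference: str = "median"):
        self.top_k = top_k
        self.reference = reference

    def fit(self, X: np.ndarray, y=None, lesion_ids: Optional[Sequence[LesionId]] = None):
        E = np.asarray(X, dtype=np.float64)
        if self.reference == "median":
            ref = median_embedding(E)
        elif self.reference == "medoid":
            norms = np.linalg.norm(E, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("zero embedding row")
            U = E / norms
            total = (1.0 - U @ U.T).sum(axis=1)
            ref = E[int(np.argmin(total))]
        else:
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.reference == "medoid":
            n = E.shape[0]
            ids = list(lesion_ids) if lesion_ids is not None else list(range(n))
            distances = np.array([cosine_distance(row, ref) for row in E])
            d_min, d_max = distances.min(), distances.max()
            scores = (
                (distances - d_min) / (d_max - d_min)
                if d_max > d_min
                else np.zeros_like(distances)
            )
            table = pd.DataFrame(
                {"lesion_id": ids, "raw_distance": distances, "score": scores}
            )
            order = table.sort_values(
                ["score", "lesion_id"], ascending=[False, True], kind="mergesort"
            ).index
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
            table["rank"] = ranks
        else:
            table = ud_scores(E, lesion_ids=lesion_ids)
        self.reference_embedding_ = ref
        self.score_table_ = table
        self.ranking_ = top_k(table, k=len(table))
        self.top_k_ids_ = self.ranking_[: self.top_k]
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Raw cosine distances of new embeddings from the fitted reference."""
        E = np.asarray(X, dtype=np.float64)
        return np.array([cosine_distance(row, self.reference_embedding_) for row in E])


def render_overlay(
    image_pixels: np.ndarray,
    boxes: Sequence[BoundingBox],
    table: pd.DataFrame,
    k: int = 10,
) -> "PIL.Image.Image":
    """Review overlay: top-k boxes in red, the rest in green, scores printed.

    Returns a PIL image ready to be saved as PNG.
    """
    from PIL import Image, ImageDraw

    img = Image.fromarray(
        (np.clip(image_pixels, 0, 1) * 255).astype(np.uint8), mode="RGB"
    )
    draw = ImageDraw.Draw(img)
    top = set(top_k(table, k=k))
    scores = dict(zip(table["lesion_id"], table["score"]))
    for box in boxes:
        color = (255, 0, 0) if box.lesion_id in top else (0, 200, 0)
        draw.rectangle(
            [box.x_min, box.y_min, box.x_max - 1, box.y_max - 1], outline=color, width=2
        )
        if box.lesion_id in scores:
            draw.text(
                (box.x_min, max(0, box.y_min - 12)),
                f"{scores[box.lesion_id]:.2f}",
                fill=color,
            )
    return img
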