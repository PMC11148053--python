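"""Exclusion of poorly illuminated lesions.

Wide-field photographs contain shadowed regions (armpits, shoulder edges)
where lesion appearance is unreliable and tends to produce spuriously high
outlier scores. Each lesion crop's surrounding-skin ring gives a hand-crafted
illumination feature — the mean intensity of the frame pixels — whose
patient-level distribution is roughly Gaussian with a left tail of shadowed
lesions. Lesions more than ``k_sigma`` (default 2) standard deviations below
the patient's mean are flagged and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import LesionCrop, frame_ring_pixels, luma


@dataclass
class IlluminationStats:
    """Patient-level location/spread of the frame-intensity feature."""

    mu: float
    sigma: float
    k_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")

    @property
    def cutoff(self) -> float:
        return self.mu - self.k_sigma * self.sigma


def frame_mean_intensity(crop: LesionCrop) -> float:
    """Mean grayscale intensity over the crop's frame ring."""
    ring = frame_ring_pixels(crop)
    return float(np.mean(luma(ring)))


def fit_illumination_stats(
    features: Sequence[float], k_sigma: float = 2.0, robust: bool = False
) -> IlluminationStats:
    """Estimate the patient-level feature distribution.

    Uses the sample mean and population standard deviation (one pass, no
    trimming). ``robust=True`` swaps in median and scaled MAD for patients
    whose feature histogram is heavily contaminated.
    """
    feats = np.asarray(features, dtype=np.float64)
    if feats.size < 2:
        raise ValueError("need at least 2 features to estimate spread")
    if robust:
        mu = float(np.median(feats))
        # 1.4826 scales MAD to the SD of a Gaussian
        sigma = float(1.4826 * np.median(np.abs(feats - mu)))
    else:
        mu = float(np.mean(feats))
        sigma = float(np.std(feats))
    return IlluminationStats(mu=mu, sigma=sigma, k_sigma=k_sigma)


def flag_poorly_illuminated(
    features: Sequence[float], stats: IlluminationStats
) -> np.ndarray:
    """Boolean mask: True where a lesion sits below the two-sigma cutoff.

    Strictly below ``mu - k_sigma * sigma``; with ``sigma == 0`` nothing is
    flagged (no feature lies strictly below its own mean).
    """
    feats = np.asarray(features, dtype=np.float64)
    return feats < stats.cutoff


def illumination_mask(
    crops: Sequence[LesionCrop], k_sigma: float = 2.0, robust: bool = False
) -> tuple[np.ndarray, IlluminationStats]:
    """Convenience wrapper: features -> stats -> mask for one patient's crops."""
    features = [frame_mean_intensity(c) for c in crops]
    stats = fit_illumination_stats(features, k_sigma=k_sigma, robust=robust)
    return flag_poorly_illuminated(features, stats), stats
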