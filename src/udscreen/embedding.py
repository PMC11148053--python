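"""Per-patient self-supervised lesion embeddings.

The ugly-duckling sign is defined within a single patient's context, so one
embedding model is trained from scratch per patient on that patient's lesion
patches only — no pretrained weights, no other patients' data. Training
follows the self-distillation (DINO-style) recipe: a student network matches
the sharpened, centered output distribution of an exponential-moving-average
teacher across augmented views of the same patch. Augmentations are random
resized crops (global + local views), brightness jitter to mimic uneven
illumination, and per-channel color jitter whose strength is multiplied
tenfold relative to the usual default so that color differences — clinically
the strongest outlier cue — dominate the invariance structure.

Training runs for at least ``min_epochs``; afterwards, every
``check_interval_epochs`` the current top-k ugly-duckling ranking (computed
from teacher-backbone embeddings) is compared with the previous check and
training stops as soon as the ranking no longer changes, with a hard cap at
``max_epochs``. Inference embeddings come from the teacher backbone (before
the projection head) with no augmentation.

The network is a small multilayer perceptron over downsampled patch pixels,
implemented directly in numpy (forward, backward, Adam) so training is fully
deterministic under a seed and runs in seconds per patient on one CPU core.
A deterministic hand-crafted feature embedder with the same estimator
contract is provided for fast, training-free pipeline runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import LesionId, luma, frame_ring_mask
from .patches import Patch
from .scoring import top_k, ud_scores

# ---------------------------------------------------------------------------
# configuration


@dataclass
class EmbedderConfig:
    """Everything the per-patient self-distillation embedder needs.

    ``backbone`` identifies the network family; this package ships the "mlp"
    backbone (hidden layer over downsampled pixels). ``view_size`` is the
    resolution views are resampled to before entering the network;
    ``patch_size`` is the resolution of the stored patches.
    """

    backbone: str = "mlp"
    patch_size: int = 224
    view_size: int = 16
    hidden_dim: int = 256
    embedding_dim: int = 64
    projection_dim: int = 64
    min_epochs: int = 200
    max_epochs: int = 300
    check_interval_epochs: int = 10
    top_k_monitor: int = 10
    teacher_momentum: float = 0.996
    student_temp: float = 0.1
    teacher_temp: float = 0.04
    center_momentum: float = 0.9
    learning_rate: float = 1e-3
    brightness_jitter_strength: float = 0.2
    color_jitter_base_strength: float = 0.04
    color_jitter_multiplier: float = 10.0
    n_global_views: int = 2
    n_local_views: int = 4
    global_scale: tuple[float, float] = (0.4, 1.0)
    local_scale: tuple[float, float] = (0.1, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_epochs > self.max_epochs:
            raise ValueError("min_epochs must be <= max_epochs")
        if self.check_interval_epochs < 1:
            raise ValueError("check_interval_epochs must be >= 1")
        if self.student_temp <= 0 or self.teacher_temp <= 0:
            raise ValueError("temperatures must be positive")
        if not (0.0 < self.teacher_momentum < 1.0):
            raise ValueError("teacher_momentum must be in (0, 1)")

    def estimator(self) -> "SelfDistillationEmbedder":
        kwargs = asdict(self)
        kwargs.pop("backbone")
        kwargs.pop("patch_size")
        seed = kwargs.pop("seed")
        return SelfDistillationEmbedder(random_state=seed, **kwargs)


#: Full-scale profile: full patch resolution and the long epoch schedule.
FULL_SCALE = EmbedderConfig()

#: Desk-scale profile: small patches and a short schedule so a patient trains
#: in seconds on one CPU core; intended for tests and demonstrations.
DESK_SCALE = EmbedderConfig(
    patch_size=64,
    min_epochs=20,
    max_epochs=30,
    check_interval_epochs=2,
)

PROFILES = {"full-scale": FULL_SCALE, "desk-scale": DESK_SCALE}


# ---------------------------------------------------------------------------
# stopping rule


def ranking_converged(previous: Sequence[LesionId], current: Sequence[LesionId]) -> bool:
    """True iff two top-k rankings are identical as ordered sequences."""
    return len(previous) == len(current) and all(
        p == c for p, c in zip(previous, current)
    )


class RankingStabilityMonitor:
    """Implements the ranking-stability stopping rule.

    Checks happen at epochs ``min_epochs, min_epochs + interval, ...``; the
    run is converged at the first check whose ranking equals the previous
    check's ranking. Never signals before ``min_epochs``.
    """

    def __init__(self, min_epochs: int, max_epochs: int, check_interval: int):
        self.min_epochs = min_epochs
        self.max_epochs = max_epochs
        self.check_interval = check_interval
        self._previous: Optional[list[LesionId]] = None
        self.history: list[tuple[int, list[LesionId]]] = []

    def is_check_epoch(self, epoch: int) -> bool:
        return epoch >= self.min_epochs and (
            (epoch - self.min_epochs) % self.check_interval == 0
        )

    def observe(self, epoch: int, ranking: Sequence[LesionId]) -> bool:
        """Record a check; returns True when the ranking has stabilized."""
        ranking = list(ranking)
        self.history.append((epoch, ranking))
        converged = self._previous is not None and ranking_converged(
            self._previous, ranking
        )
        self._previous = ranking
        return converged


def stopping_epoch(
    ranking_at: Callable[[int], Sequence[LesionId]],
    min_epochs: int,
    max_epochs: int,
    check_interval: int,
) -> tuple[int, str]:
    """Epoch at which training stops, given the ranking produced at each check.

    Returns ``(stop_epoch, reason)`` with reason "converged" or "max_epochs".
    """
    monitor = RankingStabilityMonitor(min_epochs, max_epochs, check_interval)
    for epoch in range(1, max_epochs + 1):
        if monitor.is_check_epoch(epoch) and monitor.observe(epoch, ranking_at(epoch)):
            return epoch, "converged"
    return max_epochs, "max_epochs"


@dataclass
class TrainingLog:
    """Record of one per-patient training run."""

    loss_per_epoch: list[float] = field(default_factory=list)
    ranking_checks: list[tuple[int, list[LesionId]]] = field(default_factory=list)
    stop_epoch: int = 0
    stop_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "loss_per_epoch": self.loss_per_epoch,
            "ranking_checks": [
                {"epoch": e, "ranking": [str(x) for x in r]}
                for e, r in self.ranking_checks
            ],
            "stop_epoch": self.stop_epoch,
            "stop_reason": self.stop_reason,
        }


# ---------------------------------------------------------------------------
# augmentation


def _bilinear_resample(img: np.ndarray, y0: float, x0: float, h: float, w: float, out: int) -> np.ndarray:
    """Bilinear sample of the window [y0, y0+h) x [x0, x0+w) onto out x out."""
    S = img.shape[0]
    ys = y0 + (np.arange(out) + 0.5) * h / out - 0.5
    xs = x0 + (np.arange(out) + 0.5) * w / out - 0.5
    ys = np.clip(ys, 0, S - 1)
    xs = np.clip(xs, 0, S - 1)
    yi = np.floor(ys).astype(int)
    xi = np.floor(xs).astype(int)
    yf = (ys - yi)[:, None, None]
    xf = (xs - xi)[None, :, None]
    yi1 = np.minimum(yi + 1, S - 1)
    xi1 = np.minimum(xi + 1, S - 1)
    a = img[np.ix_(yi, xi)]
    b = img[np.ix_(yi, xi1)]
    c = img[np.ix_(yi1, xi)]
    d = img[np.ix_(yi1, xi1)]
    return (
        a * (1 - yf) * (1 - xf)
        + b * (1 - yf) * xf
        + c * yf * (1 - xf)
        + d * yf * xf
    )


def _one_view(
    patch: np.ndarray,
    scale_range: tuple[float, float],
    view_size: int,
    brightness_strength: float,
    channel_strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    S = patch.shape[0]
    img = patch
    # brightness jitter (counteracts residual uneven illumination)
    if brightness_strength > 0:
        img = np.clip(img * (1.0 + rng.uniform(-brightness_strength, brightness_strength)), 0.0, 1.0)
    # random resized crop
    lo, hi = scale_range
    if lo == 1.0 and hi == 1.0:
        view = img if S == view_size else _bilinear_resample(img, 0, 0, S, S, view_size)
    else:
        area = rng.uniform(lo, hi) * S * S
        log_aspect = rng.uniform(np.log(3 / 4), np.log(4 / 3))
        aspect = np.exp(log_aspect)
        w = min(S, max(1.0, np.sqrt(area * aspect)))
        h = min(S, max(1.0, np.sqrt(area / aspect)))
        y0 = rng.uniform(0, S - h)
        x0 = rng.uniform(0, S - w)
        view = _bilinear_resample(img, y0, x0, h, w, view_size)
    # per-channel color jitter; strength capped so factors stay positive
    if channel_strength > 0:
        s = min(channel_strength, 0.95)
        factors = 1.0 + rng.uniform(-s, s, size=3)
        view = np.clip(view * factors[None, None, :], 0.0, 1.0)
    return np.ascontiguousarray(view, dtype=np.float64)


def build_views(
    patch: Patch | np.ndarray,
    config: EmbedderConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Augmented global + local views of one patch, all at ``view_size``.

    Deterministic given the generator state. Global views cover most of the
    patch; local views are small crops that must map onto the same teacher
    distribution, which is what drives the representation to encode
    lesion-level appearance rather than position.
    """
    pixels = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    cs = config.color_jitter_base_strength * config.color_jitter_multiplier
    views = [
        _one_view(
            pixels, config.global_scale, config.view_size,
            config.brightness_jitter_strength, cs, rng,
        )
        for _ in range(config.n_global_views)
    ]
    views += [
        _one_view(
            pixels, config.local_scale, config.view_size,
            config.brightness_jitter_strength, cs, rng,
        )
        for _ in range(config.n_local_views)
    ]
    return views


# ---------------------------------------------------------------------------
# numpy MLP with Adam


class _MLPNet:
    """Two-layer backbone + linear projection head, with manual backprop."""

    PARAM_KEYS = ("W1", "b1", "W2", "b2", "Wp", "bp")

    def __init__(self, d_in: int, hidden: int, d_embed: int, d_proj: int, rng: np.random.Generator):
        self.params = {
            "W1": rng.normal(0, np.sqrt(2.0 / d_in), (d_in, hidden)),
            "b1": np.zeros(hidden),
            "W2": rng.normal(0, np.sqrt(2.0 / hidden), (hidden, d_embed)),
            "b2": np.zeros(d_embed),
            "Wp": rng.normal(0, np.sqrt(2.0 / d_embed), (d_embed, d_proj)),
            "bp": np.zeros(d_proj),
        }

    def forward(self, x: np.ndarray):
        p = self.params
        h1 = np.maximum(x @ p["W1"] + p["b1"], 0.0)
        z = h1 @ p["W2"] + p["b2"]
        logits = z @ p["Wp"] + p["bp"]
        return h1, z, logits

    def backbone(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        h1 = np.maximum(x @ p["W1"] + p["b1"], 0.0)
        return h1 @ p["W2"] + p["b2"]

    def backward(self, x: np.ndarray, h1: np.ndarray, z: np.ndarray, dlogits: np.ndarray) -> dict:
        p = self.params
        grads = {}
        grads["Wp"] = z.T @ dlogits
        grads["bp"] = dlogits.sum(axis=0)
        dz = dlogits @ p["Wp"].T
        grads["W2"] = h1.T @ dz
        grads["b2"] = dz.sum(axis=0)
        dh1 = dz @ p["W2"].T
        dh1[h1 <= 0] = 0.0
        grads["W1"] = x.T @ dh1
        grads["b1"] = dh1.sum(axis=0)
        return grads

    def copy(self) -> "_MLPNet":
        clone = object.__new__(_MLPNet)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def ema_update(self, student: "_MLPNet", momentum: float) -> None:
        for k in self.PARAM_KEYS:
            self.params[k] = momentum * self.params[k] + (1 - momentum) * student.params[k]


class _Adam:
    def __init__(self, param_shapes: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in param_shapes.items()}
        self.v = {k: np.zeros(s) for k, s in param_shapes.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# estimators

MIN_PATCHES = 12


class SelfDistillationEmbedder(BaseEstimator, TransformerMixin):
    """Per-patient DINO-style self-distillation embedder (numpy MLP backbone).

    ``fit`` trains student and teacher from random initialization on the given
    patches only; ``transform`` returns teacher-backbone embeddings (before
    the projection head) with no augmentation. Fully deterministic under
    ``random_state``.

    Fitted attributes: ``teacher_``, ``student_``, ``training_log_``,
    ``stop_epoch_``, ``stop_reason_``, ``n_features_in_``.
    """

    def __init__(
        self,
        view_size: int = 16,
        hidden_dim: int = 256,
        embedding_dim: int = 64,
        projection_dim: int = 64,
        min_epochs: int = 200,
        max_epochs: int = 300,
        check_interval_epochs: int = 10,
        top_k_monitor: int = 10,
        teacher_momentum: float = 0.996,
        student_temp: float = 0.1,
        teacher_temp: float = 0.04,
        center_momentum: float = 0.9,
        learning_rate: float = 1e-3,
        brightness_jitter_strength: float = 0.2,
        color_jitter_base_strength: float = 0.04,
        color_jitter_multiplier: float = 10.0,
        n_global_views: int = 2,
        n_local_views: int = 4,
        global_scale: tuple[float, float] = (0.4, 1.0),
        local_scale: tuple[float, float] = (0.1, 0.4),
        random_state: int = 0,
    ):
        self.view_size = view_size
        self.hidden_dim = hidden_dim
        self.embedding_dim = embedding_dim
        self.projection_dim = projection_dim
        self.min_epochs = min_epochs
        self.max_epochs = max_epochs
        self.check_interval_epochs = check_interval_epochs
        self.top_k_monitor = top_k_monitor
        self.teacher_momentum = teacher_momentum
        self.student_temp = student_temp
        self.teacher_temp = teacher_temp
        self.center_momentum = center_momentum
        self.learning_rate = learning_rate
        self.brightness_jitter_strength = brightness_jitter_strength
        self.color_jitter_base_strength = color_jitter_base_strength
        self.color_jitter_multiplier = color_jitter_multiplier
        self.n_global_views = n_global_views
        self.n_local_views = n_local_views
        self.global_scale = global_scale
        self.local_scale = local_scale
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _view_config(self) -> EmbedderConfig:
        return EmbedderConfig(
            view_size=self.view_size,
            hidden_dim=self.hidden_dim,
            embedding_dim=self.embedding_dim,
            projection_dim=self.projection_dim,
            min_epochs=self.min_epochs,
            max_epochs=self.max_epochs,
            check_interval_epochs=self.check_interval_epochs,
            top_k_monitor=self.top_k_monitor,
            teacher_momentum=self.teacher_momentum,
            student_temp=self.student_temp,
            teacher_temp=self.teacher_temp,
            center_momentum=self.center_momentum,
            learning_rate=self.learning_rate,
            brightness_jitter_strength=self.brightness_jitter_strength,
            color_jitter_base_strength=self.color_jitter_base_strength,
            color_jitter_multiplier=self.color_jitter_multiplier,
            n_global_views=self.n_global_views,
            n_local_views=self.n_local_views,
            global_scale=self.global_scale,
            local_scale=self.local_scale,
            seed=self.random_state,
        )

    @staticmethod
    def _as_pixel_list(X) -> tuple[list[np.ndarray], list[LesionId]]:
        pixels, ids = [], []
        for i, item in enumerate(X):
            if isinstance(item, Patch):
                pixels.append(item.pixels)
                ids.append(item.lesion_id if item.lesion_id is not None else i)
            else:
                pixels.append(np.asarray(item, dtype=np.float64))
                ids.append(i)
        return pixels, ids

    def _inference_inputs(self, pixel_list: list[np.ndarray]) -> np.ndarray:
        out = self.view_size
        rows = []
        for img in pixel_list:
            S = img.shape[0]
            small = img if S == out else _bilinear_resample(img, 0, 0, S, S, out)
            rows.append(small.ravel())
        return np.asarray(rows)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y=None):
        """Train the per-patient embedder on this patient's patches only."""
        pixel_list, lesion_ids = self._as_pixel_list(X)
        n = len(pixel_list)
        if n < MIN_PATCHES:
            raise ValueError(
                f"need at least {MIN_PATCHES} lesion patches to train "
                f"(got {n}); multi-view batch statistics degenerate below that"
            )
        cfg = self._view_config()
        rng = np.random.default_rng(self.random_state)
        d_in = self.view_size * self.view_size * 3
        student = _MLPNet(d_in, self.hidden_dim, self.embedding_dim, self.projection_dim, rng)
        teacher = student.copy()
        opt = _Adam({k: v.shape for k, v in student.params.items()}, self.learning_rate)
        center = np.zeros(self.projection_dim)
        infer_X = self._inference_inputs(pixel_list)
        V = self.n_global_views + self.n_local_views
        g = self.n_global_views
        st, tt = self.student_temp, self.teacher_temp

        monitor = RankingStabilityMonitor(
            self.min_epochs, self.max_epochs, self.check_interval_epochs
        )
        log = TrainingLog()
        stop_epoch, stop_reason = self.max_epochs, "max_epochs"

        for epoch in range(1, self.max_epochs + 1):
            views = np.empty((n, V, d_in))
            for i, img in enumerate(pixel_list):
                for j, view in enumerate(build_views(img, cfg, rng)):
                    views[i, j] = view.ravel()
            flat = views.reshape(n * V, d_in)
            h1, z, s_logits = student.forward(flat)
            s_logits = s_logits.reshape(n, V, -1)
            g_flat = views[:, :g].reshape(n * g, d_in)
            _, _, t_logits = teacher.forward(g_flat)
            t_logits = t_logits.reshape(n, g, -1)
            p = _softmax((t_logits - center) / tt)  # (n, g, K)

            ls = _log_softmax(s_logits / st)  # (n, V, K)
            q = np.exp(ls)
            p_sum = p.sum(axis=1)  # (n, K)
            n_pairs = n * g * (V - 1)
            dlogits = np.empty_like(s_logits)
            loss = 0.0
            for j in range(V):
                target = p_sum - (p[:, j] if j < g else 0.0)
                count = g - (1 if j < g else 0)
                loss -= float((target * ls[:, j]).sum())
                dlogits[:, j] = (count * q[:, j] - target) / st
            loss /= n_pairs
            dlogits = dlogits.reshape(n * V, -1) / n_pairs
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite self-distillation loss at epoch {epoch}"
                )
            grads = student.backward(flat, h1, z, dlogits)
            opt.step(student.params, grads)
            teacher.ema_update(student, self.teacher_momentum)
            batch_mean = t_logits.reshape(n * g, -1).mean(axis=0)
            center = self.center_momentum * center + (1 - self.center_momentum) * batch_mean
            log.loss_per_epoch.append(loss)

            if monitor.is_check_epoch(epoch):
                embeddings = teacher.backbone(infer_X)
                table = ud_scores(embeddings, lesion_ids=lesion_ids)
                ranking = top_k(table, k=self.top_k_monitor)
                log.ranking_checks.append((epoch, ranking))
                if monitor.observe(epoch, ranking):
                    stop_epoch, stop_reason = epoch, "converged"
                    break

        log.stop_epoch, log.stop_reason = stop_epoch, stop_reason
        self.teacher_ = teacher
        self.student_ = student
        self.training_log_ = log
        self.stop_epoch_ = stop_epoch
        self.stop_reason_ = stop_reason
        self.lesion_ids_ = lesion_ids
        self.n_features_in_ = d_in
        return self

    def transform(self, X) -> np.ndarray:
        """Teacher-backbone embeddings (no augmentation, deterministic)."""
        if not hasattr(self, "teacher_"):
            raise RuntimeError("embedder is not fitted")
        pixel_list, _ = self._as_pixel_list(X)
        infer_X = self._inference_inputs(pixel_list)
        if infer_X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"input dimension {infer_X.shape[1]} does not match the fitted "
                f"dimension {self.n_features_in_}"
            )
        E = self.teacher_.backbone(infer_X)
        if not np.all(np.isfinite(E)):
            raise FloatingPointError("non-finite embedding values")
        return E


class HandcraftedFeatureEmbedder(BaseEstimator, TransformerMixin):
    """Deterministic lesion descriptor fulfilling the embedder contract.

    Per patch: lesion mask by thresholding at the midpoint between the
    frame-ring intensity and the darkest pixel, then mean lesion RGB, RGB
    spread, border contrast, area fraction, eccentricity and axis elongation
    of the largest component. ``fit`` records per-feature center and scale
    over the patient's lesions; ``transform`` emits robust z-scores plus a
    constant anchor coordinate. The anchor makes the coordinate-wise median
    embedding point along it, so cosine distance from the median grows
    monotonically with a lesion's normalized feature deviation — exactly the
    outlier geometry the scorer expects.

    Useful for training-free pipeline runs and as the downstream-testing
    stand-in for the trained embedder.
    """

    n_features_ = 8

    def __init__(self, frame_fraction: float = 0.1):
        self.frame_fraction = frame_fraction

    def _features(self, pixels: np.ndarray) -> np.ndarray:
        S = pixels.shape[0]
        fw = max(1, round(self.frame_fraction * S))
        ring = frame_ring_mask(S, S, fw)
        lum = luma(pixels)
        ring_mean = lum[ring].mean()
        thr = 0.5 * (ring_mean + lum.min())
        mask = lum < thr
        if mask.sum() < 4:  # nearly featureless patch: fall back to center disk
            yy, xx = np.mgrid[0:S, 0:S]
            mask = (yy - S / 2) ** 2 + (xx - S / 2) ** 2 < (S / 4) ** 2
        mean_rgb = pixels[mask].mean(axis=0)
        rgb_spread = float(pixels[mask].std())
        contrast = float(ring_mean - lum[mask].mean())
        area_frac = float(mask.mean())
        labels = measure.label(mask, connectivity=2)
        regions = measure.regionprops(labels)
        largest = max(regions, key=lambda r: r.area)
        ecc = float(largest.eccentricity)
        minor = max(largest.axis_minor_length, 1e-6)
        elongation = float(np.log(largest.axis_major_length / minor + 1e-12))
        return np.array(
            [*mean_rgb, rgb_spread, contrast, area_frac, ecc, elongation]
        )

    def fit(self, X, y=None):
        pixel_list, ids = SelfDistillationEmbedder._as_pixel_list(X)
        if len(pixel_list) < 2:
            raise ValueError("need at least 2 patches")
        F = np.asarray([self._features(p) for p in pixel_list])
        self.center_ = np.median(F, axis=0)
        # floor the scale so near-constant features cannot amplify pixel noise
        self.scale_ = np.maximum(F.std(axis=0), 1e-2)
        self.lesion_ids_ = ids
        self.n_features_in_ = F.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "scale_"):
            raise RuntimeError("embedder is not fitted")
        pixel_list, _ = SelfDistillationEmbedder._as_pixel_list(X)
        F = np.asarray([self._features(p) for p in pixel_list])
        Z = (F - self.center_) / self.scale_
        anchor = np.full((Z.shape[0], 1), np.sqrt(Z.shape[1]))
        return np.hstack([Z, anchor])
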