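"""Trainable patch classifier: augmentation, losses, SGD training, inference.

The classifier contract is pluggable: anything exposing ``predict_proba``
and ``train_batch`` over RGB patch images can be trained by
:func:`train_patch_classifier`.  The desk-scale default,
:class:`MLPPatchClassifier`, is a small fully-connected network on
block-averaged pixels, trained with plain SGD (momentum 0.9, weight decay
5e-4), a learning rate halved every 2 epochs, and early stopping on
validation accuracy — the same optimisation recipe used for large
backbones, at a size that trains in seconds on one CPU.

Losses: cross-entropy for balanced patch sets, focal loss
``-alpha_t (1 - p_t)**gamma * log(p_t)`` for imbalanced sets, which
down-weights easy examples and focuses learning on hard, misclassified
ones.  ``gamma=0, alpha=1`` recovers cross-entropy exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .categories import CATEGORIES, Category
from .slide_io import SlidePyramid

__all__ = [
    "AugmentParams",
    "LossConfig",
    "TrainingConfig",
    "augment",
    "apply_augment",
    "normalize_image",
    "focal_loss",
    "cross_entropy_loss",
    "MLPPatchClassifier",
    "PatchEnsemble",
    "PatchDataset",
    "load_patch_folder",
    "train_patch_classifier",
    "infer_patches",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12
_GRAY = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AugmentParams:
    """Training-time augmentation: right-angle rotation plus colour jitter.

    Jitter factors are drawn uniformly from ``[max(0, 1 - r), 1 + r]`` for
    brightness/contrast/saturation half-range ``r`` and ``[-r, +r]`` for
    hue; the output is normalized per channel to ``[-1, 1]``.
    """

    brightness: float = 0.25
    contrast: float = 0.75
    saturation: float = 0.25
    hue: float = 0.04
    norm_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    norm_sd: tuple[float, float, float] = (0.5, 0.5, 0.5)


def normalize_image(img: np.ndarray, params: AugmentParams = AugmentParams()) -> np.ndarray:
    """Map an RGB image in [0, 1] to the normalized training range [-1, 1]."""
    img = np.asarray(img, dtype=np.float64)
    return (img - np.asarray(params.norm_mean)) / np.asarray(params.norm_sd)


def _adjust_hue(img: np.ndarray, shift: float) -> np.ndarray:
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(img)
    hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
    return hsv2rgb(hsv)


def apply_augment(
    img: np.ndarray,
    k_rot: int,
    brightness: float,
    contrast: float,
    saturation: float,
    hue_shift: float,
    params: AugmentParams = AugmentParams(),
) -> np.ndarray:
    """Deterministic core of :func:`augment` with explicit draws.

    With ``k_rot=0`` and unit factors only normalization is applied.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("augment expects an RGB image in [0, 1]")
    out = np.rot90(img, k=k_rot)
    if brightness != 1.0:
        out = np.clip(out * brightness, 0.0, 1.0)
    if contrast != 1.0:
        mean_gray = (out @ _GRAY).mean()
        out = np.clip(contrast * out + (1.0 - contrast) * mean_gray, 0.0, 1.0)
    if saturation != 1.0:
        gray = (out @ _GRAY)[..., None]
        out = np.clip(saturation * out + (1.0 - saturation) * gray, 0.0, 1.0)
    if hue_shift != 0.0:
        out = np.clip(_adjust_hue(out, hue_shift), 0.0, 1.0)
    return normalize_image(out, params)


def augment(
    img: np.ndarray,
    params: AugmentParams = AugmentParams(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random rotation + colour jitter + normalization of one RGB patch."""
    rng = rng or np.random.default_rng()
    k = int(rng.integers(0, 4))
    b = rng.uniform(max(0.0, 1 - params.brightness), 1 + params.brightness)
    c = rng.uniform(max(0.0, 1 - params.contrast), 1 + params.contrast)
    s = rng.uniform(max(0.0, 1 - params.saturation), 1 + params.saturation)
    h = rng.uniform(-params.hue, params.hue)
    return apply_augment(img, k, b, c, s, h, params)


# ---------------------------------------------------------------------------
# Losses


@dataclass(frozen=True)
class LossConfig:
    """Loss selection: ``cross_entropy`` or ``focal`` with gamma and alpha.

    ``alpha`` is a per-class weight vector (``None`` means uniform 1).
    """

    kind: str = "cross_entropy"
    gamma: float = 2.0
    alpha: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.alpha is not None and any(a < 0 for a in self.alpha):
            raise ValueError("alpha weights must be >= 0")


def _alpha_for(targets: np.ndarray, alpha, n_classes: int) -> np.ndarray:
    if alpha is None:
        return np.ones(len(targets))
    a = np.asarray(alpha, dtype=float)
    if a.ndim == 0:
        return np.full(len(targets), float(a))
    if len(a) != n_classes:
        raise ValueError("alpha length must equal the number of classes")
    return a[targets]


def focal_loss(
    probs: np.ndarray, targets: np.ndarray, gamma: float = 2.0, alpha=None
) -> float:
    """Batch-averaged focal loss ``-alpha_t (1 - p_t)**gamma log(p_t)``."""
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=int)
    p_t = probs[np.arange(len(targets)), targets]
    if (p_t <= 0).any():
        logger.warning("clamping %d zero probabilities in focal loss", int((p_t <= 0).sum()))
    p_t = np.clip(p_t, _EPS, 1.0)
    a_t = _alpha_for(targets, alpha, probs.shape[1])
    return float(np.mean(-a_t * (1.0 - p_t) ** gamma * np.log(p_t)))


def cross_entropy_loss(probs: np.ndarray, targets: np.ndarray, alpha=None) -> float:
    return focal_loss(probs, targets, gamma=0.0, alpha=alpha)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_dlogits(
    logits: np.ndarray, targets: np.ndarray, cfg: LossConfig
) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. logits for CE or focal loss."""
    n, k = logits.shape
    p = _softmax(logits)
    gamma = cfg.gamma if cfg.kind == "focal" else 0.0
    a_t = _alpha_for(targets, cfg.alpha, k)
    idx = np.arange(n)
    p_t = np.clip(p[idx, targets], _EPS, 1.0 - _EPS)
    loss = float(np.mean(-a_t * (1.0 - p_t) ** gamma * np.log(p_t)))

    onehot = np.zeros_like(p)
    onehot[idx, targets] = 1.0
    if gamma == 0.0:
        coef = -np.ones(n)
    else:
        # d/dz of -a (1-p_t)^g log p_t, via dp_t/dz_j = p_t (delta - p_j)
        coef = (1.0 - p_t) ** (gamma - 1.0) * (
            gamma * p_t * np.log(p_t) - (1.0 - p_t)
        )
    dlogits = (a_t * coef)[:, None] * (onehot - p) / n
    return loss, dlogits


# ---------------------------------------------------------------------------
# Training configuration


@dataclass(frozen=True)
class TrainingConfig:
    """SGD hyperparameters and the early-stopping policy."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0005
    lr_step_epochs: int = 2
    lr_factor: float = 0.5
    max_epochs: int = 20
    patience: int = 10
    batch_size: int = 64
    #: global gradient-norm clip; small final batches under heavy
    #: augmentation otherwise produce destabilizing updates
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "momentum", "weight_decay", "lr_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for ``epoch`` (0-based) under the halving schedule."""
        return self.learning_rate * self.lr_factor ** (epoch // self.lr_step_epochs)


# ---------------------------------------------------------------------------
# Default model


class MLPPatchClassifier:
    """Small fully-connected classifier over block colour and nucleus density.

    Input images are normalized RGB arrays in [-1, 1].  The front end
    average-pools the image by ``pool`` into a block grid and describes
    each block by its mean RGB plus the fraction of pixels darker than a
    set of thresholds relative to the patch's mean luminance — a proxy for
    nucleus density that is invariant to overall brightness changes (the
    strongest augmentation axis and the dominant stain-shift direction).
    Features are standardized with training-set statistics
    (:meth:`set_feature_stats`); layers are ReLU-activated and the final
    layer emits one logit per category.
    """

    #: dark-pixel thresholds as fractions of the patch mean luminance
    DARK_LEVELS = (0.6, 0.75, 0.9)
    #: global per-patch summaries: mean RGB, mean log R/G and B/G
    #: chromaticity, mean saturation, and one dark fraction per level
    N_GLOBAL = 6 + len(DARK_LEVELS)

    def __init__(
        self,
        n_classes: int = 4,
        input_size: int = 64,
        pool: int = 8,
        hidden: tuple[int, ...] = (64,),
        seed: int = 0,
    ):
        if input_size % pool:
            raise ValueError("input_size must be divisible by pool")
        self.n_classes = n_classes
        self.input_size = input_size
        self.pool = pool
        self.hidden = tuple(hidden)
        side = input_size // pool
        dims = [
            side * side * (3 + len(self.DARK_LEVELS)) + self.N_GLOBAL,
            *hidden,
            n_classes,
        ]
        rng = np.random.default_rng(seed)
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(d) for d in dims[1:]]
        self._vel_w = [np.zeros_like(w) for w in self.weights]
        self._vel_b = [np.zeros_like(b) for b in self.biases]
        self._feat_mu: np.ndarray | None = None
        self._feat_sd: np.ndarray | None = None
        #: softmax temperature; focal-loss training systematically
        #: under-sharpens probabilities, so the trainer calibrates this on
        #: the validation set after model selection
        self.temperature: float = 1.0

    # -- feature extraction

    def _features(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        n, h, w, _ = x.shape
        if (h, w) != (self.input_size, self.input_size):
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} patches, got {h}x{w}"
            )
        p = self.pool
        # pixel values back on the [0, 1] scale for photometric statistics
        x01 = np.clip((x + 1.0) / 2.0, 1e-3, 1.0)
        lum = x01 @ _GRAY
        mean_lum = lum.mean(axis=(1, 2), keepdims=True)
        parts = [x.reshape(n, h // p, p, w // p, p, 3).mean(axis=(2, 4)).reshape(n, -1)]
        dark_fracs = []
        for level in self.DARK_LEVELS:
            dark = (lum < level * mean_lum).astype(np.float64)
            parts.append(
                dark.reshape(n, h // p, p, w // p, p).mean(axis=(2, 4)).reshape(n, -1)
            )
            dark_fracs.append(dark.mean(axis=(1, 2)))
        # global summaries: high signal-to-noise statistics of the whole
        # patch; log-chromaticity and relative dark fractions are invariant
        # to the multiplicative brightness jitter and to lab stain scaling
        mx = x01.max(axis=3)
        mn = x01.min(axis=3)
        saturation = ((mx - mn) / mx).mean(axis=(1, 2))
        log_rg = np.log(x01[..., 0] / x01[..., 1]).mean(axis=(1, 2))
        log_bg = np.log(x01[..., 2] / x01[..., 1]).mean(axis=(1, 2))
        global_part = np.column_stack(
            [x01.mean(axis=(1, 2)).reshape(n, 3), log_rg, log_bg, saturation]
            + dark_fracs
        )
        parts.append(global_part)
        feats = np.concatenate(parts, axis=1)
        if self._feat_mu is not None:
            feats = (feats - self._feat_mu) / self._feat_sd
        return feats

    def set_feature_stats(self, images: np.ndarray) -> None:
        """Fit the feature standardization to a (training) image batch."""
        self._feat_mu = None
        feats = self._features(images)
        self._feat_mu = feats.mean(axis=0)
        # all features are O(1); flooring the spread keeps constant-in-train
        # features (e.g. a dark fraction that never fires) from being
        # amplified into training instability
        self._feat_sd = np.maximum(feats.std(axis=0), 0.05)

    def calibrate(self, valid_images: np.ndarray, valid_labels: np.ndarray) -> None:
        """Fit the softmax temperature on held-out data (minimum NLL)."""
        self.temperature = 1.0
        self.temperature = _fit_temperature(
            self.predict_logits(valid_images), valid_labels
        )

    def _forward(self, feats: np.ndarray):
        acts = [feats]
        z = feats
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ w + b
            if i < len(self.weights) - 1:
                z = np.maximum(z, 0.0)
            acts.append(z)
        return acts

    # -- public contract

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        return self._forward(self._features(images))[-1]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Softmax category probabilities, deterministic in evaluation."""
        return _softmax(self.predict_logits(images) / self.temperature)

    def train_batch(
        self,
        images: np.ndarray,
        targets: np.ndarray,
        loss_cfg: LossConfig,
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
        grad_clip: float | None = 1.0,
    ) -> float:
        """One SGD-with-momentum step on a batch; returns the batch loss.

        Gradients are clipped to a global norm of ``grad_clip`` before the
        momentum update.
        """
        feats = self._features(images)
        acts = self._forward(feats)
        targets = np.asarray(targets, dtype=int)
        loss, grad = _loss_and_dlogits(acts[-1], targets, loss_cfg)

        grads_w, grads_b = [], []
        for i in reversed(range(len(self.weights))):
            grads_w.append(acts[i].T @ grad + weight_decay * self.weights[i])
            grads_b.append(grad.sum(axis=0))
            if i > 0:
                grad = (grad @ self.weights[i].T) * (acts[i] > 0)
        grads_w.reverse()
        grads_b.reverse()

        if grad_clip is not None:
            norm = math.sqrt(
                sum(float((g**2).sum()) for g in grads_w)
                + sum(float((g**2).sum()) for g in grads_b)
            )
            if norm > grad_clip:
                scale = grad_clip / norm
                grads_w = [g * scale for g in grads_w]
                grads_b = [g * scale for g in grads_b]

        for i in range(len(self.weights)):
            self._vel_w[i] = momentum * self._vel_w[i] - lr * grads_w[i]
            self._vel_b[i] = momentum * self._vel_b[i] - lr * grads_b[i]
            self.weights[i] += self._vel_w[i]
            self.biases[i] += self._vel_b[i]
        return loss

    def state_dict(self) -> dict:
        return {
            "weights": [w.copy() for w in self.weights],
            "biases": [b.copy() for b in self.biases],
        }

    def load_state_dict(self, state: dict) -> None:
        self.weights = [w.copy() for w in state["weights"]]
        self.biases = [b.copy() for b in state["biases"]]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        if self._feat_mu is not None:
            arrays["feat_mu"] = self._feat_mu
            arrays["feat_sd"] = self._feat_sd
        np.savez(
            path,
            meta=np.array(
                [self.n_classes, self.input_size, self.pool, *self.hidden], dtype=int
            ),
            temperature=np.array([self.temperature]),
            **arrays,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MLPPatchClassifier":
        data = np.load(path)
        meta = data["meta"]
        model = cls(
            n_classes=int(meta[0]),
            input_size=int(meta[1]),
            pool=int(meta[2]),
            hidden=tuple(int(v) for v in meta[3:]),
        )
        n_layers = len(model.weights)
        model.load_state_dict(
            {
                "weights": [data[f"w{i}"] for i in range(n_layers)],
                "biases": [data[f"b{i}"] for i in range(n_layers)],
            }
        )
        if "feat_mu" in data:
            model._feat_mu = data["feat_mu"]
            model._feat_sd = data["feat_sd"]
        if "temperature" in data:
            model.temperature = float(data["temperature"][0])
        return model


class PatchEnsemble:
    """Committee of independently initialized patch classifiers.

    Members are trained on identical batches but from different random
    initializations; predictions average the members' calibrated
    probabilities.  At the few-hundred-patch training sizes of desk-scale
    cohorts a single small network is high-variance — one unlucky
    initialization can collapse an entire category's heatmap — and the
    committee average is the standard remedy.
    """

    DEFAULT_MEMBERS = 9

    def __init__(self, members: list):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = list(members)
        self.n_classes = members[0].n_classes

    @classmethod
    def default(
        cls,
        input_size: int = 64,
        seed: int = 0,
        n_members: int | None = None,
        **kwargs,
    ) -> "PatchEnsemble":
        n = n_members or cls.DEFAULT_MEMBERS
        return cls(
            [
                MLPPatchClassifier(
                    input_size=input_size, seed=seed * 1000 + k, **kwargs
                )
                for k in range(n)
            ]
        )

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(images) for m in self.members], axis=0)

    def train_batch(
        self, images, targets, loss_cfg, lr, momentum=0.9, weight_decay=0.0,
        grad_clip=1.0,
    ):
        return float(
            np.mean(
                [
                    m.train_batch(
                        images, targets, loss_cfg, lr, momentum, weight_decay, grad_clip
                    )
                    for m in self.members
                ]
            )
        )

    def set_feature_stats(self, images: np.ndarray) -> None:
        for m in self.members:
            m.set_feature_stats(images)

    def calibrate(self, valid_images: np.ndarray, valid_labels: np.ndarray) -> None:
        for m in self.members:
            m.calibrate(valid_images, valid_labels)

    def state_dict(self) -> dict:
        return {"members": [m.state_dict() for m in self.members]}

    def load_state_dict(self, state: dict) -> None:
        for m, ms in zip(self.members, state["members"]):
            m.load_state_dict(ms)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {"n_members": np.array([len(self.members)])}
        for k, m in enumerate(self.members):
            arrays[f"m{k}_meta"] = np.array(
                [m.n_classes, m.input_size, m.pool, *m.hidden], dtype=int
            )
            arrays[f"m{k}_temp"] = np.array([m.temperature])
            for i, (w, b) in enumerate(zip(m.weights, m.biases)):
                arrays[f"m{k}_w{i}"] = w
                arrays[f"m{k}_b{i}"] = b
            if m._feat_mu is not None:
                arrays[f"m{k}_feat_mu"] = m._feat_mu
                arrays[f"m{k}_feat_sd"] = m._feat_sd
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PatchEnsemble":
        data = np.load(path)
        members = []
        for k in range(int(data["n_members"][0])):
            meta = data[f"m{k}_meta"]
            m = MLPPatchClassifier(
                n_classes=int(meta[0]),
                input_size=int(meta[1]),
                pool=int(meta[2]),
                hidden=tuple(int(v) for v in meta[3:]),
            )
            m.load_state_dict(
                {
                    "weights": [data[f"m{k}_w{i}"] for i in range(len(m.weights))],
                    "biases": [data[f"m{k}_b{i}"] for i in range(len(m.biases))],
                }
            )
            m.temperature = float(data[f"m{k}_temp"][0])
            if f"m{k}_feat_mu" in data:
                m._feat_mu = data[f"m{k}_feat_mu"]
                m._feat_sd = data[f"m{k}_feat_sd"]
            members.append(m)
        return cls(members)


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class PatchDataset:
    """In-memory patch set: raw RGB uint8 images plus integer labels."""

    images: np.ndarray  # (N, H, W, 3) uint8
    labels: np.ndarray  # (N,) int, severity-rank encoding

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels lengths differ")

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self, n_classes: int = 4) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)

    @property
    def is_balanced(self) -> bool:
        counts = self.class_counts()
        present = counts[counts > 0]
        return len(present) > 0 and (present == present[0]).all()


def load_patch_folder(root: str | Path) -> PatchDataset:
    """Load a patch dataset from category-named PNG folders."""
    root = Path(root)
    images, labels = [], []
    for rank, cat in enumerate(CATEGORIES):
        folder = root / cat.value
        if not folder.is_dir():
            continue
        for f in sorted(folder.glob("*.png")):
            images.append(np.asarray(Image.open(f).convert("RGB")))
            labels.append(rank)
    if not images:
        raise ValueError(f"no patches found under {root}")
    return PatchDataset(np.stack(images), np.asarray(labels, dtype=int))


def collect_patch_dataset(
    slides: dict[str, SlidePyramid], sampled: pd.DataFrame, patch_size: int
) -> PatchDataset:
    """Read sampled patch pixels from their slides into memory."""
    images = np.empty((len(sampled), patch_size, patch_size, 3), dtype=np.uint8)
    labels = np.empty(len(sampled), dtype=int)
    for i, row in enumerate(sampled.itertuples()):
        slide = slides[row.slide_id]
        images[i] = slide.read_region(
            0, (int(row.x0), int(row.y0)), (patch_size, patch_size)
        )
        labels[i] = Category.parse(row.label).severity_rank
    return PatchDataset(images, labels)


# ---------------------------------------------------------------------------
# Training and inference


def default_loss_for(dataset: PatchDataset) -> LossConfig:
    """Cross-entropy for balanced patch sets, focal loss otherwise.

    Focal alpha defaults to the normalized inverse class frequency of the
    training set.
    """
    if dataset.is_balanced:
        return LossConfig(kind="cross_entropy")
    counts = dataset.class_counts().astype(float)
    inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0)
    alpha = inv / inv.sum() * (inv > 0).sum()
    return LossConfig(kind="focal", gamma=2.0, alpha=tuple(alpha))


def train_patch_classifier(
    train_set: PatchDataset | str | Path,
    valid_set: PatchDataset | str | Path,
    model_factory=None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainingConfig = TrainingConfig(),
    augment_params: AugmentParams = AugmentParams(),
):
    """Train a patch classifier and return ``(best_model, history)``.

    The learning rate is halved every ``lr_step_epochs``; training stops
    when validation accuracy has not improved for ``patience`` epochs, and
    the checkpoint with the highest validation accuracy is returned.
    ``history`` is one record per completed epoch (lr, loss, val accuracy).
    """
    if not isinstance(train_set, PatchDataset):
        train_set = load_patch_folder(train_set)
    if not isinstance(valid_set, PatchDataset):
        valid_set = load_patch_folder(valid_set)
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if loss_cfg is None:
        loss_cfg = default_loss_for(train_set)
    size = train_set.images.shape[1]
    if model_factory is None:
        model = PatchEnsemble.default(input_size=size, seed=train_cfg.seed)
    else:
        model = model_factory()
    if hasattr(model, "set_feature_stats"):
        model.set_feature_stats(
            normalize_image(train_set.images / 255.0, augment_params)
        )
    probe = model.predict_proba(normalize_image(train_set.images[:1] / 255.0, augment_params))
    if probe.shape[1] != 4:
        raise ValueError(f"model emits {probe.shape[1]} classes, expected 4")

    rng = np.random.default_rng(train_cfg.seed)
    valid_images = normalize_image(valid_set.images / 255.0, augment_params)

    history: list[dict] = []
    best_acc, best_epoch, best_state = -1.0, -1, model.state_dict()
    for epoch in range(train_cfg.max_epochs):
        lr = train_cfg.lr_at(epoch)
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            batch = np.stack(
                [
                    augment(train_set.images[i] / 255.0, augment_params, rng)
                    for i in idx
                ]
            )
            losses.append(
                model.train_batch(
                    batch,
                    train_set.labels[idx],
                    loss_cfg,
                    lr,
                    momentum=train_cfg.momentum,
                    weight_decay=train_cfg.weight_decay,
                    grad_clip=train_cfg.grad_clip,
                )
            )
        pred = model.predict_proba(valid_images).argmax(axis=1)
        val_acc = float((pred == valid_set.labels).mean()) if len(valid_set) else 0.0
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)),
                "val_accuracy": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()
        if epoch - best_epoch >= train_cfg.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    model.load_state_dict(best_state)
    if hasattr(model, "calibrate") and len(valid_set):
        model.calibrate(valid_images, valid_set.labels)
    return model, history


def _fit_temperature(logits: np.ndarray, targets: np.ndarray) -> float:
    """Softmax temperature minimizing validation NLL (grid + refinement).

    Focal-loss training yields under-confident probabilities; temperature
    scaling is the standard post-hoc calibration and preserves the argmax.
    """
    targets = np.asarray(targets, dtype=int)

    def nll(t: float) -> float:
        p = _softmax(logits / t)
        return float(-np.mean(np.log(np.clip(p[np.arange(len(targets)), targets], _EPS, 1.0))))

    grid = np.geomspace(0.05, 5.0, 60)
    best = min(grid, key=nll)
    # local refinement around the best grid point
    lo, hi = best / 1.3, best * 1.3
    fine = np.geomspace(lo, hi, 40)
    return float(min(fine, key=nll))


PROB_COLUMNS = tuple(f"p_{c.value}" for c in CATEGORIES)


def infer_patches(
    model,
    slide: SlidePyramid,
    patch_table: pd.DataFrame,
    patch_size: int,
    augment_params: AugmentParams = AugmentParams(),
    batch_size: int = 256,
) -> pd.DataFrame:
    """Predict category probabilities for every tissue patch of one slide.

    Returns the tissue rows of ``patch_table`` with probability columns
    appended (one per category, summing to 1 per patch).
    """
    tissue = patch_table[patch_table["is_tissue"]].reset_index(drop=True)
    probs = np.empty((len(tissue), len(CATEGORIES)))
    for start in range(0, len(tissue), batch_size):
        chunk = tissue.iloc[start : start + batch_size]
        images = np.stack(
            [
                slide.read_region(0, (int(r.x0), int(r.y0)), (patch_size, patch_size))
                for r in chunk.itertuples()
            ]
        ) if len(chunk) else np.empty((0, patch_size, patch_size, 3))
        if len(chunk):
            probs[start : start + len(chunk)] = model.predict_proba(
                normalize_image(images / 255.0, augment_params)
            )
    out = tissue.copy()
    for j, col in enumerate(PROB_COLUMNS):
        out[col] = probs[:, j] if len(tissue) else np.empty(0)
    return out
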