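"""Supervised training: composite Dice + cross-entropy loss, k-fold
construction, Adam optimization and the epoch loop.

The loss is a convex combination

    L = a * (1 - softDice(p, y)) + (1 - a) * CE(p, y)

where the soft Dice similarity per foreground class is
(2 Σ p·y + s) / (Σ p + Σ y + s), averaged over the four organ classes, and
CE is the categorical cross-entropy of the 5-way softmax. The Dice term as
a similarity cannot be minimized directly, so training descends 1 − Dice.
The weight ``a`` defaults to 0.5.

Loss operands put the class axis first: shape (5, ...) with everything
else treated as voxels. Batches are folded into the voxel axes (batch
Dice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .core import (
    ContractError,
    ConfigurationError,
    LabelMap,
    N_CLASSES,
    ORGAN_CLASSES,
    TrainingDivergedError,
    Volume,
)
from .network import NetworkConfig, UNet, build_unet, save_checkpoint, softmax
from .preprocess import augment, extract_patch

_CE_EPS = 1e-7


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class LossConfig:
    """Composite-loss weights: ``a`` is the Dice share, in [0, 1]."""

    a: float = 0.5
    smooth: float = 1e-5
    class_weights: Optional[Sequence[float]] = None

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ConfigurationError(f"a must lie in [0, 1], got {self.a}")
        if self.smooth <= 0:
            raise ConfigurationError("smooth must be > 0")
        if self.class_weights is not None:
            self.class_weights = tuple(float(w) for w in self.class_weights)
            if len(self.class_weights) != N_CLASSES:
                raise ConfigurationError("class_weights must have 5 entries")


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The reference settings for full-scale runs are 250 epochs, initial
    learning rate 0.01 and Adam; the defaults here are CPU desk-scale.
    ``lr_schedule`` is "poly" (lr0 * (1 - epoch/epochs)^0.9) or "constant".
    """

    epochs: int = 10
    learning_rate: float = 0.01
    optimizer: str = "adam"
    optimizer_params: Dict[str, float] = field(
        default_factory=lambda: {"beta1": 0.9, "beta2": 0.999, "eps": 1e-8})
    batch_size: int = 4
    patch_size: Tuple[int, int, int] = (1, 64, 64)
    target_spacing: Optional[Tuple[float, float, float]] = None
    seed: int = 0
    lr_schedule: str = "poly"
    poly_power: float = 0.9
    #: batches per epoch; None = one pass over all training slices/patches
    steps_per_epoch: Optional[int] = None
    foreground_fraction: float = 0.33
    rotation_deg: float = 15.0
    jitter_vox: int = 2

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.lr_schedule not in ("poly", "constant"):
            raise ConfigurationError("lr_schedule must be 'poly' or 'constant'")
        self.patch_size = tuple(int(s) for s in self.patch_size)


@dataclass
class OneHotTarget:
    """One-hot encoded labels, class axis first; exactly one 1 per voxel."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape[0] != N_CLASSES:
            raise ContractError("OneHotTarget must have 5 leading channels")
        s = self.data.sum(axis=0)
        if self.data.size and (s.min() != 1 or s.max() != 1):
            raise ContractError("each voxel must have exactly one active class")


def one_hot(labels: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    """Encode integer labels (any shape) as (n_classes, *shape) floats."""
    labels = np.asarray(labels)
    out = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = labels == c
    return out


def _arr(x):
    return x.data if isinstance(x, OneHotTarget) else np.asarray(x)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def soft_dice(probs, target, smooth: float = 1e-5) -> float:
    """Soft Dice similarity, mean over the four foreground classes.

    Per class: (2 Σ p·y + s) / (Σ p + Σ y + s). Equals 1 for a perfect
    one-hot prediction as s → 0; a class absent from both operands
    contributes 1 (s/s).
    """
    p, y = np.asarray(probs, dtype=np.float64), _arr(target).astype(np.float64)
    if p.shape != y.shape:
        raise ContractError(f"shape mismatch: {p.shape} vs {y.shape}")
    return float(np.mean([_dice_class(p[c], y[c], smooth) for c in ORGAN_CLASSES]))


def soft_dice_per_class(probs, target, smooth: float = 1e-5) -> Dict[int, float]:
    p, y = np.asarray(probs, dtype=np.float64), _arr(target).astype(np.float64)
    return {c: _dice_class(p[c], y[c], smooth) for c in ORGAN_CLASSES}


def _dice_class(p, y, smooth):
    num = 2.0 * float((p * y).sum()) + smooth
    den = float(p.sum()) + float(y.sum()) + smooth
    return num / den


def cross_entropy(probs, target, class_weights=None) -> float:
    """Categorical cross-entropy, mean over voxels.

    −(1/n) Σ_voxels w_y ln p_y with probabilities clipped at 1e-7. Zero (up
    to the clipping) iff the prediction equals the target exactly.
    """
    p, y = np.asarray(probs, dtype=np.float64), _arr(target).astype(np.float64)
    if p.shape != y.shape:
        raise ContractError(f"shape mismatch: {p.shape} vs {y.shape}")
    p = np.clip(p, _CE_EPS, 1.0)
    n = p[0].size
    w = np.ones(N_CLASSES) if class_weights is None else np.asarray(class_weights,
                                                                    dtype=np.float64)
    per_vox = -(w.reshape((N_CLASSES,) + (1,) * (p.ndim - 1)) * y * np.log(p)).sum(axis=0)
    val = float(per_vox.sum() / n)
    if not np.isfinite(val):
        raise TrainingDivergedError("cross-entropy is not finite")
    return val


def bernoulli_cross_entropy(probs, target) -> float:
    """Channel-wise Bernoulli form −(1/n) Σ [y ln p + (1−y) ln(1−p)].

    Provided for the two-class limit, where it coincides with the
    categorical form up to a factor of two (each voxel is counted from both
    channels); the categorical form is what training uses.
    """
    p, y = np.asarray(probs, dtype=np.float64), _arr(target).astype(np.float64)
    p = np.clip(p, _CE_EPS, 1.0 - _CE_EPS)
    n = p[0].size
    val = -float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum() / n)
    return val


def composite_loss(probs, target, config: LossConfig = LossConfig()) -> float:
    """a·(1 − softDice) + (1 − a)·crossEntropy; minimized by the target."""
    d = 1.0 - soft_dice(probs, target, config.smooth)
    ce = cross_entropy(probs, target, config.class_weights)
    return config.a * d + (1.0 - config.a) * ce


def composite_loss_and_logit_grad(logits: np.ndarray, target: np.ndarray,
                                  config: LossConfig) -> Tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the logits, class axis first.

    Both loss terms are differentiated w.r.t. the softmax probabilities and
    chained through the softmax Jacobian in one pass.
    """
    y = _arr(target).astype(np.float64)
    p = softmax(logits, axis=0).astype(np.float64)
    n = p[0].size

    loss = composite_loss(p, y, config)

    g = np.zeros_like(p)
    if config.a > 0:
        s = config.smooth
        for c in ORGAN_CLASSES:
            num = 2.0 * (p[c] * y[c]).sum() + s
            den = p[c].sum() + y[c].sum() + s
            # d(1 - meanDice)/dp_c = -(1/4) * (2 y den - num) / den^2
            g[c] += -config.a * (2.0 * y[c] * den - num) / (4.0 * den * den)
    if config.a < 1:
        w = (np.ones(N_CLASSES) if config.class_weights is None
             else np.asarray(config.class_weights, dtype=np.float64))
        wv = w.reshape((N_CLASSES,) + (1,) * (p.ndim - 1))
        g += -(1.0 - config.a) * wv * y / (np.maximum(p, 1e-12) * n)

    dz = p * (g - (p * g).sum(axis=0, keepdims=True))
    return loss, dz.astype(np.float32)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """Partition of labeled cases into k folds of near-equal size."""

    k: int
    assignment: Dict[str, int]
    seed: int

    def fold_cases(self, fold: int) -> List[str]:
        return [c for c, f in self.assignment.items() if f == fold]

    def train_val(self, fold: int) -> Tuple[List[str], List[str]]:
        val = self.fold_cases(fold)
        train = [c for c, f in self.assignment.items() if f != fold]
        return train, val


def make_folds(case_ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldSplit:
    """Random permutation then round-robin assignment into k folds.

    Fold sizes differ by at most one; deterministic under the seed.
    """
    ids = list(case_ids)
    if len(ids) < k:
        raise ContractError(f"need at least k={k} cases, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ContractError("case ids must be unique")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    perm = rng.permutation(len(ids))
    assignment = {ids[int(pi)]: i % k for i, pi in enumerate(perm)}
    return FoldSplit(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)).astype(
                np.float32)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: UNet
    history: pd.DataFrame
    best_epoch: int
    checkpoint_path: Optional[str] = None


def _batch(cases, cfg: TrainConfig, dims: int, rng) -> Tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for _ in range(cfg.batch_size):
        vol, lab = cases[int(rng.integers(len(cases)))]
        pair = extract_patch(vol, lab, cfg.patch_size, rng,
                             foreground_fraction=cfg.foreground_fraction)
        pair = augment(pair, rng, rotation_deg=cfg.rotation_deg,
                       jitter_vox=cfg.jitter_vox)
        img, lbl = pair.image_patch, pair.label_patch
        if dims == 2:
            img, lbl = img[0], lbl[0]  # patch z-extent is 1 for 2D nets
        xs.append(img[None])  # channel axis
        ys.append(one_hot(lbl))
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


def _validation_dsc(model: UNet, val_cases) -> float:
    from .metrics import dsc  # deferred: metrics is downstream in the pipeline
    from .network import predict_probabilities
    from .selfannotate import labels_from_probabilities

    scores = []
    for vol, lab in val_cases:
        pred = labels_from_probabilities(predict_probabilities(model, vol))
        for c in ORGAN_CLASSES:
            if np.any(lab.data == c):
                scores.append(dsc(pred.data == c, lab.data == c))
    return float(np.mean(scores)) if scores else float("nan")


def train_model(
    train_cases: Sequence[Tuple[Volume, LabelMap]],
    val_cases: Sequence[Tuple[Volume, LabelMap]],
    net_config: NetworkConfig,
    train_config: TrainConfig,
    loss_config: LossConfig = LossConfig(),
    checkpoint_path=None,
) -> TrainResult:
    """Run the supervised training loop on preprocessed cases.

    Cases are (volume, labels) pairs already resampled and z-score
    normalized. Each epoch samples ``steps_per_epoch`` augmented patch
    batches (by default sized to one pass over the training data, so larger
    training sets receive proportionally more optimization), descends the composite loss with Adam, and (if ``val_cases``
    is nonempty) scores mean validation DSC by full-volume inference; the
    best-validation weights are restored at the end (without validation the
    final weights are kept). Fixed seeds reproduce the loss history
    bit-for-bit on CPU.
    """
    if len(train_cases) < 1:
        raise ContractError("need at least one training case")
    dims = net_config.dims
    if dims == 2 and train_config.patch_size[0] != 1:
        raise ConfigurationError("2D networks require patch z-extent 1")
    model = build_unet(net_config, seed=train_config.seed)
    spatial = train_config.patch_size[3 - dims:]
    model.validate_input_shape(spatial)

    rng = np.random.default_rng(int(train_config.seed) & 0x7FFFFFFF)
    opt = Adam(model.parameters(), **train_config.optimizer_params)

    steps = train_config.steps_per_epoch
    if steps is None:
        # one pass over the training data per epoch: for 2D nets a sample is
        # a slice, for 3D nets a patch-sized chunk of each volume
        if dims == 2:
            n_samples = sum(v.shape[0] for v, _ in train_cases)
        else:
            n_samples = sum(
                max(1, int(np.prod(np.ceil(np.array(v.shape)
                                           / train_config.patch_size))))
                for v, _ in train_cases)
        steps = max(1, int(np.ceil(n_samples / train_config.batch_size)))

    rows = []
    best_dsc, best_epoch, best_state = -np.inf, -1, None
    for epoch in range(train_config.epochs):
        if train_config.lr_schedule == "poly":
            lr = train_config.learning_rate * (
                1.0 - epoch / train_config.epochs) ** train_config.poly_power
        else:
            lr = train_config.learning_rate
        losses = []
        for _ in range(steps):
            x, y = _batch(train_cases, train_config, dims, rng)
            logits = model.forward(x)
            # class axis first for the loss: (N, C, *sp) -> (C, N, *sp)
            loss, dz = composite_loss_and_logit_grad(
                np.moveaxis(logits, 1, 0), np.moveaxis(y, 1, 0), loss_config)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}")
            model.zero_grad()
            model.backward(np.ascontiguousarray(np.moveaxis(dz, 0, 1)))
            opt.step(lr)
            losses.append(loss)
        val_dsc = _validation_dsc(model, val_cases) if len(val_cases) else np.nan
        record = {"epoch": epoch, "lr": lr,
                  "train_loss": float(np.mean(losses)), "val_dsc": val_dsc}
        logger.info("epoch %d: loss %.4f lr %.2e val_dsc %s",
                    epoch, record["train_loss"], lr,
                    f"{val_dsc:.4f}" if np.isfinite(val_dsc) else "n/a")
        rows.append(record)
        if len(val_cases) and (val_dsc > best_dsc):
            best_dsc, best_epoch = val_dsc, epoch
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    else:
        best_epoch = train_config.epochs - 1
    path = None
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
        path = str(checkpoint_path)
    history = pd.DataFrame(rows)
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       checkpoint_path=path)
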