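"""Loss functions and training protocols for the multi-branch ensemble.

Two objectives drive the ensemble:

* cross-entropy over the softmax head's class probabilities, and
* the supervised contrastive loss over projected embeddings z_i,

      L_sup = sum_i  -1/|P(i)| sum_{p in P(i)}
              log[ exp(z_i.z_p / tau) / sum_{a != i} exp(z_i.z_a / tau) ]

  where P(i) collects the other same-class samples of the mini-batch and
  tau is the temperature (0.05 by default).

Sequential optimization trains in three stages on disjoint parameter sets:
(1) each base learner is pretrained independently with a temporary softmax
head on cross-entropy; (2) the heads are detached, extractor features are
concatenated and frozen, and the projector alone is trained on the
supervised contrastive loss with class-balanced batches; (3) the classifier
head alone is fine-tuned on the (frozen) projected embeddings.  Joint
optimization instead trains everything at once on L = L_cls + L_sup.

Early stopping monitors the current stage's training loss and halts when it
has stopped improving for ``patience`` epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cropping import CropSet
from .networks import BaseLearner, EnsembleModel

__all__ = [
    "TrainConfig", "ContrastiveBatch", "TrainingError",
    "supervised_contrastive_loss", "cross_entropy_loss",
    "pretrain_base_learners", "contrastive_stage", "finetune_classifier",
    "joint_train", "iterate_minibatches", "class_balanced_batches",
]

from .nn import Adam, softmax

_LOG_FLOOR = 1e-12


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 32
    dropout_p: float = 0.5
    patience: int = 10
    tau: float = 0.05
    max_epochs: int = 500
    seed: int = 0
    optimization_mode: str = "sequential"   # or "joint"
    windowing_mode: str = "sliding"         # or "trial_wise"

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch size must be >= 2")
        if self.optimization_mode not in ("sequential", "joint"):
            raise ValueError(f"unknown mode {self.optimization_mode!r}")
        if self.windowing_mode not in ("sliding", "trial_wise"):
            raise ValueError(f"unknown windowing {self.windowing_mode!r}")


@dataclass
class ContrastiveBatch:
    """Mini-batch view for the contrastive loss: embeddings + labels."""

    z: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.z) != len(self.y):
            raise ValueError("z and y must align")
        if len(self.z) < 2:
            raise ValueError("contrastive batch needs at least 2 samples")


# ---------------------------------------------------------------------------
# Losses


def _supcon_with_grad(z: np.ndarray, y: np.ndarray,
                      tau: float) -> tuple[float, np.ndarray]:
    n = len(z)
    z = np.asarray(z, dtype=np.float64)
    s = (z @ z.T) / tau
    eye = np.eye(n, dtype=bool)
    s_off = np.where(eye, -np.inf, s)
    row_max = s_off.max(axis=1, keepdims=True)
    e = np.exp(s_off - row_max)                       # stabilized
    denom = e.sum(axis=1, keepdims=True)
    log_denom = np.log(denom) + row_max               # log sum_{a!=i} exp
    pos = (y[:, None] == y[None, :]) & ~eye
    n_pos = pos.sum(axis=1)
    anchors = n_pos > 0
    # L_i = mean_p [log_denom_i - s_ip]
    per_anchor = np.zeros(n)
    per_anchor[anchors] = (log_denom[anchors, 0]
                           - (s * pos)[anchors].sum(axis=1)
                           / n_pos[anchors])
    loss = float(per_anchor.sum())
    # gradient wrt s, then wrt z
    g = np.zeros_like(s)
    p_ij = e / denom
    g[anchors] = p_ij[anchors]
    g[anchors] -= (pos[anchors] / n_pos[anchors, None])
    g[~anchors] = 0.0
    np.fill_diagonal(g, 0.0)
    grad_z = (g + g.T) @ z / tau
    return loss, grad_z


def supervised_contrastive_loss(z: np.ndarray, y: np.ndarray,
                                tau: float = 0.05) -> float:
    """Supervised contrastive loss summed over anchors; anchors with no
    positive partner contribute zero."""
    if tau <= 0:
        raise ValueError("temperature must be positive")
    batch = ContrastiveBatch(z, y)
    loss, _ = _supcon_with_grad(batch.z, batch.y, tau)
    return loss


def cross_entropy_loss(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log predicted probability of the true class."""
    probs = np.asarray(probs, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if probs.ndim != 2 or len(probs) != len(y):
        raise ValueError("probs must be N x cls aligned with y")
    if y.size and (y.min() < 0 or y.max() >= probs.shape[1]):
        raise ValueError("label outside [0, n_classes)")
    p = probs[np.arange(len(y)), y]
    return float(-np.log(np.maximum(p, _LOG_FLOOR)).mean())


def _ce_from_logits(logits: np.ndarray,
                    y: np.ndarray) -> tuple[float, np.ndarray]:
    """Fused softmax + cross-entropy: returns (loss, grad wrt logits)."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], _LOG_FLOOR)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


# ---------------------------------------------------------------------------
# Batch iteration and early stopping


def iterate_minibatches(n: int, batch_size: int,
                        rng: np.random.Generator):
    """Shuffled contiguous mini-batches covering all n samples once."""
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield perm[start:start + batch_size]


def class_balanced_batches(labels: np.ndarray, batch_size: int,
                           n_batches: int, rng: np.random.Generator):
    """Batches with >= 2 samples of every represented class, so every anchor
    of the contrastive loss has at least one positive."""
    classes = np.unique(labels)
    pools = {c: np.flatnonzero(labels == c) for c in classes}
    per_class = max(2, batch_size // len(classes))
    n_classes_per_batch = max(1, batch_size // per_class)
    for _ in range(n_batches):
        chosen = rng.choice(classes, size=min(n_classes_per_batch,
                                              len(classes)), replace=False)
        batch = []
        for c in chosen:
            pool = pools[c]
            take = max(2, min(per_class, len(pool)))
            batch.append(rng.choice(pool, size=take,
                                    replace=len(pool) < take))
        yield np.concatenate(batch)


class _EarlyStopper:
    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, loss: float) -> bool:
        """Record an epoch loss; True means stop now."""
        if loss < self.best:
            self.best = loss
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def _check_finite(loss: float, what: str) -> None:
    if not np.isfinite(loss):
        raise TrainingError(f"non-finite loss while training {what}")


# ---------------------------------------------------------------------------
# Stage 1: pretraining


def pretrain_base_learners(learners: list[BaseLearner], train: CropSet,
                           cfg: TrainConfig) -> dict[int, list[float]]:
    """Independently optimize each base learner (extractor + temporary
    softmax head) on cross-entropy; returns per-learner loss histories."""
    if train.n_crops == 0:
        raise ValueError("empty training set")
    x = train.crops.astype(np.float32)
    y = train.labels
    histories: dict[int, list[float]] = {}
    for li, learner in enumerate(learners):
        rng = np.random.default_rng(cfg.seed + 7919 * li)
        opt = Adam(learner.params(), lr=cfg.learning_rate)
        stopper = _EarlyStopper(cfg.patience)
        history: list[float] = []
        for _epoch in range(cfg.max_epochs):
            learner.set_training(True)
            losses = []
            for idx in iterate_minibatches(len(x), cfg.batch_size, rng):
                opt.zero_grad()
                feats = learner.extractor.forward(x[idx])
                logits = learner.head.logits(feats)
                loss, glog = _ce_from_logits(logits, y[idx])
                _check_finite(loss, f"base learner {li} "
                                    f"({learner.extractor.spec.architecture})")
                gfeat = learner.head.backward(glog)
                learner.extractor.backward(gfeat)
                opt.step()
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            history.append(epoch_loss)
            if stopper.update(epoch_loss):
                break
        learner.set_training(False)
        histories[li] = history
    return histories


# ---------------------------------------------------------------------------
# Cached forward passes (frozen sub-stacks run in inference mode)


def _cached_concat(ensemble: EnsembleModel, x: np.ndarray,
                   batch_size: int = 256) -> np.ndarray:
    ensemble.set_training(False)
    outs = [ensemble.concat(x[i:i + batch_size])
            for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# Stage 2: contrastive representation learning


def contrastive_stage(ensemble: EnsembleModel, train: CropSet,
                      cfg: TrainConfig) -> list[float]:
    """Train the projector alone on the supervised contrastive loss over
    concatenated frozen-extractor features; returns the loss history."""
    if ensemble.projector is None:
        raise ValueError("ensemble has no projector to train")
    x = train.crops.astype(np.float32)
    y = train.labels
    feats = _cached_concat(ensemble, x)     # extractors frozen: compute once
    rng = np.random.default_rng(cfg.seed + 104729)
    opt = Adam(ensemble.projector.params(), lr=cfg.learning_rate)
    stopper = _EarlyStopper(cfg.patience)
    n_batches = max(1, int(np.ceil(len(x) / cfg.batch_size)))
    history: list[float] = []
    for _epoch in range(cfg.max_epochs):
        losses = []
        for idx in class_balanced_batches(y, cfg.batch_size, n_batches, rng):
            opt.zero_grad()
            z = ensemble.projector.forward(feats[idx])
            loss, gz = _supcon_with_grad(z.astype(np.float64), y[idx], cfg.tau)
            _check_finite(loss, "projector (contrastive stage)")
            ensemble.projector.backward(gz.astype(np.float32))
            opt.step()
            losses.append(loss / len(idx))   # per-anchor scale for comparability
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if stopper.update(epoch_loss):
            break
    return history


# ---------------------------------------------------------------------------
# Stage 3: classifier fine-tuning


def finetune_classifier(ensemble: EnsembleModel, train: CropSet,
                        cfg: TrainConfig) -> list[float]:
    """Train the softmax head alone on cross-entropy over frozen embeddings."""
    x = train.crops.astype(np.float32)
    y = train.labels
    ensemble.set_training(False)
    embeds = []
    for i in range(0, len(x), 256):
        embeds.append(ensemble.embed(x[i:i + 256]))
    z = np.concatenate(embeds, axis=0)
    rng = np.random.default_rng(cfg.seed + 224737)
    opt = Adam(ensemble.head.params(), lr=cfg.learning_rate)
    stopper = _EarlyStopper(cfg.patience)
    history: list[float] = []
    for _epoch in range(cfg.max_epochs):
        losses = []
        for idx in iterate_minibatches(len(z), cfg.batch_size, rng):
            opt.zero_grad()
            logits = ensemble.head.logits(z[idx])
            loss, glog = _ce_from_logits(logits, y[idx])
            _check_finite(loss, "classifier head")
            ensemble.head.backward(glog)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if stopper.update(epoch_loss):
            break
    return history


# ---------------------------------------------------------------------------
# Joint optimization


def joint_train(ensemble: EnsembleModel, train: CropSet, cfg: TrainConfig,
                sup_weight: float = 1.0) -> list[float]:
    """End-to-end training on L = L_cls + L_sup with unit weights.

    All parameters are trainable.  The contrastive term applies only when a
    projector is present; ``sup_weight=0`` reduces to plain end-to-end
    cross-entropy.  Returns the epoch history of the total loss.
    """
    x = train.crops.astype(np.float32)
    y = train.labels
    dims = [e.out_dim for e in ensemble.extractors]
    splits = np.cumsum(dims)[:-1]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(ensemble.params(), lr=cfg.learning_rate)
    stopper = _EarlyStopper(cfg.patience)
    use_sup = sup_weight != 0 and ensemble.projector is not None
    history: list[float] = []
    for _epoch in range(cfg.max_epochs):
        ensemble.set_training(True)
        losses = []
        for idx in iterate_minibatches(len(x), cfg.batch_size, rng):
            if len(idx) < 2:
                continue
            opt.zero_grad()
            feats = [e.forward(x[idx]) for e in ensemble.extractors]
            concat = feats[0] if len(feats) == 1 \
                else np.concatenate(feats, axis=1)
            z = ensemble.projector.forward(concat) if ensemble.projector \
                else concat
            logits = ensemble.head.logits(z)
            ce, glog = _ce_from_logits(logits, y[idx])
            gz = ensemble.head.backward(glog)
            total = ce
            if use_sup:
                sup, gz_sup = _supcon_with_grad(z.astype(np.float64), y[idx],
                                                cfg.tau)
                gz = gz + sup_weight * gz_sup.astype(np.float32)
                total = ce + sup_weight * sup
            _check_finite(total, "joint ensemble")
            gcat = ensemble.projector.backward(gz) if ensemble.projector \
                else gz
            for e, chunk in zip(ensemble.extractors,
                                np.split(gcat, splits, axis=1)):
                e.backward(np.ascontiguousarray(chunk))
            opt.step()
            losses.append(total)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if stopper.update(epoch_loss):
            break
    ensemble.set_training(False)
    return history
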