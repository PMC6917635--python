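"""Training loop: weighted cross-entropy, Adam, and plateau-driven LR decay.

The loss is categorical cross-entropy over pixels, optionally weighted
per class by median frequency balancing (see
:func:`tinyseg.data.median_frequency_weights`) so that the dominant
background class does not drown out small foreground structures.

The optimizer is Adam at learning rate 1e-3; when the validation loss
stops improving for ``patience`` epochs the learning rate is multiplied
by ``lr_factor``.  The parameters kept at the end are those of the
best-validation-loss epoch, not the last one.

Softmax and cross-entropy are fused: the network is run up to (but not
including) its softmax layer and the gradient at the logits is the
closed form ``w * (p - y) / M`` with ``p`` the softmax probabilities,
``y`` the one-hot targets, ``w`` the per-pixel class weight and ``M``
the number of weighted pixels in the batch.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .archspec import ModelSpec
from .metrics import ConfusionMatrix, evaluate_confusion
from .nn import backward, check_params, forward, init_params, softmax_channels

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "weighted_cross_entropy",
    "AdamState",
    "PlateauScheduler",
    "adam_step",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of a training run (defaults: published protocol)."""

    epochs: int = 200
    batch_size: int = 6
    learning_rate: float = 1e-3
    lr_factor: float = 0.1
    lr_patience: int = 10
    min_delta: float = 1e-4
    class_balancing: bool = True
    seed: int = 0
    shuffle: bool = True

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """A preset small enough to train in minutes on one CPU core."""
        base = cls(epochs=30, batch_size=4)
        return replace(base, **overrides)


@dataclass
class TrainHistory:
    """Per-epoch record of a run."""

    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["epoch", "train_loss", "val_loss", "learning_rate"])
            for i, (tr, va, lr) in enumerate(
                zip(self.train_loss, self.val_loss, self.learning_rate)
            ):
                writer.writerow([i, tr, va, lr])


def weighted_cross_entropy(logits, targets, class_weights=None):
    """Mean weighted cross-entropy and its gradient at the logits.

    ``logits`` is (N, H, W, C); ``targets`` is one-hot of the same shape.
    The mean is taken over the total class weight of the batch, so with
    uniform weights it is the ordinary per-pixel mean.
    """
    logits = np.asarray(logits)
    targets = np.asarray(targets, logits.dtype)
    if logits.shape != targets.shape:
        raise ValueError(
            f"logits {logits.shape} and targets {targets.shape} differ"
        )
    probs = softmax_channels(logits)
    c = logits.shape[-1]
    if class_weights is None:
        w_pix = np.ones(logits.shape[:-1], logits.dtype)
    else:
        class_weights = np.asarray(class_weights, logits.dtype)
        if class_weights.shape != (c,):
            raise ValueError(f"need {c} class weights, got {class_weights.shape}")
        w_pix = (targets * class_weights).sum(axis=-1)
    total_w = w_pix.sum()
    logp = np.log(np.clip(probs, 1e-12, None))
    loss = -(w_pix * (targets * logp).sum(axis=-1)).sum() / total_w
    grad = w_pix[..., None] * (probs - targets) / total_w
    return float(loss), grad.astype(logits.dtype, copy=False)


class PlateauScheduler:
    """Multiplies the learning rate by ``factor`` after ``patience``
    epochs without a validation-loss improvement of at least
    ``min_delta``."""

    def __init__(self, lr: float, *, factor: float, patience: int, min_delta: float):
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = float("inf")
        self.wait = 0

    def step(self, val_loss: float) -> float:
        """Record an epoch's validation loss; returns the LR to use next."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.lr *= self.factor
                self.wait = 0
        return self.lr


@dataclass
class AdamState:
    """First/second-moment accumulators mirroring the parameter tree."""

    m: dict
    v: dict
    t: int = 0

    @classmethod
    def for_params(cls, grad_keys: dict) -> "AdamState":
        zeros = lambda tree: {
            ln: {k: np.zeros_like(a) for k, a in arrs.items()}
            for ln, arrs in tree.items()
        }
        return cls(m=zeros(grad_keys), v=zeros(grad_keys))


def adam_step(
    params: dict,
    grads: dict,
    state: AdamState,
    lr: float,
    *,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-7,
) -> None:
    """One in-place Adam update of every array that received a gradient."""
    state.t += 1
    bc1 = 1.0 - beta1 ** state.t
    bc2 = 1.0 - beta2 ** state.t
    for lname, arrs in grads.items():
        for key, g in arrs.items():
            m = state.m[lname][key]
            v = state.v[lname][key]
            m *= beta1
            m += (1.0 - beta1) * g
            v *= beta2
            v += (1.0 - beta2) * np.square(g)
            params[lname][key] -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)


def _batch_loss(spec, params, images, targets, weights, *, training):
    logits, cache = forward(
        spec, params, images, training=training,
        keep_cache=training, stop_before="softmax",
    )
    loss, grad = weighted_cross_entropy(logits, targets, weights)
    return loss, grad, cache


def train(
    spec: ModelSpec,
    train_set,
    val_set,
    config: TrainConfig | None = None,
    *,
    params: dict | None = None,
    class_weights=None,
    callback=None,
):
    """Fit a model and return ``(best_params, history)``.

    ``train_set`` / ``val_set`` are ``(images, targets)`` pairs with
    ``images`` (N, H, W, 3) in [0, 1] and ``targets`` one-hot
    (N, H, W, C).  ``class_weights`` overrides the weights computed from
    the training targets; pass ``config.class_balancing=False`` for
    uniform weighting.  ``callback(epoch, history)``, if given, runs
    after each epoch.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    x_tr, y_tr = (np.asarray(a, np.float32) for a in train_set)
    x_va, y_va = (np.asarray(a, np.float32) for a in val_set)
    n_classes = spec.n_classes
    if y_tr.shape[-1] != n_classes:
        raise ValueError(
            f"targets have {y_tr.shape[-1]} classes, model expects {n_classes}"
        )

    if params is None:
        params = init_params(spec, rng=np.random.default_rng(config.seed))
    else:
        check_params(spec, params)
        params = copy.deepcopy(params)

    if config.class_balancing and class_weights is None:
        counts = y_tr.sum(axis=(0, 1, 2))
        if (counts == 0).any():
            raise ValueError("a class never occurs in the training targets")
        freq = counts / counts.sum()
        class_weights = np.median(freq) / freq
    elif not config.class_balancing:
        class_weights = None

    history = TrainHistory()
    scheduler = PlateauScheduler(
        config.learning_rate,
        factor=config.lr_factor,
        patience=config.lr_patience,
        min_delta=config.min_delta,
    )
    lr = scheduler.lr
    state = None
    best_params = copy.deepcopy(params)

    n = x_tr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses, batch_w = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grad, cache = _batch_loss(
                spec, params, x_tr[idx], y_tr[idx], class_weights, training=True
            )
            grads = backward(spec, params, cache, grad)
            if state is None:
                state = AdamState.for_params(grads)
            adam_step(params, grads, state, lr)
            losses.append(loss)
            batch_w.append(len(idx))
        train_loss = float(np.average(losses, weights=batch_w))

        val_losses, val_w = [], []
        for start in range(0, x_va.shape[0], config.batch_size):
            sl = slice(start, start + config.batch_size)
            loss, _, _ = _batch_loss(
                spec, params, x_va[sl], y_va[sl], class_weights, training=False
            )
            val_losses.append(loss)
            val_w.append(x_va[sl].shape[0])
        val_loss = float(np.average(val_losses, weights=val_w))

        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.learning_rate.append(lr)

        if val_loss < history.best_val_loss - config.min_delta:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_params = copy.deepcopy(params)
        lr = scheduler.step(val_loss)
        if callback is not None:
            callback(epoch, history)

    if history.best_epoch < 0:  # pragma: no cover - every run records epoch 0
        best_params = params
    return best_params, history


def evaluate(spec: ModelSpec, params: dict, images, label_maps, *, batch_size: int = 6):
    """Confusion-matrix metrics of a model over a labelled set."""
    check_params(spec, params)
    images = np.asarray(images, np.float32)
    cm = ConfusionMatrix(spec.n_classes)
    for start in range(0, images.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        probs, _ = forward(spec, params, images[sl], training=False)
        preds = probs.argmax(axis=-1)
        for p, t in zip(preds, label_maps[sl]):
            cm.accumulate(t, p)
    return evaluate_confusion(cm), cm
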