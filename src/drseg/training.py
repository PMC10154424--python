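"""Supervised training on the on-the-fly synthetic stream with soft Dice loss.

Every optimiser step draws one fresh synthetic pair {I, T} from the
generative model (batch size 1) and performs one Adam update of the
segmentation network. The loss is the average soft Dice over the foreground
labels,

    Loss(Y, T) = 1 - (1/K') * sum_k [ 2 * <Y_k, T_k> / (||Y_k||^2 + ||T_k||^2) ],

where Y_k is the softmax output for label k and T_k its one-hot target. The
public metric averages over the K' foreground labels; the training objective
also includes the background channel, which is essential for stability at
batch size 1 (see docs/methods.md). The loss is 0 exactly when the included
channels are the one-hot encoding of the target, and at most 1. Checkpoints
are kept periodically; the retained model is the weight average of the
decay-tail checkpoints unless validation (mean foreground Dice on held-out
synthetic pairs) vetoes it in favour of the best single checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GenerationConfig
from .generator import sample_training_pair
from .nn import Adam, ModelConfig, UNet3D, softmax
from .volumes import LabelVolume

__all__ = [
    "ModelConfig",
    "Checkpoint",
    "soft_dice_loss",
    "soft_dice_loss_grad",
    "one_hot_target",
    "train",
    "select_checkpoint",
    "average_checkpoints",
    "validation_dice",
    "retain_model",
    "build_model",
    "hard_dice_channels",
    "desk_learning_rate",
]


def desk_learning_rate(step: int) -> float:
    """Step-decay schedule for the reduced desk-scale configuration.

    2e-3 to step 2,500, 1e-3 to 3,500, then 5e-4 — rates scaled up from the
    reference 1e-4 because the desk network and volume are ~100x smaller.
    """
    if step <= 2500:
        return 2e-3
    if step <= 3500:
        return 1e-3
    return 5e-4


def channel_labels(segmentation_labels) -> list:
    """Channel order of the softmax: background 0 first, then sorted labels."""
    return [0] + sorted(int(l) for l in segmentation_labels)


def one_hot_target(target: LabelVolume, segmentation_labels) -> np.ndarray:
    """One-hot encode a target over [background] + segmentation labels."""
    chans = channel_labels(segmentation_labels)
    t = np.zeros((len(chans),) + target.shape, dtype=np.float32)
    for c, lab in enumerate(chans):
        t[c] = target.data == lab
    return t


def _dice_terms(y: np.ndarray, t: np.ndarray, first_channel: int):
    k = y.shape[0] - first_channel
    if k < 1:
        raise ValueError("at least one foreground label is required")
    yf = y[first_channel:].reshape(k, -1)
    tf = t[first_channel:].reshape(k, -1)
    inter = (yf * tf).sum(axis=1)
    denom = (yf * yf).sum(axis=1) + (tf * tf).sum(axis=1)
    return yf, tf, inter, denom


def soft_dice_loss(y: np.ndarray, t: np.ndarray,
                   include_background: bool = False) -> float:
    """Average soft Dice loss between probabilities and a one-hot target.

    Both arguments are channels-first ``(K'+1, D, H, W)`` with channel 0 the
    background. By default the mean runs over the K' foreground labels only;
    ``include_background=True`` adds the background channel to the average
    (the variant used as the training objective — see the methods note). A
    label absent from both prediction and target contributes a perfect
    overlap (its Dice ratio is taken as 1).
    """
    if y.shape != t.shape:
        raise ValueError("prediction and target shapes differ")
    _, _, inter, denom = _dice_terms(y, t, 0 if include_background else 1)
    ratio = np.where(denom > 0, 2.0 * inter / np.where(denom > 0, denom, 1.0), 1.0)
    return float(1.0 - ratio.mean())


def soft_dice_loss_grad(y: np.ndarray, t: np.ndarray,
                        include_background: bool = False):
    """Loss value and its gradient with respect to the probabilities Y."""
    if y.shape != t.shape:
        raise ValueError("prediction and target shapes differ")
    first = 0 if include_background else 1
    yf, tf, inter, denom = _dice_terms(y, t, first)
    k = yf.shape[0]
    safe = np.where(denom > 0, denom, 1.0)
    ratio = np.where(denom > 0, 2.0 * inter / safe, 1.0)
    loss = float(1.0 - ratio.mean())
    # d(ratio_k)/dY_k = (2 T_k * denom - 4 inter * Y_k) / denom^2
    dyf = -(2.0 * tf * safe[:, None] - 4.0 * inter[:, None] * yf) / (safe ** 2)[:, None] / k
    dyf = np.where((denom > 0)[:, None], dyf, 0.0)
    dy = np.zeros_like(y)
    dy[first:] = dyf.reshape(k, *y.shape[1:])
    return loss, dy.astype(np.float32)


def softmax_backward(y: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Gradient through the softmax: dL/dz = Y * (dL/dY - sum_c dL/dY_c Y_c)."""
    dot = (dy * y).sum(axis=0, keepdims=True)
    return (y * (dy - dot)).astype(np.float32)


@dataclass
class Checkpoint:
    """Weights snapshot plus the metadata needed to rebuild the network."""

    step: int
    weights: list
    model_config: ModelConfig
    segmentation_labels: tuple
    loss: float = float("nan")
    path: Path | None = None

    def build(self) -> UNet3D:
        n_classes = len(self.segmentation_labels) + 1
        net = UNet3D(1, n_classes, self.model_config, np.random.default_rng(0))
        net.set_weights(self.weights)
        return net

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path, *self.weights, step=self.step,
                 segmentation_labels=np.asarray(self.segmentation_labels),
                 n_levels=self.model_config.n_levels,
                 first_features=self.model_config.first_features)
        self.path = path


def build_model(gen_config: GenerationConfig, model_config: ModelConfig,
                rng: np.random.Generator) -> UNet3D:
    n_classes = len(gen_config.segmentation_labels) + 1
    return UNet3D(1, n_classes, model_config, rng)


def hard_dice_channels(y: np.ndarray, t: np.ndarray) -> float:
    """Mean foreground Dice of the argmax prediction against a one-hot target."""
    pred = y.argmax(axis=0)
    ref = t.argmax(axis=0)
    scores = []
    for c in range(1, y.shape[0]):
        p = pred == c
        r = ref == c
        s = p.sum() + r.sum()
        scores.append(1.0 if s == 0 else 2.0 * np.logical_and(p, r).sum() / s)
    return float(np.mean(scores))


def train(
    corpus,
    gen_config: GenerationConfig,
    model_config: ModelConfig,
    n_steps: int,
    checkpoint_every: int,
    rng: np.random.Generator,
    learning_rate=1e-4,
    out_dir=None,
    lesion_masks=None,
    model: UNet3D | None = None,
    max_grad_norm: float | None = 2.0,
):
    """Train for ``n_steps`` single-sample Adam updates on the synthetic stream.

    ``learning_rate`` is a float or a callable ``step -> lr`` (1-based step),
    allowing stepwise decay schedules. Gradients are rescaled to a global norm
    of at most ``max_grad_norm`` (None disables): with batch size 1, rare
    draws with near-singular Dice denominators (a foreground structure
    reduced to a handful of voxels) produce gradient spikes that can knock
    the network into a degenerate basin. Returns ``(checkpoints, log)`` where
    the log is a DataFrame with one row per step (step index, loss, lr). A
    checkpoint is stored every ``checkpoint_every`` steps and always at the
    final step; if ``out_dir`` is given each checkpoint is also saved as an
    ``.npz`` file.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if checkpoint_every < 1:
        raise ValueError("checkpoint_every must be >= 1")
    net = model if model is not None else build_model(gen_config, model_config, rng)
    lr_fn = learning_rate if callable(learning_rate) else (lambda step: learning_rate)
    opt = Adam(learning_rate=lr_fn(1))
    seg_labels = tuple(sorted(int(l) for l in gen_config.segmentation_labels))
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    checkpoints, rows = [], []
    for step in range(1, n_steps + 1):
        sample = sample_training_pair(corpus, gen_config, rng, lesion_masks=lesion_masks)
        x = sample.image.data.astype(np.float32)[None]
        t = one_hot_target(sample.target, seg_labels)
        logits = net.forward(x, train=True)
        y = softmax(logits)
        # background included in the objective: it gives the background
        # channel a direct gradient, removing the degenerate attractor in
        # which a foreground channel invades unsupervised background
        loss, dy = soft_dice_loss_grad(y, t, include_background=True)
        net.backward(softmax_backward(y, dy))
        params = net.params()
        if max_grad_norm is not None:
            gnorm = np.sqrt(sum(float((g ** 2).sum()) for _, g in params))
            if gnorm > max_grad_norm:
                scale = max_grad_norm / gnorm
                for _, g in params:
                    g *= scale
        opt.lr = lr_fn(step)
        opt.step(params)
        rows.append({"step": step, "loss": loss, "lr": opt.lr})
        if step % checkpoint_every == 0 or step == n_steps:
            ckpt = Checkpoint(step, net.get_weights(), model_config, seg_labels, loss)
            if out_dir is not None:
                ckpt.save(out_dir / f"checkpoint_{step:06d}.npz")
            checkpoints.append(ckpt)
    log = pd.DataFrame(rows)
    if out_dir is not None:
        log.to_csv(out_dir / "training_log.csv", index=False)
    return checkpoints, log


def average_checkpoints(checkpoints) -> Checkpoint:
    """Uniform weight average of checkpoints from one run (tail averaging).

    Averaging snapshots from the low-learning-rate tail of a single run is a
    cheap variance reducer; the result carries the metadata (and step) of the
    last constituent.
    """
    if not checkpoints:
        raise ValueError("no checkpoints given")
    last = checkpoints[-1]
    avg = [
        np.mean([c.weights[i] for c in checkpoints], axis=0)
        for i in range(len(last.weights))
    ]
    return Checkpoint(last.step, avg, last.model_config, last.segmentation_labels)


def validation_dice(ckpt: Checkpoint, validation_pairs) -> float:
    """Mean foreground Dice of a checkpoint's argmax predictions on pairs."""
    net = ckpt.build()
    scores = []
    for pair in validation_pairs:
        x = pair.image.data.astype(np.float32)[None]
        y = net.predict_proba(x)
        t = one_hot_target(pair.target, ckpt.segmentation_labels)
        scores.append(hard_dice_channels(y, t))
    return float(np.mean(scores))


def select_checkpoint(checkpoints, validation_pairs) -> Checkpoint:
    """Checkpoint with the best mean foreground Dice on validation pairs.

    Ties are broken in favour of the earliest checkpoint.
    """
    if not checkpoints:
        raise ValueError("no checkpoints given")
    if not validation_pairs:
        raise ValueError("no validation pairs given")
    best, best_score = None, -np.inf
    for ckpt in checkpoints:
        score = validation_dice(ckpt, validation_pairs)
        if score > best_score:
            best, best_score = ckpt, score
    return best


def retain_model(checkpoints, validation_pairs, tail: int = 3,
                 veto_margin: float = 0.02) -> Checkpoint:
    """Retention rule: tail-averaged weights, vetoed by validation.

    The candidate is the uniform weight average of the last ``tail``
    checkpoints (the low-learning-rate phase of the schedule), a cheap
    variance reducer over single snapshots. Validation keeps a veto: if the
    averaged model scores more than ``veto_margin`` mean foreground Dice
    below the best single checkpoint — e.g. because part of the tail fell
    into a degenerate state, where averaging would be harmful — the
    validation-selected single checkpoint is retained instead.
    """
    best = select_checkpoint(checkpoints, validation_pairs)
    if len(checkpoints) < 2:
        return best
    averaged = average_checkpoints(checkpoints[-tail:])
    if validation_dice(averaged, validation_pairs) >= \
            validation_dice(best, validation_pairs) - veto_margin:
        return averaged
    return best
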