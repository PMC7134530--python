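"""Optimization and experiment protocol.

Adam with a per-epoch exponentially decayed learning rate (initial 0.001,
decay 0.98), early stopping on validation loss with best-checkpoint
selection, randomized k-fold splitting, and a driver that trains every
requested ablation variant on identical splits and seeds.

A batch is one whole volume's slice stacks: the sequence branch needs the
full ordered axial stack, so gradients are taken volume-by-volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import confusion, metrics
from .network import MVTTConfig, MVTTNetwork, binarize, dice_loss, hybrid_loss
from .phantom import PhantomSample
from .volumes import Volume, normalize_slicewise, resample_to_cube


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 0.001
    lr_decay: float = 0.98
    max_epochs: int = 30
    early_stop_patience: int = 5
    batch_size: int = 1
    seed: int = 0
    k_folds: int = 10
    loss_floor: float | None = None  # optional: stop once train loss dips below
    grad_clip: float | None = 1.0    # global grad-norm clip; None disables

    def __post_init__(self) -> None:
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch record of the optimization run."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice_anatomy: list[float] = field(default_factory=list)
    val_dice_scar: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch,
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "val_dice_anatomy": self.val_dice_anatomy,
                "val_dice_scar": self.val_dice_scar,
                "lr": self.lr,
            }
        )


def lr_schedule(config: TrainConfig, epoch: int) -> float:
    """Learning rate at `epoch`: lr_init * lr_decay ** epoch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.lr_init * config.lr_decay**epoch


def make_kfold_splits(ids, k: int, seed: int) -> list[tuple[list, list]]:
    """Randomized k-fold partitions: disjoint folds covering all ids, sizes
    differing by at most one; deterministic for a given seed."""
    ids = list(ids)
    if k < 2 or k > len(ids):
        raise ValueError(f"k must be in [2, {len(ids)}], got {k}")
    order = np.random.default_rng(seed).permutation(len(ids))
    folds = np.array_split(order, k)
    splits = []
    for i in range(k):
        val = [ids[j] for j in folds[i]]
        train = [ids[j] for f in (folds[:i] + folds[i + 1:]) for j in f]
        splits.append((train, val))
    return splits


class Adam:
    """Adam optimizer over a named-parameter dict."""

    def __init__(self, params: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def prepare_sample(sample: PhantomSample, cube_edge: int):
    """Resample to the working cube and slice-normalize; returns
    (normalized voxels, anatomy target, scar target) as float32/uint8."""
    vol = resample_to_cube(sample.image, cube_edge)
    img = normalize_slicewise(vol).voxels.astype(np.float32)
    if sample.anatomy.shape == (cube_edge,) * 3:
        gl = sample.anatomy.labels
        gas = sample.scar.labels
    else:
        gl = binarize(
            resample_to_cube(
                Volume(sample.anatomy.labels.astype(float), sample.anatomy.spacing),
                cube_edge,
            ).voxels
        )
        gas = binarize(
            resample_to_cube(
                Volume(sample.scar.labels.astype(float), sample.scar.spacing), cube_edge
            ).voxels
        )
    return img, gl, gas


def _loss_for(model: MVTTNetwork, out, gl, gas):
    tasks = model.config.tasks
    if tasks == "both":
        return hybrid_loss(out.anatomy_prob, out.scar_prob, gl, gas)
    if tasks == "anatomy_only":
        return dice_loss(out.anatomy_prob, gl)
    return dice_loss(out.scar_prob, gas)


def _val_stats(model: MVTTNetwork, val_data) -> tuple[float, float, float]:
    model.set_mode("eval")
    losses, dls, dss = [], [], []
    for img, gl, gas in val_data:
        out = model.forward(img)
        losses.append(float(_loss_for(model, out, gl, gas).data))
        if out.anatomy_prob is not None:
            dls.append(metrics(confusion(binarize(out.anatomy_volume()), gl)).dice)
        if out.scar_prob is not None:
            dss.append(metrics(confusion(binarize(out.scar_volume()), gas)).dice)
    mean = lambda xs: float(np.mean(xs)) if xs else float("nan")
    return mean(losses), mean(dls), mean(dss)


def _clip_grad_norm(model: MVTTNetwork, max_norm: float) -> None:
    """Rescale all gradients so their global L2 norm is at most `max_norm`.

    The ReLU-activated memory cell is unbounded, so occasional large
    gradients through the recurrence are expected; clipping keeps the
    volume-by-volume Adam updates stable."""
    params = model.parameters().values()
    total = np.sqrt(
        sum(float((p.grad**2).sum()) for p in params if p.grad is not None)
    )
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in model.parameters().values():
            if p.grad is not None:
                p.grad *= scale


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def train(
    model_config: MVTTConfig,
    cohort: list[PhantomSample],
    config: TrainConfig,
    val_cohort: list[PhantomSample] | None = None,
) -> tuple[MVTTNetwork, TrainHistory]:
    """Train one model on a phantom cohort, minimizing the hybrid Dice loss
    (or the single-task Dice loss for single-task variants).

    If no validation cohort is given the last fifth of `cohort` is held out.
    Stops early when validation loss has not improved for
    ``early_stop_patience`` epochs; the best-validation checkpoint is
    restored into the returned model.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    if val_cohort is None:
        n_val = max(1, len(cohort) // 5) if len(cohort) > 1 else 0
        val_cohort = cohort[len(cohort) - n_val :] if n_val else cohort
        cohort = cohort[: len(cohort) - n_val] if n_val else cohort

    edge = model_config.cube_edge
    train_data = [prepare_sample(s, edge) for s in cohort]
    val_data = [prepare_sample(s, edge) for s in val_cohort]

    model = MVTTNetwork(model_config, seed=config.seed)
    opt = Adam(model.parameters())
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_loss = np.inf
    best_state = model.state_dict()
    since_best = 0

    for epoch in range(config.max_epochs):
        lr = lr_schedule(config, epoch)
        model.set_mode("train")
        epoch_losses = []
        for idx in rng.permutation(len(train_data)):
            img, gl, gas = train_data[idx]
            model.zero_grad()
            out = model.forward(img)
            loss = _loss_for(model, out, gl, gas)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch} (sample {idx})"
                )
            loss.backward()
            if config.grad_clip is not None:
                _clip_grad_norm(model, config.grad_clip)
            opt.step(lr)
            epoch_losses.append(value)

        val_loss, dice_l, dice_s = _val_stats(model, val_data)
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_dice_anatomy.append(dice_l)
        history.val_dice_scar.append(dice_s)
        history.lr.append(lr)

        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break
        if config.loss_floor is not None and history.train_loss[-1] < config.loss_floor:
            best_state = model.state_dict()
            history.best_epoch = epoch
            break

    model.load_state_dict(best_state)
    model.set_mode("eval")
    return model, history


# ---------------------------------------------------------------------------
# Ablation driver
# ---------------------------------------------------------------------------

def run_ablation_suite(
    cohort: list[PhantomSample],
    variants: dict[str, MVTTConfig],
    config: TrainConfig,
) -> pd.DataFrame:
    """Train every variant on identical train/validation splits and seeds;
    returns one row per variant and task with AC/SE/SP/DI columns."""
    if len(variants) < 2:
        raise ValueError("an ablation suite needs at least two variants")
    n_val = max(1, len(cohort) // 5)
    train_set, val_set = cohort[:-n_val], cohort[-n_val:]
    rows = []
    for name, mcfg in variants.items():
        model, history = train(mcfg, train_set, config, val_cohort=val_set)
        val_data = [prepare_sample(s, mcfg.cube_edge) for s in val_set]
        per_task: dict[str, list] = {"anatomy": [], "scar": []}
        for img, gl, gas in val_data:
            out = model.forward(img)
            if out.anatomy_prob is not None:
                per_task["anatomy"].append(
                    metrics(confusion(binarize(out.anatomy_volume()), gl))
                )
            if out.scar_prob is not None:
                per_task["scar"].append(
                    metrics(confusion(binarize(out.scar_volume()), gas))
                )
        for task, recs in per_task.items():
            if not recs:
                continue
            rows.append(
                {
                    "variant": name,
                    "task": task,
                    "accuracy": float(np.mean([r.accuracy for r in recs])),
                    "sensitivity": float(np.mean([r.sensitivity for r in recs])),
                    "specificity": float(np.mean([r.specificity for r in recs])),
                    "dice": float(np.mean([r.dice for r in recs])),
                    "best_epoch": history.best_epoch,
                }
            )
    return pd.DataFrame(rows)
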