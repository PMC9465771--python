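"""Training of the skull-stripping network on an endless synthetic stream.

Every optimization step samples one label map uniformly from the training
set, synthesizes a fresh (image, mask, SDT) triple from it, and performs
one Adam update of the banded SDT regression loss (or the negated soft
Dice loss).  Validation loss is computed on a frozen-seed synthetic
validation set; the learning rate is halved whenever a configured number
of optimization steps elapses without a new validation-loss minimum —
the published schedule uses 20,000 steps, a batch size of one and an
initial rate of 1e-4.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .network import UNet, UNetSpec, build_unet
from .sdt_loss import (SdtLossConfig, band_sdt, sdt_loss, sdt_loss_grad,
                       soft_dice_loss, soft_dice_loss_grad)
from .synth import SynthesisRanges, generate_training_pair
from .volumes import DistanceMap

__all__ = ["TrainConfig", "Adam", "PlateauScheduler", "train", "TrainResult"]


@dataclass
class TrainConfig:
    max_steps: int
    learning_rate: float = 1e-4
    batch_size: int = 1
    plateau_steps: int = 20000
    lr_factor: float = 0.5
    val_interval: int = 100
    val_set_size: int = 2
    loss_mode: str = "sdt"
    rng_seed: int = 0
    sdt_cfg: SdtLossConfig = field(default_factory=SdtLossConfig)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.plateau_steps < 1:
            raise ValueError("plateau_steps must be >= 1")
        if self.loss_mode not in ("sdt", "dice"):
            raise ValueError("loss_mode must be 'sdt' or 'dice'")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


class PlateauScheduler:
    """Halve (by ``factor``) when ``patience_steps`` optimization steps pass
    without a decrease in validation loss."""

    def __init__(self, lr: float, factor: float = 0.5, patience_steps: int = 20000):
        self.lr = lr
        self.factor = factor
        self.patience_steps = patience_steps
        self.best = np.inf
        self.best_step = 0

    def observe(self, step: int, val_loss: float) -> float:
        """Record a validation loss at an optimization step; return the lr."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_step = step
        elif step - self.best_step >= self.patience_steps:
            self.lr *= self.factor
            self.best_step = step  # restart the plateau window
        return self.lr


@dataclass
class TrainResult:
    net: UNet
    history: list            # (step, train_loss, lr)
    val_history: list        # (step, val_loss)

    def write_history_csv(self, path):
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "train_loss", "lr"])
            w.writerows(self.history)


def _loss_and_grad(net: UNet, x, y_hat, d_hat, cfg: TrainConfig):
    out = net.forward(x.data, train=True)
    if cfg.loss_mode == "sdt":
        d = DistanceMap(np.asarray(out, float), x.geometry)
        loss = sdt_loss(d, d_hat, cfg.sdt_cfg)
        grad_out = sdt_loss_grad(d, d_hat, cfg.sdt_cfg)
    else:
        loss = soft_dice_loss(np.asarray(out, float), y_hat)
        grad_out = soft_dice_loss_grad(np.asarray(out, float), y_hat)
    grads = net.backward(grad_out)
    return loss, grads


def _validation_loss(net: UNet, val_pairs, cfg: TrainConfig) -> float:
    losses = []
    for x, y_hat, d_hat in val_pairs:
        out = net.forward(x.data, train=False)
        if cfg.loss_mode == "sdt":
            losses.append(sdt_loss(DistanceMap(out, x.geometry), d_hat, cfg.sdt_cfg))
        else:
            losses.append(soft_dice_loss(out, y_hat))
    return float(np.mean(losses))


def train(label_maps, ranges: SynthesisRanges, unet, cfg: TrainConfig,
          net_seed: int = 0, log=None) -> TrainResult:
    """Optimize the network on images synthesized from ``label_maps``.

    Parameters
    ----------
    label_maps : list of LabelMap
        Source anatomies; one is drawn uniformly per step.
    ranges : SynthesisRanges
        Synthesis hyperparameter ranges.
    unet : UNetSpec or UNet
        Architecture (a fresh network is built from a spec) or an existing
        network to continue training.
    cfg : TrainConfig
        Optimization settings; ``loss_mode`` must match the head mode.
    log : callable, optional
        Called with (step, loss, lr) after each step.
    """
    if not label_maps:
        raise ValueError("need at least one training label map")
    net = unet if isinstance(unet, UNet) else build_unet(unet, seed=net_seed)
    if net.spec.head_mode != cfg.loss_mode:
        raise ValueError(
            f"loss_mode {cfg.loss_mode!r} inconsistent with head_mode "
            f"{net.spec.head_mode!r}"
        )

    ss = np.random.SeedSequence(cfg.rng_seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    pair_ss, val_ss = ss.spawn(2)
    pair_seeds = pair_ss.spawn(cfg.max_steps * cfg.batch_size)
    val_pairs = [
        generate_training_pair(
            label_maps[i % len(label_maps)], ranges, val_ss.spawn(1)[0]
        )
        for i in range(cfg.val_set_size)
    ]

    opt = Adam(net.params)
    sched = PlateauScheduler(cfg.learning_rate, cfg.lr_factor, cfg.plateau_steps)
    history, val_history = [], []
    k = 0
    for step in range(1, cfg.max_steps + 1):
        batch_loss = 0.0
        grads_acc = None
        for _ in range(cfg.batch_size):
            s = label_maps[pick_rng.integers(len(label_maps))]
            x, y_hat, d_hat = generate_training_pair(s, ranges, pair_seeds[k])
            k += 1
            loss, grads = _loss_and_grad(net, x, y_hat, d_hat, cfg)
            batch_loss += loss / cfg.batch_size
            if grads_acc is None:
                grads_acc = grads
            else:
                for key in grads_acc:
                    grads_acc[key] += grads[key]
        if not np.isfinite(batch_loss):
            raise RuntimeError(
                f"training diverged at step {step}: loss={batch_loss!r} "
                f"(lr={sched.lr:g}, loss_mode={cfg.loss_mode})"
            )
        if cfg.batch_size > 1:
            for key in grads_acc:
                grads_acc[key] /= cfg.batch_size
        opt.step(net.params, grads_acc, sched.lr)
        history.append((step, float(batch_loss), sched.lr))
        if log is not None:
            log(step, float(batch_loss), sched.lr)
        if cfg.val_interval and step % cfg.val_interval == 0 and val_pairs:
            vloss = _validation_loss(net, val_pairs, cfg)
            val_history.append((step, vloss))
            sched.observe(step, vloss)
    return TrainResult(net, history, val_history)
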