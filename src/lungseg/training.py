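"""Training loop, dataset splitting, ablation variants, and evaluation.

The schedule follows the published recipe: Adam at initial learning rate
2e-4, batch size 64, up to 70 epochs, dice loss, and halving of the learning
rate whenever the monitored validation quantity has not improved for 10
epochs. Data are split 2/3 for training (of which 20% is held out for
validation) and 1/3 for testing.

Six ablation variants of the decoder sub-block are named Method 1–6:

====== ============ =========================
method activation   residual blocks / stage
====== ============ =========================
1      relu         0
2      leaky_relu   0
3      relu         1
4      leaky_relu   1
5      leaky_relu   2   (the full model)
6      leaky_relu   3
====== ============ =========================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .metrics import MetricReport, aggregate, batch_soft_dice_loss, score_pair
from .morphology import repair
from .network import ModelConfig, UNet, predict_mask
from .nn.autograd import Tensor
from .phantom import ImageSample

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ABLATION_VARIANTS",
    "TrainingDivergedError",
    "ReduceLROnPlateau",
    "Adam",
    "split_dataset",
    "build_variant",
    "train",
    "evaluate",
    "EvaluationResult",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults are the published recipe."""

    initial_lr: float = 2e-4
    batch_size: int = 64
    max_epochs: int = 70
    plateau_patience: int = 10
    lr_factor: float = 0.5
    train_fraction: float = 2.0 / 3.0
    val_fraction_of_train: float = 0.2
    seed: int = 0
    monitor: str = "val_loss"  # or "val_dice"

    def validate(self) -> "TrainConfig":
        for name in ("train_fraction", "val_fraction_of_train"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.plateau_patience < 1:
            raise ValueError(f"plateau_patience must be >= 1, got {self.plateau_patience}")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError(f"lr_factor must be in (0, 1), got {self.lr_factor}")
        if self.monitor not in ("val_loss", "val_dice"):
            raise ValueError(f"monitor must be 'val_loss' or 'val_dice', got {self.monitor!r}")
        return self


#: method_id -> (activation, residual_blocks_per_decoder)
ABLATION_VARIANTS: dict[int, tuple[str, int]] = {
    1: ("relu", 0),
    2: ("leaky_relu", 0),
    3: ("relu", 1),
    4: ("leaky_relu", 1),
    5: ("leaky_relu", 2),
    6: ("leaky_relu", 3),
}


def build_variant(method_id: int, base: ModelConfig) -> ModelConfig:
    """Return ``base`` overridden with the Method 1–6 decoder settings."""
    if method_id not in ABLATION_VARIANTS:
        raise ValueError(f"method_id must be in 1..6, got {method_id}")
    activation, n_res = ABLATION_VARIANTS[method_id]
    return replace(base, activation=activation, residual_blocks_per_decoder=n_res).validate()


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(
    samples: Sequence[ImageSample], config: TrainConfig
) -> tuple[list[ImageSample], list[ImageSample], list[ImageSample]]:
    """Seeded disjoint (train, val, test) partition.

    Sizes use round-to-nearest at each stage: n_trainval = round(2n/3), of
    which round(20%) is validation — so every split is within one sample of
    the exact fractions.
    """
    config.validate()
    n = len(samples)
    if n < 5:
        raise ValueError(f"need at least 5 samples to form a nonempty split, got {n}")
    n_trainval = int(round(n * config.train_fraction))
    n_trainval = min(max(n_trainval, 2), n - 1)  # nonempty test and train/val
    n_val = int(round(n_trainval * config.val_fraction_of_train))
    n_val = min(max(n_val, 1), n_trainval - 1)
    perm = np.random.default_rng(config.seed).permutation(n)
    trainval, test_idx = perm[:n_trainval], perm[n_trainval:]
    val_idx, train_idx = trainval[:n_val], trainval[n_val:]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


# ---------------------------------------------------------------------------
# optimizer and scheduler
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled-from-graph state, one slot pair per parameter."""

    def __init__(
        self,
        params: Sequence[Tensor],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate after ``patience`` epochs
    without improvement of the monitored value (lower is better).

    The produced sequence is non-increasing and always equals
    initial_lr * factor**m for an integer m >= 0.
    """

    def __init__(
        self,
        initial_lr: float,
        factor: float = 0.5,
        patience: int = 10,
        min_delta: float = 0.0,
    ) -> None:
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, value: float) -> float:
        if value < self.best - self.min_delta:
            self.best = value
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr *= self.factor
                self.bad_epochs = 0
        return self.lr


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _to_batch(samples: Sequence[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image.transpose(2, 0, 1) for s in samples])
    y = np.stack([s.mask.astype(np.float64)[None] for s in samples])
    return x, y


def _forward_loss(net: UNet, x: np.ndarray, y: np.ndarray) -> Tensor:
    return batch_soft_dice_loss(net(Tensor(x)), y)


def train(
    network: UNet,
    train_samples: Sequence[ImageSample],
    val_samples: Sequence[ImageSample],
    config: TrainConfig,
) -> tuple[UNet, pd.DataFrame]:
    """Optimize the dice loss with Adam under the plateau schedule.

    Returns the trained network and a per-epoch history DataFrame with
    columns (epoch, train_loss, val_loss, lr). Fully deterministic in
    ``config.seed``.
    """
    config.validate()
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be nonempty")
    batch_size = config.batch_size
    if batch_size > len(train_samples):
        batch_size = len(train_samples)
        logger.info(
            "batch_size %d exceeds training-set size; reduced to %d",
            config.batch_size,
            batch_size,
        )
    network.reseed_dropout(config.seed)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    opt = Adam(network.parameters(), lr=config.initial_lr)
    sched = ReduceLROnPlateau(
        config.initial_lr, factor=config.lr_factor, patience=config.plateau_patience
    )
    xv, yv = _to_batch(val_samples)
    history: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        network.train()
        order = shuffle_rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            batch = [train_samples[i] for i in order[start : start + batch_size]]
            x, y = _to_batch(batch)
            loss = _forward_loss(network, x, y)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            opt.zero_grad()
            loss.backward()
            opt.lr = sched.lr
            opt.step()
            epoch_losses.append(loss.item())
        network.eval()
        val_loss = _forward_loss(network, xv, yv).item()
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}")
        monitored = val_loss
        if config.monitor == "val_dice":
            monitored = -_mean_dice(network, val_samples)
        lr_used = sched.lr
        sched.step(monitored)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "lr": lr_used,
            }
        )
    network.eval()
    return network, pd.DataFrame(history)


def _mean_dice(network: UNet, samples: Sequence[ImageSample]) -> float:
    rows = [score_pair(predict_mask(network, s.image), s.mask, s.sample_id) for s in samples]
    return float(np.mean([r["dice"] for r in rows]))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    raw: MetricReport
    repaired: MetricReport | None


Predictor = Callable[[ImageSample], np.ndarray]


def evaluate(
    network: UNet | Predictor,
    test_samples: Sequence[ImageSample],
    repair_enabled: bool = True,
    threshold: float = 0.5,
) -> EvaluationResult:
    """Score a model on a test set; optionally also after morphological repair.

    ``network`` may be a trained :class:`UNet` or any callable mapping an
    :class:`ImageSample` to a binary mask (used for oracle/stub predictors).
    A pure function of (weights, test set, flags).
    """
    if not test_samples:
        raise ValueError("test set must be nonempty")
    if isinstance(network, UNet):
        predict: Predictor = lambda s: predict_mask(network, s.image, threshold)
    else:
        predict = network
    raw_rows, rep_rows = [], []
    for s in test_samples:
        pred = np.asarray(predict(s)).astype(bool)
        if pred.shape != s.mask.shape:
            raise ValueError(
                f"prediction shape {pred.shape} does not match mask {s.mask.shape} "
                f"for sample {s.sample_id}"
            )
        raw_rows.append(score_pair(pred, s.mask, s.sample_id))
        if repair_enabled:
            rep_rows.append(score_pair(repair(pred), s.mask, s.sample_id))
    return EvaluationResult(
        raw=aggregate(raw_rows),
        repaired=aggregate(rep_rows) if repair_enabled else None,
    )
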