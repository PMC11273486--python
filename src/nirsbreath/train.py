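"""Two-phase optimization protocol for the two-stream network.

Phase 1 pre-trains the autoencoder alone on the reconstruction loss; its
weights initialize the autoencoder stream of the full model. Phase 2 jointly
optimizes ``L_total = L_R + alpha * L_C`` over both streams (the encoder is
*not* frozen — the coupled objective trains it further). Both phases use SGD
with momentum 0.9, batch size 128, and a step schedule that divides the
learning rate by 10 every 30 epochs; the published initial rates are 0.1 for
pre-training and 0.01 for the joint phase, with alpha = 10.

Augmentation, when enabled, is applied on the fly to each training batch using
statistics of the training split only; the test split is never augmented and
never read during training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, AugmentStats, augment_batch, compute_aug_stats
from .nirs_io import DatasetSplit, stack_windows
from .arch import ArchitectureSpec
from .model import SingleStreamNet, TwoStreamNet, build_scnn, build_tcnn
from .nn.losses import cross_entropy, mse_reconstruction
from .nn.optim import SGD

__all__ = [
    "TrainConfig",
    "pretrain_autoencoder",
    "train_tcnn",
    "train_scnn",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization protocol parameters (defaults are the published ones)."""

    epochs: int = 140
    batch_size: int = 128
    lr_pretrain: float = 0.1
    lr_tcnn: float = 0.01
    momentum: float = 0.9
    lr_decay_every: int = 30
    lr_decay_factor: float = 10.0
    alpha: float = 10.0
    weight_decay: float = 0.0
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    recon_reduction: str = "mean"  # optimization scale of L_R; "sum" = Eq form
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.lr_decay_every) < 1:
            raise ValueError("epochs, batch_size and lr_decay_every must be >= 1")
        if min(self.lr_pretrain, self.lr_tcnn, self.lr_decay_factor) <= 0:
            raise ValueError("learning rates and decay factor must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.recon_reduction not in ("mean", "sum"):
            raise ValueError("recon_reduction must be 'mean' or 'sum'")

    def lr_at(self, base: float, epoch: int) -> float:
        """Step-decayed learning rate for a 0-based epoch index."""
        return base / self.lr_decay_factor ** (epoch // self.lr_decay_every)


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled batch index slices; the last incomplete batch is kept."""
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def _check_finite(loss: float, what: str) -> None:
    if not np.isfinite(loss):
        raise RuntimeError(f"{what} diverged (non-finite loss); lower the learning rate")


def _train_arrays(split: DatasetSplit) -> tuple[np.ndarray, np.ndarray]:
    X, y = stack_windows(split.train)
    if np.any(y < 0):
        raise ValueError("training windows must all be labelled")
    return X, y


def pretrain_autoencoder(
    model: TwoStreamNet,
    split: DatasetSplit,
    cfg: TrainConfig,
    epochs: int | None = None,
) -> list[dict]:
    """Phase 1: minimize the reconstruction loss alone.

    Trains only the encoder/decoder parameters of ``model`` (in place) and
    returns the per-epoch loss trace. Deterministic under ``cfg.seed`` up to
    floating-point reduction order.
    """
    X, _ = _train_arrays(split)
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.autoencoder_parameters(), lr=cfg.lr_pretrain,
              momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    history = []
    for epoch in range(epochs):
        opt.lr = cfg.lr_at(cfg.lr_pretrain, epoch)
        total, seen = 0.0, 0
        per_window = X.shape[1] * X.shape[2]
        for idx in _iter_batches(X.shape[0], cfg.batch_size, rng):
            xb = X[idx]
            recon = model.forward_autoencoder(xb, train=True)
            reduction = "mean" if cfg.recon_reduction == "mean" else "sample_sum"
            loss, grad = mse_reconstruction(xb, recon, reduction=reduction)
            _check_finite(loss, "autoencoder pre-training")
            if reduction == "mean":
                loss = loss * per_window  # report in the definitional units
            opt.zero_grad()
            model.backward_autoencoder(grad)
            opt.step()
            total += loss * len(idx)
            seen += len(idx)
        history.append({"epoch": epoch, "loss_R": total / seen, "lr": opt.lr})
        logger.info("pretrain epoch %d: L_R=%.4f", epoch, total / seen)
    return history


def _augment_setup(split: DatasetSplit, cfg: TrainConfig) -> AugmentStats | None:
    if not cfg.augment:
        return None
    return compute_aug_stats(
        split.train,
        per_channel=cfg.augment_config.per_channel,
        forbid_participants=split.test_participants,
    )


def train_tcnn(
    split: DatasetSplit,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    pretrained_autoencoder: list[np.ndarray] | TwoStreamNet | None = None,
    epochs: int | None = None,
    seed: int | None = None,
) -> tuple[TwoStreamNet, list[dict]]:
    """Phase 2: joint optimization of both streams.

    ``pretrained_autoencoder`` may be a weight list from
    :meth:`TwoStreamNet.get_autoencoder_state` or a pre-trained model whose
    autoencoder weights are copied in. Returns the trained model and a
    per-epoch history of ``loss_total``, ``loss_R``, ``loss_C`` and training
    accuracy.
    """
    X, y = _train_arrays(split)
    epochs = cfg.epochs if epochs is None else epochs
    seed = cfg.seed if seed is None else seed
    model = build_tcnn(spec, seed=seed)
    if isinstance(pretrained_autoencoder, TwoStreamNet):
        model.set_autoencoder_state(pretrained_autoencoder.get_autoencoder_state())
    elif pretrained_autoencoder is not None:
        model.set_autoencoder_state(pretrained_autoencoder)
    stats = _augment_setup(split, cfg)
    rng = np.random.default_rng(seed)
    opt = SGD(model.parameters(), lr=cfg.lr_tcnn, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history = []
    for epoch in range(epochs):
        opt.lr = cfg.lr_at(cfg.lr_tcnn, epoch)
        sums = {"loss_total": 0.0, "loss_R": 0.0, "loss_C": 0.0}
        correct, seen = 0, 0
        for idx in _iter_batches(X.shape[0], cfg.batch_size, rng):
            xb, yb = X[idx], y[idx]
            if stats is not None:
                xb = augment_batch(xb, stats, cfg.augment_config, rng)
            logits, recon = model.forward(xb, train=True)
            reduction = "mean" if cfg.recon_reduction == "mean" else "sample_sum"
            loss_R, grad_R = mse_reconstruction(xb, recon, reduction=reduction)
            loss_C, grad_C = cross_entropy(logits, yb)
            loss = loss_R + cfg.alpha * loss_C
            _check_finite(loss, "joint training")
            if reduction == "mean":
                loss_R = loss_R * xb.shape[1] * xb.shape[2]  # definitional units
            opt.zero_grad()
            model.backward(cfg.alpha * grad_C, grad_R)
            opt.step()
            n = len(idx)
            sums["loss_total"] += loss * n
            sums["loss_R"] += loss_R * n
            sums["loss_C"] += loss_C * n
            correct += int((np.argmax(logits, axis=1) == yb).sum())
            seen += n
        row = {k: v / seen for k, v in sums.items()}
        row.update(epoch=epoch, train_accuracy=100.0 * correct / seen, lr=opt.lr)
        history.append(row)
        logger.info(
            "epoch %d: L_total=%.4f L_R=%.4f L_C=%.4f acc=%.2f%%",
            epoch, row["loss_total"], row["loss_R"], row["loss_C"],
            row["train_accuracy"],
        )
    return model, history


def train_scnn(
    split: DatasetSplit,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    epochs: int | None = None,
    seed: int | None = None,
) -> tuple[SingleStreamNet, list[dict]]:
    """Train the single-stream ablation on the cross-entropy loss alone."""
    X, y = _train_arrays(split)
    epochs = cfg.epochs if epochs is None else epochs
    seed = cfg.seed if seed is None else seed
    model = build_scnn(spec, seed=seed)
    stats = _augment_setup(split, cfg)
    rng = np.random.default_rng(seed)
    opt = SGD(model.parameters(), lr=cfg.lr_tcnn, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    history = []
    for epoch in range(epochs):
        opt.lr = cfg.lr_at(cfg.lr_tcnn, epoch)
        total, correct, seen = 0.0, 0, 0
        for idx in _iter_batches(X.shape[0], cfg.batch_size, rng):
            xb, yb = X[idx], y[idx]
            if stats is not None:
                xb = augment_batch(xb, stats, cfg.augment_config, rng)
            logits = model.forward(xb, train=True)
            loss, grad = cross_entropy(logits, yb)
            _check_finite(loss, "single-stream training")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            n = len(idx)
            total += loss * n
            correct += int((np.argmax(logits, axis=1) == yb).sum())
            seen += n
        history.append({
            "epoch": epoch, "loss_C": total / seen,
            "train_accuracy": 100.0 * correct / seen, "lr": opt.lr,
        })
    return model, history
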