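"""Supervised training with block-wise epochs and best-epoch restore.

Training minimizes mean absolute error in rubric points over the nine
network outputs.  Epochs run in blocks (default two blocks of 50) with a
fresh optimizer state at the start of each block — resuming therefore may
show a brief transient rise in the curve before it continues to improve.
The "training loss" recorded per epoch is the full-training-set MAE
recomputed at epoch end, not the running mini-batch average; there is no
validation split, so best-epoch selection uses this training MAE, with
ties broken toward the earliest epoch.  A checkpoint is written every
epoch so the best version can always be restored.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

from . import network
from .network import AdamState, ModelConfig, forward, forward_backward, mae_loss

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "TrainResult",
    "LeakageError",
    "EmptyCheckpointDirError",
    "loss",
    "train",
    "restore_best",
    "write_curve_csv",
]

_CKPT_RE = re.compile(r"^epoch_(\d{4})\.npz$")


class LeakageError(ValueError):
    """A test-split case was offered to the training loop."""


class EmptyCheckpointDirError(ValueError):
    """No checkpoints found where some were expected."""


@dataclass(frozen=True)
class TrainConfig:
    epoch_blocks: tuple[int, ...] = (50, 50)
    batch_size: int = 2
    learning_rate: float = 3e-3
    beta1: float = 0.9
    beta2: float = 0.999
    seed: int = 0
    checkpoint_dir: Optional[Path] = None
    loss_weights: Optional[tuple[float, ...]] = None
    #: learning-rate multiplier applied at each successive block (block k
    #: runs at learning_rate * block_lr_decay**k); the lower second-block
    #: rate settles the curve instead of oscillating around the optimum
    block_lr_decay: float = 1.0 / 3.0
    #: clip gradients to this global L2 norm before each update (None: off)
    grad_clip: Optional[float] = None

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.epoch_blocks):
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class Checkpoint:
    epoch: int
    params: dict[str, np.ndarray]
    train_mae: float
    timestamp: float
    rng_state: Optional[str] = None


@dataclass
class TrainResult:
    curve: list[float]                     # per-epoch full-set training MAE
    best_epoch: int                        # 1-based; argmin of curve
    best_mae: float
    final_params: dict[str, np.ndarray]
    best_params: dict[str, np.ndarray]
    config: ModelConfig


def loss(
    predicted: np.ndarray,
    reference: np.ndarray,
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Weighted MAE in rubric points (see :func:`network.mae_loss`)."""
    w = None if weights is None else np.asarray(weights, dtype=float)
    return mae_loss(predicted, reference, w)


def _full_set_mae(
    clouds: np.ndarray,
    targets: np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    weights: Optional[np.ndarray],
    eval_batch: int = 8,
) -> float:
    preds = np.concatenate(
        [
            np.atleast_2d(forward(clouds[i : i + eval_batch], params, config))
            for i in range(0, len(clouds), eval_batch)
        ]
    )
    return mae_loss(preds, targets, weights)


def train(
    clouds: np.ndarray,
    targets: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    splits: Optional[Sequence[str]] = None,
) -> TrainResult:
    """Run the epoch blocks and return the curve plus best/final parameters.

    ``clouds``: (n_cases, n_points, 3) normalized point clouds.
    ``targets``: (n_cases, n_outputs) rubric scores (criteria + total).
    ``splits``: optional per-case split tags; any ``"test"`` tag aborts
    training before a single gradient step (leakage guard).
    """
    clouds = np.asarray(clouds)
    targets = np.asarray(targets, dtype=np.float64)
    if clouds.ndim != 3 or clouds.shape[2] != 3:
        raise ValueError(f"clouds must be (n, n_points, 3); got {clouds.shape}")
    if len(clouds) < 1:
        raise ValueError("need at least one training case")
    if targets.shape != (len(clouds), model_config.n_outputs):
        raise ValueError(
            f"targets must be ({len(clouds)}, {model_config.n_outputs}); got {targets.shape}"
        )
    if splits is not None:
        leaked = [i for i, s in enumerate(splits) if s == "test"]
        if leaked:
            raise LeakageError(
                f"refusing to train: cases at positions {leaked} are tagged 'test'"
            )

    weights = (
        None
        if train_config.loss_weights is None
        else np.asarray(train_config.loss_weights, dtype=float)
    )
    params = network.init_params(model_config)
    rng = np.random.default_rng(np.random.SeedSequence([int(train_config.seed), 0x7124]))

    ckpt_dir = train_config.checkpoint_dir
    if ckpt_dir is not None:
        ckpt_dir = Path(ckpt_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    n = len(clouds)
    curve: list[float] = []
    best_snapshot: Optional[dict[str, np.ndarray]] = None
    best_so_far = np.inf
    epoch = 0
    for block_idx, block in enumerate(train_config.epoch_blocks):
        optimizer = AdamState(
            lr=train_config.learning_rate * train_config.block_lr_decay**block_idx,
            beta1=train_config.beta1,
            beta2=train_config.beta2,
        )  # fresh state per block
        for _ in range(block):
            epoch += 1
            order = rng.permutation(n)
            for start in range(0, n, train_config.batch_size):
                idx = order[start : start + train_config.batch_size]
                _, grads = forward_backward(
                    clouds[idx], targets[idx], params, model_config, weights
                )
                if train_config.grad_clip is not None:
                    gnorm = np.sqrt(
                        sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values())
                    )
                    if gnorm > train_config.grad_clip:
                        scale = train_config.grad_clip / gnorm
                        grads = {k: g * scale for k, g in grads.items()}
                optimizer.step(params, grads)
            epoch_mae = _full_set_mae(clouds, targets, params, model_config, weights)
            curve.append(epoch_mae)
            logger.info(
                "epoch=%d block=%d training_mae=%.6f", epoch, block_idx + 1, epoch_mae
            )
            if epoch_mae < best_so_far:  # strict: ties keep the earliest epoch
                best_so_far = epoch_mae
                best_snapshot = {k: v.copy() for k, v in params.items()}
            if ckpt_dir is not None:
                network.save_params(
                    ckpt_dir / f"epoch_{epoch:04d}.npz",
                    params,
                    model_config,
                    epoch=epoch,
                    train_mae=epoch_mae,
                    timestamp=time.time(),
                    rng_state=json.dumps(rng.bit_generator.state, default=int),
                )

    if curve:
        best_idx = int(np.argmin(curve))  # argmin returns the earliest tie
        best_epoch = best_idx + 1
        best_mae = float(curve[best_idx])
        best_params = best_snapshot
        if ckpt_dir is not None:
            best = restore_best(ckpt_dir)
            best_params = best.params
            network.save_params(
                ckpt_dir / "best.npz", best_params, model_config,
                epoch=best.epoch, train_mae=best.train_mae, timestamp=time.time(),
            )
            write_curve_csv(ckpt_dir / "curve.csv", curve)
    else:
        best_epoch, best_mae, best_params = 0, float("nan"), {
            k: v.copy() for k, v in params.items()
        }

    return TrainResult(
        curve=curve,
        best_epoch=best_epoch,
        best_mae=best_mae,
        final_params=params,
        best_params=best_params,
        config=model_config,
    )


def restore_best(checkpoint_dir: str | Path) -> Checkpoint:
    """Load the checkpoint with minimal training MAE (ties -> earliest epoch)."""
    checkpoint_dir = Path(checkpoint_dir)
    entries = []
    for p in sorted(checkpoint_dir.iterdir()) if checkpoint_dir.is_dir() else []:
        if _CKPT_RE.match(p.name):
            entries.append(p)
    if not entries:
        raise EmptyCheckpointDirError(f"no epoch checkpoints in {checkpoint_dir}")
    best: Optional[Checkpoint] = None
    for p in entries:
        params, _, meta = network.load_params(p)
        ck = Checkpoint(
            epoch=int(meta["epoch"]),
            params=params,
            train_mae=float(meta["train_mae"]),
            timestamp=float(meta.get("timestamp", 0.0)),
            rng_state=meta.get("rng_state"),
        )
        if best is None or ck.train_mae < best.train_mae or (
            ck.train_mae == best.train_mae and ck.epoch < best.epoch
        ):
            best = ck
    return best


def write_curve_csv(path: str | Path, curve: Sequence[float]) -> Path:
    path = Path(path)
    lines = ["epoch,training_mae"] + [
        f"{i + 1},{v:.10g}" for i, v in enumerate(curve)
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
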