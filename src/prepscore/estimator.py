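"""scikit-learn-style estimator wrapping the point-cloud score regressor.

``PointNetScoreRegressor`` is the fit/predict surface of the package: X is
an array of pose-normalized point clouds with shape
``(n_cases, n_points, 3)`` and y the ``(n_cases, 9)`` matrix of rubric
targets (the eight criteria in canonical order plus the total).  It plays
by the scikit-learn rules — ``get_params``/``set_params``, fitted
attributes with a trailing underscore, ``check_is_fitted``-compatible —
so it composes with pipelines and model selection, while the actual
optimization lives in :mod:`prepscore.training`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import network, training
from .network import ModelConfig
from .rubric import ScoreSheet
from .training import TrainConfig

__all__ = ["PointNetScoreRegressor", "DESK_SCALE"]

#: Reduced architecture used throughout the docs, tests and worked
#: examples: small enough to train a 20-case cohort on one CPU core in a
#: few minutes while keeping the PointNet structure intact.
DESK_SCALE: dict = {
    "trunk_widths": (32, 64, 128, 256),
    "head_widths": (128, 64),
}


class PointNetScoreRegressor(RegressorMixin, BaseEstimator):
    """PointNet-style rubric-score regressor.

    Parameters mirror :class:`~prepscore.network.ModelConfig` and
    :class:`~prepscore.training.TrainConfig`; ``random_state`` seeds both
    the weight initialization and the epoch shuffles.
    """

    def __init__(
        self,
        trunk_widths: tuple[int, ...] = (64, 64, 128, 1024),
        head_widths: tuple[int, ...] = (512, 256),
        epoch_blocks: tuple[int, ...] = (50, 50),
        batch_size: int = 2,
        learning_rate: float = 3e-3,
        block_lr_decay: float = 1.0 / 3.0,
        grad_clip: Optional[float] = None,
        loss_weights: Optional[tuple[float, ...]] = None,
        checkpoint_dir: Optional[str | Path] = None,
        random_state: int = 0,
        dtype: str = "float32",
    ):
        self.trunk_widths = trunk_widths
        self.head_widths = head_widths
        self.epoch_blocks = epoch_blocks
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.block_lr_decay = block_lr_decay
        self.grad_clip = grad_clip
        self.loss_weights = loss_weights
        self.checkpoint_dir = checkpoint_dir
        self.random_state = random_state
        self.dtype = dtype

    # ------------------------------------------------------------------

    def _validate_X(self, X: np.ndarray, n_points: Optional[int] = None) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2 and X.shape[1] == 3:
            X = X[None]
        if X.ndim != 3 or X.shape[2] != 3:
            raise ValueError(f"X must have shape (n_cases, n_points, 3); got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite coordinates")
        if n_points is not None and X.shape[1] != n_points:
            raise ValueError(
                f"expected clouds of {n_points} points, got {X.shape[1]}"
            )
        return X

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        splits: Optional[Sequence[str]] = None,
    ) -> "PointNetScoreRegressor":
        """Train on normalized clouds X (n, N, 3) and targets y (n, 9)."""
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[None]
        config = ModelConfig(
            n_points=X.shape[1],
            trunk_widths=tuple(self.trunk_widths),
            head_widths=tuple(self.head_widths),
            n_outputs=y.shape[1],
            init_seed=int(self.random_state),
            dtype=self.dtype,
        )
        tcfg = TrainConfig(
            epoch_blocks=tuple(self.epoch_blocks),
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            block_lr_decay=self.block_lr_decay,
            grad_clip=self.grad_clip,
            seed=int(self.random_state),
            checkpoint_dir=None if self.checkpoint_dir is None else Path(self.checkpoint_dir),
            loss_weights=self.loss_weights,
        )
        result = training.train(X, y, config, tcfg, splits=splits)
        self.config_ = config
        self.params_ = result.best_params
        self.final_params_ = result.final_params
        self.loss_curve_ = list(result.curve)
        self.best_epoch_ = result.best_epoch
        self.best_train_mae_ = result.best_mae
        self.n_features_in_ = X.shape[1] * 3
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted scores, (n_cases, n_outputs): criteria then total head."""
        self._check_fitted()
        X = self._validate_X(X, n_points=None)
        out = [
            np.atleast_2d(network.forward(X[i : i + 8], self.params_, self.config_))
            for i in range(0, len(X), 8)
        ]
        return np.concatenate(out, axis=0)

    def predict_sheets(
        self, X: np.ndarray, case_ids: Optional[Sequence[str]] = None
    ) -> list[tuple[ScoreSheet, float, float]]:
        """Per-case (sheet, total-head, sum-of-criteria) triples."""
        self._check_fitted()
        X = self._validate_X(X)
        ids = case_ids if case_ids is not None else [f"case_{i}" for i in range(len(X))]
        return [
            network.predict_sheet(X[i], self.params_, self.config_, case_id=ids[i])
            for i in range(len(X))
        ]

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("this PointNetScoreRegressor instance is not fitted yet")

    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        self._check_fitted()
        return network.save_params(
            Path(path), self.params_, self.config_,
            best_epoch=self.best_epoch_, best_train_mae=self.best_train_mae_,
        )

    @classmethod
    def from_checkpoint(cls, path: str | Path) -> "PointNetScoreRegressor":
        params, config, meta = network.load_params(path)
        est = cls(
            trunk_widths=config.trunk_widths,
            head_widths=config.head_widths,
            random_state=config.init_seed,
            dtype=config.dtype,
        )
        est.config_ = config
        est.params_ = params
        est.final_params_ = params
        est.loss_curve_ = []
        est.best_epoch_ = int(meta.get("best_epoch", meta.get("epoch", 0)))
        est.best_train_mae_ = float(meta.get("best_train_mae", meta.get("train_mae", np.nan)))
        est.n_features_in_ = config.n_points * 3
        return est
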