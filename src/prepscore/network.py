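"""PointNet-style regression network, implemented directly in NumPy.

The architecture follows the canonical PointNet classification trunk:
a shared per-point MLP (the same weights applied to every point), a
symmetric max-pool over points that yields a permutation-invariant global
feature, and a fully connected head.  The nine outputs — the eight rubric
criteria plus a jointly trained total head — are each passed through a
sigmoid affinely rescaled to that output's rubric range, so predictions
respect their bounds for any parameters and any input.

Forward, backward (manual reverse-mode gradients) and the Adam update all
live here; there is no deep-learning framework underneath.  Shapes are
(batch, n_points, 3) in and (batch, n_outputs) out.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import rubric
from .rubric import ScoreSheet, total_score

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "CheckpointCompatibilityError",
    "init_params",
    "forward",
    "forward_backward",
    "mae_loss",
    "AdamState",
    "predict_sheet",
    "save_params",
    "load_params",
    "parameter_count",
]

CHECKPOINT_FORMAT_VERSION = 1


class CheckpointCompatibilityError(ValueError):
    """A serialized parameter file does not match the expected config."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``trunk_widths`` are the shared per-point feature widths ending in the
    global-feature size; ``head_widths`` the fully connected head.  Bounds
    default to the rubric criterion ranges plus (0, 20) for the total head.
    ``use_input_transform`` is retained as an architecture flag but the
    learned input T-Net is not implemented: inputs arrive pose-normalized.
    """

    n_points: int = 100_000
    trunk_widths: tuple[int, ...] = (64, 64, 128, 1024)
    head_widths: tuple[int, ...] = (512, 256)
    n_outputs: int = 9
    output_bounds: Optional[tuple[tuple[float, float], ...]] = None
    use_input_transform: bool = False
    init_seed: int = 0
    dtype: str = "float32"
    #: "max" is the canonical aggregation; "max_mean" concatenates the mean
    #: alongside — still symmetric, and sensitive to concave features that
    #: never attain a per-point maximum.
    pooling: str = "max"
    #: optional shrink factor for the final-layer weight init
    out_init_scale: float = 1.0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.trunk_widths + self.head_widths):
            raise ValueError("layer widths must be positive")
        if self.pooling not in ("max", "max_mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.n_outputs != len(self.bounds_array()):
            raise ValueError("n_outputs must match the number of output bounds")
        if self.use_input_transform:
            raise NotImplementedError(
                "the learned input transform (T-Net) is not implemented; "
                "inputs are pose-normalized by preprocessing"
            )

    def bounds_array(self) -> np.ndarray:
        if self.output_bounds is not None:
            b = np.asarray(self.output_bounds, dtype=float)
        else:
            b = rubric.output_bounds(include_total=True)
        if not np.all(np.isfinite(b)) or np.any(b[:, 1] <= b[:, 0]):
            raise ValueError("output bounds must be finite with max > min")
        return b

    def layer_shapes(self) -> list[tuple[str, int, int]]:
        shapes = []
        prev = 3
        for i, w in enumerate(self.trunk_widths):
            shapes.append((f"trunk{i}", prev, w))
            prev = w
        if self.pooling == "max_mean":
            prev *= 2
        for i, w in enumerate(self.head_widths):
            shapes.append((f"head{i}", prev, w))
            prev = w
        shapes.append(("out", prev, self.n_outputs))
        return shapes

    def to_json(self) -> str:
        d = {
            "n_points": self.n_points,
            "trunk_widths": list(self.trunk_widths),
            "head_widths": list(self.head_widths),
            "n_outputs": self.n_outputs,
            "output_bounds": self.bounds_array().tolist(),
            "use_input_transform": self.use_input_transform,
            "init_seed": self.init_seed,
            "dtype": self.dtype,
            "pooling": self.pooling,
            "out_init_scale": self.out_init_scale,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        return cls(
            n_points=int(d["n_points"]),
            trunk_widths=tuple(d["trunk_widths"]),
            head_widths=tuple(d["head_widths"]),
            n_outputs=int(d["n_outputs"]),
            output_bounds=tuple(tuple(b) for b in d["output_bounds"]),
            use_input_transform=bool(d["use_input_transform"]),
            init_seed=int(d["init_seed"]),
            dtype=str(d["dtype"]),
            pooling=str(d.get("pooling", "max")),
            out_init_scale=float(d.get("out_init_scale", 1.0)),
        )


def init_params(config: ModelConfig) -> dict[str, np.ndarray]:
    """Fan-in-scaled (He) random initialization, deterministic in
    ``config.init_seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.init_seed), 0x9E7]))
    dt = np.dtype(config.dtype)
    params: dict[str, np.ndarray] = {}
    for name, fan_in, fan_out in config.layer_shapes():
        scale = np.sqrt(2.0 / fan_in)
        if name == "out":
            scale *= config.out_init_scale
        params[f"{name}_W"] = rng.normal(0.0, scale, size=(fan_in, fan_out)).astype(dt)
        params[f"{name}_b"] = np.zeros(fan_out, dtype=dt)
    return params


def parameter_count(params: dict[str, np.ndarray]) -> int:
    return int(sum(p.size for p in params.values()))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _check_normalized(points: np.ndarray) -> None:
    centroid = float(np.linalg.norm(points.reshape(-1, 3).mean(axis=0)))
    if centroid > 1e-3:
        logger.warning(
            "forward(): input cloud centroid norm %.3g — input looks "
            "un-normalized; predictions assume unit-sphere pose", centroid
        )


def forward(
    points: np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    cache: Optional[dict] = None,
) -> np.ndarray:
    """Score a batch of clouds.  ``points``: (B, N, 3) or (N, 3).

    With ``cache`` a dict, stores intermediates for ``forward_backward``.
    """
    pts = np.asarray(points, dtype=config.dtype)
    squeeze = pts.ndim == 2
    if squeeze:
        pts = pts[None]
    _check_normalized(pts)

    h = pts
    acts = []
    n_trunk = len(config.trunk_widths)
    for i in range(n_trunk):
        z = h @ params[f"trunk{i}_W"] + params[f"trunk{i}_b"]
        h = np.maximum(z, 0.0)
        acts.append(h)
    argmax = h.argmax(axis=1)                      # (B, C)
    g_max = np.take_along_axis(h, argmax[:, None, :], axis=1)[:, 0, :]  # (B, C)
    if config.pooling == "max_mean":
        g = np.concatenate([g_max, h.mean(axis=1)], axis=1)
    else:
        g = g_max

    head_acts = [g]
    h2 = g
    for i in range(len(config.head_widths)):
        z2 = h2 @ params[f"head{i}_W"] + params[f"head{i}_b"]
        h2 = np.maximum(z2, 0.0)
        head_acts.append(h2)
    z_out = h2 @ params["out_W"] + params["out_b"]
    s = _sigmoid(z_out.astype(np.float64))
    bounds = config.bounds_array()
    lo, hi = bounds[:, 0], bounds[:, 1]
    y = lo + (hi - lo) * s

    if cache is not None:
        cache.update(
            pts=pts, acts=acts, argmax=argmax, head_acts=head_acts, s=s,
            lo=lo, hi=hi,
        )
    return y[0] if squeeze else y


def mae_loss(
    predicted: np.ndarray,
    target: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Weighted mean absolute error in rubric points.

    The per-output MAEs (mean over the batch) are combined with weights
    that are normalized to sum to one; uniform weights make a single
    1.8-point error on one of nine outputs contribute 0.2 per case.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if predicted.shape != target.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {target.shape}")
    if predicted.ndim == 1:
        predicted, target = predicted[None], target[None]
    k = predicted.shape[1]
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (k,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    per_output = np.mean(np.abs(predicted - target), axis=0)
    return float(per_output @ w)


def forward_backward(
    points: np.ndarray,
    target: np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    weights: Optional[np.ndarray] = None,
) -> tuple[float, dict[str, np.ndarray]]:
    """One loss evaluation plus analytic gradients for every parameter."""
    cache: dict = {}
    y = forward(points, params, config, cache=cache)
    if y.ndim == 1:
        y = y[None]
    target = np.asarray(target, dtype=np.float64).reshape(y.shape)
    loss = mae_loss(y, target, weights)

    B, k = y.shape
    w = np.full(k, 1.0 / k) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    dy = np.sign(y - target) * w[None, :] / B                 # dL/dy
    s = cache["s"]
    dz_out = (dy * (cache["hi"] - cache["lo"]) * s * (1.0 - s)).astype(config.dtype)

    grads: dict[str, np.ndarray] = {}
    head_acts = cache["head_acts"]
    grads["out_W"] = head_acts[-1].T @ dz_out
    grads["out_b"] = dz_out.sum(axis=0)
    dh = dz_out @ params["out_W"].T
    for i in reversed(range(len(config.head_widths))):
        dz = dh * (head_acts[i + 1] > 0)
        grads[f"head{i}_W"] = head_acts[i].T @ dz
        grads[f"head{i}_b"] = dz.sum(axis=0)
        dh = dz @ params[f"head{i}_W"].T

    # route the global-feature gradient back through the pooling: the max
    # part scatters to the argmax points, the mean part spreads evenly
    acts = cache["acts"]
    dpool = np.zeros_like(acts[-1])
    n_pts = dpool.shape[1]
    if config.pooling == "max_mean":
        c = dpool.shape[2]
        np.put_along_axis(dpool, cache["argmax"][:, None, :], dh[:, None, :c], axis=1)
        dpool += dh[:, None, c:] / n_pts
    else:
        np.put_along_axis(dpool, cache["argmax"][:, None, :], dh[:, None, :], axis=1)
    dh3 = dpool
    n_trunk = len(config.trunk_widths)
    for i in reversed(range(n_trunk)):
        dz = dh3 * (acts[i] > 0)
        below = cache["pts"] if i == 0 else acts[i - 1]
        grads[f"trunk{i}_W"] = np.einsum("bnp,bnq->pq", below, dz)
        grads[f"trunk{i}_b"] = dz.sum(axis=(0, 1))
        if i > 0:
            dh3 = dz @ params[f"trunk{i}_W"].T
    return loss, grads


@dataclass
class AdamState:
    """Adaptive-moment optimizer state (fresh state per training block)."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            g64 = g.astype(np.float64)
            if key not in self.m:
                self.m[key] = np.zeros_like(g64)
                self.v[key] = np.zeros_like(g64)
            self.m[key] = b1 * self.m[key] + (1 - b1) * g64
            self.v[key] = b2 * self.v[key] + (1 - b2) * g64 * g64
            m_hat = self.m[key] / (1 - b1**self.t)
            v_hat = self.v[key] / (1 - b2**self.t)
            params[key] = (
                params[key].astype(np.float64)
                - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
            ).astype(params[key].dtype)


def predict_sheet(
    points: np.ndarray,
    params: dict[str, np.ndarray],
    config: ModelConfig,
    case_id: str = "",
) -> tuple[ScoreSheet, float, float]:
    """Predict one case: returns (sheet, total-head value, sum-of-criteria).

    The sheet holds the eight criterion outputs; the jointly trained total
    head is reported alongside the rubric total recomputed from criteria,
    since the two are trained against the same target but need not agree.
    """
    y = forward(points, params, config)
    y = np.asarray(y, dtype=float).reshape(-1)
    sheet = ScoreSheet.from_vector(y[: len(rubric.CRITERIA)], case_id=case_id)
    total_head = float(y[-1])
    return sheet, total_head, total_score(sheet)


# ---------------------------------------------------------------------------
# Parameter serialization (NumPy's native named-array archive)


def save_params(
    path: str | Path, params: dict[str, np.ndarray], config: ModelConfig, **extra
) -> Path:
    path = Path(path)
    meta = {"format_version": CHECKPOINT_FORMAT_VERSION, "config": config.to_json()}
    meta.update({k: v for k, v in extra.items()})
    with open(path, "wb") as fh:
        np.savez(
            fh,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **params,
        )
    return path


def load_params(
    path: str | Path, expect_config: Optional[ModelConfig] = None
) -> tuple[dict[str, np.ndarray], ModelConfig, dict]:
    path = Path(path)
    with np.load(path) as archive:
        if "__meta__" not in archive:
            raise CheckpointCompatibilityError(f"{path}: not a prepscore checkpoint")
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {k: archive[k] for k in archive.files if k != "__meta__"}
    if meta.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise CheckpointCompatibilityError(
            f"{path}: unsupported checkpoint version {meta.get('format_version')}"
        )
    config = ModelConfig.from_json(meta["config"])
    if expect_config is not None:
        if config.n_outputs != expect_config.n_outputs or config.trunk_widths != tuple(
            expect_config.trunk_widths
        ) or config.head_widths != tuple(expect_config.head_widths):
            raise CheckpointCompatibilityError(
                f"{path}: checkpoint architecture {config.trunk_widths}/"
                f"{config.head_widths}/{config.n_outputs} does not match the "
                "requested configuration"
            )
    expected = {f"{n}_{s}" for n, _, _ in config.layer_shapes() for s in ("W", "b")}
    if set(params) != expected:
        raise CheckpointCompatibilityError(f"{path}: parameter keys do not match config")
    return params, config, meta
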