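"""Symmetric stacked autoencoder for deep sequence features.

Architecture is palindromic (default 256-128-64-128-256 around a 468-dim
input), trained with plain minibatch SGD on mean squared reconstruction
error. Inputs are z-scored per column on the training split; the
normalization statistics travel with the model so encode/reconstruct are
self-contained. Hidden layers use ReLU (sigmoid available), the output
layer is linear.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SaeConfig:
    layer_sizes: tuple[int, ...] = (256, 128, 64, 128, 256)
    activation: str = "relu"  # "relu" | "sigmoid"
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 0.01
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        sizes = self.layer_sizes
        if len(sizes) % 2 == 0 or any(s < 1 for s in sizes):
            raise ValueError("layer_sizes must be an odd-length list of positive widths")
        if list(sizes) != list(reversed(sizes)):
            raise ValueError(f"layer_sizes must be palindromic, got {sizes}")
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def bottleneck(self) -> int:
        return self.layer_sizes[len(self.layer_sizes) // 2]


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    return 1.0 / (1.0 + np.exp(-x))


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (a > 0).astype(float)
    return a * (1.0 - a)


@dataclass
class SaeModel:
    config: SaeConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    mean: np.ndarray
    scale: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_encoder_layers(self) -> int:
        return (len(self.weights) + 1) // 2

    def _forward(self, x: np.ndarray, upto: int | None = None) -> list[np.ndarray]:
        """Activations per layer; the final layer is linear."""
        acts = [x]
        last = len(self.weights) - 1
        stop = last if upto is None else upto - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            if k > stop:
                break
            z = acts[-1] @ w + b
            acts.append(z if k == last else _act(z, self.config.activation))
        return acts

    def _check_width(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        squeeze = v.ndim == 1
        if squeeze:
            v = v[None, :]
        if v.shape[1] != self.input_dim:
            raise ValueError(f"expected width {self.input_dim}, got {v.shape[1]}")
        return v if not squeeze else v  # caller re-squeezes

    def encode(self, v: np.ndarray) -> np.ndarray:
        """Deterministic forward pass through the encoder half only."""
        arr = np.asarray(v, dtype=float)
        squeeze = arr.ndim == 1
        x = self._check_width(np.atleast_2d(arr))
        x = (x - self.mean) / self.scale
        out = self._forward(x, upto=self.n_encoder_layers)[-1]
        return out[0] if squeeze else out

    def reconstruct(self, v: np.ndarray, denormalize: bool = True) -> np.ndarray:
        """Full encoder+decoder round trip back to input space."""
        arr = np.asarray(v, dtype=float)
        squeeze = arr.ndim == 1
        x = self._check_width(np.atleast_2d(arr))
        xs = (x - self.mean) / self.scale
        out = self._forward(xs)[-1]
        if denormalize:
            out = out * self.scale + self.mean
        return out[0] if squeeze else out

    def reconstruction_mse(self, v: np.ndarray) -> float:
        """Mean squared error in the (standardized) training space."""
        x = self._check_width(np.atleast_2d(np.asarray(v, dtype=float)))
        xs = (x - self.mean) / self.scale
        return float(np.mean((xs - self._forward(xs)[-1]) ** 2))


def train_sae(
    x: np.ndarray, cfg: SaeConfig | None = None, val_fraction: float = 0.1
) -> SaeModel:
    """Fit the autoencoder to rows of ``x`` by SGD on MSE.

    Records per-epoch train and validation MSE in ``model.history``.
    """
    cfg = cfg or SaeConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("training data must be a matrix with >= 2 rows")
    if not np.isfinite(x).all():
        raise ValueError("training data contains non-finite values")
    n, in_dim = x.shape

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(n * val_fraction))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) < 1:
        raise ValueError("val_fraction leaves no training rows")

    if cfg.standardize:
        mean = x[train_idx].mean(axis=0)
        scale = x[train_idx].std(axis=0)
        # columns that are constant up to float noise must not be amplified
        scale[scale <= 1e-9] = 1.0
    else:
        mean = np.zeros(in_dim)
        scale = np.ones(in_dim)
    xt = (x[train_idx] - mean) / scale
    xv = (x[val_idx] - mean) / scale if n_val else None

    widths = [in_dim, *cfg.layer_sizes, in_dim]
    weights, biases = [], []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        std = np.sqrt(2.0 / fan_in)
        weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    model = SaeModel(cfg, weights, biases, mean, scale, {"train": [], "val": []})
    last = len(weights) - 1
    for epoch in range(cfg.epochs):
        perm = rng.permutation(len(xt))
        for lo in range(0, len(xt), cfg.batch_size):
            batch = xt[perm[lo: lo + cfg.batch_size]]
            acts = model._forward(batch)
            delta = 2.0 * (acts[-1] - batch) / batch.size  # dMSE/d(output)
            for k in range(last, -1, -1):
                gw = acts[k].T @ delta
                gb = delta.sum(axis=0)
                if k > 0:
                    delta = (delta @ weights[k].T) * _act_grad(acts[k], cfg.activation)
                weights[k] -= cfg.learning_rate * gw
                biases[k] -= cfg.learning_rate * gb
        train_mse = float(np.mean((model._forward(xt)[-1] - xt) ** 2))
        model.history["train"].append(train_mse)
        if xv is not None and len(xv):
            model.history["val"].append(float(np.mean((model._forward(xv)[-1] - xv) ** 2)))
    logger.info(
        "SAE trained: %s, final train MSE %.5f", "-".join(map(str, cfg.layer_sizes)),
        model.history["train"][-1],
    )
    return model


def mse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Plain mean squared error over all coordinates."""
    y, y_hat = np.asarray(y, dtype=float), np.asarray(y_hat, dtype=float)
    return float(np.mean((y - y_hat) ** 2))


def save_sae(path, model: SaeModel) -> None:
    """JSON checkpoint: config, normalization stats, weights, history."""
    payload = {
        "config": {
            "layer_sizes": list(model.config.layer_sizes),
            "activation": model.config.activation,
            "epochs": model.config.epochs,
            "batch_size": model.config.batch_size,
            "learning_rate": model.config.learning_rate,
            "seed": model.config.seed,
            "standardize": model.config.standardize,
        },
        "mean": model.mean.tolist(),
        "scale": model.scale.tolist(),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "history": model.history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_sae(path) -> SaeModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg_d = dict(payload["config"])
    cfg_d["layer_sizes"] = tuple(cfg_d["layer_sizes"])
    cfg = SaeConfig(**cfg_d)
    return SaeModel(
        cfg,
        [np.array(w) for w in payload["weights"]],
        [np.array(b) for b in payload["biases"]],
        np.array(payload["mean"]),
        np.array(payload["scale"]),
        payload["history"],
    )
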