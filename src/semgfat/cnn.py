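"""Spatio-temporal CNN for 4-class sEMG fatigue recognition, from scratch.

Five layers. The input I1 is a 6 x T window in %MVC (T = 120 at 60°/s,
160 at 180°/s). C2 applies ten 6 x 1 kernels spanning all channels at a
single time point (purely spatial filtering, scaled-tanh activation),
giving ten 1 x T maps. C3 applies four 1 x 10 kernels with stride 10 to
each C2 map (temporal convolution-pooling), giving forty 1 x (T/10)
maps. F4 (100 units) and O5 (4 units, one per fatigue class) are fully
connected with logistic-sigmoid activations.

Training is plain gradient descent on the mean-squared error against
one-hot targets, with the layer-wise learning rates

    shared-weight layers (C2, C3):  gamma = 2*lam / (N_shared * sqrt(fan_in))
    dense layers (F4, O5):          gamma = lam / sqrt(fan_in)

where ``N_shared`` is the number of positions sharing one kernel and
``fan_in`` the number of inputs feeding one neuron. Weights start
uniform in ±1/sqrt(fan_in). The model snapshot with the lowest
validation loss is returned (first strict minimum wins). Everything is
deterministic given the seed; the analytic backward pass is validated
against central finite differences in the test suite.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preprocessing import Window

__all__ = [
    "CNNArchitecture",
    "CNNModel",
    "TrainConfig",
    "TrainHistory",
    "TrainingError",
    "init_model",
    "forward",
    "loss",
    "backward",
    "layer_rates",
    "train",
    "predict",
    "windows_to_arrays",
    "save_model",
    "load_model",
]

#: scaled hyperbolic tangent constants for the convolutional layers
TANH_A = 1.71159
TANH_B = 2.0 / 3.0


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class CNNArchitecture:
    """Layer geometry; only the window length T varies with speed."""

    T: int = 120
    n_channels: int = 6
    c2_filters: int = 10
    c3_filters_per_map: int = 4
    c3_kernel: int = 10
    c3_stride: int = 10
    f4_units: int = 100
    o5_units: int = 4
    #: %MVC inputs reach ~100; this keeps pre-activations in the tanh
    #: operating range without altering the architecture (value selected
    #: by validation loss on the default synthetic cohort).
    input_scale: float = 0.05
    #: "sigmoid" + MSE (default) or "softmax" + cross-entropy
    output_activation: str = "sigmoid"

    @classmethod
    def for_speed(cls, speed: int, **kw) -> "CNNArchitecture":
        return cls(T={60: 120, 180: 160}[speed], **kw)

    @property
    def c3_len(self) -> int:
        return self.T // self.c3_stride

    @property
    def c3_maps(self) -> int:
        return self.c2_filters * self.c3_filters_per_map

    @property
    def f4_fan_in(self) -> int:
        return self.c3_maps * self.c3_len

    def validate(self) -> None:
        if self.T % self.c3_stride:
            raise ValueError("window length must be divisible by the C3 stride")
        if self.output_activation not in ("sigmoid", "softmax"):
            raise ValueError("output_activation must be sigmoid or softmax")

    def fan_in(self) -> dict[str, int]:
        return {
            "C2": self.n_channels,
            "C3": self.c3_kernel,
            "F4": self.f4_fan_in,
            "O5": self.f4_units,
        }

    def n_shared(self) -> dict[str, int]:
        """Positions sharing one kernel, per convolutional layer."""
        return {"C2": self.T, "C3": self.c3_len}


@dataclass
class CNNModel:
    arch: CNNArchitecture
    k2: np.ndarray  # (10, 6)
    b2: np.ndarray  # (10,)
    k3: np.ndarray  # (10, 4, 10)
    b3: np.ndarray  # (10, 4)
    W4: np.ndarray  # (100, 40 * c3_len)
    b4: np.ndarray  # (100,)
    W5: np.ndarray  # (4, 100)
    b5: np.ndarray  # (4,)

    def params(self) -> dict[str, np.ndarray]:
        return {
            "k2": self.k2, "b2": self.b2, "k3": self.k3, "b3": self.b3,
            "W4": self.W4, "b4": self.b4, "W5": self.W5, "b5": self.b5,
        }

    #: learning-rate group of each parameter
    PARAM_LAYER = {
        "k2": "C2", "b2": "C2", "k3": "C3", "b3": "C3",
        "W4": "F4", "b4": "F4", "W5": "O5", "b5": "O5",
    }

    def copy(self) -> "CNNModel":
        return CNNModel(self.arch, **{k: v.copy() for k, v in self.params().items()})


def init_model(
    arch: CNNArchitecture, seed: int = 0, init_mode: str = "inv_sqrt"
) -> CNNModel:
    """Uniform initialisation in ±1/sqrt(fan_in) per neuron (LeCun style).

    ``init_mode="inv"`` uses ±1/fan_in instead.
    """
    arch.validate()
    rng = np.random.default_rng(seed)
    fans = arch.fan_in()

    def bound(layer: str) -> float:
        n = fans[layer]
        return 1.0 / np.sqrt(n) if init_mode == "inv_sqrt" else 1.0 / n

    def u(layer: str, shape) -> np.ndarray:
        b = bound(layer)
        return rng.uniform(-b, b, shape)

    a = arch
    return CNNModel(
        arch=arch,
        k2=u("C2", (a.c2_filters, a.n_channels)),
        b2=u("C2", (a.c2_filters,)),
        k3=u("C3", (a.c2_filters, a.c3_filters_per_map, a.c3_kernel)),
        b3=u("C3", (a.c2_filters, a.c3_filters_per_map)),
        W4=u("F4", (a.f4_units, a.f4_fan_in)),
        b4=u("F4", (a.f4_units,)),
        W5=u("O5", (a.o5_units, a.f4_units)),
        b5=u("O5", (a.o5_units,)),
    )


# ---------------------------------------------------------------------------
# Forward / loss / backward
# ---------------------------------------------------------------------------

def _scaled_tanh(x: np.ndarray) -> np.ndarray:
    return TANH_A * np.tanh(TANH_B * x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def forward(model: CNNModel, windows: np.ndarray) -> tuple[np.ndarray, dict]:
    """Batched forward pass.

    ``windows`` is (N, 6, T) or a single (6, T) matrix. Returns the O5
    class scores (N, 4) and the cached layer activations needed by
    :func:`backward`.
    """
    a = model.arch
    X = np.asarray(windows, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if X.shape[1:] != (a.n_channels, a.T):
        raise ValueError(
            f"expected windows of shape (6, {a.T}), got {X.shape[1:]}"
        )
    Xs = X * a.input_scale

    # C2: spatial projection at each time point
    x2 = np.einsum("nct,pc->npt", Xs, model.k2, optimize=True) + model.b2[None, :, None]
    y2 = _scaled_tanh(x2)

    # C3: non-overlapping stride-10 temporal convolution
    S = a.c3_len
    y2r = y2.reshape(X.shape[0], a.c2_filters, S, a.c3_stride)
    x3 = (
        np.einsum("npsj,pfj->npfs", y2r, model.k3, optimize=True)
        + model.b3[None, :, :, None]
    )
    y3 = _scaled_tanh(x3)
    y3f = y3.reshape(X.shape[0], a.f4_fan_in)

    # dense classifier
    x4 = y3f @ model.W4.T + model.b4
    y4 = _sigmoid(x4)
    x5 = y4 @ model.W5.T + model.b5
    y5 = _softmax(x5) if a.output_activation == "softmax" else _sigmoid(x5)

    cache = {"Xs": Xs, "y2": y2, "y2r": y2r, "y3": y3, "y3f": y3f, "y4": y4, "y5": y5}
    scores = y5[0] if single else y5
    return scores, cache


def _one_hot(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out


def loss(scores: np.ndarray, labels: np.ndarray, kind: str = "mse") -> float:
    """Batch loss: mean over samples and output units.

    ``mse`` (default) pairs with sigmoid outputs; ``cross_entropy``
    pairs with softmax outputs.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    target = _one_hot(labels, scores.shape[1])
    if kind == "mse":
        return float(np.mean((scores - target) ** 2))
    if kind == "cross_entropy":
        p = np.clip(scores, 1e-12, 1.0)
        return float(-np.mean(np.sum(target * np.log(p), axis=1)))
    raise ValueError("loss kind must be 'mse' or 'cross_entropy'")


def backward(
    model: CNNModel, cache: dict, labels: np.ndarray, kind: str = "mse"
) -> dict[str, np.ndarray]:
    """Exact gradients of the batch loss for every weight and bias.

    Convolutional gradients are accumulated over all positions sharing a
    kernel (weight sharing).
    """
    a = model.arch
    y5, y4, y3f, y2r, Xs = (
        cache["y5"], cache["y4"], cache["y3f"], cache["y2r"], cache["Xs"],
    )
    N = y5.shape[0]
    target = _one_hot(labels, a.o5_units)

    if kind == "mse":
        # dL/dy5 then through the sigmoid
        d5 = (2.0 * (y5 - target) / (a.o5_units * N)) * y5 * (1.0 - y5)
    elif kind == "cross_entropy":
        d5 = (y5 - target) / N  # softmax + CE shortcut
    else:
        raise ValueError("loss kind must be 'mse' or 'cross_entropy'")

    gW5 = d5.T @ y4
    gb5 = d5.sum(axis=0)

    d4 = (d5 @ model.W5) * y4 * (1.0 - y4)
    gW4 = d4.T @ y3f
    gb4 = d4.sum(axis=0)

    dy3 = (d4 @ model.W4).reshape(N, a.c2_filters, a.c3_filters_per_map, a.c3_len)
    y3 = cache["y3"]
    d3 = dy3 * TANH_B * (TANH_A ** 2 - y3 ** 2) / TANH_A
    gk3 = np.einsum("npfs,npsj->pfj", d3, y2r, optimize=True)
    gb3 = d3.sum(axis=(0, 3))

    dy2r = np.einsum("npfs,pfj->npsj", d3, model.k3, optimize=True)
    dy2 = dy2r.reshape(N, a.c2_filters, a.T)
    y2 = cache["y2"]
    d2 = dy2 * TANH_B * (TANH_A ** 2 - y2 ** 2) / TANH_A
    gk2 = np.einsum("npt,nct->pc", d2, Xs, optimize=True)
    gb2 = d2.sum(axis=(0, 2))

    return {
        "k2": gk2, "b2": gb2, "k3": gk3, "b3": gb3,
        "W4": gW4, "b4": gb4, "W5": gW5, "b5": gb5,
    }


def layer_rates(arch: CNNArchitecture, lam: float) -> dict[str, float]:
    """Per-layer learning rates from the base rate ``lam``."""
    if lam <= 0:
        raise ValueError("base learning rate must be positive")
    fans = arch.fan_in()
    shared = arch.n_shared()
    rates = {}
    for layer in ("C2", "C3"):
        rates[layer] = 2.0 * lam / (shared[layer] * np.sqrt(fans[layer]))
    for layer in ("F4", "O5"):
        rates[layer] = lam / np.sqrt(fans[layer])
    return rates


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    base_rate: float = 0.05
    max_iterations: int = 10_000
    eval_interval: int = 10
    batch_size: int | None = None  # None = full batch (deterministic default)
    loss_kind: str = "mse"
    seed: int = 0


@dataclass
class TrainHistory:
    iterations: np.ndarray
    train_loss: np.ndarray
    val_iterations: np.ndarray
    val_loss: np.ndarray
    best_iteration: int
    best_val_loss: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iteration": self.iterations, "train_loss": self.train_loss}
        )


def windows_to_arrays(windows: Sequence[Window]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([w.matrix for w in windows])
    y = np.array([w.label for w in windows], dtype=int)
    return X, y


def train(
    model: CNNModel,
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> tuple[CNNModel, TrainHistory]:
    """Gradient-descent training with validation-loss model selection.

    One iteration is one gradient step on the full training batch (or on
    a mini-batch when ``cfg.batch_size`` is set). The validation loss is
    evaluated every ``eval_interval`` iterations and the parameters at
    its first strict minimum are returned alongside the loss history.
    """
    cfg = cfg or TrainConfig()
    if len(train_X) == 0 or len(val_X) == 0:
        raise ValueError("training and validation sets must be non-empty")
    rates = layer_rates(model.arch, cfg.base_rate)
    model = model.copy()
    rng = np.random.default_rng(cfg.seed)

    iters, tr_losses, val_iters, val_losses = [], [], [], []
    best = model.copy()
    best_val = np.inf
    best_iter = 0

    for it in range(1, cfg.max_iterations + 1):
        if cfg.batch_size is None:
            bX, by = train_X, train_y
        else:
            idx = rng.choice(len(train_X), size=cfg.batch_size, replace=False)
            bX, by = train_X[idx], train_y[idx]
        scores, cache = forward(model, bX)
        l = loss(scores, by, cfg.loss_kind)
        if not np.isfinite(l):
            raise TrainingError(f"training diverged (non-finite loss) at iteration {it}")
        grads = backward(model, cache, by, cfg.loss_kind)
        for name, p in model.params().items():
            p -= rates[CNNModel.PARAM_LAYER[name]] * grads[name]
        iters.append(it)
        tr_losses.append(l)

        if it % cfg.eval_interval == 0 or it == cfg.max_iterations:
            v_scores, _ = forward(model, val_X)
            v = loss(v_scores, val_y, cfg.loss_kind)
            if not np.isfinite(v):
                raise TrainingError(
                    f"validation loss non-finite at iteration {it}"
                )
            val_iters.append(it)
            val_losses.append(v)
            if v < best_val:
                best_val = v
                best = model.copy()
                best_iter = it

    history = TrainHistory(
        iterations=np.array(iters),
        train_loss=np.array(tr_losses),
        val_iterations=np.array(val_iters),
        val_loss=np.array(val_losses),
        best_iteration=best_iter,
        best_val_loss=float(best_val),
    )
    return best, history


def predict(
    model: CNNModel, windows: np.ndarray | Sequence[Window]
) -> tuple[np.ndarray, np.ndarray]:
    """Class labels (argmax of the four O5 scores; ties -> lowest index)
    and the raw scores for ROC analysis."""
    if len(windows) and isinstance(windows[0], Window):
        windows, _ = windows_to_arrays(windows)
    scores, _ = forward(model, np.asarray(windows, dtype=float))
    scores = np.atleast_2d(scores)
    return scores.argmax(axis=1), scores


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_model(model: CNNModel, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "T": model.arch.T,
        "input_scale": model.arch.input_scale,
        "output_activation": model.arch.output_activation,
    }
    np.savez(path, _meta=json.dumps(meta), **model.params())
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> CNNModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["_meta"]))
        arch = CNNArchitecture(
            T=int(meta["T"]),
            input_scale=float(meta["input_scale"]),
            output_activation=meta["output_activation"],
        )
        params = {k: archive[k] for k in CNNModel.PARAM_LAYER}
    return CNNModel(arch=arch, **params)
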