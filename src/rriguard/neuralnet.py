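"""One-hidden-layer autoencoder / denoising autoencoder on 4-beat RRI windows.

The network maps a 4-vector of (centered) RRIs through ``h`` hidden units to
a 4-vector reconstruction:

    x_hat = s * ( W2 . act(W1 . (x / s) + b1) + b2 )

with an identity output layer.  ``s`` is a fixed input scale (ms) that keeps
pre-activations of physiological windows inside the responsive range of the
sigmoid; it is part of the model and round-trips through serialization.

Training minimises the L2-regularised mean squared reconstruction error

    J = (1/N) * sum_n ||x_target_n - x_hat_n||^2  +  lambda * Omega_L2

where ``Omega_L2`` is the sum of squared weights (biases excluded).  For a
plain autoencoder input and target coincide; for the denoising variants the
inputs are contaminated windows and the targets their clean counterparts.

Hidden-layer sizes and activations are fixed per role: the detection AE uses
3 sigmoid units, the PVC/PAC repair DAEs 2 ReLU units, and the detection-
error repair DAE 8 sigmoid units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .rri_data import WINDOW

_SCHEMA_VERSION = 1

#: role -> (hidden units, hidden activation)
ROLE_ARCH = {
    "AE": (3, "sigmoid"),
    "DAE_PVC": (2, "relu"),
    "DAE_PAC": (2, "relu"),
    "DAE_RDE": (8, "sigmoid"),
}

#: Default input scale in ms; centered windows divided by this stay O(1).
INPUT_SCALE = 100.0

__all__ = [
    "ROLE_ARCH",
    "INPUT_SCALE",
    "AEModel",
    "TrainConfig",
    "init_model",
    "forward",
    "cost",
    "gradients",
    "train",
    "reconstruction_error",
    "save_model",
    "load_model",
]


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "relu":
        return np.maximum(z, 0.0)
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "relu":
        return (z > 0.0).astype(float)
    raise ValueError(f"unknown activation {kind!r}")


@dataclass
class AEModel:
    """Weights and metadata of a trained (denoising) autoencoder."""

    W1: np.ndarray  # (h, 4)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (4, h)
    b2: np.ndarray  # (4,)
    hidden_activation: str
    role: str
    lambda_l2: float = 1e-4
    input_scale: float = INPUT_SCALE
    column_means: np.ndarray = field(
        default_factory=lambda: np.zeros(WINDOW)
    )

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        self.column_means = np.asarray(self.column_means, dtype=float)
        h = self.W1.shape[0]
        if self.W1.shape != (h, WINDOW) or self.W2.shape != (WINDOW, h):
            raise ValueError("inconsistent weight shapes")
        if self.b1.shape != (h,) or self.b2.shape != (WINDOW,):
            raise ValueError("inconsistent bias shapes")
        if self.role not in ROLE_ARCH:
            raise ValueError(f"unknown role {self.role!r}")
        if self.hidden_activation not in ("sigmoid", "relu"):
            raise ValueError(f"unknown activation {self.hidden_activation!r}")

    @property
    def n_hidden(self) -> int:
        return int(self.W1.shape[0])


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 2000
    learning_rate: float = 1e-2
    lambda_l2: float = 1e-4
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.learning_rate <= 0 or self.lambda_l2 < 0:
            raise ValueError("epochs and learning_rate must be positive")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5]")


def init_model(role: str, seed: int = 0, lambda_l2: float = 1e-4) -> AEModel:
    """Glorot-uniform initialised model of the architecture fixed for ``role``."""
    if role not in ROLE_ARCH:
        raise ValueError(f"unknown role {role!r}")
    h, activation = ROLE_ARCH[role]
    rng = np.random.default_rng(seed)
    lim1 = np.sqrt(6.0 / (WINDOW + h))
    W1 = rng.uniform(-lim1, lim1, size=(h, WINDOW))
    W2 = rng.uniform(-lim1, lim1, size=(WINDOW, h))
    return AEModel(
        W1=W1,
        b1=np.zeros(h),
        W2=W2,
        b2=np.zeros(WINDOW),
        hidden_activation=activation,
        role=role,
        lambda_l2=lambda_l2,
    )


def forward(model: AEModel, x: np.ndarray) -> np.ndarray:
    """Reconstruct one window or a batch of windows (rows)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to forward pass")
    single = x.ndim == 1
    u = np.atleast_2d(x) / model.input_scale
    z1 = u @ model.W1.T + model.b1
    a1 = _act(z1, model.hidden_activation)
    z2 = a1 @ model.W2.T + model.b2
    out = z2 * model.input_scale
    return out[0] if single else out


def cost(model: AEModel, X_in: np.ndarray, X_target: np.ndarray) -> float:
    """Mean squared reconstruction error plus L2 weight penalty (ms^2)."""
    X_in = np.atleast_2d(np.asarray(X_in, dtype=float))
    X_target = np.atleast_2d(np.asarray(X_target, dtype=float))
    if X_in.shape != X_target.shape:
        raise ValueError("input and target batches must have equal shape")
    if X_in.shape[0] < 1:
        raise ValueError("need at least one sample")
    X_hat = forward(model, X_in)
    mse = float(np.sum((X_target - X_hat) ** 2) / X_in.shape[0])
    omega = float(np.sum(model.W1**2) + np.sum(model.W2**2))
    return mse + model.lambda_l2 * omega


def gradients(
    model: AEModel, X_in: np.ndarray, X_target: np.ndarray
) -> dict[str, np.ndarray]:
    """Analytic gradients of :func:`cost` w.r.t. W1, b1, W2, b2."""
    X_in = np.atleast_2d(np.asarray(X_in, dtype=float))
    X_target = np.atleast_2d(np.asarray(X_target, dtype=float))
    n = X_in.shape[0]
    s = model.input_scale
    u = X_in / s
    v = X_target / s
    z1 = u @ model.W1.T + model.b1
    a1 = _act(z1, model.hidden_activation)
    z2 = a1 @ model.W2.T + model.b2
    # d cost / d z2; the s^2 restores ms^2 units of the squared error
    dz2 = (2.0 * s * s / n) * (z2 - v)
    gW2 = dz2.T @ a1 + 2.0 * model.lambda_l2 * model.W2
    gb2 = dz2.sum(axis=0)
    da1 = dz2 @ model.W2
    dz1 = da1 * _act_grad(z1, a1, model.hidden_activation)
    gW1 = dz1.T @ u + 2.0 * model.lambda_l2 * model.W1
    gb1 = dz1.sum(axis=0)
    return {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2}


def train(
    X_in: np.ndarray,
    X_target: np.ndarray,
    role: str,
    cfg: TrainConfig = TrainConfig(),
    column_means: np.ndarray | None = None,
) -> AEModel:
    """Full-batch Adam training of a fresh model of the given role.

    A validation split is carved off deterministically; training fails loudly
    if the cost diverges or the final held-out cost does not improve on the
    initial one.  An unlucky initialisation (e.g. all ReLU units dead) is
    retried with up to two further derived init seeds before giving up.
    """
    X_in = np.atleast_2d(np.asarray(X_in, dtype=float))
    X_target = np.atleast_2d(np.asarray(X_target, dtype=float))
    if X_in.shape != X_target.shape:
        raise ValueError("input and target batches must have equal shape")
    if X_in.shape[0] < 10:
        raise ValueError("need at least 10 training windows")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(X_in.shape[0])
    n_val = max(1, int(round(cfg.validation_fraction * X_in.shape[0])))
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xi, Xt = X_in[train_idx], X_target[train_idx]
    Vi, Vt = X_in[val_idx], X_target[val_idx]

    val_cost_init = val_cost_final = np.nan
    for attempt in range(3):
        model = init_model(
            role, seed=cfg.seed + 7919 * attempt, lambda_l2=cfg.lambda_l2
        )
        if column_means is not None:
            model.column_means = np.asarray(column_means, dtype=float)
        val_cost_init = cost(model, Vi, Vt)

        params = {"W1": model.W1, "b1": model.b1, "W2": model.W2, "b2": model.b2}
        m = {k: np.zeros_like(v) for k, v in params.items()}
        v2 = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        for step in range(1, cfg.epochs + 1):
            g = gradients(model, Xi, Xt)
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * g[k]
                v2[k] = beta2 * v2[k] + (1 - beta2) * g[k] ** 2
                mhat = m[k] / (1 - beta1**step)
                vhat = v2[k] / (1 - beta2**step)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            if step % 200 == 0 or step == cfg.epochs:
                j = cost(model, Xi, Xt)
                if not np.isfinite(j):
                    raise FloatingPointError(
                        f"training diverged (cost={j}) at learning rate "
                        f"{cfg.learning_rate}; reduce it"
                    )
        val_cost_final = cost(model, Vi, Vt)
        if val_cost_final < val_cost_init:
            return model
    raise RuntimeError(
        "training did not reduce held-out cost after 3 restarts "
        f"({val_cost_init:.3g} -> {val_cost_final:.3g})"
    )


def reconstruction_error(model: AEModel, x: np.ndarray) -> float | np.ndarray:
    """Euclidean distance between a window and its reconstruction (ms)."""
    x = np.asarray(x, dtype=float)
    x_hat = forward(model, x)
    if x.ndim == 1:
        return float(np.linalg.norm(x - x_hat))
    return np.linalg.norm(x - x_hat, axis=1)


def save_model(model: AEModel, path) -> None:
    """Serialise to a single JSON file (schema-versioned, lossless)."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "role": model.role,
        "hidden_activation": model.hidden_activation,
        "lambda_l2": model.lambda_l2,
        "input_scale": model.input_scale,
        "column_means": model.column_means.tolist(),
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> AEModel:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt model file {path}: {exc}") from exc
    version = payload.get("schema_version")
    if version != _SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version} unsupported (expected {_SCHEMA_VERSION})"
        )
    return AEModel(
        W1=np.array(payload["W1"]),
        b1=np.array(payload["b1"]),
        W2=np.array(payload["W2"]),
        b2=np.array(payload["b2"]),
        hidden_activation=payload["hidden_activation"],
        role=payload["role"],
        lambda_l2=payload["lambda_l2"],
        input_scale=payload["input_scale"],
        column_means=np.array(payload["column_means"]),
    )
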