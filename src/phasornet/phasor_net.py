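"""The phasor-feature regression network.

A small fully connected stack maps the standardized 4-vector
(g, s, tau_m, <tau>) to the biexponential parameters (a1, tau1, tau2).
The default architecture is 11 hidden layers of 6 sigmoid-activated
neurons (tanh by default; the logistic function is available as an
option) with a linear output layer.  Training minimizes the L2-penalized squared loss on
the natural-unit targets by full-batch L-BFGS; the penalty weight is
chosen from a small grid by validation relative squared error, several
random restarts are run, and the restart with the lowest validation error
is kept.  This plays the role of Bayesian-regularized training: the
contract is generalization on noisy decays, not a particular optimizer.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .decay_sim import BiexpParams, DecayHistogram, LabeledDataset
from .exceptions import ConfigurationError, InvalidParameterError, TrainingError
from .features import (
    FeatureScaler,
    PhasorFeatures,
    apply_scaler,
    extract_features_batch,
    fit_scaler,
)

__all__ = [
    "NetConfig",
    "TrainConfig",
    "TrainedModel",
    "build_network",
    "n_parameters",
    "train",
    "train_on_features",
    "predict",
    "relative_squared_error",
    "layer_sweep",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetConfig:
    """Architecture of the dense regression stack (4 -> width x layers -> 3)."""

    n_hidden_layers: int = 11
    width: int = 6
    hidden_activation: str = "tanh"
    n_inputs: int = 4
    n_outputs: int = 3

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1 or self.width < 1:
            raise ConfigurationError("need n_hidden_layers >= 1 and width >= 1")
        if self.hidden_activation not in ("logistic", "tanh"):
            raise ConfigurationError(
                f"unknown hidden_activation {self.hidden_activation!r}"
            )

    def layer_sizes(self) -> list[int]:
        return [self.n_inputs] + [self.width] * self.n_hidden_layers + [self.n_outputs]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: validation split, restarts, penalty grid, optimizer caps.

    ``polish_iters`` Gauss-Newton (Levenberg-Marquardt) iterations refine
    the restart selected by validation error; 0 disables the polish.
    """

    validation_fraction: float = 0.15
    n_restarts: int = 6
    l2_grid: tuple[float, ...] = (1e-8, 1e-6)
    max_iter: int = 2500
    polish_iters: int = 60
    tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ConfigurationError("validation_fraction must be in (0, 1)")
        if self.n_restarts < 1:
            raise ConfigurationError("n_restarts must be >= 1")
        if len(self.l2_grid) < 1 or any(l < 0 for l in self.l2_grid):
            raise ConfigurationError("l2_grid must be non-empty and non-negative")


@dataclass
class TrainedModel:
    """Layer weights, the input scaler and training metadata."""

    weights: list[tuple[np.ndarray, np.ndarray]]
    scaler: FeatureScaler
    net_config: NetConfig
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = self.net_config.layer_sizes()
        if len(self.weights) != len(sizes) - 1:
            raise ConfigurationError("weight count inconsistent with architecture")
        for i, (W, b) in enumerate(self.weights):
            if W.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],):
                raise ConfigurationError(f"layer {i} weight shapes inconsistent")


# ---------------------------------------------------------------------------
# Construction and forward/backward passes


def n_parameters(cfg: NetConfig) -> int:
    sizes = cfg.layer_sizes()
    return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


def build_network(
    cfg: NetConfig | None = None, seed: int | np.random.Generator = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministically initialized (W, b) pairs for each dense layer.

    Glorot-uniform with gain 4 for logistic hidden layers (the logistic
    slope at the origin is 1/4), gain 1 for tanh and the linear output.
    """
    cfg = cfg or NetConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = cfg.layer_sizes()
    gain_hidden = 4.0 if cfg.hidden_activation == "logistic" else 1.0
    weights = []
    for i in range(len(sizes) - 1):
        gain = gain_hidden if i < len(sizes) - 2 else 1.0
        limit = gain * np.sqrt(6.0 / (sizes[i] + sizes[i + 1]))
        W = rng.uniform(-limit, limit, size=(sizes[i], sizes[i + 1]))
        b = np.zeros(sizes[i + 1])
        weights.append((W, b))
    return weights


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-z))
    return np.tanh(z)


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return a * (1.0 - a)
    return 1.0 - a * a


def _forward(weights, X, kind):
    a = X
    for W, b in weights[:-1]:
        a = _act(a @ W + b, kind)
    W, b = weights[-1]
    return a @ W + b


def _pack(weights) -> np.ndarray:
    return np.concatenate([np.concatenate([W.ravel(), b]) for W, b in weights])

def _unpack(vec, sizes):
    weights, k = [], 0
    for i in range(len(sizes) - 1):
        nw = sizes[i] * sizes[i + 1]
        W = vec[k : k + nw].reshape(sizes[i], sizes[i + 1])
        k += nw
        b = vec[k : k + sizes[i + 1]]
        k += sizes[i + 1]
        weights.append((W, b))
    return weights


def _loss_and_grad(vec, X, Y, lam, sizes, kind):
    """Mean squared error + lam * sum(W^2) (biases unpenalized), with gradient."""
    weights = _unpack(vec, sizes)
    acts = [X]
    a = X
    for W, b in weights[:-1]:
        a = _act(a @ W + b, kind)
        acts.append(a)
    Wl, bl = weights[-1]
    out = a @ Wl + bl
    resid = out - Y
    n = X.shape[0] * Y.shape[1]
    loss = float((resid**2).sum() / n) + lam * sum(
        float((W**2).sum()) for W, _ in weights
    )

    grads = [None] * len(weights)
    delta = 2.0 * resid / n
    grads[-1] = (acts[-1].T @ delta + 2.0 * lam * Wl, delta.sum(axis=0))
    for i in range(len(weights) - 2, -1, -1):
        delta = (delta @ weights[i + 1][0].T) * _act_grad(acts[i + 1], kind)
        grads[i] = (acts[i].T @ delta + 2.0 * lam * weights[i][0], delta.sum(axis=0))
    return loss, _pack(grads)


# ---------------------------------------------------------------------------
# Gauss-Newton / Levenberg-Marquardt refinement


def _normal_equations(vec, X, Y, sizes, kind, chunk=4000):
    """Accumulate J^T J, J^T r and the residual sum of squares in chunks.

    Residuals are r = (out - Y) / sqrt(n_res); J is the exact network
    Jacobian assembled layer by layer via backpropagated output
    sensitivities.
    """
    weights = _unpack(vec, sizes)
    P = vec.size
    n_out = sizes[-1]
    scale = 1.0 / np.sqrt(X.shape[0] * n_out)
    H = np.zeros((P, P))
    g = np.zeros(P)
    sse = 0.0
    eye = np.eye(n_out)
    for lo in range(0, X.shape[0], chunk):
        Xc, Yc = X[lo : lo + chunk], Y[lo : lo + chunk]
        n = Xc.shape[0]
        acts = [Xc]
        a = Xc
        for W, b in weights[:-1]:
            a = _act(a @ W + b, kind)
            acts.append(a)
        Wl, bl = weights[-1]
        out = a @ Wl + bl
        r = ((out - Yc) * scale).reshape(n * n_out)
        sse += float(r @ r)
        # output sensitivities D_l = d out / d z_l, shape (n, n_out, h_l)
        D = np.broadcast_to(eye, (n, n_out, n_out)).copy()
        blocks = [None] * len(weights)
        for l in range(len(weights) - 1, -1, -1):
            JW = np.einsum("ip,ioq->iopq", acts[l], D)
            blocks[l] = np.concatenate(
                [JW.reshape(n, n_out, -1), D], axis=2
            )
            if l > 0:
                D = (
                    np.einsum("ioq,pq->iop", D, weights[l][0])
                    * _act_grad(acts[l], kind)[:, None, :]
                )
        J = (np.concatenate(blocks, axis=2) * scale).reshape(n * n_out, P)
        H += J.T @ J
        g += J.T @ r
    return H, g, sse


def _weight_mask(sizes):
    """1 for weight entries, 0 for biases, in packed order."""
    parts = []
    for i in range(len(sizes) - 1):
        parts.append(np.ones(sizes[i] * sizes[i + 1]))
        parts.append(np.zeros(sizes[i + 1]))
    return np.concatenate(parts)


def _polish(vec, X, Y, lam, sizes, kind, max_iter=60, tol=1e-12):
    """Levenberg-Marquardt refinement of a trained weight vector."""
    mask = _weight_mask(sizes)
    w = vec.copy()

    def objective(v):
        out = _forward(_unpack(v, sizes), X, kind)
        return float(((out - Y) ** 2).mean()) + lam * float((v**2 * mask).sum())

    f = objective(w)
    mu = 1e-4
    for _ in range(max_iter):
        H, g, _ = _normal_equations(w, X, Y, sizes, kind)
        H2 = 2.0 * H + 2.0 * lam * np.diag(mask)
        g2 = 2.0 * g + 2.0 * lam * mask * w
        if np.max(np.abs(g2)) < 1e-12:
            break
        improved = False
        d = np.diag(H2).copy()
        d[d <= 0] = 1.0
        while mu < 1e10:
            try:
                step = np.linalg.solve(H2 + mu * np.diag(d), -g2)
            except np.linalg.LinAlgError:
                mu *= 4.0
                continue
            f_new = objective(w + step)
            if np.isfinite(f_new) and f_new < f:
                w = w + step
                gain = f - f_new
                f = f_new
                mu = max(mu / 3.0, 1e-12)
                improved = True
                if gain < tol * max(f, 1.0):
                    return w
                break
            mu *= 4.0
        if not improved:
            break
    return w


# ---------------------------------------------------------------------------
# Metrics


def relative_squared_error(predictions, truths) -> float:
    """Mean over samples and outputs of ((y_hat - y) / y)^2.

    Entries with a zero target are excluded with a warning (they cannot
    occur for physical biexponential parameters).
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(truths, dtype=float)
    if p.shape != y.shape:
        raise ConfigurationError("predictions and truths must have equal shapes")
    mask = y != 0
    if not mask.all():
        warnings.warn("zero targets excluded from relative squared error")
    if not mask.any():
        raise ConfigurationError("all targets are zero")
    return float((((p[mask] - y[mask]) / y[mask]) ** 2).mean())


# ---------------------------------------------------------------------------
# Training


def train_on_features(
    X: np.ndarray,
    Y: np.ndarray,
    net_cfg: NetConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Train on a precomputed raw feature matrix and target triples.

    Splits off the validation fraction, standardizes inputs with a scaler
    fit on the training split only, minimizes the penalized squared loss
    for every (penalty, restart) combination and keeps the weights with
    the lowest validation relative squared error.
    """
    net_cfg = net_cfg or NetConfig()
    train_cfg = train_cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape[1] != net_cfg.n_inputs:
        raise ConfigurationError(f"X must be (n, {net_cfg.n_inputs})")
    if Y.shape != (X.shape[0], net_cfg.n_outputs):
        raise ConfigurationError(f"Y must be (n, {net_cfg.n_outputs})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ConfigurationError("non-finite entries in training data")

    n = X.shape[0]
    ss = np.random.SeedSequence(train_cfg.seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    perm = split_rng.permutation(n)
    n_val = max(1, int(round(train_cfg.validation_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if tr_idx.size == 0:  # tiny datasets: validate on the training points
        tr_idx, val_idx = perm, perm

    scaler = fit_scaler(X[tr_idx])
    Xtr, Xval = apply_scaler(X[tr_idx], scaler), apply_scaler(X[val_idx], scaler)
    Yval = Y[val_idx]
    # Targets are standardized for the loss so the three outputs carry
    # comparable weight; the inverse transform is folded back into the
    # linear output layer afterwards, so trained models stay natural-unit.
    y_mean = Y[tr_idx].mean(axis=0)
    y_std = Y[tr_idx].std(axis=0)
    if np.any(y_std <= 0):
        y_std = np.where(y_std <= 0, 1.0, y_std)
    Ytr = (Y[tr_idx] - y_mean) / y_std
    sizes = net_cfg.layer_sizes()

    def denormalized(weights):
        (W, b), rest = weights[-1], weights[:-1]
        return rest + [(W * y_std, b * y_std + y_mean)]

    init_seeds = ss.spawn(len(train_cfg.l2_grid) * train_cfg.n_restarts)
    best = None
    k = 0
    for lam in train_cfg.l2_grid:
        for restart in range(train_cfg.n_restarts):
            w0 = _pack(build_network(net_cfg, np.random.default_rng(init_seeds[k])))
            k += 1
            res = minimize(
                _loss_and_grad,
                w0,
                args=(Xtr, Ytr, lam, sizes, net_cfg.hidden_activation),
                jac=True,
                method="L-BFGS-B",
                options={
                    "maxiter": train_cfg.max_iter,
                    "maxfun": 3 * train_cfg.max_iter,
                    "ftol": train_cfg.tol,
                    "gtol": 1e-10,
                    "maxcor": 40,
                },
            )
            vec = res.x
            if train_cfg.polish_iters > 0:
                vec = _polish(
                    vec,
                    Xtr,
                    Ytr,
                    lam,
                    sizes,
                    net_cfg.hidden_activation,
                    max_iter=train_cfg.polish_iters,
                )
            w = denormalized(_unpack(vec, sizes))
            pred = _forward(w, Xval, net_cfg.hidden_activation)
            try:
                val_rse = relative_squared_error(pred, Yval)
            except ConfigurationError:
                continue
            if np.isfinite(val_rse) and (best is None or val_rse < best[0]):
                best = (val_rse, lam, restart, vec)
    if best is None:
        raise TrainingError("no restart produced a finite validation error")

    val_rse, lam, restart, vec = best
    w = denormalized(_unpack(vec, sizes))
    meta = {
        "seed": train_cfg.seed,
        "validation_rse": val_rse,
        "l2": lam,
        "restart": restart,
        "n_train": int(tr_idx.size),
        "n_val": int(val_idx.size),
    }
    return TrainedModel([(W.copy(), b.copy()) for W, b in w], scaler, net_cfg, meta)


def train(
    dataset: LabeledDataset,
    net_cfg: NetConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> TrainedModel:
    """Extract features from a simulated dataset and train the network on them."""
    X = extract_features_batch(dataset.counts, dataset.config)
    model = train_on_features(X, dataset.params, net_cfg, train_cfg)
    model.metadata["n_samples"] = len(dataset)
    model.metadata["dataset_seed"] = dataset.seed
    model.metadata["snr_nominal"] = dataset.snr_nominal
    return model


# ---------------------------------------------------------------------------
# Prediction


def _postprocess(raw: np.ndarray) -> np.ndarray:
    """Clip to physical ranges and sort lifetimes (complementing a1 on swap)."""
    out = raw.copy()
    out[:, 0] = np.clip(out[:, 0], 0.0, 1.0)
    out[:, 1:] = np.maximum(out[:, 1:], 1e-3)
    swap = out[:, 1] > out[:, 2]
    out[swap, 0] = 1.0 - out[swap, 0]
    out[swap, 1], out[swap, 2] = raw[swap, 2], np.maximum(raw[swap, 1], 1e-3)
    return out


def predict(model: TrainedModel, x):
    """Estimate (a1, tau1, tau2) from features or a decay histogram.

    Accepts a :class:`PhasorFeatures`, a length-4 vector, an (n, 4) feature
    matrix, or a :class:`DecayHistogram` (features are extracted first).
    Returns a :class:`BiexpParams` for single inputs, an (n, 3) array for
    batches.  Outputs are clipped to physical ranges with tau1 <= tau2.
    """
    single = True
    if isinstance(x, DecayHistogram):
        X = extract_features_batch(x.counts[None, :], x.config)
    elif isinstance(x, PhasorFeatures):
        X = x.as_array()[None, :]
    else:
        X = np.asarray(x, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
    if X.shape[1] != model.net_config.n_inputs:
        raise ConfigurationError("feature dimension mismatch")
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("non-finite features")
    raw = _forward(
        model.weights, apply_scaler(X, model.scaler), model.net_config.hidden_activation
    )
    out = _postprocess(raw)
    if single:
        a1, t1, t2 = out[0]
        return BiexpParams(min(max(a1, 1e-9), 1.0), t1, t2)
    return out


# ---------------------------------------------------------------------------
# Architecture sweep


def layer_sweep(
    dataset: LabeledDataset,
    layer_counts=(5, 7, 9, 11, 13, 15, 17),
    width: int = 6,
    train_cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Validation error and wall time versus hidden-layer count.

    Trains one network per entry of ``layer_counts`` under identical data
    and seeds; returns a DataFrame with columns ``layers``, ``n_params``,
    ``validation_rse`` and ``train_seconds``.
    """
    train_cfg = train_cfg or TrainConfig()
    X = extract_features_batch(dataset.counts, dataset.config)
    rows = []
    for layers in layer_counts:
        cfg = NetConfig(n_hidden_layers=layers, width=width)
        t0 = time.perf_counter()
        model = train_on_features(X, dataset.params, cfg, train_cfg)
        rows.append(
            {
                "layers": layers,
                "n_params": n_parameters(cfg),
                "validation_rse": model.metadata["validation_rse"],
                "train_seconds": time.perf_counter() - t0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Persistence (single JSON archive)


def save_model(model: TrainedModel, path: str | Path) -> None:
    doc = {
        "net_config": {
            "n_hidden_layers": model.net_config.n_hidden_layers,
            "width": model.net_config.width,
            "hidden_activation": model.net_config.hidden_activation,
            "n_inputs": model.net_config.n_inputs,
            "n_outputs": model.net_config.n_outputs,
        },
        "scaler": model.scaler.to_dict(),
        "weights": [[W.tolist(), b.tolist()] for W, b in model.weights],
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    cfg = NetConfig(**doc["net_config"])
    weights = [(np.asarray(W), np.asarray(b)) for W, b in doc["weights"]]
    return TrainedModel(weights, FeatureScaler.from_dict(doc["scaler"]), cfg, doc["metadata"])
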