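"""Multilayer perceptrons on raw time-domain epochs, trained by SCG.

No feature extraction happens anywhere in this package: one flattened
epoch (channel-major, channels x samples values) is the network input, so
the first hidden layer is free to learn spatial and temporal filters
jointly.  Hidden layers use tanh; the output layer is either
softmax + cross-entropy (default) or tanh + sum-of-squares.  Training is
Møller's scaled conjugate gradient (SCG) — a conjugate-gradient
backpropagation that sidesteps line searches via a scaled model-trust
update — with early stopping on validation kappa.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import cohens_kappa_labels

__all__ = [
    "MAX_LAYERS",
    "MAX_NEURONS",
    "Architecture",
    "NetworkModel",
    "TrainConfig",
    "TrainingTrace",
    "init_network",
    "forward",
    "predict_class",
    "loss_and_gradient",
    "scg_train",
    "stratified_split",
    "save_model",
    "load_model",
]

MAX_LAYERS = 3
MAX_NEURONS = 500

SOFTMAX_XENT = "SOFTMAX_XENT"
TANH_SSE = "TANH_SSE"


@dataclass(frozen=True)
class Architecture:
    """Hidden-layer specification: 1-3 layers of 1-500 neurons each."""

    hidden_sizes: tuple[int, ...]

    def __init__(self, hidden_sizes: Sequence[int]):
        sizes = tuple(int(h) for h in hidden_sizes)
        if not 1 <= len(sizes) <= MAX_LAYERS:
            raise ValueError(
                f"architecture must have 1..{MAX_LAYERS} hidden layers, "
                f"got {len(sizes)}"
            )
        for h in sizes:
            if not 1 <= h <= MAX_NEURONS:
                raise ValueError(
                    f"hidden sizes must lie in [1, {MAX_NEURONS}], got {h}"
                )
        object.__setattr__(self, "hidden_sizes", sizes)

    @property
    def n_layers(self) -> int:
        return len(self.hidden_sizes)


@dataclass
class NetworkModel:
    """A concrete MLP: layer sizes, parameters and training provenance."""

    input_dim: int
    hidden_sizes: tuple[int, ...]
    n_classes: int
    weights: list[np.ndarray]  # per layer, (fan_in, fan_out)
    biases: list[np.ndarray]   # per layer, (fan_out,)
    output_mode: str = SOFTMAX_XENT
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = [self.input_dim, *self.hidden_sizes, self.n_classes]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],):
                raise ValueError(
                    f"layer {i}: weight shape {w.shape} / bias shape "
                    f"{b.shape} inconsistent with sizes {sizes}"
                )
        if self.output_mode not in (SOFTMAX_XENT, TANH_SSE):
            raise ValueError(f"unknown output mode {self.output_mode!r}")

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            input_dim=self.input_dim,
            hidden_sizes=tuple(self.hidden_sizes),
            n_classes=self.n_classes,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            output_mode=self.output_mode,
            seed=self.seed,
            meta=copy.deepcopy(self.meta),
        )


@dataclass
class TrainConfig:
    """SCG training hyperparameters.

    ``scg_sigma`` and ``scg_lambda0`` are Møller's published defaults; the
    validation fraction and kappa-patience control early stopping.
    """

    max_iterations: int = 500
    val_fraction: float = 0.2
    patience: int = 6
    scg_sigma: float = 5e-5
    scg_lambda0: float = 5e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.patience < 1:
            raise ValueError("max_iterations and patience must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.scg_sigma <= 0 or self.scg_lambda0 <= 0:
            raise ValueError("SCG constants must be positive")


@dataclass
class TrainingTrace:
    """Per-iteration record of one SCG run."""

    train_loss: list[float] = field(default_factory=list)
    val_kappa: list[float] = field(default_factory=list)
    n_iterations: int = 0
    stopped_by: str = ""
    best_val_kappa: float = float("-inf")


# ---------------------------------------------------------------------------
# Construction and forward pass
# ---------------------------------------------------------------------------

def init_network(
    input_dim: int,
    arch: Architecture | Sequence[int],
    n_classes: int,
    seed: int = 0,
    output_mode: str = SOFTMAX_XENT,
) -> NetworkModel:
    """Glorot-uniform initialisation (range +/- sqrt(6/(fan_in+fan_out)))."""
    if not isinstance(arch, Architecture):
        arch = Architecture(arch)
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    sizes = [input_dim, *arch.hidden_sizes, n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkModel(
        input_dim=input_dim,
        hidden_sizes=arch.hidden_sizes,
        n_classes=n_classes,
        weights=weights,
        biases=biases,
        output_mode=output_mode,
        seed=seed,
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_pass(model: NetworkModel, X: np.ndarray):
    """Return (activations per layer, output scores)."""
    acts = [X]
    a = X
    n_layers = len(model.weights)
    for i in range(n_layers - 1):
        a = np.tanh(a @ model.weights[i] + model.biases[i])
        acts.append(a)
    z = a @ model.weights[-1] + model.biases[-1]
    if model.output_mode == SOFTMAX_XENT:
        out = _softmax(z)
    else:
        out = np.tanh(z)
    acts.append(out)
    return acts, out


def forward(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Class scores for flattened-epoch rows (softmax probs or tanh outputs)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"input width {X.shape[1]} != model input_dim {model.input_dim}"
        )
    _, out = _forward_pass(model, X)
    return out


def predict_class(model: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the output neurons; ties break to the lowest class index."""
    return np.argmax(forward(model, X), axis=1)


# ---------------------------------------------------------------------------
# Loss / gradient (backpropagation)
# ---------------------------------------------------------------------------

def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def loss_and_gradient(model: NetworkModel, X: np.ndarray, y: np.ndarray):
    """Mean loss over rows and its gradient w.r.t. all parameters.

    Returns ``(loss, grad_w, grad_b)`` with gradients shaped like
    ``model.weights`` / ``model.biases``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = len(y)
    acts, out = _forward_pass(model, X)
    T = _one_hot(y, model.n_classes)
    if model.output_mode == SOFTMAX_XENT:
        eps = 1e-300
        loss = -np.log(out[np.arange(n), y] + eps).mean()
        dz = (out - T) / n
    else:
        target = 2.0 * T - 1.0  # +1 / -1 coding
        loss = 0.5 * ((out - target) ** 2).sum(axis=1).mean()
        dz = (out - target) * (1.0 - out**2) / n
    grad_w = [np.empty_like(w) for w in model.weights]
    grad_b = [np.empty_like(b) for b in model.biases]
    delta = dz
    for i in range(len(model.weights) - 1, -1, -1):
        grad_w[i] = acts[i].T @ delta
        grad_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (1.0 - acts[i] ** 2)
    return loss, grad_w, grad_b


def _pack(weights, biases) -> np.ndarray:
    return np.concatenate([a.ravel() for pair in zip(weights, biases)
                           for a in pair])


def _unpack(model: NetworkModel, vec: np.ndarray) -> None:
    pos = 0
    for i, w in enumerate(model.weights):
        model.weights[i] = vec[pos : pos + w.size].reshape(w.shape)
        pos += w.size
        b = model.biases[i]
        model.biases[i] = vec[pos : pos + b.size].copy()
        pos += b.size


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def stratified_split(y: np.ndarray, val_fraction: float, seed: int):
    """Seeded stratified train/validation index split."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(y))
    train_idx, val_idx = train_test_split(
        idx, test_size=val_fraction, stratify=y, random_state=seed % (2**32)
    )
    return np.sort(train_idx), np.sort(val_idx)


def scg_train(
    model: NetworkModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    split: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[NetworkModel, TrainingTrace]:
    """Train by scaled conjugate gradient with kappa early stopping.

    The data is split (stratified, seeded) into a training portion that
    drives the SCG loss and an internal validation portion scored with
    Cohen's kappa after every weight update; the returned model is the
    snapshot with the best validation kappa.  ``split`` overrides the
    internal split with explicit ``(train_idx, val_idx)`` — used by the
    annealing loop so accept/reject decisions share one split.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if split is None:
        split = stratified_split(y, cfg.val_fraction, cfg.seed)
    tr, va = split
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]

    model = model.copy()
    trace = TrainingTrace()

    def f_and_g(vec):
        _unpack(model, vec)
        loss, gw, gb = loss_and_gradient(model, Xtr, ytr)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss ({loss}); input scale or "
                f"architecture {model.hidden_sizes} likely pathological"
            )
        return loss, _pack(gw, gb)

    def val_kappa(vec):
        _unpack(model, vec)
        pred = predict_class(model, Xva)
        return cohens_kappa_labels(yva, pred, model.n_classes)

    w = _pack(model.weights, model.biases)
    n_par = w.size

    # --- Møller's SCG state ---
    lam, lam_bar = cfg.scg_lambda0, 0.0
    f, r = f_and_g(w)
    r = -r
    p = r.copy()
    success = True
    delta = 0.0

    best_vec = w.copy()
    best_kappa = val_kappa(w)
    trace.val_kappa.append(best_kappa)
    trace.train_loss.append(f)
    fails = 0

    for k in range(cfg.max_iterations):
        p_norm2 = float(p @ p)
        if p_norm2 < 1e-300:
            trace.stopped_by = "zero direction"
            break
        if success:
            sigma_k = cfg.scg_sigma / np.sqrt(p_norm2)
            _, g_plus = f_and_g(w + sigma_k * p)
            s = (g_plus + r) / sigma_k  # r holds -grad at w
            delta = float(p @ s)
        # scale: make the local quadratic model positive definite
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, _ = f_and_g(w + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / mu**2
        if comparison >= 0:  # successful step: loss did not increase
            w = w + alpha * p
            f = f_new
            _, g_new = f_and_g(w)
            r_new = -g_new
            lam_bar = 0.0
            success = True
            if (k + 1) % n_par == 0:  # restart along the gradient
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam / 4.0, 1e-30)
            trace.train_loss.append(f)
            kappa = val_kappa(w)
            trace.val_kappa.append(kappa)
            if kappa > best_kappa:
                best_kappa, best_vec, fails = kappa, w.copy(), 0
            else:
                fails += 1
                if fails >= cfg.patience:
                    trace.stopped_by = "patience"
                    trace.n_iterations = k + 1
                    break
            if float(r @ r) < 1e-20:
                trace.stopped_by = "gradient converged"
                trace.n_iterations = k + 1
                break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2
        trace.n_iterations = k + 1
    else:
        trace.stopped_by = "max_iterations"

    _unpack(model, best_vec)
    trace.best_val_kappa = best_kappa
    model.meta.update(
        trained="scg",
        best_val_kappa=best_kappa,
        stopped_by=trace.stopped_by,
    )
    return model, trace


# ---------------------------------------------------------------------------
# Serialization: JSON header + weight arrays in one HDF5 file
# ---------------------------------------------------------------------------

def save_model(model: NetworkModel, path) -> None:
    import json

    import h5py

    header = {
        "input_dim": model.input_dim,
        "hidden_sizes": list(model.hidden_sizes),
        "n_classes": model.n_classes,
        "output_mode": model.output_mode,
        "seed": model.seed,
        "meta": model.meta,
    }
    with h5py.File(path, "w") as fh:
        fh.attrs["header"] = json.dumps(header)
        for i, (w, b) in enumerate(zip(model.weights, model.biases)):
            fh.create_dataset(f"w{i}", data=w)
            fh.create_dataset(f"b{i}", data=b)


def load_model(path) -> NetworkModel:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        header = json.loads(fh.attrs["header"])
        n_layers = len(header["hidden_sizes"]) + 1
        weights = [fh[f"w{i}"][()] for i in range(n_layers)]
        biases = [fh[f"b{i}"][()] for i in range(n_layers)]
    return NetworkModel(
        input_dim=header["input_dim"],
        hidden_sizes=tuple(header["hidden_sizes"]),
        n_classes=header["n_classes"],
        weights=weights,
        biases=biases,
        output_mode=header["output_mode"],
        seed=header["seed"],
        meta=header.get("meta", {}),
    )
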