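"""Simulated-annealing augmentation of SCG training.

Backpropagation on a raw-signal MLP lands in one of many local minima.
The annealing loop escapes some of them: after an initial SCG run, every
weight w is jittered by a value drawn uniformly from [-w, w] (so each
weight at most doubles and never flips sign), the network is retrained,
and the retrained candidate is adopted if its validation kappa improved —
or, with a probability that decays exponentially across iterations, even
if it got worse.  The best snapshot ever seen is what comes back.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mlp import NetworkModel, TrainConfig, scg_train, stratified_split

__all__ = [
    "SAConfig",
    "AnnealingTrace",
    "perturb_weights",
    "acceptance_probability",
    "sa_train",
]


@dataclass
class SAConfig:
    """Annealing schedule: number of perturb/retrain cycles and decay.

    ``tau`` sets the acceptance schedule p(k) = exp(-(k+1)/tau) for
    adopting a *worse* retrained network at iteration k (0-based).
    """

    iterations: int = 10
    tau: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class AnnealingTrace:
    """Per-iteration record of the accept/reject loop."""

    kappa_before: list[float] = field(default_factory=list)
    kappa_after: list[float] = field(default_factory=list)
    p_accept: list[float] = field(default_factory=list)
    adopted: list[bool] = field(default_factory=list)
    best_kappa: list[float] = field(default_factory=list)
    initial_kappa: float = float("nan")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "iteration": np.arange(len(self.adopted)),
            "kappa_before": self.kappa_before,
            "kappa_after": self.kappa_after,
            "p_accept": self.p_accept,
            "adopted": self.adopted,
            "best_kappa": self.best_kappa,
        }).to_csv(path, index=False)


def perturb_weights(model: NetworkModel, seed: int) -> NetworkModel:
    """Jitter every weight and bias w by U(-|w|, |w|).

    Equivalently w' = w * U(0, 2): magnitudes at most double, signs never
    flip, exact zeros stay zero.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out = model.copy()
    for arrs in (out.weights, out.biases):
        for i, a in enumerate(arrs):
            arrs[i] = a + rng.uniform(-1.0, 1.0, size=a.shape) * np.abs(a)
    return out


def acceptance_probability(k: int, cfg: SAConfig) -> float:
    """p(k) = exp(-(k+1)/tau): strictly decreasing, in (0, 1]."""
    if k < 0:
        raise ValueError("iteration index must be >= 0")
    return float(np.exp(-(k + 1) / cfg.tau))


def sa_train(
    model: NetworkModel,
    X: np.ndarray,
    y: np.ndarray,
    train_cfg: TrainConfig | None = None,
    sa_cfg: SAConfig | None = None,
) -> tuple[NetworkModel, AnnealingTrace]:
    """SCG training with a simulated-annealing outer loop.

    One stratified train/validation split is fixed up front and shared by
    the initial SCG run and every retraining, so the accept/reject
    comparisons are on the same footing.  Returns the best-validation-
    kappa model observed at any point, plus the acceptance trace.
    """
    train_cfg = train_cfg or TrainConfig()
    sa_cfg = sa_cfg or SAConfig()
    y = np.asarray(y, dtype=int)
    split = stratified_split(y, train_cfg.val_fraction, train_cfg.seed)

    current, trace0 = scg_train(model, X, y, train_cfg, split=split)
    current_kappa = trace0.best_val_kappa
    best, best_kappa = current, current_kappa

    trace = AnnealingTrace(initial_kappa=current_kappa)
    rng = np.random.default_rng(sa_cfg.seed)
    for k in range(sa_cfg.iterations):
        perturbed = perturb_weights(current, seed=int(rng.integers(2**31)))
        candidate, ctrace = scg_train(perturbed, X, y, train_cfg, split=split)
        cand_kappa = ctrace.best_val_kappa
        p = acceptance_probability(k, sa_cfg)
        improved = cand_kappa > current_kappa
        adopt = improved or (rng.random() < p)
        trace.kappa_before.append(current_kappa)
        trace.kappa_after.append(cand_kappa)
        trace.p_accept.append(1.0 if improved else p)
        trace.adopted.append(bool(adopt))
        if adopt:
            current, current_kappa = candidate, cand_kappa
        if cand_kappa > best_kappa:
            best, best_kappa = candidate, cand_kappa
        trace.best_kappa.append(best_kappa)
    best = best.copy()
    best.meta.update(trained="sa", best_val_kappa=best_kappa,
                     sa_iterations=sa_cfg.iterations)
    return best, trace
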