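"""Post-hoc interpretation of trained raw-signal MLPs.

Because the first hidden layer sees every time point of every channel, its
weight matrix can be read as a bank of spatio-temporal filters.  Averaging
absolute first-layer weights over time and neurons scores each electrode's
influence (a data-driven spatial map that, on motor tasks, should single
out sensors over motor cortex); averaging signed weights over channels and
neurons leaves a single temporal filter whose periodogram shows which
frequencies the network emphasises.  Also here: the rank-sum comparison of
selected layer counts and the inter-subject transfer test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .containers import EpochSet
from .metrics import cohens_kappa_labels
from .mlp import NetworkModel, predict_class

__all__ = [
    "SpatialMap",
    "spatial_weight_map",
    "temporal_weight_psd",
    "compare_layer_counts",
    "transfer_test",
    "TransferReport",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialMap:
    """Per-channel influence scores min-max normalised to [0, 1]."""

    values: np.ndarray
    channel_names: Sequence[str]
    raw: np.ndarray | None = None

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"channel": list(self.channel_names),
                      "weight": self.values}).to_csv(path, index=False)

    def plot(self, path=None):  # pragma: no cover - optional plotting
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(self.values)), 3))
        ax.bar(range(len(self.values)), self.values)
        ax.set_xticks(range(len(self.values)))
        ax.set_xticklabels(self.channel_names, rotation=90, fontsize=7)
        ax.set_ylabel("normalised |weight|")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _first_layer(model: NetworkModel, n_channels: int,
                 samples_per_epoch: int) -> np.ndarray:
    """First-layer weights reshaped to (channels, samples, neurons)."""
    if model.input_dim != n_channels * samples_per_epoch:
        raise ValueError(
            f"input_dim {model.input_dim} != "
            f"{n_channels} channels x {samples_per_epoch} samples"
        )
    w = model.weights[0]  # (input_dim, n_hidden), channel-major rows
    return w.reshape(n_channels, samples_per_epoch, w.shape[1])


def spatial_weight_map(
    model: NetworkModel | Sequence[NetworkModel],
    n_channels: int,
    samples_per_epoch: int,
    channel_names: Sequence[str] | None = None,
) -> SpatialMap:
    """Per-channel mean absolute first-layer weight, min-max normalised.

    A sequence of models (e.g. the five cross-validation folds) is
    averaged per channel *before* normalisation, matching how fold-level
    maps are combined into a subject-level map.
    """
    models = [model] if isinstance(model, NetworkModel) else list(model)
    per_model = [
        np.abs(_first_layer(m, n_channels, samples_per_epoch)).mean(axis=(1, 2))
        for m in models
    ]
    raw = np.mean(per_model, axis=0)
    rng_ = raw.max() - raw.min()
    if rng_ <= 0:
        logger.warning("constant spatial map: normalisation undefined, "
                       "returning 0.5 for every channel")
        values = np.full_like(raw, 0.5)
    else:
        values = (raw - raw.min()) / rng_
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_channels)]
    return SpatialMap(values=values, channel_names=list(channel_names),
                      raw=raw)


def temporal_weight_psd(
    model: NetworkModel | Sequence[NetworkModel],
    n_channels: int,
    samples_per_epoch: int,
    fs: float,
    signed: bool = True,
):
    """Periodogram of the space/neuron-averaged first-layer weights.

    Each model's first-layer weights are averaged over channels and
    neurons (signed by default, preserving oscillatory structure) into one
    time series of length ``samples_per_epoch``; its mean (DC) is removed
    and a one-sided rectangular-window periodogram taken.  Returns
    ``(freqs, mean_psd, min_psd, max_psd)`` across the supplied models.
    """
    if samples_per_epoch < 4:
        raise ValueError("need at least 4 samples per epoch for a PSD")
    models = [model] if isinstance(model, NetworkModel) else list(model)
    psds = []
    freqs = None
    for m in models:
        w = _first_layer(m, n_channels, samples_per_epoch)
        series = (w if signed else np.abs(w)).mean(axis=(0, 2))
        series = series - series.mean()
        freqs, pxx = sps.periodogram(series, fs=fs, window="boxcar",
                                     detrend=False, scaling="density")
        psds.append(pxx)
    psds = np.asarray(psds)
    return freqs, psds.mean(axis=0), psds.min(axis=0), psds.max(axis=0)


def compare_layer_counts(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on two sets of layer counts.

    Exact enumeration when both groups have <= 10 tie-free values,
    otherwise the normal approximation with midrank tie correction.
    Returns ``(U statistic, p_value)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymptotic"
    import warnings

    with warnings.catch_warnings():
        # ties make the classic exact null an approximation; accepted for
        # the small layer-count samples this is used on
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class TransferReport:
    """Own-subject vs cross-subject decoding comparison."""

    own_kappa_a: np.ndarray
    cross_kappa_a: np.ndarray  # model A on subject B's folds
    own_kappa_b: np.ndarray
    cross_kappa_b: np.ndarray
    p_value_a: float
    p_value_b: float

    def summary_dict(self) -> dict:
        return {
            "own_mean_a": float(self.own_kappa_a.mean()),
            "own_sd_a": float(self.own_kappa_a.std(ddof=1)),
            "cross_mean_a": float(self.cross_kappa_a.mean()),
            "cross_sd_a": float(self.cross_kappa_a.std(ddof=1)),
            "p_value_a": self.p_value_a,
            "own_mean_b": float(self.own_kappa_b.mean()),
            "own_sd_b": float(self.own_kappa_b.std(ddof=1)),
            "cross_mean_b": float(self.cross_kappa_b.mean()),
            "cross_sd_b": float(self.cross_kappa_b.std(ddof=1)),
            "p_value_b": self.p_value_b,
        }


def _fold_kappas(models, data: EpochSet, test_indices) -> np.ndarray:
    X = data.flatten()
    out = []
    for m, te in zip(models, test_indices):
        pred = predict_class(m, X[te])
        out.append(cohens_kappa_labels(data.labels[te], pred, data.n_classes))
    return np.asarray(out)


def transfer_test(
    models_a, data_a: EpochSet, test_idx_a,
    models_b, data_b: EpochSet, test_idx_b,
) -> TransferReport:
    """Evaluate each subject's fold models on the other subject's data.

    ``models_x`` are per-fold trained networks and ``test_idx_x`` the
    matching held-out index sets.  Own-subject kappas come from each
    model's own test fold; cross-subject kappas from the *other* subject's
    test folds (pairing fold i with fold i).  Each subject gets a
    two-tailed paired t-test across folds.  Montages must match.
    """
    if list(data_a.channel_names) != list(data_b.channel_names):
        diff = set(data_a.channel_names) ^ set(data_b.channel_names)
        raise ValueError(f"channel montages differ: {sorted(diff)}")
    if (data_a.n_samples != data_b.n_samples
            or data_a.n_classes != data_b.n_classes):
        raise ValueError("epoch geometry or class count differs")
    own_a = _fold_kappas(models_a, data_a, test_idx_a)
    cross_a = _fold_kappas(models_a, data_b, test_idx_b)
    own_b = _fold_kappas(models_b, data_b, test_idx_b)
    cross_b = _fold_kappas(models_b, data_a, test_idx_a)

    def paired_p(own, cross):
        if np.allclose(own, cross):
            return 1.0
        return float(stats.ttest_rel(own, cross).pvalue)

    return TransferReport(
        own_kappa_a=own_a, cross_kappa_a=cross_a,
        own_kappa_b=own_b, cross_kappa_b=cross_b,
        p_value_a=paired_p(own_a, cross_a),
        p_value_b=paired_p(own_b, cross_b),
    )
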