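"""Model/Results front end for the whole decoding pipeline.

:class:`RawSignalDecoder` is built from a labeled :class:`EpochSet` (or
straight from a continuous recording via the EMG labeling chain);
``fit()`` runs stratified cross-validation of the chosen training route —
plain SCG backpropagation, annealing-augmented SCG, or the full genetic
architecture search — and returns a :class:`DecoderResults` carrying the
pooled and per-fold performance, significance against chance, the trained
fold networks, and the weight-analysis and transfer utilities.

Example
-------
>>> from evobci import synthetic, model
>>> es = synthetic.synth_epochs()
>>> res = model.RawSignalDecoder(es).fit(method="sa", architecture=[16],
...                                      seed=7)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis, metrics
from .annealing import SAConfig, sa_train
from .containers import EpochSet, Recording
from .evolution import GAConfig, run_ga
from .labeling import LabelingConfig, label_recording
from .mlp import (
    Architecture,
    TrainConfig,
    init_network,
    predict_class,
    scg_train,
)
from .signals_io import demean_epochs

__all__ = ["RawSignalDecoder", "DecoderResults"]


class _Predictor:
    """Trained network wrapped as a label-predicting callable."""

    def __init__(self, model):
        self.model = model

    def __call__(self, X):
        return predict_class(self.model, X)


class RawSignalDecoder:
    """Feature-free decoder of labeled multichannel epochs.

    Parameters
    ----------
    data : EpochSet
        Labeled epochs.  Per-epoch, per-channel demeaning (the only input
        normalisation the networks receive) is applied unless
        ``demean=False``.
    demean : bool
        Subtract the within-epoch channel means (default True).  Channel
        variance is never rescaled.
    input_scale : "rms" | float | None
        A single global scalar dividing every input value so the network
        operates on O(1) quantities ("rms": the root-mean-square of the
        training fold).  One shared scalar preserves all relative channel
        variance (no per-channel standardisation) while keeping the tanh
        hidden layer out of saturation at microvolt input magnitudes.
        After training the scale is folded into the first-layer weights,
        so returned networks always act on raw microvolt epochs.
    """

    def __init__(self, data: EpochSet, demean: bool = True,
                 input_scale="rms"):
        self.data = demean_epochs(data) if demean else data
        self.input_scale = input_scale
        if self.data.n_epochs == 0:
            raise ValueError("cannot build a decoder from 0 epochs")

    @classmethod
    def from_recording(
        cls,
        rec: Recording,
        labeling_cfg: LabelingConfig | None = None,
        include_rest: bool = False,
        demean: bool = True,
    ) -> "RawSignalDecoder":
        """Label a continuous EEG+EMG recording and build the decoder."""
        cfg = labeling_cfg or LabelingConfig()
        epochs, events = label_recording(rec, cfg, include_rest=include_rest)
        obj = cls(epochs, demean=demean)
        obj.events = events
        return obj

    def fit(
        self,
        method: str = "sa",
        architecture=None,
        cv: int = 5,
        seed: int = 0,
        train_cfg: TrainConfig | None = None,
        sa_cfg: SAConfig | None = None,
        ga_cfg: GAConfig | None = None,
    ) -> "DecoderResults":
        """Cross-validate the decoder and return results.

        ``method`` selects the training route: ``"scg"`` (plain
        backpropagation), ``"sa"`` (annealing-augmented, default) or
        ``"ga"`` (genetic architecture search per fold; ``architecture``
        is then ignored).  ``architecture`` defaults to a single
        16-neuron hidden layer for the non-GA routes.
        """
        if method not in ("scg", "sa", "ga"):
            raise ValueError(f"unknown method {method!r}")
        train_cfg = train_cfg or TrainConfig()
        sa_cfg = sa_cfg or SAConfig()
        ga_cfg = ga_cfg or GAConfig()
        arch = Architecture(architecture if architecture is not None else [16])
        data = self.data

        def pipeline(train_set: EpochSet, fold_seed: int):
            X, y = train_set.flatten(), train_set.labels
            if self.input_scale == "rms":
                s = float(np.sqrt((X**2).mean())) or 1.0
            elif self.input_scale is None:
                s = 1.0
            else:
                s = float(self.input_scale)
            X = X / s
            tcfg = TrainConfig(
                max_iterations=train_cfg.max_iterations,
                val_fraction=train_cfg.val_fraction,
                patience=train_cfg.patience,
                scg_sigma=train_cfg.scg_sigma,
                scg_lambda0=train_cfg.scg_lambda0,
                seed=fold_seed,
            )
            if method == "ga":
                gcfg = GAConfig(
                    population=ga_cfg.population,
                    generations=ga_cfg.generations,
                    elites=ga_cfg.elites,
                    mutation_rate=ga_cfg.mutation_rate,
                    seed=fold_seed,
                )
                result = run_ga(X, y, gcfg, tcfg, sa_cfg)
                trained = result.best_model
            else:
                net = init_network(train_set.input_dim, arch,
                                   train_set.n_classes, seed=fold_seed)
                if method == "scg":
                    trained, _ = scg_train(net, X, y, tcfg)
                else:
                    scfg = SAConfig(iterations=sa_cfg.iterations,
                                    tau=sa_cfg.tau, seed=fold_seed)
                    trained, _ = sa_train(net, X, y, tcfg, scfg)
            # fold the input scale into the first layer: the returned
            # network acts on raw microvolt epochs
            trained = trained.copy()
            trained.weights[0] = trained.weights[0] / s
            trained.meta["input_scale"] = s
            return _Predictor(trained)

        report = metrics.crossval(data, pipeline, k=cv, seed=seed)
        report.meta.update(method=method, cv=cv, seed=seed)
        return DecoderResults(model=self, report=report, method=method,
                              seed=seed)


@dataclass
class DecoderResults:
    """Cross-validated decoding performance plus trained fold networks."""

    model: RawSignalDecoder
    report: metrics.EvaluationReport
    method: str
    seed: int
    extras: dict = field(default_factory=dict)

    # -- headline numbers ---------------------------------------------------
    @property
    def kappa(self) -> float:
        return self.report.kappa

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def kappa_mean(self) -> float:
        return self.report.kappa_mean

    @property
    def kappa_sd(self) -> float:
        return self.report.kappa_sd

    @property
    def accuracy_mean(self) -> float:
        return self.report.accuracy_mean

    @property
    def p_value(self) -> float:
        return self.report.p_value

    @property
    def fold_models(self) -> list:
        return self.report.fold_models

    @property
    def fold_test_indices(self) -> list:
        return self.report.fold_test_indices

    @property
    def architectures(self) -> list[tuple[int, ...]]:
        """Hidden-layer sizes selected/used in each fold."""
        return [tuple(m.hidden_sizes) for m in self.fold_models]

    # -- analysis -----------------------------------------------------------
    def spatial_map(self) -> analysis.SpatialMap:
        """Fold-averaged per-channel influence map (normalised |weights|)."""
        d = self.model.data
        return analysis.spatial_weight_map(
            self.fold_models, d.n_channels, d.n_samples,
            channel_names=d.channel_names,
        )

    def temporal_psd(self, signed: bool = True):
        """Periodogram of the fold networks' averaged temporal weights."""
        d = self.model.data
        return analysis.temporal_weight_psd(
            self.fold_models, d.n_channels, d.n_samples, d.fs, signed=signed,
        )

    def detection_and_laterality(self) -> tuple[float, float]:
        """3-class only: (laterality-given-detected, detection) accuracy."""
        return metrics.detection_and_laterality(self.report.confusion)

    def transfer_to(self, other: "DecoderResults") -> analysis.TransferReport:
        """Own- vs cross-subject comparison against another fitted decoder."""
        return analysis.transfer_test(
            self.fold_models, self.model.data, self.fold_test_indices,
            other.fold_models, other.model.data, other.fold_test_indices,
        )

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        r = self.report
        d = self.model.data
        lines = [
            "Raw-signal MLP decoder results",
            "=" * 58,
            f"method: {self.method:<12} folds: {len(r.per_fold):<4}"
            f" seed: {self.seed}",
            f"epochs: {d.n_epochs:<8} channels: {d.n_channels:<4}"
            f" samples/epoch: {d.n_samples} (fs={d.fs:g} Hz)",
            f"classes: {', '.join(d.class_names)}",
            "-" * 58,
            f"pooled kappa     {r.kappa:8.3f}   (SE0 {r.kappa_se0:.3f},"
            f" p {r.p_value:.2e}{' **' if r.significant_001 else ''})",
            f"pooled accuracy  {r.accuracy:8.3f}",
            f"fold kappa       {r.kappa_mean:8.3f} +/- {r.kappa_sd:.3f}",
            f"fold accuracy    {r.accuracy_mean:8.3f} +/- {r.accuracy_sd:.3f}",
            f"architectures    {self.architectures}",
            "-" * 58,
            "confusion (rows true, cols predicted):",
        ]
        width = max(len(c) for c in d.class_names) + 2
        header = " " * width + "".join(f"{c:>{width}}" for c in d.class_names)
        lines.append(header)
        for name, row in zip(d.class_names, r.confusion.counts):
            lines.append(f"{name:>{width}}"
                         + "".join(f"{int(v):>{width}}" for v in row))
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        return self.report.to_json(path)
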