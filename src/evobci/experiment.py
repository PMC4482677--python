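"""Experiment orchestration: one config object, one reproducible run.

An :class:`ExperimentConfig` gathers every stage's parameters (labeling,
training, annealing, GA, synthesis) under a single global seed, loadable
from a versioned YAML file whose defaults match the reference operating
point: population 30, 20 generations, 1 elite, 2% mutation, 10 annealing
iterations, at most 3 hidden layers of 500 neurons, 0.4 s epochs at
250 Hz.  :func:`run_experiment` executes label -> cross-validated fit ->
analysis and writes all artifacts (report JSON, fitness tables, maps,
log) into an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .annealing import SAConfig
from .containers import EpochSet
from .evolution import GAConfig
from .labeling import LabelingConfig
from .mlp import TrainConfig
from .model import RawSignalDecoder
from .signals_io import read_edf, read_epochs
from .synthetic import SynthConfig, synth_epochs

__all__ = ["ExperimentConfig", "run_experiment", "load_config", "save_config"]

SCHEMA_VERSION = 1

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """All knobs of a full pipeline run.

    Exactly one input source is used: ``input_epochs`` (HDF5 container),
    ``input_edf`` (continuous EDF, labeled via EMG), or — when both are
    None — the synthetic generator.
    """

    seed: int = 0
    method: str = "ga"          # scg | sa | ga
    cv_folds: int = 5
    include_rest: bool = False
    architecture: list[int] | None = None  # for scg/sa routes
    input_epochs: str | None = None
    input_edf: str | None = None
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sa: SAConfig = field(default_factory=SAConfig)
    ga: GAConfig = field(default_factory=GAConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


def _to_dict(cfg: ExperimentConfig) -> dict:
    doc = {"version": SCHEMA_VERSION}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        doc[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
    return _listify(doc)


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    version = doc.pop("version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    sections = {
        "labeling": LabelingConfig, "train": TrainConfig, "sa": SAConfig,
        "ga": GAConfig, "synth": SynthConfig,
    }
    kwargs = {}
    for key, val in doc.items():
        if key in sections:
            if "planted_channels" in (val or {}):
                val["planted_channels"] = tuple(
                    tuple(c) for c in val["planted_channels"])
            kwargs[key] = sections[key](**val)
        else:
            kwargs[key] = val
    if kwargs.get("architecture") is not None:
        kwargs["architecture"] = list(kwargs["architecture"])
    return ExperimentConfig(**kwargs)


def _propagate_seed(cfg: ExperimentConfig) -> ExperimentConfig:
    """Derive every stage seed deterministically from the global seed."""
    ss = np.random.SeedSequence(cfg.seed)
    kids = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]
    cfg = dataclasses.replace(cfg)
    cfg.labeling = dataclasses.replace(cfg.labeling, seed=kids[0])
    cfg.train = dataclasses.replace(cfg.train, seed=kids[1])
    cfg.sa = dataclasses.replace(cfg.sa, seed=kids[2])
    cfg.ga = dataclasses.replace(cfg.ga, seed=kids[3])
    cfg.synth = dataclasses.replace(cfg.synth, seed=kids[4])
    return cfg


def _load_input(cfg: ExperimentConfig) -> EpochSet:
    if cfg.input_epochs is not None:
        if not Path(cfg.input_epochs).exists():
            raise FileNotFoundError(cfg.input_epochs)
        return read_epochs(cfg.input_epochs)
    if cfg.input_edf is not None:
        if not Path(cfg.input_edf).exists():
            raise FileNotFoundError(cfg.input_edf)
        rec = read_edf(cfg.input_edf)
        from .labeling import label_recording

        epochs, events = label_recording(rec, cfg.labeling,
                                         include_rest=cfg.include_rest)
        logger.info("labeled %d events -> %d epochs", len(events),
                    epochs.n_epochs)
        return epochs
    synth_cfg = cfg.synth
    if cfg.include_rest and synth_cfg.classes != 3:
        synth_cfg = dataclasses.replace(synth_cfg, classes=3)
    return synth_epochs(synth_cfg)


def run_experiment(cfg: ExperimentConfig, out_dir) -> "DecoderResults":
    """Run the full pipeline and write artifacts under ``out_dir``.

    Writes ``report.json``, ``spatial_map.csv``, ``temporal_psd.csv``,
    ``config.yaml`` (the fully resolved, seed-propagated config) and
    ``experiment.log``.  Two runs with the same config produce identical
    ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _propagate_seed(cfg)

    handler = logging.FileHandler(out / "experiment.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("evobci")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        save_config(cfg, out / "config.yaml")
        try:
            data = _load_input(cfg)
        except Exception as exc:
            raise RuntimeError(f"[input] {exc}") from exc
        logger.info("input: %d epochs, %d channels, %d classes, seed=%d",
                    data.n_epochs, data.n_channels, data.n_classes, cfg.seed)
        try:
            dec = RawSignalDecoder(data)
            res = dec.fit(
                method=cfg.method, architecture=cfg.architecture,
                cv=cfg.cv_folds, seed=cfg.seed, train_cfg=cfg.train,
                sa_cfg=cfg.sa, ga_cfg=cfg.ga,
            )
        except Exception as exc:
            raise RuntimeError(f"[fit] {exc}") from exc
        try:
            res.to_json(out / "report.json")
            res.spatial_map().to_csv(out / "spatial_map.csv")
            freqs, mean_psd, lo, hi = res.temporal_psd()
            import pandas as pd

            pd.DataFrame({"freq_hz": freqs, "psd_mean": mean_psd,
                          "psd_min": lo, "psd_max": hi}).to_csv(
                out / "temporal_psd.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"[analysis] {exc}") from exc
        logger.info("pooled kappa=%.3f accuracy=%.3f p=%.3g",
                    res.kappa, res.accuracy, res.p_value)
        return res
    finally:
        root.removeHandler(handler)
        handler.close()
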