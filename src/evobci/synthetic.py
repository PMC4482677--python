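"""Seeded generators for class-conditional epochs and EEG+EMG streams.

The generators emulate the structure of a self-paced hand-squeeze
experiment so every pipeline stage is testable without recorded data:

* :func:`synth_epochs` draws labeled multichannel epochs in which each
  movement class adds a low-frequency (default 8 Hz), Hann-enveloped,
  onset-locked oscillation on its own small set of "motor" channels, on
  top of white or pink (1/f) background noise.  An optional third class
  carries noise only (the no-movement state).
* :func:`synth_stream` builds a continuous recording: EEG channels with
  the same class-conditional components time-locked to known squeeze
  onsets plus two EMG channels that are quiet except for short
  high-amplitude bursts at each squeeze — exactly what the EMG
  thresholding chain expects — and returns the ground-truth events.

Defaults mirror the recorded-data conditions: 250 Hz sampling, 0.4 s
epochs (0.1 s pre / 0.3 s post), left/right (+ rest) classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, Recording
from .labeling import LEFT, NO_MOVEMENT, RIGHT, LabelingConfig, MovementEvent

__all__ = ["SynthConfig", "synth_epochs", "synth_stream"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic data.

    ``planted_channels`` maps each movement class to the channel indices
    carrying its evoked component; ``effect_amplitude`` (microvolts) and
    ``noise_sd`` set the signal-to-noise ratio; ``carrier_hz`` keeps the
    planted signature in the low-frequency band the decoders are expected
    to emphasise.
    """

    n_channels: int = 8
    fs: float = 250.0
    epoch_s: float = 0.4
    pre_s: float = 0.1
    classes: int = 2
    planted_channels: tuple[tuple[int, ...], ...] = ((2, 3), (5, 6))
    effect_amplitude: float = 6.0
    carrier_hz: float = 8.0
    noise_model: str = "PINK"
    noise_sd: float = 2.0
    n_epochs_per_class: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes not in (2, 3):
            raise ValueError("classes must be 2 or 3")
        if len(self.planted_channels) < 2:
            raise ValueError("need planted channels for LEFT and RIGHT")
        for chans in self.planted_channels:
            for c in chans:
                if not 0 <= c < self.n_channels:
                    raise ValueError(f"planted channel {c} out of range")
        if self.effect_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_model not in ("WHITE", "PINK"):
            raise ValueError("noise_model must be WHITE or PINK")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_s * self.fs))

    @property
    def class_names(self) -> list[str]:
        return [LEFT, RIGHT] + ([NO_MOVEMENT] if self.classes == 3 else [])


def _noise(rng: np.random.Generator, shape, model: str, sd: float):
    """White or pink (1/f amplitude-shaped) Gaussian noise, unit-free."""
    white = rng.standard_normal(shape)
    if model == "WHITE" or sd == 0:
        return sd * white
    n = shape[-1]
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    shaped = np.fft.irfft(spec * shaping, n=n, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    return sd * shaped


def _evoked(cfg: SynthConfig, n_samples: int, onset_sample: int) -> np.ndarray:
    """Hann-enveloped carrier starting at the onset sample."""
    length = n_samples - onset_sample
    t = np.arange(length) / cfg.fs
    burst = np.sin(2 * np.pi * cfg.carrier_hz * t) * np.hanning(length)
    out = np.zeros(n_samples)
    out[onset_sample:] = cfg.effect_amplitude * burst
    return out


def synth_epochs(cfg: SynthConfig | None = None) -> EpochSet:
    """Class-conditional epochs with planted spatial/temporal structure.

    Epoch time runs from ``-pre_s`` to ``epoch_s - pre_s`` relative to the
    onset; the evoked component starts at the onset sample on the class's
    planted channels only.  A third class (if configured) is pure noise.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    n_samp = cfg.samples_per_epoch
    onset_sample = int(round(cfg.pre_s * cfg.fs))
    n_total = cfg.classes * cfg.n_epochs_per_class

    epochs = _noise(rng, (n_total, cfg.n_channels, n_samp),
                    cfg.noise_model, cfg.noise_sd)
    labels = np.repeat(np.arange(cfg.classes), cfg.n_epochs_per_class)
    for cls in range(min(cfg.classes, 2)):
        component = _evoked(cfg, n_samp, onset_sample)
        for idx in np.flatnonzero(labels == cls):
            for ch in cfg.planted_channels[cls]:
                epochs[idx, ch] += component
    # deterministic shuffle so folds are not class-blocked
    order = rng.permutation(n_total)
    return EpochSet(
        epochs=epochs[order],
        labels=labels[order],
        class_names=cfg.class_names,
        fs=cfg.fs,
        window=(cfg.pre_s, cfg.epoch_s - cfg.pre_s),
        channel_names=[f"ch{i}" for i in range(cfg.n_channels)],
    )


def synth_stream(
    duration_s: float,
    squeeze_times: dict[str, list[float]],
    cfg: SynthConfig | None = None,
    labeling_cfg: LabelingConfig | None = None,
    emg_baseline_sd: float = 1.0,
    emg_burst_amplitude: float = 60.0,
    emg_burst_s: float = 0.2,
) -> tuple[Recording, list[MovementEvent]]:
    """Continuous EEG+EMG recording with squeezes at known onsets.

    ``squeeze_times`` maps ``"LEFT"``/``"RIGHT"`` to onset times in
    seconds.  EMG channels (the last two) hold band-limited bursts of
    ``emg_burst_s`` at >= 5x the baseline amplitude; EEG channels hold the
    class-conditional evoked component time-locked to each onset.
    Returns the recording and the ground-truth events sorted by onset.
    """
    cfg = cfg or SynthConfig()
    lab = labeling_cfg or LabelingConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration_s * cfg.fs))

    events = sorted(
        [MovementEvent(onset_s=t, side=side)
         for side in (LEFT, RIGHT) for t in squeeze_times.get(side, [])],
        key=lambda e: e.onset_s,
    )
    for ev in events:
        if ev.onset_s < lab.pre_s:
            raise ValueError(f"onset {ev.onset_s} closer than pre_s to start")
        if ev.onset_s + lab.post_s > duration_s:
            raise ValueError(f"onset {ev.onset_s} too close to the end")
    for e1, e2 in zip(events, events[1:]):
        if e2.onset_s - e1.onset_s < max(lab.refractory_s, emg_burst_s):
            raise ValueError(
                f"onsets {e1.onset_s} and {e2.onset_s} overlap "
                "(closer than the refractory/burst length)"
            )

    eeg = _noise(rng, (cfg.n_channels, n), cfg.noise_model, cfg.noise_sd)
    n_evoked = cfg.samples_per_epoch - int(round(cfg.pre_s * cfg.fs))
    for ev in events:
        cls = 0 if ev.side == LEFT else 1
        start = int(round(ev.onset_s * cfg.fs))
        length = min(n_evoked, n - start)
        t = np.arange(length) / cfg.fs
        burst = (cfg.effect_amplitude
                 * np.sin(2 * np.pi * cfg.carrier_hz * t)
                 * np.hanning(n_evoked)[:length])
        for ch in cfg.planted_channels[cls]:
            eeg[ch, start : start + length] += burst

    emg = emg_baseline_sd * rng.standard_normal((2, n))
    burst_len = int(round(emg_burst_s * cfg.fs))
    for ev in events:
        row = 0 if ev.side == LEFT else 1
        start = int(round(ev.onset_s * cfg.fs))
        length = min(burst_len, n - start)
        # instant attack (so trailing-RMS detection latency stays small),
        # cosine decay over the final quarter to avoid an edge click
        envelope = np.ones(length)
        tail = max(length // 4, 1)
        envelope[-tail:] = 0.5 * (1 + np.cos(np.linspace(0, np.pi, tail)))
        emg[row, start : start + length] += (
            emg_burst_amplitude * envelope * rng.standard_normal(length)
        )

    data = np.vstack([eeg, emg])
    names = [f"ch{i}" for i in range(cfg.n_channels)] + ["EMG_L", "EMG_R"]
    kinds = ["EEG"] * cfg.n_channels + ["EMG", "EMG"]
    rec = Recording(data=data, fs=cfg.fs, channel_names=names,
                    channel_kinds=kinds)
    return rec, events
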