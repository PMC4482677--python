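"""EMG-driven labeling of continuous recordings into movement/rest epochs.

Hand squeezes are detected from the EMG channels: the RMS power in a
trailing 500 ms window is thresholded, a 300 ms refractory period collapses
repeated crossings of a single clench, and EEG epochs from 100 ms before to
300 ms after each onset become LEFT/RIGHT examples.  Stretches with no
movement within +/-500 ms supply NO_MOVEMENT epochs of the same 400 ms
length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, Recording

__all__ = [
    "LEFT",
    "RIGHT",
    "NO_MOVEMENT",
    "MovementEvent",
    "LabelingConfig",
    "sliding_rms",
    "detect_onsets",
    "suggest_threshold",
    "extract_movement_epochs",
    "extract_rest_epochs",
    "build_epochset",
    "label_recording",
]

logger = logging.getLogger(__name__)

LEFT = "LEFT"
RIGHT = "RIGHT"
NO_MOVEMENT = "NO_MOVEMENT"


@dataclass(frozen=True)
class MovementEvent:
    """A detected hand squeeze: onset time (s) and side (LEFT/RIGHT)."""

    onset_s: float
    side: str

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.side not in (LEFT, RIGHT):
            raise ValueError(f"side must be LEFT or RIGHT, got {self.side!r}")


@dataclass
class LabelingConfig:
    """Parameters of the EMG thresholding / epoching chain.

    Durations in seconds, thresholds in microvolts (RMS).  The epoch runs
    from ``pre_s`` before to ``post_s`` after each detected onset (0.4 s
    total by default); ``quiet_min_s`` is both the minimum no-movement gap
    around rest epochs and the minimum quiet-interval length.
    """

    rms_window_s: float = 0.5
    threshold_left: float = 10.0
    threshold_right: float = 10.0
    refractory_s: float = 0.3
    pre_s: float = 0.1
    post_s: float = 0.3
    quiet_min_s: float = 0.5
    max_rest_epochs: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rms_window_s", "refractory_s", "pre_s", "post_s",
                     "quiet_min_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def epoch_s(self) -> float:
        return self.pre_s + self.post_s


def sliding_rms(x, fs: float, window_s: float = 0.5) -> np.ndarray:
    """Trailing-window RMS of a 1-D signal, one value per sample.

    The first ``window_s * fs - 1`` samples use the partial window that is
    available, so the output warms up rather than being undefined.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-D sequence")
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("window must span at least one sample")
    csum = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - w, 0)
    return np.sqrt((csum[idx] - csum[lo]) / (idx - lo))


def suggest_threshold(baseline, fs: float, window_s: float = 0.5,
                      percentile: float = 99.0, margin: float = 1.5) -> float:
    """Reproducible default for the manual threshold.

    Returns ``margin`` times the given percentile of the RMS trace of a
    user-marked movement-free baseline segment.
    """
    rms = sliding_rms(baseline, fs, window_s)
    return margin * float(np.percentile(rms, percentile))


def _rising_edges(rms: np.ndarray, threshold: float) -> np.ndarray:
    above = rms >= threshold
    edges = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    return edges


def detect_onsets(
    rms_left, rms_right, fs: float, cfg: LabelingConfig
) -> list[MovementEvent]:
    """Threshold both RMS traces and apply the refractory rule.

    An event is placed at the first sample of each excursion above
    threshold; any candidate (either side) within ``refractory_s`` of the
    previously accepted event is suppressed.  A simultaneous left/right
    crossing resolves to LEFT (logged) — the alternating-hands task makes
    this a corner case only.
    """
    rms_left = np.asarray(rms_left, dtype=float)
    rms_right = np.asarray(rms_right, dtype=float)
    if rms_left.shape != rms_right.shape:
        raise ValueError("left and right RMS traces must have equal length")
    if cfg.threshold_left <= 0 or cfg.threshold_right <= 0:
        raise ValueError("thresholds must be positive")

    cand = [(int(i), LEFT) for i in _rising_edges(rms_left, cfg.threshold_left)]
    cand += [(int(i), RIGHT)
             for i in _rising_edges(rms_right, cfg.threshold_right)]
    # left sorts before right at the same sample: documented tie-break
    cand.sort(key=lambda c: (c[0], c[1] != LEFT))

    refractory = int(round(cfg.refractory_s * fs))
    events: list[MovementEvent] = []
    last = -refractory - 1
    for i, side in cand:
        if events and i - last < refractory:
            continue  # inside refractory (covers simultaneous L/R crossings)
        events.append(MovementEvent(onset_s=i / fs, side=side))
        last = i
    simultaneous = {i for i, s in cand if s == LEFT} & {
        i for i, s in cand if s == RIGHT}
    if simultaneous:
        logger.warning(
            "simultaneous left/right crossings at %d sample(s); LEFT kept",
            len(simultaneous),
        )
    return events


def extract_movement_epochs(
    rec: Recording, events, cfg: LabelingConfig
) -> EpochSet:
    """Cut EEG epochs [onset - pre_s, onset + post_s) around each event."""
    eeg = rec.pick("EEG")
    fs = rec.fs
    n_samp = int(round(cfg.epoch_s * fs))
    epochs, labels = [], []
    dropped = 0
    for ev in events:
        start = int(round((ev.onset_s - cfg.pre_s) * fs))
        if start < 0 or start + n_samp > eeg.n_samples:
            dropped += 1
            continue
        epochs.append(eeg.data[:, start : start + n_samp])
        labels.append(0 if ev.side == LEFT else 1)
    if dropped:
        logger.warning("%d event(s) dropped: window outside recording", dropped)
    arr = (np.stack(epochs) if epochs
           else np.empty((0, eeg.n_channels, n_samp)))
    return EpochSet(
        epochs=arr,
        labels=np.asarray(labels, dtype=int),
        class_names=[LEFT, RIGHT],
        fs=fs,
        window=(cfg.pre_s, cfg.post_s),
        channel_names=list(eeg.channel_names),
    )


def _quiet_intervals(duration_s: float, events, quiet_min_s: float):
    """Maximal intervals containing no event within +/- quiet_min_s."""
    blocked = sorted(
        (max(0.0, ev.onset_s - quiet_min_s), ev.onset_s + quiet_min_s)
        for ev in events
    )
    intervals, cursor = [], 0.0
    for lo, hi in blocked:
        if lo > cursor:
            intervals.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < duration_s:
        intervals.append((cursor, duration_s))
    return [(a, b) for a, b in intervals if b - a >= quiet_min_s]


def extract_rest_epochs(
    rec: Recording, events, cfg: LabelingConfig
) -> EpochSet:
    """Non-overlapping rest epochs tiled from the start of quiet intervals.

    Quiet intervals are stretches of at least ``quiet_min_s`` with no
    detected movement within ``quiet_min_s`` on either side.  If
    ``cfg.max_rest_epochs`` is set, a seeded RNG subsamples the candidates.
    """
    eeg = rec.pick("EEG")
    fs = rec.fs
    n_samp = int(round(cfg.epoch_s * fs))
    epochs = []
    for lo, hi in _quiet_intervals(rec.duration, events, cfg.quiet_min_s):
        t = lo
        while t + cfg.epoch_s <= hi + 1e-12:
            start = int(round(t * fs))
            if start + n_samp <= eeg.n_samples:
                epochs.append(eeg.data[:, start : start + n_samp])
            t += cfg.epoch_s
    if cfg.max_rest_epochs is not None and len(epochs) > cfg.max_rest_epochs:
        rng = np.random.default_rng(cfg.seed)
        keep = np.sort(rng.choice(len(epochs), cfg.max_rest_epochs,
                                  replace=False))
        epochs = [epochs[i] for i in keep]
    arr = (np.stack(epochs) if epochs
           else np.empty((0, eeg.n_channels, n_samp)))
    return EpochSet(
        epochs=arr,
        labels=np.zeros(len(epochs), dtype=int),
        class_names=[NO_MOVEMENT],
        fs=fs,
        window=(cfg.pre_s, cfg.post_s),
        channel_names=list(eeg.channel_names),
    )


def build_epochset(
    movement: EpochSet, rest: EpochSet | None = None,
    include_rest: bool = False,
) -> EpochSet:
    """Combine movement and rest epochs into the 2- or 3-class dataset.

    Class order is fixed: (LEFT, RIGHT) or (LEFT, RIGHT, NO_MOVEMENT).
    """
    if not include_rest:
        return movement.subset(np.arange(movement.n_epochs))
    if rest is None or rest.n_epochs == 0:
        raise ValueError(
            "include_rest=True but the rest set is empty — record more "
            "movement-free data or lower quiet_min_s"
        )
    if list(movement.channel_names) != list(rest.channel_names):
        raise ValueError("movement and rest epochs use different channels")
    if movement.fs != rest.fs or movement.window != rest.window:
        raise ValueError("movement and rest epoch geometry differs")
    epochs = np.concatenate([movement.epochs, rest.epochs])
    labels = np.concatenate([movement.labels,
                             np.full(rest.n_epochs, 2, dtype=int)])
    return EpochSet(
        epochs=epochs,
        labels=labels,
        class_names=[LEFT, RIGHT, NO_MOVEMENT],
        fs=movement.fs,
        window=movement.window,
        channel_names=list(movement.channel_names),
    )


def label_recording(
    rec: Recording, cfg: LabelingConfig, include_rest: bool = False
) -> tuple[EpochSet, list[MovementEvent]]:
    """Full chain: EMG RMS -> onsets -> movement (+ rest) EpochSet.

    Expects exactly two EMG channels (left then right, by channel order).
    """
    emg = rec.pick("EMG")
    if emg.n_channels != 2:
        raise ValueError(
            f"expected 2 EMG channels (left, right), found {emg.n_channels}"
        )
    rms_l = sliding_rms(emg.data[0], rec.fs, cfg.rms_window_s)
    rms_r = sliding_rms(emg.data[1], rec.fs, cfg.rms_window_s)
    events = detect_onsets(rms_l, rms_r, rec.fs, cfg)
    movement = extract_movement_epochs(rec, events, cfg)
    rest = extract_rest_epochs(rec, events, cfg) if include_rest else None
    return build_epochset(movement, rest, include_rest), events
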