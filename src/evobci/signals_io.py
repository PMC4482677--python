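"""Reading, writing and offline preprocessing of signals and epoch sets.

Continuous recordings come in as EDF/EDF+ (via :mod:`mne`); epoch sets live
in a small self-describing HDF5 container.  Preprocessing mirrors a typical
offline EEG chain: zero-phase FIR band-pass + mains notch, integer-factor
decimation with anti-aliasing, and per-epoch demeaning (the only
normalisation the classifiers receive — channel variance is deliberately
left untouched because it carries task information).

HDF5 layout
-----------
``/epochs``  float64, (n_epochs, n_channels, n_samples), microvolts
``/labels``  int64, (n_epochs,)
``/meta``    empty group whose ``json`` attribute holds class names,
             sampling rate, epoch window and channel names.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
from scipy import signal as sps

from .containers import EpochSet, Recording

__all__ = [
    "FormatError",
    "read_edf",
    "write_edf",
    "read_epochs",
    "write_epochs",
    "bandpass_notch",
    "decimate",
    "demean_epochs",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_channel_labels(path) -> list[str]:
    """Read raw channel labels from an EDF header.

    mne silently de-duplicates repeated labels, so uniqueness must be
    checked against the bytes on disk.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError(f"{path}: truncated EDF header (fixed block)")
        try:
            ns = int(header[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(
                f"{path}: invalid 'number of signals' header field"
            ) from exc
        raw = fh.read(ns * 16)
        if len(raw) < ns * 16:
            raise FormatError(f"{path}: truncated EDF header (label block)")
    return [raw[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
            for i in range(ns)]


def _infer_kind(name: str, mne_type: str) -> str:
    if mne_type == "emg" or "EMG" in name.upper():
        return "EMG"
    if mne_type in ("eeg", "meg", "mag", "grad"):
        return "EEG"
    return "OTHER"


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    Channel kinds are inferred from the mne channel type, falling back on
    the label (anything containing ``EMG`` is tagged EMG).
    """
    import mne

    labels = _edf_channel_labels(path)
    annot = [lb for lb in labels if lb.upper().startswith("EDF ANNOTATION")]
    signal_labels = [lb for lb in labels if lb not in annot]
    if len(set(signal_labels)) != len(signal_labels):
        raise FormatError(f"{path}: duplicate channel names in EDF header")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises a mixture of types
        raise FormatError(f"{path}: unreadable EDF ({exc})") from exc
    kinds = [
        _infer_kind(name, t)
        for name, t in zip(raw.ch_names, raw.get_channel_types())
    ]
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        channel_kinds=kinds,
        start_time=0.0,
    )


def write_edf(rec: Recording, path) -> None:
    """Write a Recording as a minimal 16-bit EDF file.

    Covers the plain-EDF subset this package needs (fixtures and the
    ``simulate`` subcommand): one or more equal-length data records,
    microvolt physical units, no annotations.
    """
    n_ch, n = rec.n_channels, rec.n_samples
    fs = rec.fs
    if float(fs).is_integer() and n % int(fs) == 0 and n > 0:
        spr = int(fs)               # 1-second records
        n_rec, rec_dur = n // spr, 1.0
    else:
        spr, n_rec, rec_dur = n, 1, n / fs
    dur_str = f"{rec_dur:.6f}"[:8].rstrip("0").rstrip(".") or "0"

    phys_min = np.minimum(rec.data.min(axis=1), -1.0)
    phys_max = np.maximum(rec.data.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round(
        (rec.data - phys_min[:, None]) / scale[:, None] + dig_min
    ).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("", 44),
        pad(str(n_rec), 8), pad(dur_str, 8), pad(str(n_ch), 4),
    ])
    fields = [
        [pad(nm, 16) for nm in rec.channel_names],
        [pad("", 80)] * n_ch,
        [pad("uV", 8)] * n_ch,
        [pad(f"{v:.6g}"[:8], 8) for v in phys_min],
        [pad(f"{v:.6g}"[:8], 8) for v in phys_max],
        [pad(str(dig_min), 8)] * n_ch,
        [pad(str(dig_max), 8)] * n_ch,
        [pad("", 80)] * n_ch,
        [pad(str(spr), 8)] * n_ch,
        [pad("", 32)] * n_ch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(b"".join(f))
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------

def write_epochs(es: EpochSet, path) -> None:
    """Write an EpochSet to the HDF5 container (lossless)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("epochs", data=es.epochs)
        fh.create_dataset("labels", data=es.labels.astype(np.int64))
        meta = fh.create_group("meta")
        meta.attrs["json"] = json.dumps({
            "class_names": list(es.class_names),
            "fs": es.fs,
            "window": list(es.window),
            "channel_names": list(es.channel_names),
        })


def read_epochs(path) -> EpochSet:
    """Read an EpochSet back from the HDF5 container."""
    with h5py.File(path, "r") as fh:
        for key in ("epochs", "labels", "meta"):
            if key not in fh:
                raise FormatError(f"{path}: missing required dataset '{key}'")
        if "json" not in fh["meta"].attrs:
            raise FormatError(f"{path}: /meta lacks the 'json' attribute")
        meta = json.loads(fh["meta"].attrs["json"])
        return EpochSet(
            epochs=fh["epochs"][()],
            labels=fh["labels"][()],
            class_names=meta["class_names"],
            fs=meta["fs"],
            window=tuple(meta["window"]),
            channel_names=meta["channel_names"],
        )


# ---------------------------------------------------------------------------
# Filtering / resampling / demeaning
# ---------------------------------------------------------------------------

def _zero_phase_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR kernel with reflected edges (zero phase)."""
    half = len(taps) // 2
    padded = np.pad(data, [(0, 0), (half, half)], mode="reflect")
    out = sps.oaconvolve(padded, taps[None, :], mode="valid", axes=1)
    return out


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def bandpass_notch(
    rec: Recording,
    low_hz: float,
    high_hz: float,
    notch_hz: float | None = 50.0,
    notch_width_hz: float = 2.0,
) -> Recording:
    """Zero-phase FIR band-pass plus mains notch.

    The band-pass is a Hann-windowed linear-phase FIR whose order scales
    with the low edge (3 x fs / low_hz, rounded odd, capped at the signal
    length); the notch is a Hann-windowed band-stop of width
    ``notch_width_hz`` centred on ``notch_hz``.  Symmetric kernels applied
    over reflected edges give zero phase delay in a single pass.
    """
    fs = rec.fs
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low_hz}, high={high_hz}, fs={fs}"
        )
    if notch_hz is not None and not (0 < notch_hz < nyq):
        raise ValueError(f"notch frequency {notch_hz} outside (0, fs/2)")

    n = rec.n_samples
    numtaps = min(_odd(int(round(3 * fs / low_hz))), _odd(max(n - 1, 3)))
    bp = sps.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                    window="hann", fs=fs)
    out = _zero_phase_fir(rec.data, bp)
    if notch_hz is not None:
        half_w = notch_width_hz / 2.0
        ntaps = min(_odd(int(round(6 * fs / notch_width_hz))),
                    _odd(max(n - 1, 3)))
        stop = sps.firwin(ntaps, [notch_hz - half_w, notch_hz + half_w],
                          pass_zero=True, window="hann", fs=fs)
        out = _zero_phase_fir(out, stop)
    return rec.copy_with(data=out)


def decimate(rec: Recording, target_fs: float) -> Recording:
    """Anti-alias low-pass then subsample to an integer-divisor rate."""
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9 or round(factor) < 1:
        raise ValueError(
            f"fs/target_fs must be a positive integer, got "
            f"{rec.fs}/{target_fs} = {factor}"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec.copy_with(data=rec.data.copy())
    out = sps.decimate(rec.data, factor, ftype="fir", zero_phase=True, axis=1)
    return rec.copy_with(data=out, fs=rec.fs / factor)


def demean_epochs(es: EpochSet, per_channel: bool = True) -> EpochSet:
    """Subtract the within-epoch mean; never rescale variance.

    ``per_channel=True`` (default) removes each channel's own DC offset
    inside each epoch; ``False`` removes a single scalar mean per epoch.
    """
    if es.n_epochs == 0:
        return es.subset(np.arange(0))
    if per_channel:
        mean = es.epochs.mean(axis=2, keepdims=True)
    else:
        mean = es.epochs.mean(axis=(1, 2), keepdims=True)
    out = es.subset(np.arange(es.n_epochs))
    out.epochs = es.epochs - mean
    return out


def events_to_csv(events, path) -> None:
    """Write movement events as a two-column CSV (onset_s, label)."""
    import pandas as pd

    pd.DataFrame(
        {"onset_s": [e.onset_s for e in events],
         "label": [e.side for e in events]}
    ).to_csv(path, index=False)


def events_from_csv(path):
    """Read a CSV event list written by :func:`events_to_csv`."""
    import pandas as pd

    from .labeling import MovementEvent

    df = pd.read_csv(path)
    for col in ("onset_s", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return [MovementEvent(onset_s=float(r.onset_s), side=str(r.label))
            for r in df.itertuples()]
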