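"""EMG RMS thresholding, onset detection and epoch extraction."""

import numpy as np
import pytest

from evobci.containers import Recording
from evobci.labeling import (
    LEFT,
    NO_MOVEMENT,
    RIGHT,
    LabelingConfig,
    MovementEvent,
    build_epochset,
    detect_onsets,
    extract_movement_epochs,
    extract_rest_epochs,
    sliding_rms,
)


def brute_force_onsets(rms_left, rms_right, fs, cfg):
    """Independent re-derivation: scan rising edges, greedy refractory."""
    cands = []
    for trace, thr, side in ((rms_left, cfg.threshold_left, LEFT),
                             (rms_right, cfg.threshold_right, RIGHT)):
        for i, v in enumerate(trace):
            prev = trace[i - 1] if i else -np.inf
            if v >= thr and prev < thr:
                cands.append((i, side))
    cands.sort(key=lambda c: (c[0], c[1] != LEFT))
    out, last = [], None
    for i, side in cands:
        if last is None or i - last >= int(round(cfg.refractory_s * fs)):
            out.append((i, side))
            last = i
    return out


class TestSlidingRms:
    def test_constant_signal(self):
        rms = sliding_rms(np.full(100, 3.0), fs=100.0, window_s=0.2)
        assert np.allclose(rms, 3.0)

    def test_zeros(self):
        assert np.allclose(sliding_rms(np.zeros(50), 100.0, 0.1), 0.0)

    def test_sinusoid_closed_form(self):
        fs = 1000.0
        t = np.arange(int(2 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)  # window 0.5 s = 5 full periods
        rms = sliding_rms(x, fs, 0.5)
        assert np.abs(rms[600:] - 1 / np.sqrt(2)).max() < 1e-3

    def test_output_length_and_empty_input(self):
        assert sliding_rms(np.ones(7), 10.0, 0.3).shape == (7,)
        with pytest.raises(ValueError):
            sliding_rms(np.array([]), 10.0, 0.3)


class TestDetectOnsets:
    cfg = LabelingConfig(threshold_left=5.0, threshold_right=5.0)

    def test_silent_trace_gives_no_events(self):
        quiet = np.full(1000, 0.5)
        assert detect_onsets(quiet, quiet, 250.0, self.cfg) == []

    def test_refractory_collapses_close_crossings(self):
        fs = 250.0
        trace = np.zeros(500)
        trace[100:110] = 10.0
        trace[150:160] = 10.0  # 200 ms later, inside 300 ms refractory
        events = detect_onsets(trace, np.zeros(500), fs, self.cfg)
        assert len(events) == 1
        assert events[0].onset_s == pytest.approx(100 / fs)

    def test_matches_brute_force_on_random_traces(self):
        fs = 250.0
        for seed in range(20):
            r = np.random.default_rng(seed)
            left = np.abs(r.normal(2, 2, size=2000))
            right = np.abs(r.normal(2, 2, size=2000))
            got = detect_onsets(left, right, fs, self.cfg)
            want = brute_force_onsets(left, right, fs, self.cfg)
            assert [(int(round(e.onset_s * fs)), e.side) for e in got] == want

    def test_inter_event_gaps_respect_refractory(self):
        fs = 250.0
        r = np.random.default_rng(3)
        left = np.abs(r.normal(3, 3, size=5000))
        right = np.abs(r.normal(3, 3, size=5000))
        events = detect_onsets(left, right, fs, self.cfg)
        onsets = [e.onset_s for e in events]
        assert len(onsets) > 2
        gaps = np.diff(onsets)
        assert (gaps >= self.cfg.refractory_s - 1e-9).all()

    def test_nonpositive_threshold_rejected(self):
        cfg = LabelingConfig(threshold_left=-1.0)
        with pytest.raises(ValueError, match="threshold"):
            detect_onsets(np.ones(10), np.ones(10), 10.0, cfg)

    def test_planted_bursts_recovered_within_20ms(self):
        from evobci.synthetic import SynthConfig, synth_stream

        rng = np.random.default_rng(1)
        times, t = {"LEFT": [], "RIGHT": []}, 1.0
        planted = []
        for i in range(30):
            side = LEFT if i % 2 == 0 else RIGHT
            times[side].append(t)
            planted.append((t, side))
            t += 1.0 + rng.uniform(0, 0.5)
        rec, _ = synth_stream(t + 1.0, times, SynthConfig(seed=7))
        emg = rec.pick("EMG")
        cfg = LabelingConfig(threshold_left=5.0, threshold_right=5.0)
        events = detect_onsets(
            sliding_rms(emg.data[0], rec.fs, cfg.rms_window_s),
            sliding_rms(emg.data[1], rec.fs, cfg.rms_window_s),
            rec.fs, cfg,
        )
        assert len(events) == 30  # precision = recall = 1
        for (true_t, true_side), ev in zip(planted, events):
            assert ev.side == true_side
            assert abs(ev.onset_s - true_t) <= 0.020


class TestExtractEpochs:
    def _recording(self, duration=20.0, fs=250.0):
        r = np.random.default_rng(0)
        n = int(duration * fs)
        return Recording(r.normal(size=(3, n)), fs,
                         ["e1", "e2", "EMG_L"], ["EEG", "EEG", "EMG"])

    def test_default_window_geometry(self):
        rec = self._recording()
        cfg = LabelingConfig()
        es = extract_movement_epochs(
            rec, [MovementEvent(10.0, LEFT)], cfg)
        assert es.n_epochs == 1
        assert es.n_samples == 100  # 0.4 s at 250 Hz
        start = int(round((10.0 - 0.1) * rec.fs))
        assert np.array_equal(es.epochs[0],
                              rec.data[:2, start:start + 100])
        assert es.channel_names == ["e1", "e2"]  # EEG only

    def test_boundary_event_dropped_with_warning(self, caplog):
        rec = self._recording()
        with caplog.at_level("WARNING"):
            es = extract_movement_epochs(
                rec, [MovementEvent(0.05, RIGHT)], LabelingConfig())
        assert es.n_epochs == 0
        assert "dropped" in caplog.text

    def test_no_events_gives_empty_set(self):
        es = extract_movement_epochs(self._recording(), [], LabelingConfig())
        assert es.n_epochs == 0
        assert es.class_names == [LEFT, RIGHT]

    def test_rest_count_without_events(self):
        rec = self._recording(duration=10.0)
        es = extract_rest_epochs(rec, [], LabelingConfig())
        assert es.n_epochs == int(np.floor(10.0 / 0.4))

    def test_dense_events_leave_no_rest(self):
        rec = self._recording(duration=12.0)
        events = [MovementEvent(t, LEFT) for t in np.arange(0.6, 11.4, 0.6)]
        es = extract_rest_epochs(rec, events, LabelingConfig())
        assert es.n_epochs == 0

    def test_rest_windows_avoid_movement_neighbourhood(self):
        rec = self._recording(duration=10.0)
        cfg = LabelingConfig()
        es = extract_rest_epochs(rec, [MovementEvent(5.0, LEFT)], cfg)
        # quiet intervals are [0, 4.5] and [5.5, 10]
        starts = []
        for ep in es.epochs:
            # locate each epoch by matching against the raw signal
            for s in range(rec.n_samples - 100 + 1):
                if np.array_equal(ep, rec.data[:2, s:s + 100]):
                    starts.append(s / rec.fs)
                    break
        assert len(starts) == es.n_epochs
        for s in starts:
            assert s + 0.4 <= 4.5 + 1e-9 or s >= 5.5 - 1e-9


class TestBuildEpochset:
    def _sets(self):
        r = np.random.default_rng(1)
        cfg = LabelingConfig()
        rec = Recording(r.normal(size=(3, 5000)), 250.0,
                        ["e1", "e2", "EMG_L"], ["EEG", "EEG", "EMG"])
        movement = extract_movement_epochs(
            rec, [MovementEvent(5.0, LEFT), MovementEvent(8.0, RIGHT)], cfg)
        rest = extract_rest_epochs(
            rec, [MovementEvent(5.0, LEFT), MovementEvent(8.0, RIGHT)], cfg)
        return movement, rest

    def test_two_class_build(self):
        movement, rest = self._sets()
        out = build_epochset(movement, rest, include_rest=False)
        assert out.class_names == [LEFT, RIGHT]

    def test_three_class_preserves_counts(self):
        movement, rest = self._sets()
        out = build_epochset(movement, rest, include_rest=True)
        assert out.class_names == [LEFT, RIGHT, NO_MOVEMENT]
        assert out.n_epochs == movement.n_epochs + rest.n_epochs
        assert (out.labels == 2).sum() == rest.n_epochs

    def test_empty_rest_is_an_error(self):
        movement, rest = self._sets()
        with pytest.raises(ValueError, match="more"):
            build_epochset(movement, rest.subset(np.arange(0)),
                           include_rest=True)
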