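import numpy as np
import pytest

from emgselect import (SessionRecording, label_windows, minmax_normalise,
                       prepare_session, slide_windows, split_by_repetition,
                       undersample_rest)
from emgselect.preprocessing import (WindowSet, assign_window_repetitions,
                                     effective_repetition, window_geometry)

from conftest import make_recording


def _recording_from_signal(sig, fs=2000.0):
    n = len(sig)
    return SessionRecording(signal=np.asarray(sig, float).reshape(n, -1), fs=fs,
                            stimulus=np.zeros(n, dtype=int),
                            repetition=np.zeros(n, dtype=int))


class TestMinmaxNormalise:
    @pytest.mark.parametrize("channel,expected", [
        ([0.0, 5.0, 10.0], [-1.0, 0.0, 1.0]),
        ([3.0, 3.0, 3.0], [0.0, 0.0, 0.0]),   # constant channel: degenerate range
        ([-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]),
    ])
    def test_endpoint_mapping(self, channel, expected):
        out = minmax_normalise(np.array(channel)[:, None])
        np.testing.assert_allclose(out.ravel(), expected)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((500, 4)) * [1, 10, 0.1, 100]
        once = minmax_normalise(x)
        np.testing.assert_allclose(minmax_normalise(once), once, atol=1e-12)

    def test_per_channel_and_order_preserving(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((200, 3)) * [1, 5, 50]
        out = minmax_normalise(x)
        assert out.min(axis=0) == pytest.approx([-1, -1, -1])
        assert out.max(axis=0) == pytest.approx([1, 1, 1])
        for c in range(3):
            assert np.array_equal(np.argsort(x[:, c]), np.argsort(out[:, c]))

    def test_empty_signal_errors(self):
        with pytest.raises(ValueError):
            minmax_normalise(np.empty((0, 2)))


class TestSlideWindows:
    @pytest.mark.parametrize("n_samples,fs,expected", [
        (400, 2000.0, 1),     # exactly one window
        (2000, 2000.0, 81),   # floor((2000-400)/20)+1
        (1000, 1000.0, 81),   # same geometry at 1 kHz (200/10 samples)
    ])
    def test_window_count(self, n_samples, fs, expected):
        rec = _recording_from_signal(np.zeros(n_samples), fs=fs)
        ws = slide_windows(rec)
        assert ws.n_windows == expected
        width, step = window_geometry(fs)
        assert ws.width_samples == width and ws.step_samples == step

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            slide_windows(_recording_from_signal(np.zeros(399)))

    def test_count_formula_random_sizes(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            fs = float(rng.choice([500, 1000, 2000, 4000]))
            width, step = window_geometry(fs)
            n = int(rng.integers(width, width + 5000))
            ws = slide_windows(_recording_from_signal(np.zeros(n), fs=fs))
            assert ws.n_windows == (n - width) // step + 1

    def test_window_content_and_stride(self):
        rec = _recording_from_signal(np.arange(600, dtype=float))
        ws = slide_windows(rec)
        assert np.array_equal(np.diff(ws.start_sample),
                              np.full(ws.n_windows - 1, ws.step_samples))
        i = 5
        np.testing.assert_array_equal(
            ws.raw[i, :, 0], np.arange(i * 20, i * 20 + 400, dtype=float))


class TestLabelWindows:
    def _ws(self, n, fs=1000.0):
        return slide_windows(_recording_from_signal(np.zeros(n), fs=fs))

    def test_homogeneous_window(self):
        ws = self._ws(200)
        stim = np.full(200, 3)
        assert label_windows(ws, stim)[0] == 3

    def test_majority_rule(self):
        ws = self._ws(200)
        stim = np.r_[np.full(120, 2), np.zeros(80, dtype=int)]  # 60% class 2
        assert label_windows(ws, stim)[0] == 2

    def test_tie_broken_toward_rest(self):
        ws = self._ws(200)
        stim = np.r_[np.zeros(100, dtype=int), np.full(100, 5)]
        assert label_windows(ws, stim)[0] == 0

    def test_invalid_stimulus_errors(self):
        ws = self._ws(200)
        with pytest.raises(ValueError):
            label_windows(ws, np.full(200, 9))


class TestRepetitionHandling:
    def test_rest_inherits_following_activation(self):
        stim = np.r_[np.zeros(5, int), np.full(4, 2), np.zeros(4, int), np.full(3, 1)]
        rep = np.r_[np.zeros(5, int), np.full(4, 3), np.zeros(4, int), np.full(3, 4)]
        eff = effective_repetition(stim, rep)
        assert list(eff[:5]) == [3] * 5        # leading rest -> next activation
        assert list(eff[9:13]) == [4] * 4      # inner rest -> following activation
        assert list(eff[13:]) == [4] * 3

    def test_trailing_rest_inherits_preceding(self):
        stim = np.r_[np.full(4, 1), np.zeros(6, int)]
        rep = np.r_[np.full(4, 7), np.zeros(6, int)]
        assert list(effective_repetition(stim, rep)[4:]) == [7] * 6


class TestSplitByRepetition:
    def _labelled_ws(self, reps):
        n = len(reps)
        ws = WindowSet(raw=None, features=None, snr_db=None,
                       labels=np.zeros(n, dtype=int), repetition=np.asarray(reps),
                       start_sample=np.arange(n), fs=1000.0,
                       width_samples=200, step_samples=10)
        return ws

    def test_odd_train_even_test(self):
        ws = self._labelled_ws(np.arange(1, 13))
        train, test = split_by_repetition(ws)
        assert set(train.repetition) == {1, 3, 5, 7, 9, 11}
        assert set(test.repetition) == {2, 4, 6, 8, 10, 12}

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        reps = rng.integers(1, 13, 400)
        ws = self._labelled_ws(reps)
        train, test = split_by_repetition(ws)
        assert len(train) + len(test) == len(ws)
        assert np.all(train.repetition % 2 == 1)
        assert np.all(test.repetition % 2 == 0)

    def test_single_repetition_warns_empty_test(self):
        ws = self._labelled_ws(np.ones(10, dtype=int))
        with pytest.warns(UserWarning):
            train, test = split_by_repetition(ws)
        assert len(train) == 10 and len(test) == 0


class TestUndersampleRest:
    def _ws(self, labels):
        labels = np.asarray(labels)
        n = len(labels)
        return WindowSet(raw=None, features=None, snr_db=None, labels=labels,
                         repetition=np.ones(n, dtype=int),
                         start_sample=np.arange(n), fs=1000.0,
                         width_samples=200, step_samples=10)

    def test_rest_reduced_to_mean_activity_count(self):
        labels = np.r_[np.zeros(700, int), np.repeat(np.arange(1, 8), 100)]
        out = undersample_rest(self._ws(labels), seed=0)
        assert np.sum(out.labels == 0) == 100
        for c in range(1, 8):
            assert np.sum(out.labels == c) == 100

    def test_uneven_activity_counts(self):
        labels = np.r_[np.zeros(500, int), np.repeat(np.arange(1, 8),
                                                     [80, 120, 100, 100, 100, 100, 100])]
        out = undersample_rest(self._ws(labels), seed=1)
        assert np.sum(out.labels == 0) == 100  # round(mean) of listed counts

    def test_no_oversampling_when_rest_scarce(self):
        labels = np.r_[np.zeros(50, int), np.repeat(np.arange(1, 8), 100)]
        out = undersample_rest(self._ws(labels), seed=0)
        assert np.sum(out.labels == 0) == 50

    def test_deterministic_and_activity_untouched(self):
        rng = np.random.default_rng(4)
        labels = rng.choice(8, 900, p=[0.6] + [0.4 / 7] * 7)
        a = undersample_rest(self._ws(labels), seed=5)
        b = undersample_rest(self._ws(labels), seed=5)
        assert np.array_equal(a.start_sample, b.start_sample)
        before = np.bincount(labels, minlength=8)
        after = np.bincount(a.labels, minlength=8)
        assert np.array_equal(before[1:], after[1:])
        assert np.all(after <= before)


def test_prepare_session_full_chain(recording):
    prep = prepare_session(recording, seed=0)
    for ws in (prep.train, prep.test):
        assert ws.features is not None and np.all(np.isfinite(ws.features))
        assert ws.snr_db is not None
        assert ws.labels is not None and set(np.unique(ws.labels)) <= set(range(8))
    assert np.all(prep.train.repetition % 2 == 1)
    assert np.all(prep.test.repetition % 2 == 0)
    # normalisation bounds the raw windows
    assert prep.train.raw.min() >= -1.0 - 1e-12
    assert prep.train.raw.max() <= 1.0 + 1e-12
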