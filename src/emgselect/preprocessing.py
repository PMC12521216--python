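"""Turn raw multi-channel sEMG session recordings into balanced, labelled window sets.

The pipeline mirrors the standard real-time myoelectric-control protocol:
per-channel min-max normalisation to [-1, 1], segmentation into 200 ms
windows advanced by 10 ms, window labelling from the per-sample stimulus
vector, an odd/even repetition train/test split, and undersampling of the
over-represented rest class down to the mean activity-class count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .features import extract_rest_reference, td_features_batch, window_snr

N_CLASSES = 8  #: rest (0) plus seven grasps

WINDOW_S = 0.200  #: window width in seconds
STEP_S = 0.010  #: window step in seconds

__all__ = [
    "N_CLASSES",
    "SessionRecording",
    "WindowSet",
    "minmax_normalise",
    "slide_windows",
    "label_windows",
    "effective_repetition",
    "split_by_repetition",
    "undersample_rest",
    "prepare_session",
    "PreparedSession",
]


@dataclass
class SessionRecording:
    """One recording session: raw signal plus per-sample stimulus/repetition.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, n_channels)
        Multi-channel sEMG, raw or normalised amplitude.
    fs : float
        Sampling rate in Hz (2000 for DB6-style recordings).
    stimulus : ndarray of int, shape (n_samples,)
        Class id per sample, 0 = rest, 1..7 = grasps.  Plays the role of
        the refined ("restimulus") label vector.
    repetition : ndarray of int, shape (n_samples,)
        Repetition id per sample (>= 1 during activations, 0 during rest
        in DB6-style files).
    """

    signal: np.ndarray
    fs: float
    stimulus: np.ndarray
    repetition: np.ndarray
    session_id: int = 1
    subject_id: int = 1

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (n_samples, n_channels)")
        self.stimulus = np.asarray(self.stimulus, dtype=np.int64)
        self.repetition = np.asarray(self.repetition, dtype=np.int64)
        n = self.signal.shape[0]
        if len(self.stimulus) != n or len(self.repetition) != n:
            raise ValueError("stimulus/repetition length must match signal")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.stimulus.min(initial=0) < 0 or self.stimulus.max(initial=0) >= N_CLASSES:
            raise ValueError(f"stimulus values must lie in 0..{N_CLASSES - 1}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass
class WindowSet:
    """Segmented windows with features, per-channel SNRs and labels.

    ``raw`` may be None when windows are carried feature-only (the batch
    discriminant pipeline never touches raw samples); the feature matrix
    is ordered (MAV, SSC, ZC, WL) along its last axis.
    """

    raw: np.ndarray | None
    features: np.ndarray | None
    snr_db: np.ndarray | None
    labels: np.ndarray | None
    repetition: np.ndarray | None
    start_sample: np.ndarray
    fs: float
    width_samples: int
    step_samples: int

    def __len__(self) -> int:
        return len(self.start_sample)

    @property
    def n_windows(self) -> int:
        return len(self.start_sample)

    def subset(self, index: np.ndarray) -> "WindowSet":
        """Return a new WindowSet restricted to ``index`` (bool mask or ints)."""
        pick = lambda a: None if a is None else a[index]
        return WindowSet(
            raw=pick(self.raw),
            features=pick(self.features),
            snr_db=pick(self.snr_db),
            labels=pick(self.labels),
            repetition=pick(self.repetition),
            start_sample=self.start_sample[index],
            fs=self.fs,
            width_samples=self.width_samples,
            step_samples=self.step_samples,
        )

    def flat_features(self) -> np.ndarray:
        """Features flattened to (n_windows, n_channels * 4)."""
        if self.features is None:
            raise ValueError("features not computed for this WindowSet")
        return self.features.reshape(len(self), -1)


def minmax_normalise(signal: np.ndarray) -> np.ndarray:
    """Scale each channel linearly so its minimum maps to -1 and maximum to +1.

    A constant channel (zero range) maps to all-zero, keeping the output
    bounded without dividing by zero.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("cannot normalise an empty signal")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    lo = signal.min(axis=0, keepdims=True)
    hi = signal.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.zeros_like(signal)
    nz = span[0] > 0
    out[:, nz] = -1.0 + 2.0 * (signal[:, nz] - lo[:, nz]) / span[:, nz]
    return out


def window_geometry(fs: float) -> tuple[int, int]:
    """(width_samples, step_samples) for the 200 ms / 10 ms scheme at ``fs``."""
    return int(round(WINDOW_S * fs)), int(round(STEP_S * fs))


def slide_windows(recording: SessionRecording, keep_raw: bool = True) -> WindowSet:
    """Segment a recording into 200 ms windows advanced by a 10 ms step.

    Window ``i`` covers samples ``[i*step, i*step + width)``; the number of
    windows is ``floor((n_samples - width)/step) + 1``.
    """
    width, step = window_geometry(recording.fs)
    n = recording.n_samples
    if n < width:
        raise ValueError(f"signal of {n} samples is shorter than one {width}-sample window")
    n_windows = (n - width) // step + 1
    starts = np.arange(n_windows, dtype=np.int64) * step
    raw = None
    if keep_raw:
        view = np.lib.stride_tricks.sliding_window_view(recording.signal, width, axis=0)
        # view: (n-width+1, n_channels, width) -> (n_windows, width, n_channels)
        raw = np.ascontiguousarray(view[::step][:n_windows].transpose(0, 2, 1))
    return WindowSet(
        raw=raw,
        features=None,
        snr_db=None,
        labels=None,
        repetition=None,
        start_sample=starts,
        fs=recording.fs,
        width_samples=width,
        step_samples=step,
    )


def _windowed_majority(values: np.ndarray, starts: np.ndarray, width: int,
                       n_bins: int) -> np.ndarray:
    """Majority value per window; ties resolved toward the lowest bin."""
    counts = np.zeros((len(starts), n_bins), dtype=np.int64)
    for b in range(n_bins):
        csum = np.concatenate(([0], np.cumsum(values == b)))
        counts[:, b] = csum[starts + width] - csum[starts]
    return np.argmax(counts, axis=1)


def label_windows(windowset: WindowSet, stimulus: np.ndarray) -> np.ndarray:
    """Assign one class label per window by majority over its samples.

    Ties are broken toward the lowest class index, so a 50/50
    rest/activity window is conservatively labelled rest.
    """
    stimulus = np.asarray(stimulus, dtype=np.int64)
    if stimulus.min(initial=0) < 0 or stimulus.max(initial=0) >= N_CLASSES:
        raise ValueError(f"stimulus values must lie in 0..{N_CLASSES - 1}")
    last = windowset.start_sample[-1] + windowset.width_samples
    if len(stimulus) < last:
        raise ValueError("stimulus does not cover every window's sample span")
    return _windowed_majority(stimulus, windowset.start_sample,
                              windowset.width_samples, N_CLASSES)


def effective_repetition(stimulus: np.ndarray, repetition: np.ndarray) -> np.ndarray:
    """Repetition vector with rest samples inheriting a repetition id.

    Rest samples take the id of the nearest *following* activation sample
    (the trailing rest at the end of a recording takes the preceding one),
    so rest windows can participate in the odd/even repetition split.
    """
    stimulus = np.asarray(stimulus, dtype=np.int64)
    rep = np.asarray(repetition, dtype=np.int64).copy()
    active = stimulus > 0
    if not active.any():
        return rep
    idx = np.where(active, np.arange(len(rep)), -1)
    # backward fill: index of next active sample
    nxt = np.full(len(rep), -1, dtype=np.int64)
    last = -1
    for i in range(len(rep) - 1, -1, -1):
        if idx[i] >= 0:
            last = i
        nxt[i] = last
    out = rep.copy()
    restmask = ~active
    have_next = nxt >= 0
    out[restmask & have_next] = rep[nxt[restmask & have_next]]
    if (restmask & ~have_next).any():
        last_active = np.where(active)[0][-1]
        out[restmask & ~have_next] = rep[last_active]
    return out


def assign_window_repetitions(windowset: WindowSet, stimulus: np.ndarray,
                              repetition: np.ndarray) -> np.ndarray:
    """Per-window repetition id: majority of the effective per-sample ids."""
    eff = effective_repetition(stimulus, repetition)
    n_bins = int(eff.max()) + 1 if len(eff) else 1
    return _windowed_majority(eff, windowset.start_sample,
                              windowset.width_samples, max(n_bins, 1))


def split_by_repetition(windowset: WindowSet) -> tuple[WindowSet, WindowSet]:
    """Split into (train, test): odd repetition ids train, even ids test."""
    if windowset.repetition is None:
        raise ValueError("windowset has no repetition ids")
    odd = windowset.repetition % 2 == 1
    train, test = windowset.subset(odd), windowset.subset(~odd)
    if len(test) == 0:
        warnings.warn("repetition split produced an empty test set", stacklevel=2)
    return train, test


def undersample_rest(windowset: WindowSet, seed: int = 0) -> WindowSet:
    """Downsample rest windows to the mean count of the activity classes.

    Rest windows are drawn uniformly without replacement with the given
    seed; activity windows are never touched and no class is oversampled.
    """
    if windowset.labels is None:
        raise ValueError("windowset has no labels")
    labels = windowset.labels
    activity_counts = [np.sum(labels == c) for c in range(1, N_CLASSES)]
    activity_counts = [c for c in activity_counts if c > 0]
    if not activity_counts:
        raise ValueError("windowset contains no activity class")
    target = int(round(float(np.mean(activity_counts))))
    rest_idx = np.where(labels == 0)[0]
    if len(rest_idx) <= target:
        return windowset
    rng = np.random.default_rng(seed)
    kept_rest = np.sort(rng.choice(rest_idx, size=target, replace=False))
    keep = np.concatenate((np.where(labels != 0)[0], kept_rest))
    return windowset.subset(np.sort(keep))


@dataclass
class PreparedSession:
    """A session after the full preprocessing chain, ready for the protocol."""

    session_id: int
    train: WindowSet
    test: WindowSet
    rest_reference: "object"  # features.RestReference
    subject_id: int = 1


def prepare_session(recording: SessionRecording, seed: int = 0,
                    keep_raw: bool = True, normalise: bool = True) -> PreparedSession:
    """Run the full chain: normalise → window → feature/SNR → label → split → undersample.

    The rest-power reference for SNR is extracted once per session from the
    normalised signal and reused for every window.
    """
    rec = recording
    if normalise:
        rec = replace(recording, signal=minmax_normalise(recording.signal))
    ref = extract_rest_reference(rec)
    ws = slide_windows(rec, keep_raw=True)
    ws.features = td_features_batch(ws.raw)
    ws.snr_db = window_snr(ws.raw, ref)
    ws.labels = label_windows(ws, rec.stimulus)
    ws.repetition = assign_window_repetitions(ws, rec.stimulus, rec.repetition)
    if not keep_raw:
        ws.raw = None
    train, test = split_by_repetition(ws)
    train = undersample_rest(train, seed=seed)
    test = undersample_rest(test, seed=seed + 1)
    return PreparedSession(session_id=rec.session_id, train=train, test=test,
                           rest_reference=ref, subject_id=rec.subject_id)
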