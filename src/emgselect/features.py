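"""Time-domain features and the SNR quality metric for sEMG windows.

Four classic features are computed per channel of each window:

* MAV  — mean absolute value, ``sum(|x_i|)/N``
* SSC  — slope-sign changes, the count of interior samples that are strict
  local extrema (greater than both neighbours, or less than both)
* ZC   — zero crossings, the count of strict sign changes between
  consecutive samples
* WL   — waveform length, ``sum(|x_{i+1} - x_i|)``

and the window signal-to-noise ratio ``SNR = 10 log10(P_s / P_r)`` where
``P_s`` is the window's mean squared amplitude and ``P_r`` the mean squared
amplitude of a clean one-second rest reference found once per recording.
Mean (not summed) power makes the ratio invariant to the differing lengths
of window and reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FEATURE_NAMES = ("MAV", "SSC", "ZC", "WL")

__all__ = ["FEATURE_NAMES", "RestReference", "td_features", "td_features_batch",
           "extract_rest_reference", "window_snr"]


@dataclass
class RestReference:
    """One second of clean rest and its per-channel mean power ``P_r``."""

    segment: np.ndarray  # (round(fs), n_channels)
    power_per_channel: np.ndarray  # (n_channels,)
    source_interval: tuple[int, int]

    @classmethod
    def from_segment(cls, segment: np.ndarray, interval: tuple[int, int]) -> "RestReference":
        segment = np.asarray(segment, dtype=np.float64)
        power = np.mean(segment**2, axis=0)
        return cls(segment=segment, power_per_channel=power, source_interval=interval)


def td_features_batch(windows: np.ndarray) -> np.ndarray:
    """(MAV, SSC, ZC, WL) per channel for a batch of windows.

    Parameters
    ----------
    windows : ndarray, shape (n_windows, width, n_channels)

    Returns
    -------
    ndarray, shape (n_windows, n_channels, 4)
    """
    x = np.asarray(windows, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected (n_windows, width, n_channels)")
    if x.shape[1] < 3:
        raise ValueError("windows need at least 3 samples (SSC uses interior samples)")
    mav = np.mean(np.abs(x), axis=1)
    d = np.diff(x, axis=1)
    wl = np.sum(np.abs(d), axis=1)
    # strict local extrema: sign of consecutive slopes flips and neither is flat
    ssc = np.sum((d[:, :-1] * d[:, 1:]) < 0, axis=1)
    zc = np.sum((x[:, :-1] * x[:, 1:]) < 0, axis=1)
    return np.stack([mav, ssc, zc, wl], axis=-1)


def td_features(window: np.ndarray) -> np.ndarray:
    """(MAV, SSC, ZC, WL) per channel of a single (width, n_channels) window."""
    window = np.asarray(window, dtype=np.float64)
    if window.ndim == 1:
        window = window[:, None]
    if window.ndim != 2:
        raise ValueError("expected (width, n_channels)")
    return td_features_batch(window[None])[0]


def _rest_runs(stimulus: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, end) runs where stimulus == 0, in order."""
    rest = np.asarray(stimulus) == 0
    if not rest.any():
        return []
    padded = np.concatenate(([False], rest, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def extract_rest_reference(recording) -> RestReference:
    """Locate one second of clean rest for the SNR reference.

    Scans the stimulus vector for rest runs strictly longer than 2 s and
    takes the central 1 s of the first qualifying run.  Raises if the
    recording has no such run (no clean rest available).
    """
    fs = recording.fs
    one_s = int(round(fs))
    min_len = int(round(2.0 * fs))
    for start, end in _rest_runs(recording.stimulus):
        if end - start > min_len:
            centre_off = (end - start - one_s) // 2
            s = start + centre_off
            return RestReference.from_segment(recording.signal[s:s + one_s],
                                              (int(s), int(s + one_s)))
    raise ValueError(
        f"recording session {getattr(recording, 'session_id', '?')} has no rest run "
        "strictly longer than 2 s; cannot build a clean-rest SNR reference")


def window_snr(windows: np.ndarray, ref: RestReference) -> np.ndarray:
    """Per-channel SNR in dB of one window or a batch of windows.

    ``10 log10(P_s / P_r)`` with ``P_s`` the mean squared window amplitude.
    Windows of pure silence get ``-inf`` dB; a zero-power reference channel
    is degenerate and rejected.
    """
    p_r = ref.power_per_channel
    if np.any(p_r <= 0):
        raise ValueError("rest reference has zero power on some channel (degenerate)")
    x = np.asarray(windows, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    p_s = np.mean(x**2, axis=1)
    with np.errstate(divide="ignore"):
        snr = 10.0 * np.log10(p_s / p_r)
    return snr[0] if single else snr
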