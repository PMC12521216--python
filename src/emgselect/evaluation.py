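"""Per-session performance metrics, majority-vote stream smoothing, and
paired significance testing for the inter-session protocol."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, f1_score

from .preprocessing import N_CLASSES

__all__ = ["SessionResult", "metrics", "majority_vote", "f1_delta",
           "wilcoxon_signed_rank", "CHANCE_LEVEL_PCT", "vote_neighbourhood",
           "window_overlap_pct", "half_overlap_neighbours"]

CHANCE_LEVEL_PCT = 100.0 / N_CLASSES  #: 12.5% for the 8-class problem


def vote_neighbourhood(step_ms: float = 10.0, delay_ms: float = 100.0) -> int:
    """Majority-vote window size 2m+1, with m the largest integer whose
    lookahead m*step_ms stays within the acceptable control delay."""
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    return 2 * int(delay_ms // step_ms) + 1


def window_overlap_pct(width_s: float = 0.200, step_s: float = 0.010) -> float:
    """Share of samples two consecutive sliding windows have in common (95%)."""
    return 100.0 * (width_s - step_s) / width_s


def half_overlap_neighbours(width_s: float = 0.200, step_s: float = 0.010) -> int:
    """Number of neighbouring windows (both sides) sharing at least half
    their samples with a given window — the count the edited-nearest-
    neighbour paradigm must skip (20 for 200 ms / 10 ms)."""
    return 2 * int(width_s / (2 * step_s))


@dataclass
class SessionResult:
    """Scores of one session under one protocol configuration.

    ``accuracy_pct`` is None when rejection removed every test window — an
    undefined score is reported as missing, never as zero.
    """

    session_id: int
    accuracy_pct: float | None
    confusion: np.ndarray  # (8, 8), row-normalised %
    f1_per_class: np.ndarray  # (8,)
    macro_f1: float
    retention_pct: np.ndarray | None = None  # per-class training retention
    rejection_pct: float = 0.0  # share of the balanced test set rejected
    n_test_windows_used: int = 0


def metrics(preds: np.ndarray, labels: np.ndarray
            ) -> tuple[float, np.ndarray, np.ndarray, float]:
    """(accuracy %, row-normalised confusion %, per-class F1, macro F1).

    Confusion rows of classes absent from the labels stay all-zero; a
    class absent from both predictions and labels scores F1 = 0, keeping
    the macro average total over the fixed 8-class space.
    """
    preds = np.asarray(preds, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if len(preds) != len(labels):
        raise ValueError("preds/labels length mismatch")
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    acc = 100.0 * float(np.mean(preds == labels))
    cm = confusion_matrix(labels, preds, labels=np.arange(N_CLASSES)).astype(float)
    row = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cm_pct = np.where(row > 0, 100.0 * cm / row, 0.0)
    f1 = f1_score(labels, preds, labels=np.arange(N_CLASSES), average=None,
                  zero_division=0)
    return acc, cm_pct, f1, float(np.mean(f1))


def majority_vote(pred_stream: np.ndarray, step_ms: float = 10.0,
                  delay_ms: float = 100.0) -> np.ndarray:
    """Smooth a prediction stream with a centred modal filter.

    The neighbourhood half-width is the largest integer ``m`` with
    ``m * step_ms <= delay_ms`` (the acceptable control delay), i.e.
    2m+1 = 21 neighbours for the 10 ms step.  At the stream edges the
    window shrinks symmetrically; modal ties go to the lowest class index.
    """
    if step_ms <= 0:
        raise ValueError("step_ms must be positive")
    stream = np.asarray(pred_stream, dtype=np.int64)
    n = len(stream)
    if n == 0:
        return stream.copy()
    m = int(delay_ms // step_ms)
    if m == 0:
        return stream.copy()
    out = np.empty(n, dtype=np.int64)
    n_bins = int(stream.max()) + 1
    for i in range(n):
        h = min(m, i, n - 1 - i)
        out[i] = np.argmax(np.bincount(stream[i - h:i + h + 1], minlength=n_bins))
    return out


def f1_delta(result_start: SessionResult, result_end: SessionResult
             ) -> tuple[np.ndarray, float]:
    """Per-class and macro F1 change between two sessions (end minus start).

    Negative entries mean the class scored lower in the later session.
    """
    delta = result_end.f1_per_class - result_start.f1_per_class
    return delta, result_end.macro_f1 - result_start.macro_f1


def wilcoxon_signed_rank(paired_a, paired_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Significance is conventionally judged at alpha = 0.05.  Identical
    samples (all differences zero) return p = 1 with a warning instead of
    erroring.
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    stat, p = stats.wilcoxon(a, b, alternative="two-sided")
    return float(stat), float(p)
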