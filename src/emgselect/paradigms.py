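"""The three window-selection paradigms for retraining and rejection.

* **QA** (quality acceptance): keep a window only if its strongest channels
  exceed an SNR threshold — by default all three largest per-channel SNRs
  must be strictly above 1.8 dB.  Purely data-driven; no classifier needed.
* **ENN** (edited nearest neighbour): keep a window only if an
  inverse-distance-weighted vote of its nearest *non-overlapping*
  neighbours (the 20 nearest are skipped because consecutive 200 ms/10 ms
  windows share up to 95% of their samples; the next 7 vote) agrees with
  its true label.
* **CR** (confidence retraining): keep a window only if the current
  classifier's maximum class probability is at or above 75%.  Kept windows
  always carry their true labels (supervised variant).

Each paradigm doubles as a test-time rejection rule via
:func:`reject_test`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.neighbors import KDTree

from .preprocessing import N_CLASSES

__all__ = ["SelectionConfig", "SelectionMask", "qa_select", "enn_select",
           "cr_select", "reject_test", "PARADIGMS"]

PARADIGMS = ("QA", "ENN", "CR", "NONE")

_ZERO_DIST_EPS = 1e-12  # cap for 1/d weights of duplicate feature vectors


@dataclass
class SelectionConfig:
    """Tunable thresholds of the three paradigms.

    Defaults follow the reference protocol: 75% confidence threshold,
    1.8 dB SNR threshold on the top 3 channels, ENN voting with neighbours
    21 through 27 (skip 20, vote 7) under Euclidean distance on
    standardised time-domain features.
    """

    cr_threshold: float = 0.75
    snr_threshold_db: float = 1.8
    snr_top_channels: int = 3
    snr_aggregate: str = "all"  # "all": every top-k SNR must clear; "any": one suffices
    enn_vote_k: int = 7
    enn_skip: int = 20
    distance: str = "euclidean"
    enn_standardise: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.cr_threshold <= 1.0:
            raise ValueError("cr_threshold must lie in [0, 1]")
        if self.enn_vote_k < 1 or self.enn_skip < 0:
            raise ValueError("enn_vote_k must be >= 1 and enn_skip >= 0")
        if self.snr_aggregate not in ("all", "any"):
            raise ValueError("snr_aggregate must be 'all' or 'any'")


@dataclass
class SelectionMask:
    """Per-window keep/reject decision of one paradigm, with provenance."""

    keep: np.ndarray
    paradigm: str
    retention_per_class: np.ndarray | None = None
    score: np.ndarray | None = None  # the quantity each decision compared
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def retention_pct(self) -> float:
        return 100.0 * self.keep.mean() if len(self.keep) else 0.0


def _retention_per_class(keep: np.ndarray, labels: np.ndarray | None) -> np.ndarray | None:
    if labels is None:
        return None
    out = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        m = labels == c
        if m.any():
            out[c] = 100.0 * keep[m].mean()
    return out


def qa_select(snr_db: np.ndarray, cfg: SelectionConfig | None = None,
              labels: np.ndarray | None = None) -> SelectionMask:
    """Quality-acceptance selection from per-window, per-channel SNRs.

    Under the default ``all`` aggregation a window is kept iff its
    ``snr_top_channels`` largest SNRs are *all* strictly above the
    threshold — equivalently, iff its k-th largest SNR clears it.
    """
    cfg = cfg or SelectionConfig()
    snr_db = np.atleast_2d(np.asarray(snr_db, dtype=np.float64))
    k = cfg.snr_top_channels
    if snr_db.shape[1] < k:
        raise ValueError(f"need at least {k} channels, got {snr_db.shape[1]}")
    top = np.sort(snr_db, axis=1)[:, -k:]
    score = top[:, 0] if cfg.snr_aggregate == "all" else top[:, -1]
    keep = score > cfg.snr_threshold_db
    return SelectionMask(keep=keep, paradigm="QA", score=score,
                         retention_per_class=_retention_per_class(keep, labels),
                         config=asdict(cfg))


def enn_weighted_vote(features: np.ndarray, labels: np.ndarray,
                      cfg: SelectionConfig) -> np.ndarray:
    """Per-window class predicted by the inverse-distance neighbour vote.

    For each window, every *other* window is ranked by distance; the
    ``enn_skip`` nearest are excluded (overlapping information) and the
    next ``enn_vote_k`` each add weight ``1/d`` to their class.  Zero
    distances are capped at ``1/1e-12`` so duplicates still dominate.
    Ties in the vote go to the lowest class index.
    """
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = len(X)
    if n <= cfg.enn_skip + cfg.enn_vote_k:
        raise ValueError(
            f"need more than enn_skip + enn_vote_k = {cfg.enn_skip + cfg.enn_vote_k} "
            f"windows, got {n}")
    if cfg.enn_standardise:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    tree = KDTree(X, metric=cfg.distance)
    k_query = cfg.enn_skip + cfg.enn_vote_k + 1  # +1: the query point itself
    dist, idx = tree.query(X, k=k_query)
    # drop self (distance-0 column; guaranteed within the first column set)
    self_col = idx == np.arange(n)[:, None]
    # keep first occurrence of self only; mask it out
    keep_cols = ~(self_col & (np.cumsum(self_col, axis=1) == 1))
    voters_d = np.empty((n, k_query - 1))
    voters_l = np.empty((n, k_query - 1), dtype=np.int64)
    for i in range(n):
        cols = np.flatnonzero(keep_cols[i])[: k_query - 1]
        voters_d[i] = dist[i, cols]
        voters_l[i] = labels[idx[i, cols]]
    voters_d = voters_d[:, cfg.enn_skip:]
    voters_l = voters_l[:, cfg.enn_skip:]
    w = 1.0 / np.maximum(voters_d, _ZERO_DIST_EPS)
    votes = np.zeros((n, N_CLASSES))
    for j in range(voters_l.shape[1]):
        np.add.at(votes, (np.arange(n), voters_l[:, j]), w[:, j])
    return np.argmax(votes, axis=1)


def enn_select(features: np.ndarray, labels: np.ndarray,
               cfg: SelectionConfig | None = None) -> SelectionMask:
    """Edited-nearest-neighbour selection: keep windows whose neighbour vote
    agrees with their true label."""
    cfg = cfg or SelectionConfig()
    labels = np.asarray(labels, dtype=np.int64)
    expected = enn_weighted_vote(features, labels, cfg)
    keep = expected == labels
    return SelectionMask(keep=keep, paradigm="ENN", score=expected.astype(float),
                         retention_per_class=_retention_per_class(keep, labels),
                         config=asdict(cfg))


def cr_select(probabilities: np.ndarray, labels: np.ndarray | None = None,
              cfg: SelectionConfig | None = None) -> SelectionMask:
    """Confidence-based selection: keep windows whose maximum class
    probability is at or above the threshold (default 75%)."""
    cfg = cfg or SelectionConfig()
    P = np.atleast_2d(np.asarray(probabilities, dtype=np.float64))
    if np.any(P < 0):
        raise ValueError("probability rows contain negative entries")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValueError("probability rows do not sum to 1")
    score = P.max(axis=1)
    keep = score >= cfg.cr_threshold
    return SelectionMask(keep=keep, paradigm="CR", score=score,
                         retention_per_class=_retention_per_class(
                             keep, None if labels is None else np.asarray(labels)),
                         config=asdict(cfg))


def reject_test(paradigm: str, cfg: SelectionConfig | None = None, *,
                snr_db: np.ndarray | None = None,
                probabilities: np.ndarray | None = None,
                features: np.ndarray | None = None,
                labels: np.ndarray | None = None) -> SelectionMask:
    """Apply a paradigm's acceptance rule to a test set for rejection.

    The decision rules are identical to the select operations; rejected
    windows are simply excluded from performance metrics downstream.  ENN
    rejection needs true labels — a documented supervision requirement
    that limits its online use.
    """
    cfg = cfg or SelectionConfig()
    paradigm = paradigm.upper()
    if paradigm == "QA":
        if snr_db is None:
            raise ValueError("QA rejection needs per-window SNRs")
        return qa_select(snr_db, cfg, labels=labels)
    if paradigm == "CR":
        if probabilities is None:
            raise ValueError("CR rejection needs classifier probabilities")
        return cr_select(probabilities, labels=labels, cfg=cfg)
    if paradigm == "ENN":
        if features is None or labels is None:
            raise ValueError("ENN rejection needs features and true labels "
                             "(supervised requirement)")
        return enn_select(features, labels, cfg)
    if paradigm == "NONE":
        n = len(snr_db) if snr_db is not None else (
            len(probabilities) if probabilities is not None else len(features))
        return SelectionMask(keep=np.ones(n, dtype=bool), paradigm="NONE",
                             retention_per_class=_retention_per_class(
                                 np.ones(n, dtype=bool), labels))
    raise ValueError(f"unknown paradigm {paradigm!r}")
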