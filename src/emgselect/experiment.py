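"""The inter-session train/retrain/test protocol as a model/results pair.

:class:`InterSessionExperiment` is built from session recordings (or
already-prepared window sets) plus a paradigm, classifier kind and mode;
``fit()`` executes the protocol — fit on session 1's training split,
expose each later session's training split to the paradigm, retrain on the
accepted windows, score on that session's test split with optional
paradigm-based rejection or majority-vote smoothing — and returns an
:class:`ExperimentResults` carrying per-session accuracies, confusion
matrices, F1 scores, retention and rejection rates, with a ``summary()``
table and a paired Wilcoxon ``compare()``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import evaluation
from .classifiers import make_classifier
from .evaluation import SessionResult, f1_delta, majority_vote, metrics, \
    wilcoxon_signed_rank
from .paradigms import SelectionConfig, SelectionMask, cr_select, enn_select, \
    qa_select, reject_test
from .preprocessing import N_CLASSES, PreparedSession, SessionRecording, \
    WindowSet, prepare_session

__all__ = ["InterSessionExperiment", "ExperimentResults", "run_protocol"]

MODES = ("none", "retrain", "reject", "both")


class InterSessionExperiment:
    """Protocol model: sessions + paradigm + classifier + mode.

    Parameters
    ----------
    sessions : list of SessionRecording or PreparedSession
        Raw recordings are preprocessed (normalise, window, feature/SNR,
        label, odd/even split, rest undersample) on construction.
    paradigm : {"qa", "enn", "cr", "none"}
    classifier : {"lda", "convnet"}
        The batch discriminant retrains by refitting on its cumulative
        pool; the convolutional net retrains incrementally on accepted
        windows only.
    mode : {"none", "retrain", "reject", "both"}
    vote : bool
        Apply 21-neighbour majority-vote smoothing to each session's test
        prediction stream (an alternative post-processing to rejection).
    """

    def __init__(self, sessions, paradigm: str = "none", classifier: str = "lda",
                 mode: str = "none", selection: SelectionConfig | None = None,
                 seed: int = 0, vote: bool = False, normalise: bool = True):
        self.paradigm = paradigm.upper()
        self.classifier_kind = classifier
        self.mode = mode.lower()
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        if self.paradigm not in ("QA", "ENN", "CR", "NONE"):
            raise ValueError(f"unknown paradigm {paradigm!r}")
        if self.mode != "none" and self.paradigm == "NONE":
            raise ValueError(f"mode {mode!r} needs a paradigm")
        self.selection = selection or SelectionConfig()
        self.seed = seed
        self.vote = vote
        needs_raw = make_classifier(classifier).kind == "incremental_convnet"
        self.sessions: list[PreparedSession] = []
        for i, s in enumerate(sessions):
            if isinstance(s, SessionRecording):
                s = prepare_session(s, seed=seed + 7919 * i, keep_raw=needs_raw,
                                    normalise=normalise)
            self.sessions.append(s)
        if not self.sessions:
            raise ValueError("need at least one session")

    # -- classifier I/O selection -----------------------------------------
    def _inputs(self, ws: WindowSet) -> np.ndarray:
        if make_classifier(self.classifier_kind).kind == "incremental_convnet":
            if ws.raw is None:
                raise ValueError("convnet requires raw windows (keep_raw=True)")
            return ws.raw
        return ws.flat_features()

    def _select_training(self, clf, ws: WindowSet) -> SelectionMask:
        labels = ws.labels
        if self.paradigm == "QA":
            return qa_select(ws.snr_db, self.selection, labels=labels)
        if self.paradigm == "ENN":
            return enn_select(ws.flat_features(), labels, self.selection)
        if self.paradigm == "CR":
            probs = clf.predict_proba(self._inputs(ws))
            return cr_select(probs, labels=labels, cfg=self.selection)
        raise ValueError(f"paradigm {self.paradigm!r} cannot select windows")

    def _reject_testing(self, clf, ws: WindowSet) -> SelectionMask:
        aux = {}
        if self.paradigm == "QA":
            aux["snr_db"] = ws.snr_db
        elif self.paradigm == "CR":
            aux["probabilities"] = clf.predict_proba(self._inputs(ws))
        elif self.paradigm == "ENN":
            aux["features"] = ws.flat_features()
        return reject_test(self.paradigm, self.selection, labels=ws.labels, **aux)

    def fit(self) -> "ExperimentResults":
        """Run the protocol over all sessions, in session order."""
        clf = make_classifier(self.classifier_kind, seed=self.seed)
        results: list[SessionResult] = []
        retrain_mode = self.mode in ("retrain", "both")
        reject_mode = self.mode in ("reject", "both")

        first = self.sessions[0]
        clf.fit(self._inputs(first.train), first.train.labels)

        for i, sess in enumerate(self.sessions):
            retention = None
            if i > 0 and retrain_mode:
                mask = self._select_training(clf, sess.train)
                retention = mask.retention_per_class
                clf.retrain(self._inputs(sess.train)[mask.keep],
                            sess.train.labels[mask.keep])

            test = sess.test
            preds = clf.predict(self._inputs(test))
            if self.vote:
                step_ms = 1000.0 * test.step_samples / test.fs
                preds = majority_vote(preds, step_ms=step_ms)

            keep = np.ones(len(test), dtype=bool)
            rejection_pct = 0.0
            if reject_mode:
                rmask = self._reject_testing(clf, test)
                keep = rmask.keep
                rejection_pct = 100.0 - rmask.retention_pct

            if keep.sum() == 0:
                warnings.warn(
                    f"session {sess.session_id}: every test window was rejected; "
                    "accuracy is undefined for this session", stacklevel=2)
                results.append(SessionResult(
                    session_id=sess.session_id, accuracy_pct=None,
                    confusion=np.zeros((N_CLASSES, N_CLASSES)),
                    f1_per_class=np.zeros(N_CLASSES), macro_f1=0.0,
                    retention_pct=retention, rejection_pct=rejection_pct,
                    n_test_windows_used=0))
                continue

            acc, cm, f1, macro = metrics(preds[keep], test.labels[keep])
            results.append(SessionResult(
                session_id=sess.session_id, accuracy_pct=acc, confusion=cm,
                f1_per_class=f1, macro_f1=macro, retention_pct=retention,
                rejection_pct=rejection_pct, n_test_windows_used=int(keep.sum())))
        return ExperimentResults(self, results)


class ExperimentResults:
    """Per-session scores of one fitted protocol configuration."""

    def __init__(self, model: InterSessionExperiment, session_results: list[SessionResult]):
        self.model = model
        self.session_results = session_results

    @property
    def accuracies(self) -> np.ndarray:
        """Accuracy (%) per session; NaN where rejection emptied the test set."""
        return np.array([np.nan if r.accuracy_pct is None else r.accuracy_pct
                         for r in self.session_results])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.session_results:
            rows.append({
                "session": r.session_id,
                "accuracy_pct": np.nan if r.accuracy_pct is None else r.accuracy_pct,
                "macro_f1": r.macro_f1,
                "rejection_pct": r.rejection_pct,
                "n_test_windows": r.n_test_windows_used,
                "mean_retention_pct": (np.nan if r.retention_pct is None
                                       else float(np.nanmean(r.retention_pct))),
            })
        df = pd.DataFrame(rows)
        df.insert(0, "mode", self.model.mode)
        df.insert(0, "classifier", self.model.classifier_kind)
        df.insert(0, "paradigm", self.model.paradigm)
        return df

    def f1_delta(self, start: int = 0, end: int = -1) -> tuple[np.ndarray, float]:
        """Per-class and macro F1 change between two sessions (default first→last)."""
        return f1_delta(self.session_results[start], self.session_results[end])

    def compare(self, other: "ExperimentResults") -> tuple[float, float]:
        """Paired Wilcoxon signed-rank test on per-session accuracies."""
        return wilcoxon_signed_rank(self.accuracies, other.accuracies)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Inter-session sEMG protocol results",
            "=" * 58,
            f"paradigm: {m.paradigm:<6} classifier: {m.classifier_kind:<8} "
            f"mode: {m.mode:<8} vote: {m.vote}",
            f"sessions: {len(self.session_results)}   seed: {m.seed}",
            "-" * 58,
            f"{'session':>7} {'accuracy%':>10} {'macroF1':>8} "
            f"{'reject%':>8} {'n_test':>7}",
        ]
        for r in self.session_results:
            acc = "   --" if r.accuracy_pct is None else f"{r.accuracy_pct:10.2f}"
            lines.append(f"{r.session_id:>7} {acc:>10} {r.macro_f1:8.3f} "
                         f"{r.rejection_pct:8.2f} {r.n_test_windows_used:>7}")
        accs = self.accuracies
        if np.isfinite(accs).any():
            lines.append("-" * 58)
            lines.append(f"mean accuracy: {np.nanmean(accs):.2f}%   "
                         f"final session: {accs[-1]:.2f}%")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<ExperimentResults paradigm={self.model.paradigm} "
                f"classifier={self.model.classifier_kind} mode={self.model.mode} "
                f"sessions={len(self.session_results)}>")


def run_protocol(sessions, paradigm: str, classifier_kind: str, mode: str,
                 seed: int = 0, selection: SelectionConfig | None = None,
                 vote: bool = False) -> list[SessionResult]:
    """Functional wrapper: run the protocol and return the SessionResult list."""
    exp = InterSessionExperiment(sessions, paradigm=paradigm,
                                 classifier=classifier_kind, mode=mode,
                                 selection=selection, seed=seed, vote=vote)
    return exp.fit().session_results
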