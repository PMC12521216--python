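"""Reading and writing session recordings.

Two formats are supported: DB6-style MATLAB ``.mat`` files (fields ``emg``
[samples x channels], ``restimulus``, ``rerepetition``) and a portable
container (a ``.npz`` array bundle beside a JSON metadata sidecar carrying
sampling rate, subject and session ids).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.io import loadmat, savemat

from .preprocessing import SessionRecording

__all__ = ["load_mat_session", "save_mat_session",
           "load_session", "save_session"]

DEFAULT_FS = 2000.0


def load_mat_session(path, fs: float = DEFAULT_FS, session_id: int = 1,
                     subject_id: int = 1) -> SessionRecording:
    """Read a DB6-style .mat session (emg, restimulus, rerepetition).

    Repetition ids are preserved exactly as stored (1-based during
    activations, 0 during rest).
    """
    mat = loadmat(str(path))
    missing = [k for k in ("emg", "restimulus", "rerepetition") if k not in mat]
    if missing:
        raise ValueError(f"{path}: missing .mat fields {missing}")
    return SessionRecording(
        signal=np.asarray(mat["emg"], dtype=np.float64),
        fs=float(mat.get("fs", fs).squeeze()) if "fs" in mat else fs,
        stimulus=np.asarray(mat["restimulus"]).ravel(),
        repetition=np.asarray(mat["rerepetition"]).ravel(),
        session_id=session_id, subject_id=subject_id)


def save_mat_session(recording: SessionRecording, path) -> None:
    """Write a recording in the DB6-style .mat field layout."""
    savemat(str(path), {
        "emg": recording.signal,
        "restimulus": recording.stimulus[:, None],
        "rerepetition": recording.repetition[:, None],
        "fs": np.array([[recording.fs]]),
    })


def save_session(recording: SessionRecording, path) -> None:
    """Write the portable container: <path>.npz arrays + <path>.json metadata."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             signal=recording.signal, stimulus=recording.stimulus,
             repetition=recording.repetition)
    meta = {"fs": recording.fs, "session_id": recording.session_id,
            "subject_id": recording.subject_id,
            "n_samples": int(recording.n_samples),
            "n_channels": int(recording.n_channels)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def load_session(path) -> SessionRecording:
    """Read the portable container written by :func:`save_session`."""
    path = Path(path)
    npz = path.with_suffix(".npz")
    meta_path = path.with_suffix(".json")
    if not npz.exists() or not meta_path.exists():
        raise FileNotFoundError(f"missing container files {npz} / {meta_path}")
    arrays = np.load(npz)
    meta = json.loads(meta_path.read_text())
    return SessionRecording(
        signal=arrays["signal"], stimulus=arrays["stimulus"],
        repetition=arrays["repetition"], fs=meta["fs"],
        session_id=meta["session_id"], subject_id=meta["subject_id"])
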