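import numpy as np
import pytest

from emgselect import SessionRecording, SimulationConfig, simulate_multisession


def make_recording(fs=1000.0, n_channels=3, segments=None, seed=0,
                   session_id=1) -> SessionRecording:
    """Hand-built recording from (duration_s, class, repetition, amplitude) segments."""
    if segments is None:
        segments = [(3.0, 0, 0, 0.05), (2.0, 1, 1, 0.6), (3.0, 0, 0, 0.05),
                    (2.0, 1, 2, 0.6), (2.5, 0, 0, 0.05)]
    rng = np.random.default_rng(seed)
    sig, stim, rep = [], [], []
    for dur, cls, r, amp in segments:
        n = int(round(dur * fs))
        sig.append(amp * rng.standard_normal((n, n_channels)))
        stim.append(np.full(n, cls, dtype=np.int64))
        rep.append(np.full(n, r, dtype=np.int64))
    return SessionRecording(signal=np.concatenate(sig), fs=fs,
                            stimulus=np.concatenate(stim),
                            repetition=np.concatenate(rep),
                            session_id=session_id)


@pytest.fixture
def recording():
    return make_recording()


@pytest.fixture(scope="session")
def tiny_sessions():
    """Three small drifting synthetic sessions, shared across tests."""
    cfg = SimulationConfig.desk_scale(n_sessions=3, n_reps=2, n_channels=4,
                                      activation_s=1.0, rest_s=1.0, seed=42)
    return simulate_multisession(cfg)
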