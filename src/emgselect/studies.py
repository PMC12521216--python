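"""Reproducible desk-scale studies of inter-session drift and retraining.

These functions package the full simulation → preprocessing → protocol
chain at a reduced problem size (4 repetitions of each grasp, 1.5 s
activations/rests, 1 kHz, 8 channels, 10 sessions) so the qualitative
phenomena — accuracy collapse of a fixed classifier under drift, recovery
through paradigm-selected retraining — can be reproduced in minutes on a
single CPU.  Only the batch discriminant classifier is used here; the
incremental network follows the same protocol but trains far longer.
"""

from __future__ import annotations

import numpy as np

from .experiment import InterSessionExperiment
from .paradigms import SelectionConfig
from .preprocessing import prepare_session
from .simulate import SimulationConfig, simulate_multisession

__all__ = ["drift_recovery_study", "no_drift_control"]


def _prepared_sessions(cfg: SimulationConfig, seed: int):
    recs = simulate_multisession(cfg)
    return [prepare_session(r, seed=seed + 7919 * i, keep_raw=False)
            for i, r in enumerate(recs)]


def drift_recovery_study(n_seeds: int = 10, base_seed: int = 0,
                         paradigms: tuple[str, ...] = ("qa", "enn", "cr"),
                         sim_overrides: dict | None = None) -> dict:
    """Baseline vs paradigm-retrained accuracy across 10 drifting sessions.

    For each seed, one synthetic subject is simulated at the calibrated
    default drift; a batch discriminant is fit on session 1 and either
    left alone (baseline) or retrained on each later session's
    paradigm-accepted windows.  Returns per-paradigm mean accuracies per
    session plus the baseline's session-1→2 and 1→10 losses, averaged
    over seeds.
    """
    acc = {p: [] for p in ("none", *paradigms)}
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = SimulationConfig.desk_scale(seed=seed, **(sim_overrides or {}))
        prepared = _prepared_sessions(cfg, seed)
        for p in acc:
            mode = "none" if p == "none" else "retrain"
            res = InterSessionExperiment(
                prepared, paradigm=p, classifier="lda", mode=mode,
                selection=SelectionConfig(), seed=seed).fit()
            acc[p].append(res.accuracies)
    mean_acc = {p: np.mean(np.vstack(v), axis=0) for p, v in acc.items()}
    base = mean_acc["none"]
    return {
        "mean_accuracy_per_session": mean_acc,
        "baseline_session2_drop_pct": float(base[0] - base[1]),
        "baseline_session10_drop_pct": float(base[0] - base[-1]),
        "final_session_gain_pct": {
            p: float(mean_acc[p][-1] - base[-1]) for p in paradigms},
        "n_seeds": n_seeds,
    }


def no_drift_control(n_seeds: int = 10, base_seed: int = 0,
                     sim_overrides: dict | None = None) -> float:
    """Mean session-1→2 accuracy loss with drift switched off (should be ~0)."""
    drops = []
    for s in range(n_seeds):
        seed = base_seed + s
        cfg = SimulationConfig.desk_scale(n_sessions=2, drift_scale=0.0,
                                          seed=seed, **(sim_overrides or {}))
        prepared = _prepared_sessions(cfg, seed)
        res = InterSessionExperiment(prepared, paradigm="none", classifier="lda",
                                     mode="none", seed=seed).fit()
        drops.append(res.accuracies[0] - res.accuracies[1])
    return float(np.mean(drops))
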