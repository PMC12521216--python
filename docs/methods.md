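# Methods

This note documents the models and procedures `emgselect` implements, the
choices made where the protocol leaves details open, and what the
synthetic data can and cannot establish.

## Preprocessing

Each session is processed independently. Signals are min-max normalised
per channel to [−1, 1] (channels have different gains; sessions are
processed independently, so the bounds come from the whole session). A
constant channel maps to all-zero rather than dividing by zero. Windows
are 200 ms wide and advance by 10 ms — the standard real-time operating
point — giving `floor((n − width)/step) + 1` windows.

Each window takes the majority class of its samples; ties break toward
the lowest class index, so a 50/50 rest/activity transition window is
conservatively labelled rest. The stimulus vector plays the role of a
refined activity annotation; no rule for boundary windows is canonical,
and majority labelling is a deliberate choice (discarding straddling
windows is the obvious alternative).

Rest samples carry no repetition id, so rest windows inherit the id of
the nearest *following* activation (trailing rest takes the preceding
one); odd repetitions form the training split and even repetitions the
test split of every session. Because roughly half of each recording is
rest, rest windows are undersampled (uniformly, seeded) down to the
rounded mean of the activity-class counts, in both splits.

## Features and SNR

Per channel of each window: MAV `Σ|xᵢ|/N`, SSC (count of strict interior
local extrema), ZC (count of strict sign changes), WL `Σ|xᵢ₊₁ − xᵢ|`.
A common printed form of the ZC indicator assigns 1 to the
"otherwise" branch, which would make ZC ≡ N−1; the standard
0-otherwise count is implemented. No amplitude deadzone is applied to ZC
or SSC.

`SNR = 10 log₁₀(P_s/P_r)` uses **mean** squared amplitude on both sides
so the 200 ms window and the 1 s reference are comparable. The reference
is the central second of the first rest run strictly longer than 2 s,
found once per recording and reused for all of its windows; a recording
without such a run has no clean rest and is rejected. SNR is computed for
every window uniformly (the QA rule needs it on rest windows too).

## Selection paradigms

* **QA**: a window is kept iff *all* of its three largest channel SNRs
  strictly exceed 1.8 dB — equivalently its third-largest SNR does. The
  "all-of-top-3" aggregation is the stricter reading of comparing "the
  three largest SNRs" with the threshold and gives the expected low
  rest-class retention on noisy data; `snr_aggregate="any"` exposes the
  lenient alternative.
* **ENN**: Euclidean nearest neighbours on standardised flattened
  time-domain features (standardisation stops WL's magnitude from
  dominating the metric; the neighbour search uses a k-d tree). The 20
  nearest neighbours are skipped — exactly the windows sharing ≥ 50% of
  their samples at the 200 ms/10 ms geometry — and the next 7 vote with
  weight 1/d into the 8 class slots; zero distances are capped at
  1/10⁻¹². The window is kept iff the argmax of the vote (lowest index on
  ties) equals its true label.
* **CR**: kept iff the classifier's maximum class probability is ≥ 0.75
  (inclusive). Kept windows always carry their true labels; the
  unsupervised variant (predicted labels) is deliberately not offered.

For test-time rejection the same rules apply to the test split; rejection
only shrinks the evaluation support, never alters predictions of kept
windows. ENN rejection requires true labels — a documented supervision
requirement that limits its online use.

## Classifiers

The batch discriminant is an LDA with lsqr/Ledoit-Wolf shrinkage
(degenerate covariances from duplicated features must not crash). It
keeps a cumulative pool: retraining refits from scratch on pool ∪
accepted windows, so old sessions weigh as much as new ones. The
incremental classifier is a compact convolutional network on raw windows
— conv(k=11, stride 4, 16 filters) → ReLU → conv(k=5, stride 2, 32
filters) → ReLU → global average pooling → dense → softmax(8) — written
directly in numpy, trained with Adam at 0.001 (30 epochs by default) and
retrained *only on accepted new windows* at 0.0001 (10 epochs). Epoch
counts are fixed, early stopping is off, and one root seed drives
initialisation and batch order, so runs repeat exactly. Whether
retraining should also replay session-1 data is an open design point;
pure incremental updating is the default here because it is what makes
iterative nets attractive for drift. The output space is pinned to 8
classes even when a retraining batch misses classes, keeping confusion
matrices comparable across sessions.

## Augmentation and simulation

Pink noise is synthesised by 1/√f spectral shaping of white Gaussian
noise (PSD ∝ 1/f, measured log-log slope ≈ −1 over 1–500 Hz),
renormalised to unit variance per channel. Augmentation adds
`k · noise_rms · pink` with the *largest integer* k that keeps the
recording's average SNR — the mean over windows of the mean of each
window's three largest channel SNRs — at or above 1.8 dB. The noise is
generated once and scaled, never redrawn per candidate k, and the scan
evaluates the quadratic-in-k window powers in closed form. `noise_rms`
(default 0.05 in normalised units) sets the step of the integer search;
against [−1, 1]-bounded signals a unit step would almost always force
k = 0. Downstream SNR uses a rest reference re-extracted from the
augmented signal, as a deployed system would only see the augmented
stream.

The multi-session generator emulates the DB6-style acquisition: per
session, `n_reps` repetitions of each of 7 grasps (defaults: 12
repetitions, 4 s activations and rests, 14 channels, 2 kHz), as
band-limited (20–450 Hz) amplitude-modulated Gaussian noise under
class-specific smooth spatial gain patterns across the electrode ring,
with trapezoidal 0.25 s onset/offset ramps (so transition windows
exercise the labelling rule) over a Gaussian baseline floor
(σ = 0.02). Each channel is clipped at ±3.5 of its standard deviation,
emulating the acquisition chain's symmetric dynamic range; this also pins
the per-channel extremes so min-max normalisation is stable across
sessions (without it, the extremes are single random samples and their
asymmetry injects a random DC offset comparable to the rest amplitude —
an artificial drift).

Drift accumulates from session 2 onward: multiplicative channel-gain
jitter, multiplicative-plus-additive perturbation of the class gain
patterns, and a resampled baseline noise level, all scaled by
`drift_scale`. The default `drift_scale = 0.5` is calibrated over seed batches so the
no-retraining baseline loses ≥ 15 accuracy points from session 1 to 2 at
desk scale, reproducing the qualitative multi-day degradation; with
`drift_scale = 0` inter-session loss is below one point. The generator
does not model motor-unit physiology, real electrode geometry,
within-session fatigue, or the exact SNR statistics of any real dataset —
passing tests show the *protocol and paradigms* behave correctly under
controlled drift, not that any particular real-data accuracy is attained.

## Evaluation protocol

Session 1: fit on its training split, score on its test split. Every
later session: expose its (balanced) training split to the paradigm
(modes `retrain`/`both`), retrain on the accepted windows, then score on
its test split, optionally rejecting windows by the same paradigm (modes
`reject`/`both`). Mode `none` never retrains. Majority-vote smoothing
replaces each streamed prediction with the modal class of its 2m+1
neighbourhood, m = ⌊delay/step⌋ (21 neighbours at 10 ms step and 100 ms
acceptable delay); the window is centred — the delay bound counts
neighbours on either side — and shrinks symmetrically at stream edges,
with modal ties to the lowest class.

Accuracy is the percentage of correct classifications on the (possibly
rejection-reduced) test split; confusion matrices are row-normalised to
percent with all-zero rows for absent classes; per-class F1 uses the 0/0
→ 0 convention so macro-F1 and session deltas stay total. A session whose
test windows are all rejected reports accuracy as *missing* (with a
warning), never 0. Rejection rates are computed on the balanced test
split. Paired accuracies are compared with the two-sided Wilcoxon
signed-rank test at α = 0.05; identical samples return p = 1 with a
warning.

## Desk-scale study conditions

The drift-recovery study in `emgselect.studies` (used by the test suite
and `scripts/acceptance.py`) runs 10 seeds × 10 sessions at a reduced
problem size chosen to keep a full study to minutes on one CPU: 4
repetitions per grasp, 1.5 s activations/rests, 1 kHz, 8 channels
(≈ 8 500 windows per session, ≈ 2 400 balanced training windows), batch
discriminant classifier only. The generator's *defaults* remain the
full-scale acquisition; the reduced sizes are run conditions, and all
thresholds (1.8 dB, 75%, neighbours 21–27) are identical at either scale.

## Known limitations

* ENN is O(n log n) per query but still the slowest paradigm by far; its
  supervision requirement rules out unsupervised online rejection.
* The incremental network is a compact stand-in sized for CPU training;
  it fixes optimiser, learning rates and activation conventions, not any
  particular published architecture.
* Simulated drift is statistical, not biophysical; absolute accuracies on
  synthetic sessions say nothing about real multi-day recordings beyond
  the qualitative collapse-and-recovery pattern.
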