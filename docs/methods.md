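# Methods

This note documents the models, conventions and design decisions behind
`ppgarousal`, in the order data flows through the pipeline.

## Event selection

An arousal enters the analysis when it passes, in this order (only the first
failing rule is logged): duration 3–15 s; a scored sleep stage in its own or
the previous 30-s epoch; no other arousal and no respiratory event other
than the assumed cause within 10 s of its start or end; a scored cause of
spontaneous or respiratory (limb-movement and other arousals are out of
scope); and, for respiratory arousals, a *unique* obstructive event
(obstructive apnea or hypopnea) of ≥ 10 s ending between 5 s before the
arousal start and the arousal end. Respiratory causes are split by event
type and by whether a ≥3% desaturation accompanied the event.

Two conventions are ours where the scoring rules leave a gap:

* **Desaturation accompaniment.** A desaturation "accompanies" an event when
  it overlaps `[event start, event end + D)` with `D = 20 s` by default
  (config `desat_window_s`), allowing for circulatory delay between the
  airway event and the oximeter reading.
* **Proximity exemption.** Obstructive events that end inside the
  association window of a scored-respiratory arousal are treated as "the
  assumed cause" for the proximity rule even when they later fail the 10-s
  length gate, so such arousals are logged under `association` (the rule
  that actually disqualifies them) rather than `proximity`.

Stable-sleep references are 10-s windows free of any scored event and of
stage transitions, enumerated on a 1-s grid and greedily thinned to be
non-overlapping (the enumeration grid is a convention; no scored quantity
depends on it). Per stage they are randomly permuted and drawn up to the
subject's number of included respiratory arousals in that stage.

## Characteristics

Segments cover `[start − 10 s, end + 10 s)` at 64 Hz (polyphase FIR
resampling for other input rates; IIR decimation was rejected because its
passband droop is ~1%, visible in amplitude comparisons). The mean
instantaneous frequency is the power-weighted mean of a spectrogram with a
2-s boxcar window, hop 1 sample and a zero-padded 1024-point transform
(bins 0–32 Hz, 1/16 Hz); windows are raw (no detrend): the residual DC
power deflates the estimate slightly but identically across a trace, so
before/after contrasts are unaffected. The instantaneous amplitude is
max − min over the same 2-s window. Both traces are smoothed with a 2-s
moving average; windowing and smoothing each consume half a window per end,
so the final trace spans `[−8 s, end + 8 s)` — the arousal duration plus
16 s — with t = 0 at the EEG arousal start.

Known estimator properties, visible in the synthetic-truth comparisons:

* Spectral leakage of the boxcar window biases the weighted mean upward by
  ≈ 0.05–0.1 Hz for band-limited signals; the bias is common mode.
* For a pulse train, harmonics pull the weighted mean above the pulse rate
  by the power-weighted mean harmonic index (≈ 1.15 for the synthetic pulse
  shape); again common mode within a subject.
* The max − min amplitude lags *falling* envelopes by up to ~1 s (the
  largest cycle in the window dominates until it leaves the window), so
  amplitude-response delays read systematically ~0.5–1 s later than the
  planted envelope midpoint. Frequency delays are unbiased to within the
  pulse-period quantisation.

## Response model

The triple-logistic step model (growth rate fixed at 5, comparable to the
time scale of arousal responses) is fitted by bounded least squares
(trust-region reflective, analytic Jacobian, tolerances 1e-8, ≤ 2000
evaluations) from all 45 combinations of the documented initial-guess grids:
`c₁ ∈ {−4,−2,0,2,4}` s around the arousal start, `c₂ᵣ ∈ {0.25,0.5,0.75}`
around the halfway point, `c₃ᵣ ∈ {0.6,0.8,0.95}` biased late to catch very
late changes; `a` starts at the pre-arousal median, `b₁` at 0 (no
directional bias), the relative magnitudes at 1. Bounds:
`a ∈ [0, y_max]`, `b₁ ∈ [−y_max, y_max]`, `b₂ᵣ, b₃ᵣ ∈ [0, 20]`,
`c₁ ∈ [t_min, t_max − 3]`, `c₂ᵣ, c₃ᵣ ∈ [0, 1]`, where `y_max` is the
largest trace value in the window. The minimum-SSR fit wins; ties break by
grid order. Residuals are evaluated on every 4th trace sample
(`fit_stride`); the 2-s-smoothed trace carries no structure finer than
that, and reported SSR is always recomputed on the full grid. Arousals
where every start fails are discarded and logged.

**Categorisation.** A step is considerable when its magnitude exceeds 5% of
the mean fitted value over the window (config `considerable_fraction`; the
threshold is relative, making calls invariant to signal rescaling — the 5%
level itself is a convention and is exposed in config). The sign of the
first step (2 options) times the considerability pattern of the three steps
(8 options) yields 16 fit classes. The response is the considerable step in
the response direction — frequency increase, amplitude decrease — whose
post-step level lies farthest from the window-start level `a`; magnitude is
`|level_after − a|` (with `level_before = a`), delay is the step's logistic
midpoint (negative delays are legitimate: autonomic changes can precede the
EEG arousal), and recovery is any later considerable step in the opposite
direction. These semantics were fixed by requiring both worked examples in
the README's reference fit to reproduce exactly.

## Inference

Arousal groups share subjects, so all magnitude/delay/level comparisons use
the Wilcoxon signed-rank test on within-subject pairs, iterated 1000 times:
per iteration the larger side of each shared subject is sampled without
replacement down to the smaller side and paired at random; pairs are pooled
and tested; the median p over iterations is reported against a global
threshold of 0.01 (no further multiplicity correction — the threshold is
deliberately strict instead). The signed-rank implementation uses the exact
null for ≤ 25 zero-free pairs and the normal approximation with Pratt zero
handling otherwise; all-zero difference sets are degenerate and reported as
p = 1. One-sided directions are set by the tested hypothesis (recorded per
comparison). Proportions are compared as relative risks of *not* detecting
the outcome, with log-normal 99% CIs
(`exp(log rr ± z₀.₉₉₅·√(1/x₁ − 1/n₁ + 1/x₂ − 1/n₂))`, Haldane 0.5
correction for zero counts, flagged); treating arousals as independent
within the RR is a simplification — the iterated paired tests, not the RRs,
carry the subject structure. Before/after levels are compared against the
pooled median of stable-sleep sample means; the one-sample test is iterated
with per-subject subsampling down to the subject's stable-sample count
(switchable to a plain one-sample test, since a resampled one-sample
variant is a design choice, not a given).

## Synthetic cohort

The generator exists so every stage is testable without clinical data. A
subject is an amplitude-modulated pulse train `A(t)·w(φ(t)) + ε`, where `w`
is a fixed three-harmonic pulse shape (amplitudes 1, 0.35, 0.15 before
unit-energy normalisation; phases 0, 0.6, 1.2) giving the dicrotic-like
spectral spread of real PPG, `φ' = 2π r(t)` with pulse rate `r` carrying
planted logistic frequency steps, `A` carrying planted logistic dips, and
`ε` white Gaussian noise (default sd 0.05 a.u.). Planted frequency
magnitudes are specified in observable mean-instantaneous-frequency units
(the pulse-rate step is divided by the shape's harmonic weight factor);
amplitude drops in measured max − min a.u. Responses without recovery are
closed out 12 s after the arousal end — outside the analysis window — so
effects do not accumulate across arousals. A config switch replaces the
logistic transitions with raised-cosine ones for robustness checks, and a
generator flag plants deliberately excludable arousals (too short/long,
close pairs, sub-10-s events) for testing the selection rules.

Default effect sizes follow the reported clinical group medians where those
exist (frequency magnitudes 0.25/0.18/0.15 Hz for apnea/hypopnea/spontaneous
causes, delays 3.8–4.7 s, amplitude drops 1.29–1.50 a.u. on a 6.32 a.u.
baseline, response proportions 71–84%, recovery proportions 41–68%); spreads,
the cause mix, arousal spacing (90 s), durations (8–12 s) and stage structure
(all N2) are stand-in conventions with no clinical counterpart. What the
generator does **not** emulate: motion artefacts, beat-morphology variability,
respiratory-induced amplitude oscillations, stage-dependent autonomic tone,
and within-night nonstationarity. Passing tests therefore demonstrate that
the pipeline recovers the effects it models under clean-to-moderately-noisy
conditions — not that it is robust to all failure modes of real PPG.

## Problem sizes and validation design

Desk-scale runs use 20-subject cohorts with 6 arousals/subject (analysis
scripts, seed 11) and a 40-subject cohort for end-to-end validation. At 40
subjects the clinical median gaps (e.g. 0.18 vs 0.15 Hz) are not resolvable
at p < 0.01 — the cohorts they come from had hundreds of subjects — so the
ordering-recovery validation plants clearly separated magnitudes
(0.30/0.20/0.12 Hz, unchanged spread) with a balanced cause mix; the
analysis defaults keep the clinical medians. Null calibration of the
iterated test runs on measurement-level cohorts (the property being checked
— type-I error under exchangeable data — is a property of the inference
procedure, not of waveform synthesis).

## Known limitations

* Exact reproduction of the clinical cohort's result tables is out of scope
  by construction: the generator is a stand-in, and all cohort-level numbers
  in `results/` describe synthetic data.
* The 16-class table and the fit-grid constants are reconstructions
  validated against the two worked examples; alternative response/recovery
  semantics could be encoded on top of the same class structure.
* Fitted magnitudes underestimate planted ones by ~10–15% when a recovery
  follows within a few seconds (the plateau is never reached — an honest
  property of step-model quantification, shared with the amplitude
  estimator's envelope lag above).
* No artefact rejection is performed; segments containing movement artefacts
  would be fitted like any other signal.
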