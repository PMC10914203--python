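# ppgarousal

Detection and quantification of photoplethysmogram (PPG) responses to
arousals from sleep.

Cortical arousals — abrupt EEG shifts of 3–15 s scored from polysomnography —
are accompanied by autonomic activation: heart rate rises and peripheral
vasoconstriction shrinks the pulse wave. Both effects are visible in the PPG:
its dominant frequency tracks pulse rate and its amplitude tracks peripheral
blood-volume pulsation. This package implements a pipeline that measures
those responses per arousal and compares them across arousal causes
(spontaneous vs. obstructive apnea/hypopnea, with or without ≥3% oxygen
desaturation). It is aimed at sleep-research groups who have PSG exports
(PPG waveform + event scorings) and want per-arousal autonomic response
magnitudes and delays, and at methods developers who need a testbed with
known ground truth — a synthetic cohort generator is included.

## Method

For each included arousal, a PPG segment from 10 s before the arousal start
to 10 s after its end (64 Hz, decimated if needed) yields two characteristics:

* **Mean instantaneous frequency** — power-weighted mean of the short-time
  spectrum with a 2-s boxcar window, one-sample hop and a zero-padded
  transform of length 16·f_s (bins F = 0…32 Hz, step 1/16 Hz):

      f̄_inst(t) = Σ_{f∈F} f · PSD_f(x[t−1 s, t+63/64 s]) / Σ_{f∈F} PSD_f(·)

* **Instantaneous amplitude** — max − min of the PPG in the same 2-s sliding
  window.

Both are smoothed with a 2-s moving average, leaving a trace of the arousal
duration plus 16 s anchored at the EEG arousal start. A sum of three
logistic steps with alternating signs and fixed growth rate 5,

    f(t) = a + b₁/(1+e^{−5(t−c₁)}) − b₁b₂ᵣ/(1+e^{−5(t−c₂)}) + b₁b₃ᵣ/(1+e^{−5(t−c₃)}),
    c₂ = c₁ + 1 + c₂ᵣ(t_max − c₁ − 3),   c₃ = c₂ + 1 + c₃ᵣ(t_max − c₂ − 2),

is fitted by bounded least squares from a grid of 45 initial guesses, keeping
the minimum-SSR fit. A step is *considerable* if its magnitude exceeds 5% of
the mean fitted value; the signed considerability pattern of the three steps
defines 16 fit classes from which the pipeline reads response presence,
magnitude (|level after the response step − a|), delay (the step's logistic
midpoint) and recovery (a later considerable step in the opposite
direction). Group inference uses subject-paired iterated Wilcoxon
signed-rank tests (1000 random within-subject pairings, median p, threshold
0.01), relative risks with 99% CIs for response/recovery proportions,
comparisons of pre/post levels against a stable-sleep baseline, and Pearson
magnitude–delay correlations.

## Worked example

The response categorisation applied to a fitted frequency characteristic of
one arousal (parameters `a=1.44 Hz, b₁=0.120, b₁b₂ᵣ=0.136, b₁b₃ᵣ=0.263 Hz,
c₁=−4.45, c₂=−2.53, c₃=4.23 s`):

```python
from ppgarousal.respmodel import FitWindow, LogisticFit, categorize

fit = LogisticFit.from_absolute(
    a=1.44, b1=0.120, b1_b2_rel=0.136, b1_b3_rel=0.263,
    c1=-4.45, c2=-2.53, c3=4.23, window=FitWindow(-8.0, 18.6, 2.0),
)
call = categorize(fit, "frequency")
print(call.response_step, round(call.magnitude, 3), call.delay, call.recovery_present)
# 3 0.247 4.23 False
```

All three steps are considerable; the response is the third (rising) step:
the frequency settles 0.247 Hz above the pre-arousal level
(1.44 + 0.120 − 0.136 + 0.263 − 1.44), 4.23 s after the EEG arousal start,
with no later considerable decrease — no recovery inside the window.

The end-to-end synthetic analysis lives in `analysis/`:

```sh
python analysis/01_simulate_cohort.py    # 20 subjects with planted responses
python analysis/02_detect_responses.py   # inclusion rules + fits -> results/pipeline/
python analysis/03_group_inference.py    # report tables -> results/
```

On the default cohort (seed 11), detection against the planted truth prints

```
frequency: called 91.4% of planted responses; false-call rate on null arousals 0.0%
amplitude: called 100.0% of planted responses; false-call rate on null arousals 0.0%
```

i.e. essentially every planted amplitude drop and nine of ten planted
frequency rises are called (the misses are planted magnitudes below the 5%
considerability threshold), with no spurious calls on null arousals. At this
deliberately small scale only the largest group contrasts reach p < 0.01 in
the iterated tests; the per-cause medians still order as planted.

A command-line interface mirrors the scripts for user-supplied data
(`ppgarousal run --config cfg.yaml --out outdir`), reading per-subject
waveform/annotation CSVs (or EDF via the `edf` extra) as described in
`ppgarousal.io`.

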