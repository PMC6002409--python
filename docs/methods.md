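# Methods

This note documents the models, defaults, and numerical choices behind
`cardiostop`, and what the synthetic cohort does and does not emulate.

## Task and gating model

A session comprises 360 trials: 60 each of go-systole, go-diastole,
control-go (systole tracker), control-go (diastole tracker), stop-systole
and stop-diastole, shuffled into four blocks of 90. Systole is
operationalised as R-peak + 290 ms (near the T-wave peak), diastole as
R-peak − 10 ms. Before each trial the (simulated) ECG is monitored for
three beats; the next R-peak is predicted as the last observed R plus the
**median** of the last three inter-beat intervals — the median makes the
prediction robust to a single ectopic-like interval. Stop trials place the
stop cue at the phase point and the go cue one SSD earlier; control-go
trials place the go cue where the matching stop trial's go cue would fall
(phase point minus the current tracker SSD) with no stop cue, so that go
onset position in the cardiac cycle cannot act as a subliminal trial-type
cue. If a scheduled go onset would precede the end of monitoring (large
SSD, early beat), the whole event rolls to the next predicted beat; this is
logged, never an error. Trials are separated by a 1000 ms inter-trial
interval plus the next three-beat monitoring period.

**Timing precision.** The achieved offset of an event is its signed
distance to the nearest true R-peak. The within-tolerance statistic is
computed from the R-prediction error (predicted R vs nearest true R): for
phase-locked go and stop events this equals achieved minus intended offset,
and it remains the correct error measure for control-go events, whose cue
is *deliberately* displaced from the phase point by one SSD. Histograms use
50 ms bins over [−500, +800] ms, which covers the visible offset range at
~58 bpm; offsets outside the range are clipped into the end bins so counts
always total the event count.

## Race model and staircases

Go finishing times are ex-Gaussian (defaults μ = 370, σ = 50, τ = 100 ms;
mean 470 ms). A response occurs iff the go process finishes before
SSD + stop latency + within-trial Gaussian noise (SD 20 ms — a purely
deterministic stop latency makes the staircase oscillate degenerately), and
within the 1000 ms response window; slower go finishes (or spontaneous
omissions, rate 0.02) are recorded as omissions. Two independent
one-up/one-down staircases start at 200 ms and step ±50 ms with a floor at
0 ms and no ceiling (a negative SSD is physically meaningless; no printed
ceiling exists). At 50% stop success the equilibrium satisfies
SSD ≈ median(go RT) − stop latency, so with the default latencies
(203/221 ms) the staircases settle near 246/228 ms — and a *slower* stop
process yields a *shorter* equilibrium SSD. Choice errors (wrong arrow
direction) are not modelled; blocks are bookkeeping only.

## Synthetic cohort

Defaults define the emulated study conditions: 60 entrants; resting HR
drawn from a truncated normal (mean 58, SD 10.05 bpm, bounds 35–110);
RMSSD uniform on 20–60 ms; stop latencies 203/221 ms with 30 ms
between-participant SD; 8 "waiters" and 6 staircase "non-convergers"
(fractions rounded to nearest count, assigned to disjoint subsets).

- **RR series**: lag-1 autoregressive Gaussian IBIs (φ = 0.3) around
  60000/HR, with stationary SD s = RMSSD / √(2(1−φ)) so the population
  RMSSD equals the target; IBIs clipped to [300, 2000] ms. This captures
  short-range sinus variability with a controllable RMSSD but not
  respiration-locked oscillations, circadian drift, or arrhythmia.
- **ECG**: each beat is a tall narrow Gaussian R deflection (SD 12 ms) plus
  a lower, wider T deflection (amplitude 0.3, SD 45 ms) centred 290 ms
  later — the minimal trace on which threshold detection and R-vs-T
  confusability are testable. Detection uses a threshold on local maxima
  with a 250 ms refractory window (prevents T-wave double counting,
  consistent with physiological QT); it is an automated stand-in for an
  operator-set interactive threshold.
- **Waiters** have go μ inflated by +3 between-participant SDs (slowing to
  await the stop cue). **Non-convergers** draw each trial's stop latency
  from a bimodal mixture with probability 0.65 on an effectively infinite
  (1500 ms) component: a *symmetric* bimodal latency would still let the
  one-up/one-down rule find its 50% point, whereas capping attainable
  success at ~35% pins the tracker at the floor with success far from 50% —
  the exclusion class the filter is meant to catch.
- **Questionnaire/counting structure**: a latent Gaussian copula couples
  HRV, interoceptive sensibility, and the two stop latencies (default
  target correlations 0.32, 0.366, 0.308; 0.62 between the stop
  latencies); the matrix is eigenvalue-clipped to the nearest correlation
  matrix if a user-supplied target is not positive semi-definite.
  Counting responses are binomial thinnings of the true beat count at the
  participant's counting ability plus rounded Gaussian integer noise;
  confidence (0–100, a continuous stand-in for an unanchored visual
  analogue scale) is coupled to per-trial accuracy at the participant's
  configured coupling. Body-perception items are ordinal 1–5 (45 items);
  the impulsivity total lies on the conventional 30–120 range.

Passing tests on this cohort show the *pipeline* is correct under the race
model and AR(1) sinus variability; they do not certify behaviour on real
ECG morphology, movement artefact, or strategic behaviour beyond the two
modelled phenotypes.

## Analysis choices

- **SSRT**: integration method with omissions replaced by the 1000 ms
  maximum before ranking (consensus practice), 1-based rank ⌈n·p⌉ clamped
  to [1, n]; p(respond) = 0 is undefined (missing), p = 1 is computed at
  rank n but flagged unreliable. The go-RT pool defaults to *all* go trials
  of the session (phase-timed + control), since cardiac phase has no
  material go-RT effect; a per-phase pool is available
  (`--ssrt-go-pool per-phase`).
- **Mean SSD** per condition is the mean of the SSDs actually used on that
  condition's stop trials (the conventional reading), not the final tracker
  value.
- **Exclusions**: pass 1 removes participants whose mean go RT or mean SSD
  (either condition) exceeds the entrant-group mean by 2 SD (one-sided —
  "long" is directional); pass 2, computed on pass-1 survivors only,
  removes participants whose per-tracker inhibition success deviates from
  the survivor mean by 2 SD (two-sided). The passes are order-faithful:
  pass-2 statistics never include pass-1 exclusions.
- **Statistics**: two-level repeated-measures comparisons are reported as
  paired t-tests (mathematically equivalent), with 95% CIs of the mean
  difference and η² derived as t²/(t²+df). Regressions are OLS with
  intercept. The correlation family is all 45 pairs of the 10 analysis
  variables, adjusted jointly by Benjamini–Hochberg step-up (cumulative
  minimum, capped at 1); missing values propagate by pairwise deletion
  (pairs with < 4 complete cases or a constant variable stay missing).

## Problem sizes and determinism

Every generator and simulation is deterministic under its seed. The test
suite exercises staircase convergence over 10,000 stop trials, SSRT
estimator fidelity on 1,000 random instances against a brute-force oracle,
parameter recovery over 100 replicate 46-participant cohorts (behavioural
path, no gating — identical for every behavioural index), type-I
calibration of the phase contrast over 200 null cohorts, and timing
precision over a 46-participant fully gated cohort.

## Known limitations

- The ECG model has no P/Q/S morphology, baseline wander, or noise, so
  detection performance on the synthetic traces is an upper bound.
- The interoceptive accuracy formula (Schandry-style, unclipped) and the
  confidence scale are field conventions, not values printed by any single
  instrument; real VAS anchors and clipping conventions may differ.
- Go RTs are stationary within a session: no fatigue, post-stop slowing, or
  block effects.
- The awareness score estimated from six counting trials is inherently
  noisy; cohort-level correlations with it are strongly attenuated.
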