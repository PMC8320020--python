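# Methods

`wearcast` implements a patient-specific seizure-likelihood forecasting
pipeline driven by consumer-wearable streams: photoplethysmography heart
rate (5 s resolution), per-minute step counts, per-minute sleep-stage labels
with a main-sleep flag, and a self-reported seizure diary.  Because
long-term clinical wearable cohorts of this kind are not publicly
deposited, the package ships a synthetic-cohort generator with known ground
truth; every claim the test suite makes is a claim about recovery of that
ground truth, not about clinical data.

## Synthetic cohorts

A participant's heart rate is

    BPM(t) = baseline + A_c · cos φ_24(t) + Σ_i A_i · cos φ_Pi(t)
             + AR(1) noise − dip(t),

with a circadian (24 h) sinusoid, one or more multiday sinusoids (default:
one 7-day cycle), AR(1) noise generated at the 1-min scale (lag-1
autocorrelation 0.9, stationary SD 3 BPM) and linearly interpolated to 5 s
— wearable-derived heart rate is strongly autocorrelated, and white noise
would make cycle detection unrealistically easy — and a smooth 8 BPM
nocturnal dip during main sleep with 30-min raised-cosine ramps.  Each
cycle's phase offset is drawn uniformly per participant and recorded; phase
0 is defined at the cycle peak.  Defaults (70 BPM baseline, amplitudes
5/3 BPM, ~4 seizures/month, 5% missing data in exponential off-wrist gaps
of mean 2 h, 23:00 ± 30 min sleep onset, 8 h ± 45 min duration) are chosen
to resemble long-term refractory-epilepsy wearable cohorts (reported
seizure frequencies of roughly 1.4–37 per month; ≥80% wear adherence).

Seizures are drawn from a discretized (1-min) inhomogeneous Poisson process
whose intensity multiplies the base rate by `2π · f_vM(φ_c(t); κ_c, μ_c)`
for every cycle; each von Mises factor averages to 1 over a cycle, so the
realized rate tracks the configured rate while events concentrate at the
preferred phase with concentration κ.  κ = 0 yields uniform timing.  Diary
timing jitter (uniform, ±10 min scale) is available but off by default;
self-reported diary timing error is poorly quantified in practice, so the
magnitude is a free parameter.

What the generator does **not** emulate: raw PPG waveforms and their
artifacts, accelerometry, the proprietary sleep-staging classifier
(stage labels are consumed as given), cycle drift over months, state-
dependent missingness (gaps are independent of seizures), and behavioral
feedback between seizures and activity or sleep.  Passing tests therefore
show that the pipeline recovers the structure this model plants, at these
noise levels — not that it forecasts clinical seizures.

One interaction deserves emphasis: any heart-rate-borne cycle leaks into
*every* HR-derived feature.  The mean overnight heart rate is effectively a
nightly sample of a multiday cycle, and the daily resting heart rate tracks
it too.  "Signal planted only in cycles" is therefore only approximately
achievable; the ablation benchmark uses the hourly horizon, where cycle
phase carries strictly finer-grained information than any day-resolution
proxy, so withholding the cycles group produces a clean positive AUC delta
while the redundant day-level proxies contribute none.

## Preprocessing

Heart rate is down-sampled to 1-min means; gaps shorter than 2 h are
linearly interpolated, longer gaps filled at the series mean, and the
missing mask is kept.  The walk-forward engine uses a causal variant that
fills long gaps with the mean of data *before* the gap.  Short-gap linear
interpolation retains a bounded two-hour look-ahead (a gap's fill uses its
closing flank); the causality audit in the test suite perturbs future data
beyond that guard and asserts feature invariance.

RCH (rate of change in heart rate, the package's crude heart-rate
variability proxy) is the minute-to-minute difference of 1-min means.  The
aggregation to the forecast grid is the mean *absolute* per-minute RCH over
the preceding hour/day: variability is a magnitude, and a signed mean would
cancel to ~0 regardless of variability.  Daily resting heart rate is the
mean of the lowest BPM quintile among zero-step, unmasked minutes of each
calendar day; days with fewer than 30 such minutes carry the previous value
forward so a forecast can always be issued.  Sleep yields seven features
per wake from main sleep: total asleep (wake-within-sleep and naps
excluded), REM / deep / light minutes, mean overnight heart rate, and
signed onset/wake deviations from rolling medians over up to 90 prior
nights (emitted as 0 and flagged before 14 nights of history).  Two clocks
coexist deliberately: calendar days for steps and resting heart rate, wake
time for sleep features and the daily forecast issue time.

Eligibility requires ≥2 months of recording, ≥80% heart-rate adherence and
≥20 reported seizures; the training cut-off is the earliest date with two
months of span and 15 seizures; testing requires five lead seizures
(≥1 h/≥1 day from the previous event) after the cut-off.

## Cycles

Candidate periods come from a time-averaged complex Morlet (ω₀ = 6)
wavelet spectrum on a logarithmic grid (64 periods per decade by default)
from 2.4 h to one third of the record, computed on a block-averaged series
(10-min default).  The transform is evaluated in the frequency domain with
zero padding and spectrum-normalized wavelets so that the expected power of
an AR(1) input is known exactly per scale; columns inside the cone of
influence (√2 · scale from either edge) or on mostly-masked data are
excluded, and scales with fewer than two usable interior periods are
dropped.  Peaks must exceed an AR(1) red-noise envelope whose χ² quantile
carries a Šidák correction over the effective number of independent scales
(log-bandwidth of the grid over the filter bandwidth) — without it, a
per-scale 95% rule over ~100 correlated scales produces spurious peaks on
pure noise in most records.  Peak locations are refined by a parabolic fit
in log-period; peaks within one filter bandwidth (ratio < 1.33) merge; the
24 h circadian period is always a candidate.

Each candidate is isolated with a zero-phase (forward–backward) 2nd-order
Butterworth band-pass at ±33% of the period — "zero-phase" because the
Hilbert instantaneous phase must not be lagged — and the analytic-signal
phase is mapped to [0, 2π) with 0 at the cycle peak.  When forecasting
beyond the filtered record, the unwrapped phase is extrapolated by a line
fitted over the final ten periods excluding the last half period, where the
Hilbert edge artifact concentrates; the fitted slope absorbs small period
errors over a multi-week forecast block.

A cycle becomes a feature only if the training seizures are phase-locked to
it: Hodges–Ajne omnibus test, p < 0.05, at least five events.  The m
statistic is the exact minimum half-circle count (boundary sweep anchored
at data points and antipodes); p uses the exact Hodges (1955) formula for
n ≤ 50 and the normal-theory approximation beyond.  Being an exact test of
a discrete statistic, its true size at α = 0.05 is conservative — about
0.02 at n = 10 or 30 and about 0.03 at n = 100 under uniformity; it never
exceeds the nominal level.  The daily horizon keeps multiday cycles only
(circadian class = periods under 36 h).  Elapsed time since the last and
second-last seizure is encoded as sin/cos pairs with each retained multiday
period as the modulus, falling back to the 95th-percentile training
inter-seizure interval when no multiday cycle is retained; the normalizing
modulus for this encoding is this package's design choice.

## Forecaster

Per horizon (hourly: likelihood for [t, t+1 h) at each hour; daily: wake to
next wake, issued at waking):

* **Sleep model** — an LSTM (64 units, two dense layers, linear output)
  over a 7 × 7 array of the previous seven nights' seven sleep features,
  trained 100 epochs with MSE loss and Adam.  Implemented as a compact
  seeded numpy LSTM with full backpropagation through time (gradients are
  verified against finite differences in the test suite); outputs are
  clipped to [0, 1].  Absent nights are forward-filled with their deviation
  features zeroed.  The day's output is broadcast to every hour after
  waking.
* **Random-forest regressor** — 1000 trees, minimum 120 samples per leaf,
  on all other features (retained cycle phases, elapsed-seizure encodings,
  RCH, resting heart rate, steps) plus the sleep-model likelihood, after
  duplicating seizure steps to a 1:1 ratio (exact copies, training folds
  only).  Note that with ~100–300 daily rows the 120-sample leaf floor
  leaves daily-horizon trees nearly unsplit, so the daily forecast is
  dominated by the sleep model and stacker — a direct consequence of the
  default leaf size at daily sample counts.
* **Logistic stacker** — trained on *out-of-fold* base outputs (contiguous
  temporal folds, 10 by default; random folds would leak autocorrelated
  structure), with the step immediately before and after each seizure's
  step removed.  The final forest is likewise trained on the out-of-fold
  sleep column: feeding it the full sleep model's in-sample predictions
  lets it overweight a feature whose apparent accuracy does not transfer
  to forecast time (this measurably degrades held-out AUC).  Stacker
  weights are constrained non-negative — the base outputs are likelihood
  estimates, and with few positives an unconstrained fit can assign a
  negative weight and invert sound forecasts.  With fewer than ten
  positive rows after adjacency removal (or no non-negative informative
  input) the stacker falls back to a rank-average of the base outputs,
  rescaled to the training event rate so that concatenated traces remain
  comparable across retraining epochs.

Walk-forward protocol: initial training on data up to the cut-off, then for
each successive block (7 days by default) the frozen ensemble emits
likelihoods, the block is appended, and everything — cycle detection, the
phase-locking gate, base models, stacker and risk thresholds — is refit.
All accumulated data are kept (a rolling-window option exists but is off by
default).  A master seed fans out per retraining epoch.  Every feature at
step t uses data strictly before t; the suite asserts this by rewriting all
post-block data and comparing first-block forecasts.

Risk tiers: thresholds (θ_med, θ_high) are chosen per epoch by a grid
search over the 1st–99th percentile pairs of the training likelihoods.
Pairs satisfying strictly "time low > time medium > time high" (C1) and
"seizures high > seizures medium > seizures low" (C2, counted as events)
are preferred, maximizing time-in-low × seizures-in-high (C3 × C4); if none
satisfies both, the global product maximizer is returned and flagged.  Ties
break toward larger θ_high then larger θ_med for determinism.

## Evaluation

AUC is the midrank Mann–Whitney statistic.  Chance reference: B = 1000
(200 in reduced-scale runs) rate-matched random forecasts — binary traces
flagging each step independently with the training seizure rate — scored
by a closed-form binary-forecast AUC; "above chance" means exceeding the
null's 95th percentile.  Brier score, 10-bin equal-width reliability
tables (empty bins reported empty), tier occupancy, per-tier seizure
counts, and prediction time — the duration of the unbroken high-tier run
strictly before a seizure's step, zero when that step is not high — are
reported per trace.  The "accuracy" metric is an explicit stand-in
(agreement between tier = high and the label, medium collapsed to low);
tiered forecast accuracy has no standard definition.  The
feature-group ablation compares full-pipeline AUC against the pipeline
with one group withheld (cycles / heart rate / sleep / activity), averaged
over seeded runs, with a cohort-level one-sided t-test.

## Reduced-scale benchmark conditions

The full-scale hyperparameters (1000 trees, leaf 120, 10 folds, 100
epochs, weekly retraining) remain the library defaults.  The benchmark
experiments in `wearcast.benchmarks` (driven by `scripts/acceptance.py`
and `tests/test_acceptance.py`) run a reduced-scale profile chosen as
this package's benchmark condition: 200 trees on 12% bootstrap draws with
40-tree fold models behind the out-of-fold stacker inputs, 5 stacking
folds, 12-epoch full-batch LSTM, 42-day retraining cadence, a
24-periods-per-decade periodogram on 20-min blocks capped at 400 h.
Fold count matters beyond speed: with very few folds the pooled
out-of-fold outputs mix differently calibrated fold models and the
stacker degrades, so the profile keeps five.
End-to-end discrimination uses 20 twelve-month participants per arm
(~4 seizures/month, κ = 2 locking to a 7-day cycle vs κ = 0); the
ablation uses 8 six-month participants (~8/month, κ = 4) at the hourly
horizon with 2 runs per participant; cycle recovery uses 100 ninety-day
records at multiday SNR 1.

## Known limitations

* The conservative size of the exact Hodges–Ajne test at small n is
  intrinsic; no continuity correction is attempted.
* Phase extrapolation into a forecast block assumes the cycle's period is
  locally stable; drifting cycles degrade gracefully (the weekly refit
  re-estimates them) but are not modelled.
* Likelihoods from different retraining epochs are concatenated for
  evaluation although each epoch's stacker is calibrated on its own
  training set; this mildly depresses trace-level AUC relative to
  within-epoch discrimination and mirrors the deployed protocol.
* The nocturnal dip makes the *total* circadian component of heart rate a
  mixture of the injected sinusoid and the sleep-locked depression, so
  ground-truth circadian phase recovery is evaluated on dip-free
  configurations.
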