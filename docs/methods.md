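# Methods

This note documents the models, conventions and parameter choices behind
`gestwear`, in the spirit of a statistical software methods appendix.  It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model (synthetic cohorts)

The generator emulates a 20 Hz wrist accelerometer worn continuously over
multiple weeks.  It is deliberately the *simplest* model under which the
0.01 g moving-SD separatrix is meaningful, not a biomechanical simulation:

* **Schedule.**  Activity unfolds in bouts of integer-second duration
  (wear bouts Uniform(10, 40) min, non-wear bouts Uniform(30, 120) min).
  A bout is non-wear with the probability that makes the expected non-wear
  *time* fraction equal `1 − target_monitoring_ratio` (default target
  0.74); because two non-wear bouts never abut, the bout-type process is a
  two-state Markov chain and the probability is corrected through its
  stationary distribution.  Wear bouts are ambulatory with probability
  `ambulatory_frac` (default 0.20).  Durations sum exactly to
  days × 86 400 s.
* **Stationary states.**  Unit gravity along a per-state wrist orientation
  (sitting, standing, lying down, hand work differ by fixed rotations)
  plus i.i.d. Gaussian device noise with per-axis SD
  `idle_noise_sd_g = 0.005` (< 0.01 g by construction; the generator
  rejects configurations violating this premise).  Since the magnitude of
  `g + ε` linearises to `1 + ε_∥`, the magnitude SD is ≈ the per-axis SD.
* **Ambulatory states.**  A state-specific fundamental (walking 1.8 Hz,
  stairs 1.4, cycling 1.0, jogging 2.6; per-entry ±5% jitter) plus one
  harmonic at twice the fundamental, amplitudes 0.12–0.5 g, with 0.05 g
  noise.  The magnitude SD is then ≫ 0.01 g.
* **Gestures.**  During stationary entries, bursts of additional Gaussian
  noise (per-axis SD `gesture_amp_sd_g = 0.05` > 0.01 g) with durations
  Uniform(0.5, 5) s — spanning sub-window to multi-window events so the
  gap-merge rule is exercised.  Bursts arrive as a Poisson process in
  stationary time (default 6 h⁻¹) thinned to a hard-core process: ≥ 3 s
  separation and ≥ 6 s margin from entry edges, so neighbouring events
  remain separable under the sub-second merge rule.  At default rates the
  hard-core correction changes expected counts by ~1%, within the test
  suite's 3-SE Poisson check.

**Ground-truth convention.**  Each planted burst is recorded twice over:
the physical burst interval, and the *window-support event interval* — the
burst dilated by (window − one sample period) per side, clipped to its
stationary entry.  The latter is what an ideal detector reports under the
windowed event definition (the event is *defined* through its eligible
windows, so every reported event carries ≥ 1 s of window support), and it
is the interval used for IoU matching in the fidelity checks.  Matching
detected events against raw burst intervals at IoU > 0.5 would be
structurally impossible for bursts shorter than ~1.5 s regardless of
signal quality.  True per-event power is computed from the rendered burst
samples.

What the generator does **not** emulate: device noise spectra and drift,
temperature/light channels, realistic gait biomechanics, posture
transitions, circadian structure, or gestures during ambulation.  Passing
tests therefore demonstrate correctness of the *analysis* under the stated
signal model, not performance on real recordings.

## Wear time and monitoring ratio

The trial convention "hours with sensor data / hours enrolled" needs a
wear definition; none is standard.  Here coverage is spacing-based:
consecutive samples at most 2 nominal periods apart belong to one covered
run, and a run of samples `t_0 … t_k` covers `[t_0, t_k + 1/fs)` — so a
continuous 24 h recording covers exactly 24 h and partial hours count pro
rata.  Days are study-origin-relative 24 h blocks, half-open
`[d·86400, (d+1)·86400)`; no timezone or DST handling (the dialect carries
no timezone metadata).  Whether the original convention counted partial
hours is unverifiable; the coverage sum is reproducible and
threshold-explicit.

## Gesture detection

* Magnitude `m_t = √(ax² + ay² + az²)`; detection depends on the signal
  only through `m_t` and is therefore invariant to axis rotation.
* Moving window of 1 s (20 samples), sliding one sample at a time within
  covered runs only; **population** SD (denominator n).  The n vs n−1
  choice is unspecified in the underlying heuristic; at n = 20 the
  difference is < 3% on a threshold that is itself a heuristic, and fixing
  n makes results reproducible.  The streaming implementation centres each
  run before forming cumulative sums, keeping cancellation error below
  10⁻⁹ g (checked against per-window recomputation on 1 000 random
  series).
* A window is *eligible* when its SD strictly exceeds 0.01 g **and** every
  covering sample is labeled stationary; events never overlap ambulatory
  time or data gaps.
* **Merge rule.**  Consecutive eligible windows belong to one event when
  their *start positions* differ by less than 1 s (strict).  Measuring the
  gap between window start positions, rather than end-to-start, is the
  reading under which the intended behaviour — bursts separated by ~0.5 s
  of idle merge, bursts separated by ~1.5 s split — is achievable at all:
  eligibility smears up to one window beyond each burst edge, so
  end-to-start gaps between eligible coverage are near zero even for
  well-separated bursts.
* Event extent is `[first eligible window start, last eligible window
  end)`, merged gaps included; a single eligible window is a valid event
  (minimum support one window).  Events are assigned to days by start
  time.
* Power `Σ_t (m_t − m̄)²` over the event's samples; requires ≥ 2 samples.

## HAR

Windows default to 5 s, non-overlapping (standard practice for wrist HAR;
both are configurable), dropped below 80% sample coverage, with majority
ground-truth labels when annotations exist.  The feature map (19 values
per window) is per-axis and magnitude mean, SD, dominant frequency and
band power in 0.5–5 Hz, plus the three inter-axis correlations; the
classifier is a standardised multinomial logistic regression —
deterministic given its seed, and sufficient for the
ambulatory/stationary separation that the downstream features need.  A
9-layer convolutional-recurrent variant (4 conv + 2 recurrent + 2 dense +
softmax) is reserved as a plug-in slot and raises `NotImplementedError`.
Adapters for public wrist-HAR corpora are likewise interface stubs: tests
never download data.

Evaluation is strictly subject-wise: from each of two sources, one subject
is held out for validation and one for testing; the split object rejects
any overlap.  Per-sample labels are bridged from overlapping windows by
majority vote with earliest-window tie-break — gesture detection needs
sample-resolution stationarity, and the bridge is a convention this
package fixes explicitly.

## Features

A day qualifies when wear ≥ 8 h (`min_wear_h`); without a valid-day rule,
low-wear days would bias daily counts downward.  Gesture power aggregates
as the median over qualifying days of the per-day median per-event power,
symmetric with the "median daily" count; the patient-level aggregation of
the original analysis is not stated anywhere we could verify, so this
choice is flagged as a convention (a mean option exists).  The activity
ratio's denominator is *monitored* time: unclassified covered samples
count in the denominator only.  Missing features are NaN markers, never
zero.

## Cohort coupling and statistics

Per-patient behavioural latents (gesture rate, ambulatory fraction,
symptom severity, effort motivation) are drawn from a Gaussian copula.
Rank-correlation targets are converted to latent Pearson correlations via
`ρ = 2 sin(π ρ_s / 6)` (exact for the bivariate normal), and infeasible
(non-PSD) target matrices are rejected.  Defaults plant gesture-rate vs
BNSS-total −0.438 and activity vs high-effort +0.58.  Observed
feature-level correlations are mildly attenuated relative to the latent
targets by Poisson (daily counts) and Bernoulli (effort trials)
measurement noise — e.g. the high-effort percentage over 12 qualifying
trials carries binomial noise worth roughly 10% attenuation.  This is a
property of the generative model, not a calibration error; tests assert
recovery bands that account for it.

Score maps: BNSS total ~ round(N(36, 11.5)) clipped to 13–78; diminished
expression, apathy and PANSS NSFS are noisy monotone functions of the same
severity latent (loadings 0.85 / 0.75 / 0.70); PSFS is independent.
Effort-choice trials cross effort (100/120/150 presses) × reward (3/5/7
points) × probability (0.5/1.0), two repetitions each; the hard-choice
probability is logistic in the motivation latent with small
reward/effort/probability effects.  The trial log records the *offered*
reward alongside the realized one, because the task score's denominator
("all effort levels, 5/7 points at 100% probability") must include easy
choices on qualifying offers.

Spearman correlations use average ranks for ties; p is the two-sided t
approximation, replaced by an exact permutation test for n ≤ 9.  Cells are
computed with pairwise listwise deletion and reported with their n; no
multiple-testing correction by default (per-cell p < 0.05 convention), a
Benjamini–Hochberg step-up is optional.

## Problem sizes and numerical conventions

Simulation scales are chosen so the full suite and the acceptance script
run in minutes on one CPU: detector fidelity uses 2 h of stationary signal
with exactly 100 planted events; HAR uses 18 subjects × 20 min; the
correlation study uses 100 cohorts of 33 patients and 200 cohorts of 200
patients on the generator's summary path (per-day Poisson counts from the
same latents), with the full signal path exercised end-to-end at 3
patients × 2 days.  Ties in window votes break toward the earliest window;
degenerate events (< 2 samples) raise; empty recordings yield a 0
monitoring ratio but reject a zero enrollment span; variance estimates are
clipped at 0 before the square root.

## Known limitations

Gestures during ambulation are out of scope by design (the event
definition requires stationarity), as is distinguishing communicative from
instrumental hand movements — both would need richer ground truth than
actigraphy provides.  The synthetic generator's simplicity means reported
accuracies and recovery rates characterise the pipeline, not any device or
population.  Clinical scale scores are generated at the scale-total level;
item-level factor computation belongs to the instruments, not this
package.
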