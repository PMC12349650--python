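# Methods

## Measurement model

A single MEMS accelerometer worn at the lumbar spine (L3–L4) records
vertical acceleration at 60 Hz in units of g. Standing still, the sensor
reads 1 g; each step adds a transient impact peak during the load-response
phase, typically 1.2–2 g, whose height tracks the vertical ground-reaction
force. The pipeline treats one 10 m walk as: a still standing lead-in (used
to initialize the axis against gravity), a sequence of step impacts, and
instructor-recorded metadata — walked distance (10 m plus the overshoot past
the finish line), stopwatch time, counted steps, and participant height.

Assumptions: the sensor stays fixed relative to the trunk; the walk is
steady-state apart from initiation/termination (handled by excluding the
first and last two detected peaks); walking speed is taken from the
stopwatch, never re-derived from the trace.

### Calibration

The standing-window mean is shifted to exactly 1 g by an additive offset
applied to the whole trace. The window must span at least 1 s, and its
standard deviation must not exceed 0.1 g — a larger spread means the
participant was moving and calibration is refused. Calibration is idempotent
and makes peak detection invariant to constant sensor bias.

### Peak detection

A candidate is a *strict* local maximum exceeding 1.2 g on the calibrated
signal; a flat plateau counts once, at its first sample. Candidates closer
together than the 0.3 s refractory interval are thinned amplitude-greedily:
candidates are visited in order of decreasing value (earlier sample wins
ties) and accepted only if at least ceil(0.3·fs) samples — 18 at 60 Hz —
from every already-accepted peak. Keeping the larger rather than the earlier
candidate reflects the purpose of the interval: suppressing noise-induced
secondary maxima riding on a true impact. The unit tests hold this detector
to exact agreement with an independent O(n²) brute-force implementation of
the same rule.

No low-pass filter is applied before detection; the refractory interval and
the 1.2 g threshold are the only noise defenses.

If fewer than five peaks are detected, the impact summary raises an
"insufficient steps" error rather than returning a mean of nothing — after
the first/last-two exclusion no retained peak would remain.

### Metrics and normalization

Because preferred speed differs between trials, each metric except speed is
divided by the trial's walking speed before comparison: step length
(expressed as a body-height ratio), cadence (steps per minute), and the
average impact converted to m/s² first (1 g = 9.81 m/s²). The normalized
quantities keep their customary unit labels although they are dimensionally
mixed; "m/s²" on a normalized impact means the speed-divided value. Step
length always uses the metadata step count; the detected-peak count is
carried alongside for quality control but never substituted. Nothing is
rounded during computation; summary tables round at presentation (2
decimals, 3 for ratios).

The participant result sheet instead rescales the measured impact (in g) to
a fixed reference speed of 1.39 m/s (5 km/h): measured ÷ speed × 1.39. Since
1 g is the standing load, the normalized value doubles as a body-weight
multiple. Multiplying by a fixed speed proportionally rescales measurement
error too, which the sheet's documentation flags. The sheet reports the
absolute change in g and the relative change (before − after)/before; a
spoken-feedback convention that calls a 1.6→1.5 g drop "about 10%" is
ambiguous between the 6.25% relative change and 10% of the 1 g standing
load, so the sheet exposes both well-defined quantities and reproduces
neither phrasing numerically.

## Cohort statistics

- **Normality gate.** Shapiro–Wilk (scipy) routes each variable to a
  parametric or nonparametric comparison at α = 0.05; the gait variables are
  typically non-normal, so the nonparametric branch below is the primary
  path.
- **Wilcoxon signed-rank.** Implemented in-package. Differences are
  post − pre; zero differences are dropped before ranking (the classical
  convention; a Pratt zero-rank variant is selectable). The default method
  is the normal approximation with the tie correction
  σ² = n(n+1)(2n+1)/24 − Σ(t³−t)/48 and no continuity correction,
  appropriate at cohort sizes of a few hundred; z is signed and p two-sided.
  An exact method replaces p by full enumeration of the 2ⁿ sign assignments
  over the observed average ranks (feasible to n ≈ 20); the tests hold it to
  exact agreement with an independent enumeration oracle, and the
  approximation to agreement with scipy's.
- **Effect size.** r = |z|/√n with n the number of pairs supplied, not the
  post-zero-removal count — the formula is not universal in the literature,
  but it is the one that reproduces conventionally reported effect-size
  columns from printed Z and n, and it is documented here for that reason.
- **Change ratios.** Per participant, post/pre ratios of normalized step
  length and normalized impact, correlated with Spearman's rank coefficient
  (average-rank ties, two-sided p, scipy).
- **Regression.** OLS (statsmodels) of normalized impact on step-length
  ratio, cadence and speed — pooled pre+post rows by default, selectable —
  with standardized β_j = B_j·sd(x_j)/sd(y) and VIF_j = 1/(1−R²_j) from
  per-predictor auxiliary regressions. Rank-deficient designs are rejected
  rather than silently pseudo-inverted.

No multiple-testing correction is applied across the four paired
comparisons; the analysis plan treats them as separate confirmatory
contrasts.

## Synthetic data generator

### Single trace

Baseline 1 g (plus an optional constant sensor bias), one raised-cosine
impulse per step — smooth, unimodal, with an analytically known peak —
centered at event times snapped to the sample grid, plus i.i.d. Gaussian
noise. Defaults: 60 Hz, 2 s standing lead-in, 15 steps at 120 steps/min
(0.5 s inter-step interval, comfortably above the 0.3 s refractory), impulse
amplitude ~N(0.45, 0.10) g above baseline clipped at ≥ 0.3 g so every step
clears the 1.2 g threshold, half-width 0.1 s, noise sd 0.02 g. The amplitude
and cadence defaults put the normalized impact of a ~1.37 m/s walk in the
9–12 range typical of older community walkers. An optional ±3% uniform gain,
drawn once per trace, models sensor sensitivity error (off by default).
Exact event times and noiseless peak values are returned as ground truth.

The impulse half-width and noise level have no published reference values;
they were chosen to resemble real lumbar waveforms visually and cannot be
validated numerically.

### Paired cohort

One row per (participant, label) at the metric level. Pre-lesson draws:
height ~N(154.4, 7) cm, speed ~N(1.37, 0.26) m/s, normalized step-length
ratio ~N(0.33, 0.05). The lesson effect is two per-participant lognormal
multipliers — step length × 0.95, cadence × 1.053 by default — whose product
scales speed, so with the defaults speed is unchanged in the median while
step length falls and cadence rises. Step counts are integers (a walk
quantizes distance into whole steps), which adds realistic rounding noise to
step length. Normalized impact is linearly coupled to the normalized
step-length ratio (slope 30 per ratio-unit, intercept 0.4) plus Gaussian
noise correlated 0.7 within a participant's pre/post pair; the coupling is
linear purely as a simulation choice, and it is what induces the positive
correlation between the two post/pre change ratios that the Spearman stage
recovers (ρ ≈ 0.7 at the defaults). Setting both multipliers to 1 gives a
null cohort used for type-I-error calibration.

What the generator does **not** emulate: three-axis signals, turning,
stopping or pathological gait, fall events, left/right asymmetry,
heteroscedastic or autocorrelated sensor noise, and any nonlinearity in the
impact–step-length relationship. Passing tests therefore demonstrate that
the algorithms implement their definitions correctly and recover known
simulated effects — not that real cohorts behave like the simulation.

## Numerical choices and problem sizes

Calibration equality to 1 g is exact to 1e-9; normalized × speed = raw holds
to 1e-12. Detector/oracle agreement is checked on 1000 random traces and
step-count recovery on 100 simulated walks per noise level; Wilcoxon
type-I calibration uses 1000 null cohorts of 30 participants; the
directional end-to-end check uses one 100-participant cohort. These sizes
give stable rates (binomial se ≈ 0.7% at 1000 draws) while keeping the whole
suite fast. All simulations are seeded and reproducible.

## Known limitations

- Fewer than five detected peaks is an error, not a degraded estimate;
  trials that short need manual review anyway.
- The amplitude-greedy refractory rule and plateau-first-sample convention
  are one reasonable resolution of underspecified edge cases; both are
  documented and oracle-tested, but other conventions exist.
- At 0.05 g noise, a >4σ sample in the unprotected part of the standing
  segment can occasionally produce a false peak; the expected rate is well
  below one per hundred traces but not zero.
- The effect-size n convention (pairs supplied) and the pooled-rows default
  for the regression are configurable but opinionated defaults.
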