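# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `pursuitprior`. It is the package's own account of what it
computes; every empirical figure mentioned here is produced by the test
suite or the example scripts.

## 1. The Gaussian MAP observer

All direction inference assumes Gaussian likelihood and prior on a linear
(unwrapped) angle axis. With measurement θ_m ~ N(θ_s, σ_m) and prior
N(θ_p, σ_p), the posterior is Gaussian and its maximum is

θ_est = w θ_m + (1−w) θ_p, w = σ_p²/(σ_p²+σ_m²),

giving ensemble moments E[θ_est] = w θ_s + (1−w) θ_p and SD[θ_est] = w σ_m.
The linear-angle treatment is valid because empirical direction spreads are
far below 180°; for the wide block's ±120° geometry, every per-trial
direction is first unwrapped to within ±180° of its own target direction.

The full experiment model has eight free parameters: five σ_m (one per
motion direction, ordered by offset from the prior direction: −120°, −15°,
0°, +15°, +120°), a contrast factor c ≥ 1 multiplying σ_m for low-contrast
stimuli, and σ_p for each block. The prior mean θ_p is fixed to the task's
prior direction, not fitted: the task defines it and freeing it would only
dilute an already small (24-point) data set.

### Fitting

`fit_observer` minimises the plain sum of squared residuals over the 12
mean directions and 12 SDs, both in degrees and unweighted — means and SDs
share units and comparable magnitudes, and an unweighted quadratic loss is
the most transparent choice. Optimisation is `scipy.optimize.least_squares`
(trust-region reflective) on **log10-transformed parameters**, which makes
the σ_p axis (bounded 1°–10⁶°) well scaled; bounds are σ_m ∈ [0.5°, 90°],
c ∈ [1, 10], σ_p ∈ [1°, 10⁶°]. Twenty starting points are drawn from a
seeded Latin hypercube over the log-scaled box and the best converged fit
is kept; with noise-free summaries every start that converges reaches the
same optimum to machine precision, so the multi-start is insurance against
rare saddle captures, not a tuning knob.

The wide-prior SD is retained as a free parameter but is **not
identifiable** beyond "very large": once σ_p ≫ σ_m the shrinkage weight is
indistinguishable from 1 at any data precision. A fit that pins it at the
upper bound is expected and not flagged; no test asserts its value.
Variance explained is reported separately for the 12 means and the 12 SDs
as R² = 1 − SSE/SST.

## 2. The synthetic-data generator

`synthdata` emulates the two-block task: a narrow-prior block (prior
direction and ±15°, prior direction twice as frequent; 252 trials) and a
wide-prior block (three directions 120° apart, equiprobable; 378 trials),
with high- and low-contrast trials randomly interleaved half-and-half
within each block. `simulate_session(..., n_block_pairs=4)` produces a full
experimental day (2520 trials), which is the scale at which the per-session
statistics have the precision the analyses assume.

Each trial's pursuit direction is drawn generatively from the MAP observer:
one standard normal draw z gives θ_m = θ_s + z σ_m_eff (σ_m_eff = σ_m_base,
times c at low contrast), which is shrunk toward the prior by w. Optional
components, all off or mild by default:

- **motor noise** (default 0°) added after the MAP stage, so generated SDs
  obey √((w σ_m)² + σ_motor²);
- **single-trial adaptation** (default 0°): a fixed shift toward the
  previous trial's target direction whenever the two differ — the
  conditional-mean difference statistic then equals twice the shift;
- **time-varying likelihood** σ_m(t) = σ_∞(1 + A e^(−t/τ)): the trial's
  instantaneous direction is w(t)(θ_s + z σ_m(t)) + (1−w(t))θ_p, so both
  blocks' direction SDs fall as the sensory representation sharpens and the
  narrow−wide gap closes with time. This exists to exercise the
  time-resolved analyses.

Trace realisation: velocity is zero until a per-trial latency, then rises
as V·tanh((t−lat)/(r/2)) (a logistic-type saturating onset; rise time
r = 60 ms) toward gain × target speed along the trial direction; position
is the running integral at 1 kHz from −300 ms to +600 ms. Latency means
default to 120 ms (high contrast) and 160 ms (low contrast) with 15 ms SD,
gain to 1.00 ± 0.05 — plausible primate values, configurable, and never
treated as empirical claims. Saccades are injected in a configurable
fraction of trials (default 5%) as additive 30-ms, 200 deg/s half-sine
velocity pulses; tracker jitter is white position noise of 0.01° RMS.
Target speed defaults to 15 deg/s.

One master seed spawns an independent `numpy` stream per trial, so any
single trial is bit-reproducible regardless of block ordering.

**What the generator does not emulate:** dot-level random-walk noise (its
effect enters only through σ_m), catch-up saccade dynamics, closed-loop
corrections after ~250 ms, blinks, drift, or any latency/gain correlation
structure. Passing tests therefore demonstrate correctness of the analysis
chain under the model's assumptions, not fidelity of those nuisance
processes to real eye data.

## 3. Preprocessing

Positions are low-pass filtered with a second-order Butterworth at 20 Hz
applied forward and backward (`filtfilt`): zero phase, unit DC gain, and an
effective magnitude response equal to the squared single-pass response
(≈0.0016 amplitude transmission at 100 Hz). Zero-phase filtering is chosen
so latency estimates are not biased by filter delay. Velocity is the
central-difference derivative (one-sided at the ends).

Saccades are detected where radial speed exceeds a 50-ms running-median
baseline by 30 deg/s for at least 5 ms; the criterion and thresholds are
package choices (the underlying exclusion rule only requires *a* detector)
and are exposed in configuration. A trial is excluded when any detected
event overlaps the closed window [−100, +250] ms around motion onset. A
figure caption in the source literature starts this window at 0 ms while
the methods text says −100 ms; the package defaults to −100 ms and the
window is configurable.

## 4. Open-loop decomposition

For each condition (direction × contrast × block):

1. **Latency** — the trial-averaged speed is referenced to its value at
   +250 ms; the 10% and 50% crossing times bracket the rise, and a
   least-squares line through that segment extrapolated to zero speed gives
   the condition latency. The procedure is a documented stand-in (no
   canonical estimator exists for "average pursuit latency"); on noiseless
   synthetic conditions it is accurate to well under 5 ms. With latency
   jitter across trials the averaged rise is smeared and the extrapolation
   reads early by up to ~10 ms; this cancels in all downstream statistics,
   which use directions and within-condition contrasts, not absolute
   latencies.
2. **Template** — mean horizontal and vertical velocity over
   [latency−20, latency+100] ms, after rotating all trials so the condition
   mean direction is 45°. The rotation balances the two components so the
   per-trial direction estimate atan2(b, a) is unbiased under symmetric
   noise. Templates are per condition (direction × contrast × block); the
   per-direction-only alternative is a coarser pooling and was not adopted.
3. **Trial fit** — minimise Σ(e_h − a T_h(t−τ))² + (e_v − b T_v(t−τ))²
   over τ ∈ [−50, +50] ms and scales a, b. For fixed τ the scales have
   closed forms; τ is scanned at the 1-ms sampling grid and refined by
   parabolic interpolation of the SSE, with the scales recomputed at the
   fractional shift via linear interpolation of the trial. This replaces
   the black-box mesh-adaptive optimiser used historically for this
   problem: the problem is separable least squares, so a deterministic
   grid + closed-form solve is exact, reproducible, and testable. Samples
   whose shifted window would leave the recorded trial are dropped from the
   sums (with the default time base this never triggers). Direction is
   rotated back to the stimulus frame; the scalar speed gain is (a+b)/2 (no
   canonical scalar readout exists); latency is condition latency + τ;
   variance explained is 1 − SSE/SST over the fit window, clipped to [0,1].

Inclusion: a trial needs variance explained > 0.70 and a shift not pinned
at the search bound; within each condition, included trials beyond 3 scaled
MADs of the median direction are dropped as outliers (the outlier rule is a
package choice, exposed in configuration). A session is retained only if
strictly more than 70 included prior-direction trials remain in each block.

Recovery, measured by the test suite: over 500 synthetic trials with known
(τ, a, b) and 1 deg/s velocity noise, median absolute errors are below
(1 ms, 0.02, 0.02).

## 5. Session statistics

- **Direction-difference ratio**: |Δ mean pursuit direction| / |Δ target
  direction| for the two outer targets of a block (30° separation narrow,
  240° wide). Values below 1 indicate attraction toward the central
  direction; on generator output the ratio converges to the shrinkage
  weight w.
- **Robust direction SD**: sample SD after discarding points beyond 3
  scaled MADs of the median, divided by the normal truncation constant
  √(1 − 6φ(3)/(2Φ(3)−1)) ≈ 0.9866. Without the constant a 3σ-trimmed SD
  underestimates a clean Gaussian spread by ~1.3%; with it the estimator is
  consistent under normality and still ignores gross outliers.
- **Group tests**: one-sample two-sided t-tests on log-transformed ratios
  (ratio vs 1); Spearman rank correlation between per-session SD ratios and
  bias-ratio ratios. No multiple-comparison correction is applied — raw
  p-values are reported, as is conventional for this analysis family.
- **Single-trial adaptation**: among common-direction trials whose previous
  trial's direction differs, mean(direction | previous CCW) −
  mean(direction | previous CW); positive values mean attraction toward the
  previous direction, and a generator shift of s yields 2s in expectation.

## 6. Time-resolved analysis

The instantaneous pursuit direction at time t is atan2(v_v, v_h), masked
where speed < 1 deg/s (before pursuit onset the direction of near-zero
velocity is meaningless). Bias-ratio and SD curves are computed per session
over 0–250 ms and smoothed with a 10-ms boxcar; whether per-time direction
should use instantaneous velocity or cumulative displacement is genuinely
open — instantaneous is the default and the displacement variant can be
built from the same masked-direction primitive.

Curves are compared across prior conditions with a two-sided cluster-based
permutation test: per-time paired t statistics, cluster-forming threshold
at the two-sided α = 0.05 critical value, cluster mass = Σ|t|, and a null
distribution of the maximum mass from random within-session sign flips of
the paired differences (seeded; p = (k+1)/(n_perm+1)). Threshold,
permutation count (default 1000), and smoothing are unstated in the
analysis tradition this follows and are all configurable. Time points where
any session is undefined break cluster contiguity. Calibration, measured by
the test suite on smooth-noise curves whose 10-ms correlation length
matches the pipeline's smoothing: family-wise error ≤ 0.08 over 500 null
simulations at nominal 0.05, and >90% power for a 3-standard-error offset
spanning 0–150 ms with 30 sessions.

## 7. Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → decompose → stats →
observer fit → timecourse, writing each stage's artifacts to disk
(metadata, exclusion log, kinematics, condition summaries, fitted
parameters, curves, clusters) so stages are independently re-runnable; no
stage reads another's internals except through these files. A manifest
records the package version, the configuration and its SHA-256 hash, and
every session seed; a rerun with the same configuration and seed reproduces
`report.json` byte-for-byte. Configuration errors name the offending field
and exit with code 2 from the CLI; stage failures name the stage and
session and exit with 3.

## 8. Problem sizes

Default validation scales, chosen so the whole suite runs comfortably on a
single CPU: parameter-recovery fits use the exact 24-point design;
oracle comparisons use 100 random queries and 10⁶ Monte-Carlo draws;
decomposition recovery uses 500 trials; the end-to-end behavioural check
simulates 20 full days (2520 trials each); permutation calibration uses 500
null simulations of 10 sessions × 251 time points with 500 sign-flip
permutations each.

## 9. Known limitations

- All angle statistics are linear on unwrapped angles; they would break for
  direction spreads approaching 180°, which do not occur in this design.
- The latency estimator is biased early under latency jitter (see §4); use
  within-condition latency contrasts, not absolute values.
- σ_p of the wide block is reported but not interpretable beyond "flat".
- The generator's velocity profile, latency and gain distributions are
  plausible inventions; only the open-loop direction statistics they induce
  are matched to the behavioural model.
- The observer fit treats the 24 summaries as exact; it propagates no
  uncertainty from the per-session trial counts. Parametric bootstrap over
  the generator is the recommended route if standard errors on fitted
  parameters are needed.
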