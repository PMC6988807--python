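# pursuitprior

Simulation and analysis of **direction priors in smooth-pursuit initiation**,
built around a Gaussian Bayesian observer model.

## The problem

When a primate tracks a moving dot patch, the first ~100–250 ms of pursuit
(the *open-loop* period) is driven purely by feedforward sensory signals.
If the animal has learned that targets usually move in a particular
direction, Bayesian inference predicts two signatures in that period:

1. **Bias** — pursuit directions are attracted toward the expected
   direction, more strongly when the sensory signal is weak (low contrast);
2. **Variance reduction** — trial-to-trial variability of pursuit direction
   shrinks under a strong prior.

The experimental design that isolates these effects interleaves two block
types: a *narrow-prior* block (targets at a prior direction and ±15°, the
prior direction shown twice as often; 252 trials) and a *wide-prior* block
(three directions 120° apart; 378 trials), each with randomly interleaved
high- and low-contrast targets. One direction is common to both blocks, so
the prior's effect can be measured under identical stimuli.

Raw data for such experiments are typically available only on request, so
this package ships a first-class synthetic-data generator with the full
statistical structure of the task, and validates every analysis stage by
parameter recovery against that generator.

## The model

The observer measures the stimulus direction θ_s through a noisy channel,
θ_m ~ N(θ_s, σ_m), and combines it with a Gaussian prior N(θ_p, σ_p). The
posterior maximum (MAP) is the precision-weighted average

    θ_est = w·θ_m + (1 − w)·θ_p,   w = σ_p² / (σ_p² + σ_m²)

so across trials

    E[θ_est]  = w·θ_s + (1 − w)·θ_p        (bias toward the prior)
    SD[θ_est] = w·σ_m                       (variance reduction)

The full experiment model has **eight free parameters** — five per-direction
likelihood SDs σ_m, one multiplicative contrast factor c ≥ 1 applied to σ_m
at low contrast, and one prior SD per block — and is fit by bounded least
squares to 24 condition summaries (12 mean directions + 12 direction SDs).

## What's in the package

| module | contents |
| --- | --- |
| `pursuitprior.synthdata` | task/generator configuration, MAP-structured trial sampling, 1-kHz eye-trace realisation, session containers (CSV dir / HDF5) |
| `pursuitprior.preprocess` | zero-phase 20-Hz Butterworth filter, differentiation, running-median saccade detection, open-loop-window trial exclusion |
| `pursuitprior.decompose` | condition latency estimation, 45°-rotated velocity templates, per-trial slide-and-scale least-squares fit (direction, gain, latency, variance explained), inclusion rules |
| `pursuitprior.stats` | direction-difference ratios, robust direction SDs, log-ratio t-tests, bias–precision Spearman correlation, single-trial adaptation statistic |
| `pursuitprior.observer` | MAP arithmetic, design predictions, the 8-parameter bounded least-squares fit with seeded multi-start |
| `pursuitprior.timecourse` | instantaneous-direction curves, time-resolved bias/SD, two-sided sign-flip cluster permutation test |
| `pursuitprior.pipeline` / `cli` | configuration-driven end-to-end runs with on-disk stage artifacts and a reproducibility manifest (`pursuitprior run-all …`) |

## Worked example

```python
import numpy as np
from pursuitprior import (BayesQuery, ObserverParams, map_estimate,
                          predict_design, fit_observer)

# One trial: a 15° target seen through a 14.53°-wide likelihood,
# pulled toward a 0° prior of width 34.5°.
map_estimate(BayesQuery(theta_m=15.0, theta_p=0.0, sigma_m=14.53, sigma_p=34.5))
# 12.74  — the estimate is attracted 2.26° toward the prior

# Generate the 24 design summaries from known parameters and fit them back.
truth = ObserverParams(sigma_m=np.full(5, 7.94), contrast_factor=1.83,
                       sigma_p_narrow=34.5, sigma_p_wide=1e6, theta_p=0.0)
summaries = predict_design(truth).rename(
    columns={"pred_mean": "mean_direction_deg", "pred_sd": "sd_direction_deg"})
fit = fit_observer(summaries, theta_p=0.0, n_starts=20, seed=0)
fit.params.sigma_m.mean(), fit.params.contrast_factor, fit.params.sigma_p_narrow
# (7.94, 1.83, 34.5) — exact recovery: the fit is identifiable
```

Running `python examples/04_session_statistics.py` simulates ten full
experimental days end to end (traces → filtering → decomposition → stats)
and prints:

```
  narrow-prior bias ratio: 0.860 (observer-model prediction 0.833; < 1 means attraction to the prior)
  wide-prior bias ratio:   1.001 (flat prior: ~1)
  SD ratio narrow/wide:    0.823 (< 1: the strong prior stabilises pursuit direction)
t-test on log(narrow-prior bias ratio) vs 0: t = -5.61, p = 3.28e-04 (n = 10)
Spearman correlation, SD ratio vs bias-ratio ratio: rho = 0.66, p = 0.038
```

The bias ratio is the angular separation of mean pursuit directions for the
two outer targets divided by the target separation; the SD ratio compares
trial-direction spread at the common direction across blocks. Each
`examples/` script exercises one capability and explains its output.

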