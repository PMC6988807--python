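"""Time-resolved prior effects and the cluster-based permutation test.

Simulates sessions whose sensory likelihood sharpens over the trial,
computes per-session SD-of-direction curves for the narrow and wide prior
blocks, and tests where the two differ with the sign-flip cluster
permutation test. Optionally writes a summary figure.
"""

import sys

import numpy as np

from pursuitprior import (
    ObserverGenParams,
    TaskConfig,
    cluster_permutation_test,
    decompose_session,
    preprocess_session,
    simulate_session,
    timecourse_statistics,
)
from pursuitprior.timecourse import session_timecourse

task = TaskConfig(prior_direction=30.0)
# Likelihood SD decays by a factor (1 + 2 exp(-t/80 ms)): early pursuit sees
# a weak sensory signal, so the prior dominates early and fades later.
gen = ObserverGenParams(sigma_m_timecourse=(2.0, 80.0), saccade_rate=0.0)

sessions = []
for s in range(8):
    traces = simulate_session(task, gen, seed=900 + s, n_block_pairs=2)
    vel, _ = preprocess_session(traces)
    kin, _ = decompose_session(vel, prior_direction=30.0)
    order = vel.meta["trial_index"].to_numpy()
    inc = kin.set_index("trial_index").loc[order, "included"].to_numpy()
    sessions.append(session_timecourse(vel, inc, 30.0))

avg = timecourse_statistics(sessions)
t = avg.time_ms
for contrast in ("high", "low"):
    a = np.stack([s.sd[("narrow", contrast)] for s in sessions])
    b = np.stack([s.sd[("wide", contrast)] for s in sessions])
    res = cluster_permutation_test(a, b, t, n_perm=1000, seed=0)
    spans = ", ".join(f"[{s:.0f}, {e:.0f}] ms (p={p:.3f})"
                      for (s, e), p in zip(res.intervals, res.p_values)) or "none"
    print(f"{contrast}-contrast SD, narrow vs wide prior: significant clusters {spans}")

print("\nThe narrow prior lowers direction SD mainly early in the trial, "
      "while the sensory representation is still forming.")

if "--plot" in sys.argv:
    import matplotlib

    matplotlib.use("Agg")
    from pursuitprior.plotting import plot_timecourse

    fig = plot_timecourse(avg)
    fig.savefig("timecourse_panels.png", dpi=150)
    print("Wrote timecourse_panels.png")
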