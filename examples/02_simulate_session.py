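"""Simulate one two-block pursuit session and inspect its structure.

Shows the trial counts per direction, the effect of the narrow prior on the
generated trial directions, and writes the session to a CSV container.
"""

import tempfile
from pathlib import Path

from pursuitprior import ObserverGenParams, TaskConfig, simulate_session, write_session

task = TaskConfig(prior_direction=30.0)  # 252 narrow + 378 wide trials
gen = ObserverGenParams()  # monkey-A-like observer + kinematics

session = simulate_session(task, gen, seed=7)
meta = session.meta
print(f"Simulated {session.n_trials} trials "
      f"({session.time_ms[0]:.0f} to {session.time_ms[-1]:.0f} ms at 1 kHz)")
print("\nTrials per block and direction (prior direction shown twice as often):")
print(meta.groupby(["block", "theta_s"]).size().to_string())

print("\nGenerated pursuit direction, mean +/- SD per condition:")
for (block, contrast), sub in meta[meta.theta_s == 45.0].groupby(["block", "contrast"]):
    print(f"  {block:6s} {contrast:4s}  target 45.0 -> "
          f"{sub.theta_trial.mean():6.2f} +/- {sub.theta_trial.std():5.2f} deg")
print("Narrow-prior low-contrast trials are pulled toward 30 deg and scatter less.")

out = Path(tempfile.mkdtemp()) / "session"
write_session(session, out, fmt="csv")
print(f"\nWrote container (metadata.csv + per-trial traces) to {out}")
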