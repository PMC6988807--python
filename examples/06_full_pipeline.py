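"""Run the whole pipeline through its configuration interface.

Equivalent to `pursuitprior run-all --config cfg.yaml`; every stage's
artifacts land on disk and the aggregate report is returned.
"""

import json
import tempfile
from pathlib import Path

from pursuitprior import PipelineConfig, run_pipeline

out = Path(tempfile.mkdtemp()) / "pipeline"
cfg = PipelineConfig(
    out_dir=str(out),
    seed=42,
    n_sessions=5,
    n_block_pairs=2,
    task=dict(prior_direction=30.0),
    generator=dict(saccade_rate=0.05),
    observer=dict(n_starts=10),
)
report = run_pipeline(cfg)

print(f"Artifacts under {out}:")
for p in sorted(out.rglob("*")):
    if p.is_file():
        print("  ", p.relative_to(out))

print("\nGroup statistics from report.json:")
for key, val in report.items():
    if key.startswith("ttest/"):
        print(f"  {key}: mean ratio {val['mean_ratio']:.3f}, p = {val['p']:.2e}")
print("\nNarrow-prior low-contrast ratios sit below 1 (attraction toward the "
      "prior, reduced spread); wide-prior ratios sit at 1. At this demo scale "
      "(5 short sessions) the p-values are only indicative.")
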