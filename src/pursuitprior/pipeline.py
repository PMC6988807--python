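"""End-to-end pipeline: simulate -> preprocess -> decompose -> stats/model.

Every stage writes its artifacts to disk (session containers, exclusion
logs, kinematics tables, condition summaries, fitted observer parameters,
timecourse curves and clusters) so any stage can be re-run or inspected in
isolation.  A manifest records the configuration hash, every seed, and the
package version; a rerun with the same configuration and seed reproduces
the aggregate report bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decompose import decompose_session
from .observer import fit_observer
from .preprocess import preprocess_session
from .stats import (
    adaptation_statistic,
    bias_precision_correlation,
    log_ratio_ttest,
    session_ratios,
    summarize_conditions,
)
from .synthdata import ObserverGenParams, TaskConfig, simulate_session, write_session
from .timecourse import cluster_permutation_test, session_timecourse


class ConfigError(ValueError):
    """Invalid pipeline configuration (names the offending field)."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated configuration for a full simulate-and-analyse run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_sessions: int = 5
    n_block_pairs: int = 1
    storage: str = "csv"  # 'csv' | 'hdf5'
    task: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    decompose: dict = field(default_factory=dict)
    observer: dict = field(default_factory=dict)
    timecourse: dict = field(default_factory=dict)
    write_traces: bool = False  # per-trial trace files are large; off by default

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ConfigError("n_sessions must be >= 1")
        if self.n_block_pairs < 1:
            raise ConfigError("n_block_pairs must be >= 1")
        if self.storage not in ("csv", "hdf5"):
            raise ConfigError(f"storage must be 'csv' or 'hdf5', got {self.storage!r}")
        for name, cls in (("task", TaskConfig), ("generator", ObserverGenParams)):
            cfg = getattr(self, name)
            if not isinstance(cfg, dict):
                raise ConfigError(f"{name} must be a mapping")
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(cfg) - known
            if unknown:
                raise ConfigError(f"unknown field(s) in {name}: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def build_task(self) -> TaskConfig:
        try:
            return TaskConfig(**self.task)
        except ValueError as exc:
            raise ConfigError(f"task: {exc}") from exc

    def build_generator(self) -> ObserverGenParams:
        g = dict(self.generator)
        if "sigma_m_timecourse" in g and g["sigma_m_timecourse"] is not None:
            g["sigma_m_timecourse"] = tuple(g["sigma_m_timecourse"])
        try:
            return ObserverGenParams(**g)
        except ValueError as exc:
            raise ConfigError(f"generator: {exc}") from exc


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the aggregate report (also on disk).

    Writes, under ``config.out_dir``: per-session artifacts
    (``session_XX/``: metadata or full container, exclusion log, kinematics,
    condition summaries, observer parameters), ``report.json`` with group
    statistics, and ``manifest.json`` with seeds, versions, and the config
    hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    task = config.build_task()
    gen = config.build_generator()
    rng = np.random.SeedSequence(config.seed)
    session_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(config.n_sessions)]

    per_session = []
    tc_sessions = []
    for s_idx, s_seed in enumerate(session_seeds):
        sdir = out / f"session_{s_idx:02d}"
        sdir.mkdir(exist_ok=True)
        stage = "simulate"
        try:
            traces = simulate_session(task, gen, seed=s_seed, n_block_pairs=config.n_block_pairs)
            if config.write_traces:
                if config.storage == "csv":
                    write_session(traces, sdir / "raw", fmt="csv")
                else:
                    write_session(traces, sdir / "raw.h5", fmt="hdf5")
            traces.meta.to_csv(sdir / "trial_metadata.csv", index=False)

            stage = "preprocess"
            vel, excl_log = preprocess_session(traces, **config.preprocess)
            excl_log.to_csv(sdir / "exclusion_log.csv", index=False)

            stage = "decompose"
            kin, verdict = decompose_session(
                vel, prior_direction=task.prior_direction, **config.decompose
            )
            kin.to_csv(sdir / "kinematics.csv", index=False)

            stage = "stats"
            summaries = summarize_conditions(kin)
            summaries.to_csv(sdir / "condition_summaries.csv", index=False)
            ratios = session_ratios(summaries, task.prior_direction)
            ratios.to_csv(sdir / "session_ratios.csv", index=False)

            # Single-trial adaptation at the common direction, per block/contrast.
            kin_meta = kin.merge(
                traces.meta[["trial_index", "prev_theta_s", "theta_s"]],
                on="trial_index", suffixes=("", "_meta"),
            )
            adapt = {}
            common = kin_meta[
                np.isclose(kin_meta["theta_s"], task.prior_direction) & kin_meta["included"]
            ]
            for (block, contrast), sub in common.groupby(["block", "contrast"]):
                try:
                    adapt[f"{block}/{contrast}"] = adaptation_statistic(
                        sub["direction_deg"].to_numpy(),
                        sub["theta_s"].to_numpy(),
                        sub["prev_theta_s"].to_numpy(),
                    )
                except ValueError:
                    adapt[f"{block}/{contrast}"] = None

            stage = "fit-observer"
            fit = None
            if len(summaries) == 12 and summaries["sd_direction_deg"].notna().all():
                fit = fit_observer(
                    summaries, theta_p=task.prior_direction,
                    n_starts=int(config.observer.get("n_starts", 20)),
                    seed=int(config.observer.get("seed", s_seed)),
                )
                _dump_json(
                    dict(
                        sigma_m=fit.params.sigma_m.tolist(),
                        contrast_factor=fit.params.contrast_factor,
                        sigma_p_narrow=fit.params.sigma_p_narrow,
                        sigma_p_wide=fit.params.sigma_p_wide,
                        theta_p=fit.params.theta_p,
                        r2_mean=fit.r2_mean, r2_sd=fit.r2_sd,
                        seed=fit.seed, n_starts=fit.n_starts, at_bound=fit.at_bound,
                    ),
                    sdir / "observer_params.json",
                )

            stage = "timecourse"
            tc = session_timecourse(
                vel, kin["included"].to_numpy(), task.prior_direction,
                **{k: v for k, v in config.timecourse.items() if k not in ("n_perm",)},
            )
            tc_sessions.append(tc)
        except (ConfigError,):
            raise
        except Exception as exc:
            raise StageError(f"stage '{stage}' failed for session {s_idx}: {exc}") from exc

        row = dict(session=s_idx, seed=s_seed, retained=verdict.retained,
                   n_prior_narrow=verdict.n_prior_narrow, n_prior_wide=verdict.n_prior_wide,
                   adaptation=adapt)
        for r in ratios.itertuples():
            row[f"ratio_bias/{r.block}/{r.contrast}"] = r.ratio_bias
            row[f"sd_common/{r.block}/{r.contrast}"] = r.sd_common
        for contrast, v in ratios.attrs.get("sd_ratio_narrow_over_wide", {}).items():
            row[f"sd_ratio/{contrast}"] = v
        if fit is not None:
            row["observer/mean_sigma_m"] = float(fit.params.sigma_m.mean())
            row["observer/contrast_factor"] = fit.params.contrast_factor
            row["observer/sigma_p_narrow"] = fit.params.sigma_p_narrow
        per_session.append(row)

    df = pd.DataFrame(per_session)
    df.drop(columns=["adaptation"]).to_csv(out / "per_session.csv", index=False)

    report: dict = {"n_sessions": config.n_sessions, "per_session": per_session}
    # Group tests over sessions where defined.
    for col in [c for c in df.columns if c.startswith(("ratio_bias/", "sd_ratio/"))]:
        vals = df[col].dropna().to_numpy(dtype=float)
        if vals.size >= 5 and np.all(vals > 0):
            tt = log_ratio_ttest(vals)
            report[f"ttest/{col}"] = dict(mean_ratio=tt.mean_ratio, t=tt.t, p=tt.p, n=tt.n)
    # Bias-vs-precision correlation across sessions (low contrast).
    if {"ratio_bias/narrow/low", "ratio_bias/wide/low", "sd_ratio/low"} <= set(df.columns):
        bias_ratio = (
            df["ratio_bias/narrow/low"] / df["ratio_bias/wide/low"]
        ).to_numpy(dtype=float)
        sd_ratio = df["sd_ratio/low"].to_numpy(dtype=float)
        ok = np.isfinite(bias_ratio) & np.isfinite(sd_ratio)
        if ok.sum() >= 10:
            try:
                rho, p = bias_precision_correlation(sd_ratio[ok], bias_ratio[ok])
                report["correlation/bias_vs_sd_ratio/low"] = dict(rho=rho, p=p, n=int(ok.sum()))
            except ValueError:
                pass

    # Cluster comparison of narrow vs wide SD curves across sessions.
    n_perm = int(config.timecourse.get("n_perm", 1000))
    if len(tc_sessions) >= 5:
        t_axis = tc_sessions[0].time_ms
        tc_rows = []
        clusters = {}
        for contrast in ("high", "low"):
            key_n, key_w = ("narrow", contrast), ("wide", contrast)
            if all(key_n in s.sd and key_w in s.sd for s in tc_sessions):
                A = np.stack([s.sd[key_n] for s in tc_sessions])
                B = np.stack([s.sd[key_w] for s in tc_sessions])
                res = cluster_permutation_test(
                    A, B, t_axis, n_perm=n_perm, seed=config.seed
                )
                clusters[f"sd_narrow_vs_wide/{contrast}"] = dict(
                    intervals=res.intervals, p_values=res.p_values,
                    n_permutations=res.n_permutations,
                )
                for name, stack in (("sd_narrow", A), ("sd_wide", B)):
                    with np.errstate(invalid="ignore"):
                        mean_curve = np.nanmean(stack, axis=0)
                    for ti, v in zip(t_axis, mean_curve):
                        tc_rows.append(dict(time_ms=ti, statistic=name,
                                            contrast=contrast, value=v))
        if tc_rows:
            pd.DataFrame(tc_rows).to_csv(out / "timecourse.csv", index=False)
        if clusters:
            _dump_json(clusters, out / "clusters.json")
            report["clusters"] = clusters

    _dump_json(report, out / "report.json")

    from . import __version__

    cfg_dict = config.to_dict()
    manifest = dict(
        package_version=__version__,
        config=cfg_dict,
        config_hash=hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        seed=config.seed,
        session_seeds=session_seeds,
    )
    _dump_json(manifest, out / "manifest.json")
    return report
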