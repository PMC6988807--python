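"""Synthetic smooth-pursuit sessions with Bayesian-observer structure.

Emulates the two-block direction-prior pursuit experiment: a *narrow-prior*
block (prior direction and prior +/- 15 deg, prior direction shown twice as
often, 252 trials) and a *wide-prior* block (three directions 120 deg apart,
378 trials), with high- and low-contrast targets randomly interleaved.  Each
trial's realised pursuit direction is drawn from the generative reading of
the MAP observer: a noisy direction measurement ``theta_m ~ N(theta_s,
sigma_m_eff)`` shrunk toward the prior mean by the posterior weight, plus
optional motor noise, single-trial adaptation toward the previous trial's
direction, and an optional time-decaying likelihood width that lets the
early part of a trial express a stronger prior pull than the end.

Eye traces are realised as position time series at 1 kHz from -300 ms to the
end of target motion: zero velocity before a per-trial latency, then a
smooth saturating (logistic-type) rise toward ``gain * target_speed`` along
the trial direction, integrated to position, with optional injected saccades
(30-ms, ~200 deg/s velocity pulses) and tracker-like position jitter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import shrinkage_weight

__all__ = [
    "TaskConfig",
    "ObserverGenParams",
    "TrialTrace",
    "TrialTraceSet",
    "sample_trial_direction",
    "simulate_trial",
    "simulate_session",
    "write_session",
    "read_session",
]


@dataclass
class TaskConfig:
    """Geometry and counts of the two-block pursuit task."""

    prior_direction: float = 0.0  # degrees, CCW positive, 0 = rightward
    narrow_offsets: tuple[float, float] = (-15.0, 15.0)
    wide_offsets: tuple[float, float] = (-120.0, 120.0)
    n_trials_narrow: int = 252
    n_trials_wide: int = 378
    prior_dir_weight: float = 2.0  # prior direction shown twice as often (narrow block)
    target_speed: float = 15.0  # deg/s
    local_motion_ms: float = 100.0
    motion_duration_ms: float = 600.0
    pre_onset_ms: float = 300.0
    sample_rate_hz: float = 1000.0
    rise_time_ms: float = 60.0  # velocity onset rise time

    def __post_init__(self) -> None:
        for name in ("narrow_offsets", "wide_offsets"):
            offs = tuple(float(v) for v in getattr(self, name))
            if len(offs) != 2 or abs(offs[0] + offs[1]) > 1e-9:
                raise ValueError(f"{name} must be two offsets symmetric about 0, got {offs}")
            setattr(self, name, offs)
        if self.n_trials_narrow <= 0 or self.n_trials_wide <= 0:
            raise ValueError("trial counts must be positive")
        if self.prior_dir_weight < 1:
            raise ValueError("prior_dir_weight must be >= 1")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        narrow = {0.0, *self.narrow_offsets}
        wide = {0.0, *self.wide_offsets}
        if narrow & wide != {0.0}:
            raise ValueError(
                "narrow and wide direction sets must share only the prior direction"
            )

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    def time_axis(self) -> np.ndarray:
        """Trial time base in ms, motion onset at 0."""
        return np.arange(
            -self.pre_onset_ms, self.motion_duration_ms + 0.5 * self.dt_ms, self.dt_ms
        )

    def block_directions(self, block: str) -> np.ndarray:
        offs = self.narrow_offsets if block == "narrow" else self.wide_offsets
        return self.prior_direction + np.array([offs[0], 0.0, offs[1]])


@dataclass
class ObserverGenParams:
    """Generative parameters: observer model plus kinematic nuisance terms.

    Defaults are monkey-A-like session averages: likelihood SD ~8 deg at high
    contrast, scaled by ~1.8 at low contrast, a 34.5-deg narrow prior and an
    effectively flat wide prior.
    """

    sigma_m_base: float = 7.94  # deg, high-contrast likelihood SD (all directions)
    contrast_factor: float = 1.83  # sigma_m multiplier at low contrast
    sigma_p_narrow: float = 34.5  # deg
    sigma_p_wide: float = 1.0e6  # deg (flat)
    motor_noise_sd: float = 0.0  # deg added after the MAP stage
    latency_mean_high: float = 120.0  # ms
    latency_mean_low: float = 160.0  # ms
    latency_sd: float = 15.0  # ms
    gain_mean: float = 1.0
    gain_sd: float = 0.05
    adaptation_shift: float = 0.0  # deg pulled toward previous trial's direction
    sigma_m_timecourse: tuple[float, float] | None = None  # (amplitude, decay ms)
    saccade_rate: float = 0.05  # fraction of trials with an injected saccade
    position_noise_sd: float = 0.01  # deg RMS tracker jitter on position

    def __post_init__(self) -> None:
        if min(self.sigma_m_base, self.sigma_p_narrow, self.sigma_p_wide) <= 0:
            raise ValueError("sigma_m_base and prior SDs must be positive")
        if self.contrast_factor < 1:
            raise ValueError("contrast_factor must be >= 1")
        if min(self.motor_noise_sd, self.latency_sd, self.gain_sd,
               self.saccade_rate, self.position_noise_sd) < 0:
            raise ValueError("noise SDs and rates must be non-negative")

    def sigma_m_eff(self, contrast: str) -> float:
        return self.sigma_m_base * (self.contrast_factor if contrast == "low" else 1.0)

    def sigma_p(self, block: str) -> float:
        return self.sigma_p_narrow if block == "narrow" else self.sigma_p_wide

    def latency_mean(self, contrast: str) -> float:
        return self.latency_mean_low if contrast == "low" else self.latency_mean_high


@dataclass
class TrialTrace:
    """Raw 1-kHz eye position for one trial plus condition metadata."""

    time_ms: np.ndarray
    eye_h_deg: np.ndarray
    eye_v_deg: np.ndarray
    theta_s: float  # stimulus direction, degrees
    block: str = "narrow"
    contrast: str = "high"
    trial_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        dt = np.diff(self.time_ms)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("time_ms must be uniformly sampled")
        if not (np.all(np.isfinite(self.eye_h_deg)) and np.all(np.isfinite(self.eye_v_deg))):
            raise ValueError("eye position must be finite")


@dataclass
class TrialTraceSet:
    """A session of equal-length trials stored as stacked arrays.

    ``position`` has shape (n_trials, n_samples, 2) with horizontal and
    vertical eye position in degrees; ``meta`` carries one row per trial
    (condition labels plus generator ground truth where available).
    """

    time_ms: np.ndarray  # (T,)
    position: np.ndarray  # (n, T, 2)
    meta: pd.DataFrame
    sample_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.position.ndim != 3 or self.position.shape[2] != 2:
            raise ValueError("position must have shape (n_trials, n_samples, 2)")
        if self.position.shape[1] != self.time_ms.size:
            raise ValueError("position and time_ms length mismatch")
        if len(self.meta) != self.position.shape[0]:
            raise ValueError("meta rows must match n_trials")

    @property
    def n_trials(self) -> int:
        return self.position.shape[0]

    def trial(self, i: int) -> TrialTrace:
        row = self.meta.iloc[i]
        return TrialTrace(
            time_ms=self.time_ms,
            eye_h_deg=self.position[i, :, 0],
            eye_v_deg=self.position[i, :, 1],
            theta_s=float(row["theta_s"]),
            block=str(row["block"]),
            contrast=str(row["contrast"]),
            trial_index=int(row["trial_index"]),
            seed=int(row.get("seed", 0)),
        )

    def subset(self, mask: np.ndarray) -> "TrialTraceSet":
        mask = np.asarray(mask)
        return TrialTraceSet(
            time_ms=self.time_ms,
            position=self.position[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            sample_rate_hz=self.sample_rate_hz,
        )


def sample_trial_direction(
    theta_s: float,
    theta_p: float,
    sigma_m_eff: float,
    sigma_p: float,
    motor_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw one trial's pursuit direction from the generative MAP observer.

    A measurement ``theta_m ~ N(theta_s, sigma_m_eff)`` is shrunk toward
    ``theta_p`` by the posterior weight, then Gaussian motor noise is added.
    Over many draws the mean and SD follow the observer-model predictions
    (with motor variance added in quadrature).
    """
    if sigma_m_eff <= 0 or sigma_p <= 0:
        raise ValueError("sigma_m_eff and sigma_p must be positive")
    if motor_noise_sd < 0:
        raise ValueError("motor_noise_sd must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    theta_m = rng.normal(theta_s, sigma_m_eff)
    w = shrinkage_weight(sigma_m_eff, sigma_p)
    est = w * theta_m + (1.0 - w) * theta_p
    if motor_noise_sd > 0:
        est += rng.normal(0.0, motor_noise_sd)
    return float(est)


def _speed_profile(
    time_ms: np.ndarray, latency_ms: float, peak_speed: float, rise_time_ms: float
) -> np.ndarray:
    """Zero before latency, then a saturating logistic-type rise to peak_speed."""
    t = time_ms - latency_ms
    out = np.zeros_like(time_ms, dtype=float)
    on = t > 0
    out[on] = peak_speed * np.tanh(t[on] / (rise_time_ms / 2.0))
    return out


def simulate_trial(
    theta_trial: float | np.ndarray,
    latency: float,
    gain: float,
    task_config: TaskConfig,
    rng: np.random.Generator | None = None,
    inject_saccade_at: float | None = None,
    position_noise_sd: float = 0.0,
    **trace_meta,
) -> TrialTrace:
    """Realise one trial's eye-position trace.

    ``theta_trial`` is the pursuit direction in degrees — a scalar, or an
    array over the trial time base for a direction that evolves within the
    trial. Velocity is zero before ``latency`` (ms), then rises smoothly
    toward ``gain * target_speed``; position is the running integral.  An
    optional saccade is an additive 30-ms, ~200 deg/s half-sine velocity
    pulse along the pursuit direction.
    """
    if not (50.0 < latency < 400.0):
        raise ValueError(f"latency must be within (50, 400) ms, got {latency}")
    rng = np.random.default_rng() if rng is None else rng
    t = task_config.time_axis()
    dt_s = task_config.dt_ms / 1000.0

    speed = _speed_profile(t, latency, gain * task_config.target_speed,
                           task_config.rise_time_ms)
    theta = np.broadcast_to(np.radians(np.asarray(theta_trial, dtype=float)), t.shape)
    vel = speed[:, None] * np.stack([np.cos(theta), np.sin(theta)], axis=1)

    if inject_saccade_at is not None:
        on = inject_saccade_at
        in_pulse = (t >= on) & (t < on + 30.0)
        pulse = 200.0 * np.sin(np.pi * (t[in_pulse] - on) / 30.0)
        ang = theta[in_pulse]
        vel[in_pulse, 0] += pulse * np.cos(ang)
        vel[in_pulse, 1] += pulse * np.sin(ang)

    pos = np.cumsum(vel, axis=0) * dt_s
    if position_noise_sd > 0:
        pos = pos + rng.normal(0.0, position_noise_sd, size=pos.shape)

    return TrialTrace(
        time_ms=t,
        eye_h_deg=pos[:, 0],
        eye_v_deg=pos[:, 1],
        theta_s=float(trace_meta.pop("theta_s", np.atleast_1d(theta_trial)[-1])),
        **trace_meta,
    )


def _block_direction_counts(cfg: TaskConfig, block: str) -> dict[float, int]:
    """Per-direction trial counts within one block."""
    dirs = cfg.block_directions(block)
    n = cfg.n_trials_narrow if block == "narrow" else cfg.n_trials_wide
    if block == "narrow":
        w = cfg.prior_dir_weight
        n_outer = int(round(n / (w + 2.0)))
        counts = {dirs[0]: n_outer, dirs[1]: n - 2 * n_outer, dirs[2]: n_outer}
    else:
        n_each = n // 3
        counts = {dirs[0]: n_each, dirs[1]: n - 2 * n_each, dirs[2]: n_each}
    return counts


def _wrap180(x):
    """Wrap angle difference(s) to (-180, 180]."""
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


def simulate_session(
    task_config: TaskConfig,
    gen_params: ObserverGenParams,
    seed: int,
    n_block_pairs: int = 1,
) -> TrialTraceSet:
    """Simulate a session of alternating narrow- and wide-prior blocks.

    One master seed spawns an independent stream per trial, so any single
    trial is reproducible regardless of block ordering.  ``n_block_pairs=4``
    gives a full experimental day (2520 trials at the default counts).
    """
    cfg, gp = task_config, gen_params
    master = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(master.spawn(1)[0])

    # Build the full trial schedule first (block, theta_s, contrast).
    sched: list[tuple[str, float, str]] = []
    for _pair in range(n_block_pairs):
        for block in ("narrow", "wide"):
            counts = _block_direction_counts(cfg, block)
            trials = []
            for d, n_d in counts.items():
                n_low = n_d // 2 + (order_rng.random() < 0.5) * (n_d % 2)
                trials += [(block, d, "low")] * int(n_low)
                trials += [(block, d, "high")] * int(n_d - n_low)
            order_rng.shuffle(trials)
            sched += trials

    n_total = len(sched)
    children = master.spawn(n_total + 1)[1:]
    t_axis = cfg.time_axis()
    pos = np.empty((n_total, t_axis.size, 2))
    rows = []
    prev_theta_s: float | None = None

    for i, (block, theta_s, contrast) in enumerate(sched):
        rng = np.random.default_rng(children[i])
        sm = gp.sigma_m_eff(contrast)
        sp = gp.sigma_p(block)
        z = rng.standard_normal()  # shared measurement noise across the trial

        shift = 0.0
        if (
            gp.adaptation_shift != 0.0
            and prev_theta_s is not None
            and abs(_wrap180(prev_theta_s - theta_s)) > 1e-9
        ):
            shift = gp.adaptation_shift * np.sign(_wrap180(prev_theta_s - theta_s))
        motor = rng.normal(0.0, gp.motor_noise_sd) if gp.motor_noise_sd > 0 else 0.0

        if gp.sigma_m_timecourse is not None:
            amp, tau = gp.sigma_m_timecourse
            sm_t = sm * (1.0 + amp * np.exp(-np.clip(t_axis, 0.0, None) / tau))
            w_t = sp**2 / (sp**2 + sm_t**2)
            theta_trial = w_t * (theta_s + z * sm_t) + (1.0 - w_t) * cfg.prior_direction
            theta_trial = theta_trial + shift + motor
            theta_final = float(theta_trial[-1])
        else:
            w = shrinkage_weight(sm, sp)
            theta_final = w * (theta_s + z * sm) + (1.0 - w) * cfg.prior_direction
            theta_final += shift + motor
            theta_trial = theta_final

        latency = float(
            np.clip(rng.normal(gp.latency_mean(contrast), gp.latency_sd), 60.0, 390.0)
        )
        gain = float(max(rng.normal(gp.gain_mean, gp.gain_sd), 0.1))
        sacc_at = (
            float(rng.uniform(-50.0, 250.0)) if rng.random() < gp.saccade_rate else None
        )

        trace = simulate_trial(
            theta_trial, latency, gain, cfg, rng=rng,
            inject_saccade_at=sacc_at,
            position_noise_sd=gp.position_noise_sd,
            theta_s=theta_s, block=block, contrast=contrast, trial_index=i,
            seed=int(children[i].generate_state(1)[0] % (2**31)),
        )
        pos[i, :, 0] = trace.eye_h_deg
        pos[i, :, 1] = trace.eye_v_deg
        rows.append(
            dict(
                trial_index=i, block=block, contrast=contrast, theta_s=theta_s,
                prev_theta_s=np.nan if prev_theta_s is None else prev_theta_s,
                theta_trial=theta_final, latency_true=latency, gain_true=gain,
                saccade_ms=np.nan if sacc_at is None else sacc_at,
                seed=int(children[i].generate_state(1)[0] % (2**31)),
            )
        )
        prev_theta_s = theta_s

    return TrialTraceSet(
        time_ms=t_axis, position=pos, meta=pd.DataFrame(rows),
        sample_rate_hz=cfg.sample_rate_hz,
    )


# ---------------------------------------------------------------------------
# Session container I/O: CSV directory layout or a single HDF5 file.

def write_session(traces: TrialTraceSet, path: str | Path, fmt: str = "csv") -> Path:
    """Write a session to ``path`` as a CSV directory or an HDF5 file."""
    path = Path(path)
    if fmt == "csv":
        tr_dir = path / "traces"
        tr_dir.mkdir(parents=True, exist_ok=True)
        traces.meta.to_csv(path / "metadata.csv", index=False)
        for i in range(traces.n_trials):
            df = pd.DataFrame(
                dict(time_ms=traces.time_ms, eye_h_deg=traces.position[i, :, 0],
                     eye_v_deg=traces.position[i, :, 1])
            )
            df.to_csv(tr_dir / f"trial_{i:05d}.csv", index=False)
        return path
    if fmt == "hdf5":
        import h5py

        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=traces.time_ms)
            f.create_dataset("position", data=traces.position, compression="gzip")
            f.attrs["sample_rate_hz"] = traces.sample_rate_hz
            g = f.create_group("meta")
            for col in traces.meta.columns:
                vals = traces.meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)
        return path
    raise ValueError(f"fmt must be 'csv' or 'hdf5', got {fmt!r}")


def read_session(path: str | Path, fmt: str | None = None) -> TrialTraceSet:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.is_dir() else "hdf5"
    if fmt == "csv":
        meta = pd.read_csv(path / "metadata.csv")
        files = sorted((path / "traces").glob("trial_*.csv"))
        if len(files) != len(meta):
            raise ValueError("trace file count does not match metadata rows")
        first = pd.read_csv(files[0])
        time_ms = first["time_ms"].to_numpy()
        pos = np.empty((len(files), time_ms.size, 2))
        for i, fpath in enumerate(files):
            df = pd.read_csv(fpath) if i else first
            pos[i, :, 0] = df["eye_h_deg"].to_numpy()
            pos[i, :, 1] = df["eye_v_deg"].to_numpy()
        return TrialTraceSet(time_ms=time_ms, position=pos, meta=meta)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            time_ms = f["time_ms"][:]
            pos = f["position"][:]
            sr = float(f.attrs.get("sample_rate_hz", 1000.0))
            cols = {}
            for col in f["meta"]:
                vals = f["meta"][col][:]
                if vals.dtype.kind == "S":
                    vals = vals.astype(str)
                cols[col] = vals
        return TrialTraceSet(
            time_ms=time_ms, position=pos, meta=pd.DataFrame(cols), sample_rate_hz=sr
        )
    raise ValueError(f"fmt must be 'csv' or 'hdf5', got {fmt!r}")
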