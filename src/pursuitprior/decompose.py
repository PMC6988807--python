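"""Open-loop decomposition of pursuit trials into direction, gain, latency.

Each condition (target direction x contrast x block) gets a velocity
*template*: the across-trial mean of horizontal and vertical velocity over a
window from -20 to +100 ms around the condition's average pursuit latency,
after rotating the trials so that the mean pursuit direction is 45 deg.  The
rotation balances the horizontal and vertical components so that the
per-trial direction estimate, atan2 of the fitted component scales, is
unbiased under symmetric noise.

Each trial is then fit by sliding (time shift tau) and scaling (a, b) the
two template components simultaneously, minimising

    sum_t (e_h(t) - a T_h(t - tau))^2 + (e_v(t) - b T_v(t - tau))^2

For a fixed tau, a and b have closed-form least-squares solutions; tau is
found by a 1-ms grid search over +/-50 ms followed by parabolic refinement,
making the whole fit deterministic.  A trial is included downstream only if
the fitted template explains more than 70% of its variance, and a session
is retained only if more than 70 included prior-direction trials remain in
each block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import VelocityTraceSet

__all__ = [
    "PursuitTemplate",
    "TrialKinematics",
    "SessionVerdict",
    "estimate_session_latency",
    "build_template",
    "fit_trial",
    "fit_trials",
    "apply_session_inclusion",
    "decompose_session",
]

REFERENCE_DIRECTION = 45.0  # deg; templates are rotated to this mean direction
TEMPLATE_WINDOW = (-20.0, 100.0)  # ms around the session-average latency
SHIFT_RANGE = (-50.0, 50.0)  # ms, trial-vs-template slide
VE_THRESHOLD = 0.70  # minimum variance explained for trial inclusion
MIN_PRIOR_TRIALS = 70  # session kept iff strictly more than this per block


def _wrap180(x):
    return (np.asarray(x) + 180.0) % 360.0 - 180.0


@dataclass
class PursuitTemplate:
    """Condition-average velocity template in the rotated (45-deg) frame."""

    time_ms: np.ndarray  # (W,) absolute trial times of the window samples
    template_h: np.ndarray  # (W,) deg/s
    template_v: np.ndarray  # (W,)
    rotation_deg: float  # rotation applied to trials (45 - condition mean direction)
    session_latency_ms: float
    n_trials: int

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.template_h)) and np.all(np.isfinite(self.template_v))):
            raise ValueError("template must be finite")

    @property
    def mean_direction_deg(self) -> float:
        """Mean direction of the template over its window (45 by construction)."""
        return float(
            np.degrees(np.arctan2(self.template_v.sum(), self.template_h.sum()))
        )


@dataclass
class TrialKinematics:
    """Per-trial open-loop kinematics from the template fit."""

    direction_deg: float  # back in the stimulus frame
    gain_h: float
    gain_v: float
    latency_ms: float
    variance_explained: float
    included: bool
    shift_ms: float
    at_shift_bound: bool = False

    @property
    def gain(self) -> float:
        return 0.5 * (self.gain_h + self.gain_v)


@dataclass
class SessionVerdict:
    retained: bool
    n_prior_narrow: int
    n_prior_wide: int


def estimate_session_latency(
    time_ms: np.ndarray, speeds: np.ndarray, min_trials: int = 10
) -> float:
    """Average pursuit latency of one condition from the mean speed rise.

    The trial-averaged radial speed is referenced to its value at +250 ms;
    the 10% and 50% crossing times bracket the rise, and a least-squares
    line through that segment is extrapolated back to zero speed.
    """
    speeds = np.atleast_2d(speeds)
    if speeds.shape[0] < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {speeds.shape[0]}")
    mean_speed = speeds.mean(axis=0)
    v250 = float(np.interp(250.0, time_ms, mean_speed))
    if v250 <= 0:
        raise ValueError("condition unusable: average speed never rises")

    post = time_ms >= 0
    t, v = time_ms[post], mean_speed[post]
    above10 = v > 0.1 * v250
    if not above10.any():
        raise ValueError("condition unusable: speed never exceeds 10% of its 250-ms value")
    i10 = int(np.argmax(above10))
    above50 = v > 0.5 * v250
    i50 = int(np.argmax(above50)) if above50.any() else len(v) - 1
    if i50 <= i10 + 1:
        i50 = min(i10 + 2, len(v) - 1)

    seg_t, seg_v = t[i10 : i50 + 1], v[i10 : i50 + 1]
    slope, intercept = np.polyfit(seg_t, seg_v, 1)
    if slope <= 0:
        raise ValueError("condition unusable: no rising speed segment")
    return float(-intercept / slope)


def build_template(
    vel: VelocityTraceSet, session_latency: float, min_trials: int = 10
) -> PursuitTemplate:
    """Average the trials of one condition into a rotated velocity template."""
    if vel.n_trials < min_trials:
        raise ValueError(f"need >= {min_trials} trials to build a template")
    t = vel.time_ms
    lo, hi = TEMPLATE_WINDOW
    win = (t >= session_latency + lo) & (t <= session_latency + hi)
    if win.sum() < 10:
        raise ValueError("template window falls outside the trial time base")

    vbar = vel.velocity.mean(axis=0)  # (T, 2)
    mean_dir = np.degrees(np.arctan2(vbar[win, 1].sum(), vbar[win, 0].sum()))
    rot = REFERENCE_DIRECTION - mean_dir
    c, s = np.cos(np.radians(rot)), np.sin(np.radians(rot))
    th = c * vbar[win, 0] - s * vbar[win, 1]
    tv = s * vbar[win, 0] + c * vbar[win, 1]
    return PursuitTemplate(
        time_ms=t[win], template_h=th, template_v=tv, rotation_deg=float(rot),
        session_latency_ms=float(session_latency), n_trials=vel.n_trials,
    )


def _rotate(velocity: np.ndarray, rot_deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(rot_deg)), np.sin(np.radians(rot_deg))
    out = np.empty_like(velocity)
    out[..., 0] = c * velocity[..., 0] - s * velocity[..., 1]
    out[..., 1] = s * velocity[..., 0] + c * velocity[..., 1]
    return out


def fit_trials(
    vel: VelocityTraceSet, template: PursuitTemplate, ve_threshold: float = VE_THRESHOLD
) -> list[TrialKinematics]:
    """Fit every trial of one condition against its template (vectorised).

    Trials are rotated into the template frame, the shift grid is scanned at
    the sampling resolution with closed-form scale factors, and the best
    shift is refined parabolically.  Directions are rotated back to the
    stimulus frame.
    """
    th, tv = template.template_h, template.template_v
    den_h, den_v = float(th @ th), float(tv @ tv)
    if den_h <= 1e-12 or den_v <= 1e-12:
        raise ValueError("degenerate template (near-zero energy)")

    t = vel.time_ms
    dt = float(t[1] - t[0])
    w0 = int(round((template.time_ms[0] - t[0]) / dt))
    W = template.time_ms.size
    shifts = np.arange(
        int(round(SHIFT_RANGE[0] / dt)), int(round(SHIFT_RANGE[1] / dt)) + 1
    )
    # Keep only shifts whose window stays inside the trial time base.
    shifts = shifts[(w0 + shifts >= 0) & (w0 + shifts + W <= t.size)]
    if shifts.size == 0:
        raise ValueError("no admissible shift keeps the window inside the trial")

    E = _rotate(vel.velocity, template.rotation_deg)  # (n, T, 2)
    n = E.shape[0]
    n_s = shifts.size
    a_grid = np.empty((n, n_s))
    b_grid = np.empty((n, n_s))
    sse = np.empty((n, n_s))
    for j, sh in enumerate(shifts):
        sl = slice(w0 + sh, w0 + sh + W)
        eh, ev = E[:, sl, 0], E[:, sl, 1]
        a = (eh @ th) / den_h
        b = (ev @ tv) / den_v
        a_grid[:, j], b_grid[:, j] = a, b
        sse[:, j] = (
            np.einsum("ij,ij->i", eh, eh) - a**2 * den_h
            + np.einsum("ij,ij->i", ev, ev) - b**2 * den_v
        )

    j_best = np.argmin(sse, axis=1)
    # Parabolic refinement of the shift on the SSE grid.
    tau = shifts[j_best].astype(float)
    frac = np.zeros(n)
    interior = (j_best > 0) & (j_best < n_s - 1)
    ji = j_best[interior]
    rows = np.flatnonzero(interior)
    y0, y1, y2 = sse[rows, ji - 1], sse[rows, ji], sse[rows, ji + 1]
    denom = y0 - 2 * y1 + y2
    ok = denom > 1e-12
    delta = np.zeros_like(y1)
    delta[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
    delta = np.clip(delta, -1.0, 1.0)
    tau[rows] += delta
    frac[rows] = delta

    results: list[TrialKinematics] = []
    for i in range(n):
        j = j_best[i]
        f = frac[i]
        base = w0 + shifts[j]
        if abs(f) > 1e-9 and 0 <= base + int(np.sign(f)) and base + W + int(np.ceil(abs(f))) <= t.size:
            # linear interpolation of the trial at the fractional shift
            g = abs(f)
            step = int(np.sign(f))
            sl0 = slice(base, base + W)
            sl1 = slice(base + step, base + step + W)
            eh = (1 - g) * E[i, sl0, 0] + g * E[i, sl1, 0]
            ev = (1 - g) * E[i, sl0, 1] + g * E[i, sl1, 1]
            a = float(eh @ th) / den_h
            b = float(ev @ tv) / den_v
            sse_i = float(eh @ eh - a**2 * den_h + ev @ ev - b**2 * den_v)
        else:
            sl0 = slice(base, base + W)
            eh, ev = E[i, sl0, 0], E[i, sl0, 1]
            a, b = float(a_grid[i, j]), float(b_grid[i, j])
            sse_i = float(sse[i, j])
        sst = float(((eh - eh.mean()) ** 2).sum() + ((ev - ev.mean()) ** 2).sum())
        ve = 1.0 - sse_i / sst if sst > 0 else 0.0
        ve = float(np.clip(ve, 0.0, 1.0))
        direction = (
            np.degrees(np.arctan2(b, a)) - template.rotation_deg
        )
        shift_ms = tau[i] * dt
        at_bound = bool(j == 0 or j == n_s - 1)
        results.append(
            TrialKinematics(
                direction_deg=float(_wrap180(direction)),
                gain_h=a, gain_v=b,
                latency_ms=float(template.session_latency_ms + shift_ms),
                variance_explained=ve,
                included=bool(ve > ve_threshold and not at_bound),
                shift_ms=float(shift_ms),
                at_shift_bound=at_bound,
            )
        )
    return results


def fit_trial(
    trial_velocity: np.ndarray,
    time_ms: np.ndarray,
    template: PursuitTemplate,
    ve_threshold: float = VE_THRESHOLD,
) -> TrialKinematics:
    """Fit one trial (velocity array of shape (T, 2)) against a template."""
    vel = VelocityTraceSet(
        time_ms=time_ms,
        velocity=trial_velocity[None, ...],
        meta=pd.DataFrame({"trial_index": [0]}),
        sample_rate_hz=1000.0 / float(time_ms[1] - time_ms[0]),
    )
    return fit_trials(vel, template, ve_threshold=ve_threshold)[0]


def _mad_outliers(x: np.ndarray, k: float = 3.0) -> np.ndarray:
    """True where |x - median| exceeds k scaled MADs (returns all-False if MAD=0)."""
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad <= 0:
        return np.zeros_like(x, dtype=bool)
    return np.abs(x - med) > k * mad


def apply_session_inclusion(
    kinematics: pd.DataFrame,
    prior_direction: float,
    min_prior_trials: int = MIN_PRIOR_TRIALS,
    mad_k: float = 3.0,
) -> tuple[pd.DataFrame, SessionVerdict]:
    """Apply the per-trial outlier rule and the per-session trial-count rule.

    Within each condition, included trials whose direction lies beyond
    ``mad_k`` scaled MADs of the condition median are marked excluded.  The
    session is retained iff strictly more than ``min_prior_trials`` included
    prior-direction trials remain in each block.
    """
    kin = kinematics.copy()
    kin["outlier"] = False
    for _, idx in kin.groupby(["block", "contrast", "theta_s"]).groups.items():
        sub = kin.loc[idx]
        inc = sub["included"].to_numpy(dtype=bool)
        if inc.sum() < 3:
            continue
        out = _mad_outliers(sub.loc[inc, "direction_deg"].to_numpy(), k=mad_k)
        kin.loc[sub.index[inc][out], "outlier"] = True
    kin.loc[kin["outlier"], "included"] = False

    def _n_prior(block: str) -> int:
        m = (
            (kin["block"] == block)
            & (np.abs(_wrap180(kin["theta_s"] - prior_direction)) < 1e-6)
            & kin["included"]
        )
        return int(m.sum())

    n_nar, n_wid = _n_prior("narrow"), _n_prior("wide")
    verdict = SessionVerdict(
        retained=bool(n_nar > min_prior_trials and n_wid > min_prior_trials),
        n_prior_narrow=n_nar,
        n_prior_wide=n_wid,
    )
    return kin, verdict


def decompose_session(
    vel: VelocityTraceSet,
    prior_direction: float,
    min_trials: int = 10,
    ve_threshold: float = VE_THRESHOLD,
    mad_k: float = 3.0,
) -> tuple[pd.DataFrame, SessionVerdict]:
    """Decompose every condition of a (saccade-cleaned) session.

    Returns the per-trial kinematics table (one row per trial, merged with
    the trial metadata) and the session inclusion verdict.
    """
    frames = []
    for (block, contrast, theta_s), idx in vel.meta.groupby(
        ["block", "contrast", "theta_s"]
    ).groups.items():
        mask = np.zeros(vel.n_trials, dtype=bool)
        mask[np.asarray(idx)] = True
        cond = vel.subset(mask)
        try:
            lat = estimate_session_latency(cond.time_ms, cond.speed, min_trials=min_trials)
            template = build_template(cond, lat, min_trials=min_trials)
            kins = fit_trials(cond, template, ve_threshold=ve_threshold)
        except ValueError:
            kins = None
        rows = cond.meta[["trial_index", "block", "contrast", "theta_s"]].copy()
        if kins is None:
            for col in ("direction_deg", "gain", "latency_ms", "variance_explained"):
                rows[col] = np.nan
            rows["included"] = False
        else:
            rows["direction_deg"] = [
                theta_s + _wrap180(k.direction_deg - theta_s) for k in kins
            ]  # unwrap near the target direction
            rows["gain"] = [k.gain for k in kins]
            rows["latency_ms"] = [k.latency_ms for k in kins]
            rows["variance_explained"] = [k.variance_explained for k in kins]
            rows["included"] = [k.included for k in kins]
        frames.append(rows)
    kin = pd.concat(frames, ignore_index=True).sort_values("trial_index")
    kin = kin.reset_index(drop=True)
    return apply_session_inclusion(kin, prior_direction, mad_k=mad_k)
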