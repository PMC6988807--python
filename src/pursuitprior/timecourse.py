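"""Time-resolved pursuit bias/precision and cluster-based permutation tests.

The open-loop period (0-250 ms from motion onset) is scanned at the
sampling resolution.  At each time point the instantaneous pursuit
direction (atan2 of the vertical over horizontal eye velocity, masked where
radial speed is below a floor) yields a direction-difference ratio per
contrast and block (bias) and a cross-trial SD at the common direction
(precision).  Curves from many sessions are compared across prior
conditions with a two-sided cluster-based permutation test: contiguous
samples whose paired t statistic exceeds the cluster-forming threshold are
grouped, cluster mass is the summed |t|, and the null distribution of the
maximum mass is built by random within-session sign flips of the paired
differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .preprocess import VelocityTraceSet

__all__ = [
    "TimecourseStat",
    "ClusterResult",
    "instantaneous_direction",
    "timecourse_statistics",
    "cluster_permutation_test",
]


def _wrap180(x):
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


def instantaneous_direction(
    velocity: np.ndarray, speed_floor: float = 1.0
) -> np.ndarray:
    """Per-sample pursuit direction in degrees, NaN where speed < floor.

    ``velocity`` is (..., 2); the direction is atan2(v_v, v_h), CCW positive
    with 0 deg rightward.
    """
    v = np.asarray(velocity, dtype=float)
    speed = np.hypot(v[..., 0], v[..., 1])
    ang = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return np.where(speed >= speed_floor, ang, np.nan)


def _boxcar_nan(y: np.ndarray, width: int) -> np.ndarray:
    """NaN-aware boxcar smoothing along the last axis."""
    if width <= 1:
        return y
    kernel = np.ones(width)
    finite = np.isfinite(y)
    z = np.where(finite, y, 0.0)
    num = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), -1, z)
    den = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), -1, finite.astype(float)
    )
    out = np.full_like(y, np.nan, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


@dataclass
class TimecourseStat:
    """Per-session time-resolved bias and precision curves.

    ``ratio_bias[(block, contrast)]`` and ``sd[(block, contrast)]`` are
    arrays over ``time_ms`` (NaN where masked).
    """

    time_ms: np.ndarray
    ratio_bias: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_sessions: int = 1


def session_timecourse(
    vel: VelocityTraceSet,
    included: np.ndarray,
    prior_direction: float,
    t_range: tuple[float, float] = (0.0, 250.0),
    speed_floor: float = 1.0,
    smooth_ms: float = 10.0,
    min_trials: int = 5,
) -> TimecourseStat:
    """Time-resolved bias ratio and direction SD for one session."""
    tmask = (vel.time_ms >= t_range[0]) & (vel.time_ms <= t_range[1])
    t = vel.time_ms[tmask]
    dirs = instantaneous_direction(vel.velocity[:, tmask, :], speed_floor=speed_floor)
    meta = vel.meta
    inc = np.asarray(included, dtype=bool)
    dt = float(t[1] - t[0])
    width = max(int(round(smooth_ms / dt)), 1)

    out = TimecourseStat(time_ms=t)
    for (block, contrast), sub in meta.groupby(["block", "contrast"]):
        rows = np.flatnonzero(
            (meta["block"] == block).to_numpy()
            & (meta["contrast"] == contrast).to_numpy()
            & inc
        )
        if rows.size == 0:
            continue
        offs = _wrap180(meta["theta_s"].to_numpy()[rows] - prior_direction)
        d = dirs[rows]  # (n_cond_trials, T')
        theta = meta["theta_s"].to_numpy()[rows][:, None]
        d = theta + _wrap180(d - theta)  # unwrap near each target

        uniq = np.unique(np.round(offs, 6))
        outer = uniq[np.abs(uniq) > 1e-6]
        # Bias: separation of outer-direction mean curves over target separation.
        if outer.size == 2:
            means = {}
            for o in outer:
                sel = np.abs(offs - o) < 1e-6
                n_ok = np.sum(np.isfinite(d[sel]), axis=0)
                m = np.nansum(np.where(np.isfinite(d[sel]), d[sel], 0.0), axis=0)
                m = np.where(n_ok >= min_trials, m / np.maximum(n_ok, 1), np.nan)
                means[o] = m
            sep = abs(outer[1] - outer[0])
            ratio = np.abs(means[outer[1]] - means[outer[0]]) / sep
            out.ratio_bias[(block, contrast)] = _boxcar_nan(ratio, width)
        # Precision: cross-trial SD at the common (prior) direction.
        sel = np.abs(offs) <= 1e-6
        if sel.sum() >= min_trials:
            dc = d[sel]
            finite = np.isfinite(dc)
            n_ok = finite.sum(axis=0)
            z = np.where(finite, dc, 0.0)
            denom = np.maximum(n_ok, 1)
            mu = z.sum(axis=0) / denom
            var = (z**2).sum(axis=0) / denom - mu**2
            var *= denom / np.maximum(denom - 1, 1)
            sd = np.where(n_ok >= min_trials, np.sqrt(np.maximum(var, 0.0)), np.nan)
            out.sd[(block, contrast)] = _boxcar_nan(sd, width)
    return out


def timecourse_statistics(
    sessions: list[TimecourseStat], min_sessions: int = 5
) -> TimecourseStat:
    """Average per-session curves across sessions (NaN-aware)."""
    if len(sessions) < min_sessions:
        raise ValueError(f"need >= {min_sessions} sessions, got {len(sessions)}")
    t = sessions[0].time_ms
    out = TimecourseStat(time_ms=t, n_sessions=len(sessions))
    for attr in ("ratio_bias", "sd"):
        keys = set().union(*(getattr(s, attr).keys() for s in sessions))
        for key in keys:
            stack = np.stack(
                [getattr(s, attr).get(key, np.full(t.size, np.nan)) for s in sessions]
            )
            finite = np.isfinite(stack)
            n_ok = finite.sum(axis=0)
            total = np.where(finite, stack, 0.0).sum(axis=0)
            getattr(out, attr)[key] = np.where(
                n_ok > 0, total / np.maximum(n_ok, 1), np.nan
            )
    return out


@dataclass
class ClusterResult:
    """Significant time clusters from a permutation test."""

    intervals: list[tuple[float, float]]
    masses: list[float]
    p_values: list[float]
    n_permutations: int
    t_crit: float
    all_intervals: list[tuple[float, float]] = field(default_factory=list)
    all_p_values: list[float] = field(default_factory=list)


def cluster_permutation_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    time_ms: np.ndarray,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
    min_sessions: int = 5,
) -> ClusterResult:
    """Two-sided cluster-based permutation test on paired session curves.

    ``curves_a`` and ``curves_b`` are (n_sessions, T) arrays on a common
    time axis.  Per-time paired t statistics form clusters where |t|
    exceeds the two-sided ``cluster_alpha`` critical value; each cluster's
    mass (summed |t|) is compared with the permutation distribution of the
    maximum mass under random within-session sign flips.  Time points where
    any session is NaN are excluded and break cluster contiguity.
    """
    A = np.asarray(curves_a, dtype=float)
    B = np.asarray(curves_b, dtype=float)
    if A.shape != B.shape:
        raise ValueError("curve arrays must have the same shape")
    n, T = A.shape
    if n < min_sessions:
        raise ValueError(f"need >= {min_sessions} sessions, got {n}")
    if time_ms.size != T:
        raise ValueError("time axis length mismatch")

    D = A - B
    valid = np.all(np.isfinite(D), axis=0)
    t_crit = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1))

    def _tstat(diffs: np.ndarray) -> np.ndarray:
        m = diffs.mean(axis=0)
        s = diffs.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s > 0, m / (s / np.sqrt(n)), 0.0)

    t_obs = np.where(valid, _tstat(D), 0.0)
    supra = (np.abs(t_obs) > t_crit) & valid
    labels, n_clust = ndimage.label(supra)
    obs_masses = (
        ndimage.sum(np.abs(t_obs), labels, index=np.arange(1, n_clust + 1))
        if n_clust
        else np.array([])
    )

    # Permutation null of the maximum cluster mass (vectorised sign flips).
    rng = np.random.default_rng(seed)
    Dv = D[:, valid]
    sum_sq = np.sum(Dv**2, axis=0)  # invariant under sign flips
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    mean_p = (signs @ Dv) / n  # (n_perm, T_valid)
    var_p = (sum_sq / n - mean_p**2) * (n / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = np.where(var_p > 0, mean_p / np.sqrt(var_p / n), 0.0)
    supra_p = np.abs(t_p) > t_crit
    # Label clusters row-wise in one call (connectivity restricted to time axis).
    structure = np.array([[0, 0, 0], [1, 1, 1], [0, 0, 0]])
    lab_p, n_lab = ndimage.label(supra_p, structure=structure)
    max_mass = np.zeros(n_perm)
    if n_lab:
        masses = ndimage.sum(np.abs(t_p), lab_p, index=np.arange(1, n_lab + 1))
        rows = ndimage.minimum(
            np.repeat(np.arange(n_perm)[:, None], supra_p.shape[1], axis=1),
            lab_p,
            index=np.arange(1, n_lab + 1),
        ).astype(int)
        np.maximum.at(max_mass, rows, masses)

    intervals, masses_out, pvals = [], [], []
    all_intervals, all_pvals = [], []
    for k in range(1, n_clust + 1):
        idx = np.flatnonzero(labels == k)
        mass = float(obs_masses[k - 1])
        p = float((np.sum(max_mass >= mass) + 1) / (n_perm + 1))
        iv = (float(time_ms[idx[0]]), float(time_ms[idx[-1]]))
        all_intervals.append(iv)
        all_pvals.append(p)
        if p < alpha:
            intervals.append(iv)
            masses_out.append(mass)
            pvals.append(p)
    return ClusterResult(
        intervals=intervals, masses=masses_out, p_values=pvals,
        n_permutations=n_perm, t_crit=t_crit,
        all_intervals=all_intervals, all_p_values=all_pvals,
    )
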