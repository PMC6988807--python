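"""Session-level bias and precision statistics for the two-block design.

Bias is quantified by the *direction-difference ratio*: the angular
separation of the mean pursuit directions of the two outer targets divided
by the separation of the target directions themselves.  A ratio below 1
means attraction toward the central (prior) direction.  Precision is the
robust SD of single-trial pursuit directions at the direction common to the
two blocks; the narrow/wide SD ratio below 1 is the variance-reduction
signature of a strong prior.  All angle arithmetic is done on directions
unwrapped to within +/-180 deg of their target direction, which is valid
because empirical spreads are far below 180 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "summarize_conditions",
    "direction_difference_ratio",
    "pursuit_direction_sd",
    "robust_mean_direction",
    "session_ratios",
    "log_ratio_ttest",
    "bias_precision_correlation",
    "adaptation_statistic",
]

# Normal-consistency constant for an SD computed after discarding samples
# beyond 3 sigma: E[SD | truncation] / sigma for a standard normal.
_TRUNC3 = float(np.sqrt(1.0 - 6.0 * sps.norm.pdf(3.0) / (2.0 * sps.norm.cdf(3.0) - 1.0)))


def _wrap180(x):
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class ConditionSummary:
    block: str
    contrast: str
    theta_s: float
    n_trials: int
    mean_direction_deg: float
    sd_direction_deg: float


def _mad_keep(x: np.ndarray, k: float = 3.0) -> np.ndarray:
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad <= 0:
        return np.ones_like(x, dtype=bool)
    return np.abs(x - med) <= k * mad


def pursuit_direction_sd(
    trial_directions: np.ndarray, mad_k: float = 3.0, min_trials: int = 2
) -> float:
    """Robust SD of unwrapped trial directions.

    Samples beyond ``mad_k`` scaled MADs of the median are discarded and the
    remaining sample SD is divided by the normal truncation constant, so the
    estimator is consistent for the SD of clean Gaussian data while being
    insensitive to gross outliers (e.g. mislabelled or saccadic trials).
    """
    x = np.asarray(trial_directions, dtype=float)
    if x.size < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {x.size}")
    keep = _mad_keep(x, k=mad_k)
    kept = x[keep]
    if kept.size < 2:
        raise ValueError("too few trials after outlier removal")
    return float(np.std(kept, ddof=1) / _TRUNC3)


def robust_mean_direction(trial_directions: np.ndarray, mad_k: float = 3.0) -> float:
    """Mean of unwrapped trial directions after MAD outlier removal."""
    x = np.asarray(trial_directions, dtype=float)
    if x.size < 1:
        raise ValueError("no trials")
    return float(x[_mad_keep(x, k=mad_k)].mean())


def summarize_conditions(
    kinematics: pd.DataFrame, included_only: bool = True, mad_k: float = 3.0
) -> pd.DataFrame:
    """Per-condition mean and robust SD of pursuit direction.

    Returns a DataFrame with columns ``block, contrast, theta_s, n_trials,
    mean_direction_deg, sd_direction_deg`` (one row per condition cell).
    """
    kin = kinematics[kinematics["included"]] if included_only else kinematics
    rows = []
    for (block, contrast, theta_s), sub in kin.groupby(["block", "contrast", "theta_s"]):
        dirs = sub["direction_deg"].to_numpy(dtype=float)
        dirs = theta_s + _wrap180(dirs - theta_s)
        rows.append(
            dict(
                block=block, contrast=contrast, theta_s=float(theta_s),
                n_trials=int(len(dirs)),
                mean_direction_deg=robust_mean_direction(dirs, mad_k=mad_k),
                sd_direction_deg=pursuit_direction_sd(dirs, mad_k=mad_k)
                if len(dirs) >= 2 else np.nan,
            )
        )
    return pd.DataFrame(rows)


def direction_difference_ratio(
    outer_pursuit_dirs: tuple[float, float], outer_target_dirs: tuple[float, float]
) -> float:
    """|pursuit separation| / |target separation| for the two outer targets.

    Separations are angular, wrapped only once to the targets' geometry: the
    target separation is taken as the configured angular distance (30 deg
    narrow, 240 deg wide), and the pursuit separation is measured in the
    same unwrapped frame.
    """
    p1, p2 = (float(v) for v in outer_pursuit_dirs)
    t1, t2 = (float(v) for v in outer_target_dirs)
    dt = t1 - t2
    if abs(dt) < 1e-12:
        raise ValueError("outer target directions must differ")
    return float(abs(p1 - p2) / abs(dt))


def session_ratios(summaries: pd.DataFrame, prior_direction: float) -> pd.DataFrame:
    """Bias and SD ratios of one session from its condition summaries.

    Returns one row per (block, contrast) with the direction-difference
    ratio, plus the common-direction SD, in a tidy frame.
    """
    rows = []
    for (block, contrast), sub in summaries.groupby(["block", "contrast"]):
        sub = sub.copy()
        sub["offset"] = _wrap180(sub["theta_s"] - prior_direction)
        outer = sub[np.abs(sub["offset"]) > 1e-6].sort_values("offset")
        central = sub[np.abs(sub["offset"]) <= 1e-6]
        if len(outer) != 2 or len(central) != 1:
            raise ValueError(
                f"condition ({block}, {contrast}) must have two outer and one "
                f"central direction"
            )
        # Work in the unwrapped offset frame: pursuit offsets relative to prior.
        p = (
            outer["offset"].to_numpy()
            + _wrap180(outer["mean_direction_deg"].to_numpy() - outer["theta_s"].to_numpy())
        )
        ratio = direction_difference_ratio(
            (p[1], p[0]), (outer["offset"].iloc[1], outer["offset"].iloc[0])
        )
        rows.append(
            dict(
                block=block, contrast=contrast, ratio_bias=ratio,
                sd_common=float(central["sd_direction_deg"].iloc[0]),
                n_common=int(central["n_trials"].iloc[0]),
            )
        )
    out = pd.DataFrame(rows)
    # Narrow/wide SD ratio per contrast at the common direction.
    sd_ratio = {}
    for contrast in out["contrast"].unique():
        nar = out[(out.block == "narrow") & (out.contrast == contrast)]["sd_common"]
        wid = out[(out.block == "wide") & (out.contrast == contrast)]["sd_common"]
        if len(nar) and len(wid):
            sd_ratio[contrast] = float(nar.iloc[0] / wid.iloc[0])
    out.attrs["sd_ratio_narrow_over_wide"] = sd_ratio
    return out


@dataclass(frozen=True)
class TTestSummary:
    mean_ratio: float
    t: float
    p: float
    n: int


def log_ratio_ttest(session_ratios_: np.ndarray, min_sessions: int = 5) -> TTestSummary:
    """One-sample two-sided t-test of log(ratio) against 0 (ratio against 1)."""
    r = np.asarray(session_ratios_, dtype=float)
    if r.size < min_sessions:
        raise ValueError(f"need >= {min_sessions} sessions, got {r.size}")
    if np.any(r <= 0):
        raise ValueError("ratios must be positive for the log transform")
    logs = np.log(r)
    if np.ptp(logs) == 0:  # degenerate sample: no evidence either way
        t, p = (0.0, 1.0) if logs[0] == 0 else (np.inf * np.sign(logs[0]), 0.0)
    else:
        res = sps.ttest_1samp(logs, 0.0)
        t, p = float(res.statistic), float(res.pvalue)
    return TTestSummary(mean_ratio=float(r.mean()), t=t, p=p, n=r.size)


def bias_precision_correlation(
    sd_ratios: np.ndarray, bias_ratios: np.ndarray, min_sessions: int = 10
) -> tuple[float, float]:
    """Spearman rank correlation between per-session SD and bias ratios."""
    x = np.asarray(bias_ratios, dtype=float)
    y = np.asarray(sd_ratios, dtype=float)
    if x.size != y.size:
        raise ValueError("paired inputs must have equal length")
    if x.size < min_sessions:
        raise ValueError(f"need >= {min_sessions} paired sessions, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def adaptation_statistic(
    trial_directions: np.ndarray,
    current_target_dirs: np.ndarray,
    previous_target_dirs: np.ndarray,
) -> float:
    """Single-trial adaptation: mean(dir | prev CCW) - mean(dir | prev CW).

    Uses only trials whose previous trial's target direction differs from the
    current one.  Positive values mean the current pursuit direction is
    attracted toward the previous trial's direction.
    """
    d = np.asarray(trial_directions, dtype=float)
    cur = np.asarray(current_target_dirs, dtype=float)
    prev = np.asarray(previous_target_dirs, dtype=float)
    rel = _wrap180(prev - cur)
    valid = np.isfinite(prev) & (np.abs(rel) > 1e-9)
    ccw = valid & (rel > 0)
    cw = valid & (rel < 0)
    if not (ccw.any() and cw.any()):
        raise ValueError("need both CCW and CW previous-trial subsets")
    dirs = cur + _wrap180(d - cur)
    return float(dirs[ccw].mean() - dirs[cw].mean())
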