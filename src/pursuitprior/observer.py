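"""Gaussian Bayesian observer model of pursuit direction.

The observer receives a noisy measurement ``theta_m`` of the stimulus
direction ``theta_s`` (Gaussian likelihood, SD ``sigma_m``) and combines it
with a Gaussian direction prior (mean ``theta_p``, SD ``sigma_p``).  With
both densities Gaussian the posterior is Gaussian and its maximum
(the MAP estimate) is the precision-weighted average

    theta_est = w * theta_m + (1 - w) * theta_p,      w = sigma_p^2 / (sigma_p^2 + sigma_m^2)

Because ``theta_m ~ N(theta_s, sigma_m)``, the MAP estimate over trials has

    E[theta_est]   = w * theta_s + (1 - w) * theta_p
    SD[theta_est]  = w * sigma_m

A strong (narrow) prior therefore both biases the response toward the prior
mean and *reduces* its trial-by-trial variability — the two behavioural
signatures this package quantifies.

The full model of a pursuit experiment has eight free parameters: one
likelihood SD per motion direction (five directions across the two blocks),
a multiplicative contrast factor ``c >= 1`` applied to sigma_m for
low-contrast stimuli, and one prior SD per block (narrow / wide).  It is fit
by bounded least squares to 24 condition summaries: 12 mean directions and
12 direction SDs (3 directions x 2 contrasts x 2 blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "BayesQuery",
    "MapPrediction",
    "ObserverParams",
    "ObserverFit",
    "DesignCell",
    "standard_design",
    "shrinkage_weight",
    "map_estimate",
    "predict_mean_sd",
    "predict_design",
    "fit_observer",
]

# Canonical ordering of the five motion directions, as offsets from the
# prior direction. sigma_m arrays follow this order everywhere.
DIRECTION_OFFSETS = (-120.0, -15.0, 0.0, 15.0, 120.0)


@dataclass(frozen=True)
class BayesQuery:
    """One evaluation of the observer: a measurement plus prior."""

    theta_m: float
    theta_p: float
    sigma_m: float
    sigma_p: float

    def __post_init__(self) -> None:
        if not (self.sigma_m > 0):
            raise ValueError(f"sigma_m must be positive, got {self.sigma_m}")
        if not (self.sigma_p > 0):
            raise ValueError(f"sigma_p must be positive, got {self.sigma_p}")


@dataclass(frozen=True)
class MapPrediction:
    """Trial-ensemble moments of the MAP estimate for one condition."""

    pred_mean: float
    pred_sd: float


@dataclass
class ObserverParams:
    """The eight free parameters of the observer model.

    ``sigma_m`` is ordered by :data:`DIRECTION_OFFSETS` (offsets from the
    prior direction). ``theta_p`` is fixed to the prior direction, not fit.
    """

    sigma_m: np.ndarray  # (5,) degrees, high-contrast likelihood SDs
    contrast_factor: float  # multiplier on sigma_m at low contrast
    sigma_p_narrow: float  # degrees
    sigma_p_wide: float  # degrees
    theta_p: float  # degrees, prior mean (fixed)

    def __post_init__(self) -> None:
        self.sigma_m = np.asarray(self.sigma_m, dtype=float)
        if self.sigma_m.shape != (len(DIRECTION_OFFSETS),):
            raise ValueError(
                f"sigma_m must have shape ({len(DIRECTION_OFFSETS)},), got {self.sigma_m.shape}"
            )
        if np.any(self.sigma_m <= 0) or self.sigma_p_narrow <= 0 or self.sigma_p_wide <= 0:
            raise ValueError("all SD parameters must be positive")
        if self.contrast_factor < 1:
            raise ValueError("contrast_factor must be >= 1")

    def sigma_m_for(self, offset: float, contrast: str) -> float:
        """Likelihood SD for a direction offset and contrast level."""
        offsets = np.asarray(DIRECTION_OFFSETS)
        idx = int(np.argmin(np.abs(offsets - offset)))
        if abs(offsets[idx] - offset) > 1e-6:
            raise ValueError(f"direction offset {offset} not in design {DIRECTION_OFFSETS}")
        s = float(self.sigma_m[idx])
        if contrast == "low":
            s *= self.contrast_factor
        elif contrast != "high":
            raise ValueError(f"contrast must be 'high' or 'low', got {contrast!r}")
        return s

    def sigma_p_for(self, block: str) -> float:
        if block == "narrow":
            return self.sigma_p_narrow
        if block == "wide":
            return self.sigma_p_wide
        raise ValueError(f"block must be 'narrow' or 'wide', got {block!r}")


@dataclass(frozen=True)
class DesignCell:
    block: str  # 'narrow' | 'wide'
    contrast: str  # 'high' | 'low'
    offset: float  # direction offset from prior, degrees


def standard_design() -> list[DesignCell]:
    """The 12 cells of the two-block design (3 directions x 2 contrasts x 2 blocks)."""
    cells = []
    for block, offs in (("narrow", (-15.0, 0.0, 15.0)), ("wide", (-120.0, 0.0, 120.0))):
        for contrast in ("high", "low"):
            for off in offs:
                cells.append(DesignCell(block, contrast, off))
    return cells


def shrinkage_weight(sigma_m: float, sigma_p: float) -> float:
    """Posterior weight on the sensory measurement, sigma_p^2/(sigma_p^2+sigma_m^2)."""
    sm2, sp2 = float(sigma_m) ** 2, float(sigma_p) ** 2
    return sp2 / (sp2 + sm2)


def map_estimate(query: BayesQuery) -> float:
    """Maximum a posteriori direction estimate for one measurement."""
    w = shrinkage_weight(query.sigma_m, query.sigma_p)
    return w * query.theta_m + (1.0 - w) * query.theta_p


def predict_mean_sd(
    theta_s: float, theta_p: float, sigma_m: float, sigma_p: float
) -> MapPrediction:
    """Mean and SD of the MAP estimate when theta_m ~ N(theta_s, sigma_m)."""
    if sigma_m <= 0 or sigma_p <= 0:
        raise ValueError("sigma_m and sigma_p must be positive")
    w = shrinkage_weight(sigma_m, sigma_p)
    return MapPrediction(
        pred_mean=w * theta_s + (1.0 - w) * theta_p,
        pred_sd=w * sigma_m,
    )


def predict_design(
    params: ObserverParams, design: list[DesignCell] | None = None
) -> "pd.DataFrame":
    """Model-predicted mean and SD of pursuit direction for every design cell.

    Returns a 12-row DataFrame with columns
    ``block, contrast, theta_s, pred_mean, pred_sd``.
    """
    import pandas as pd

    if design is None:
        design = standard_design()
    rows = []
    for cell in design:
        sm = params.sigma_m_for(cell.offset, cell.contrast)
        sp = params.sigma_p_for(cell.block)
        theta_s = params.theta_p + cell.offset
        pred = predict_mean_sd(theta_s, params.theta_p, sm, sp)
        rows.append(
            dict(
                block=cell.block,
                contrast=cell.contrast,
                theta_s=theta_s,
                pred_mean=pred.pred_mean,
                pred_sd=pred.pred_sd,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ObserverFit:
    """Result of fitting the eight-parameter observer model."""

    params: ObserverParams
    r2_mean: float  # variance explained in the 12 mean directions
    r2_sd: float  # variance explained in the 12 direction SDs
    sse: float
    n_starts: int
    seed: int
    at_bound: list[str] = field(default_factory=list)  # parameters pinned at a fit bound


# Fit bounds (degrees / dimensionless), log10-parameterised internally.
SIGMA_M_BOUNDS = (0.5, 90.0)
CONTRAST_BOUNDS = (1.0, 10.0)
SIGMA_P_BOUNDS = (1.0, 1.0e6)


def _unpack(x: np.ndarray, theta_p: float) -> ObserverParams:
    v = 10.0 ** np.asarray(x, dtype=float)
    return ObserverParams(
        sigma_m=v[:5],
        contrast_factor=float(v[5]),
        sigma_p_narrow=float(v[6]),
        sigma_p_wide=float(v[7]),
        theta_p=theta_p,
    )


def fit_observer(
    summaries: "pd.DataFrame",
    theta_p: float,
    n_starts: int = 20,
    seed: int = 0,
) -> ObserverFit:
    """Fit the 8-parameter observer model to 24 condition summaries.

    Parameters
    ----------
    summaries
        DataFrame with columns ``block, contrast, theta_s, mean_direction_deg,
        sd_direction_deg`` containing one row per design cell (12 rows).
    theta_p
        Prior direction in degrees; held fixed during the fit.
    n_starts
        Number of multi-start initial points drawn from a seeded Latin
        hypercube over the (log-scaled) bounded parameter box.
    seed
        Seed for the Latin hypercube.

    Returns
    -------
    ObserverFit with the best-of-starts parameters and the variance explained
    (R^2 = 1 - SSE/SST) computed separately over the 12 means and 12 SDs.
    """
    required = {"block", "contrast", "theta_s", "mean_direction_deg", "sd_direction_deg"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    if len(summaries) != 12:
        raise ValueError(f"expected 12 condition summaries, got {len(summaries)}")

    design = [
        DesignCell(r.block, r.contrast, float(r.theta_s) - theta_p)
        for r in summaries.itertuples()
    ]
    obs_mean = summaries["mean_direction_deg"].to_numpy(dtype=float)
    obs_sd = summaries["sd_direction_deg"].to_numpy(dtype=float)
    target = np.concatenate([obs_mean, obs_sd])

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(x, theta_p)
        pred = predict_design(p, design)
        return np.concatenate(
            [pred["pred_mean"].to_numpy() - obs_mean, pred["pred_sd"].to_numpy() - obs_sd]
        )

    lo = np.log10(
        [SIGMA_M_BOUNDS[0]] * 5 + [CONTRAST_BOUNDS[0], SIGMA_P_BOUNDS[0], SIGMA_P_BOUNDS[0]]
    )
    hi = np.log10(
        [SIGMA_M_BOUNDS[1]] * 5 + [CONTRAST_BOUNDS[1], SIGMA_P_BOUNDS[1], SIGMA_P_BOUNDS[1]]
    )
    sampler = qmc.LatinHypercube(d=8, seed=seed)
    starts = qmc.scale(sampler.random(n=n_starts), lo, hi)

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("observer fit failed from every start")

    params = _unpack(best.x, theta_p)
    pred = predict_design(params, design)
    pm = pred["pred_mean"].to_numpy()
    ps = pred["pred_sd"].to_numpy()

    def r2(obs: np.ndarray, prd: np.ndarray) -> float:
        sst = float(np.sum((obs - obs.mean()) ** 2))
        sse = float(np.sum((obs - prd) ** 2))
        return 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else np.nan)

    # Flag parameters pinned at a bound; a wide prior SD at its upper bound
    # is expected (a flat prior is not identifiable beyond "very wide").
    at_bound: list[str] = []
    names = [f"sigma_m[{i}]" for i in range(5)] + [
        "contrast_factor", "sigma_p_narrow", "sigma_p_wide",
    ]
    for name, xi, l, h in zip(names, best.x, lo, hi):
        if name == "sigma_p_wide" and xi >= h - 1e-9:
            continue
        if xi <= l + 1e-9 or xi >= h - 1e-9:
            at_bound.append(name)

    return ObserverFit(
        params=params,
        r2_mean=r2(obs_mean, pm),
        r2_sd=r2(obs_sd, ps),
        sse=float(np.sum((np.concatenate([pm, ps]) - target) ** 2)),
        n_starts=n_starts,
        seed=seed,
        at_bound=at_bound,
    )
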