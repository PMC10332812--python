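"""Growth rates and extracellular fluxes from culture time courses.

The model is exponential growth with first-order metabolite decay:

    dX/dt = mu * X                      X(t) = X0 * exp(mu t)
    dM/dt = -k * M + v * X

whose solution, written for fitting, is

    M exp(k t) = v X0 / (mu + k) * (exp((mu + k) t) - 1) + M0

so the extracellular flux v of a metabolite follows from the slope of a
robust linear regression of ``M exp(kt)`` on ``exp((mu+k)t) - 1``.  Growth
rate and the degradation rates come from robust linear fits of the log
series; degradation rates are only applied when significantly nonzero.
Negative v means consumption, positive v means release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GrowthFit",
    "DegradationRate",
    "FluxEstimate",
    "HUBER_TUNING",
    "fit_growth_rate",
    "estimate_evaporation",
    "estimate_degradation",
    "estimate_flux",
    "mad_outliers",
    "estimate_fluxes_from_tables",
]

#: Huber M-estimator tuning constant (95% efficiency at the normal model).
HUBER_TUNING = 1.345

#: nmol -> fmol
_NMOL_TO_FMOL = 1.0e6


def _robust_line(x: np.ndarray, y: np.ndarray):
    """Huber robust fit of y = a + b x; returns (params, bse, pvalues)."""
    X = sm.add_constant(np.asarray(x, dtype=float))
    res = sm.RLM(np.asarray(y, dtype=float), X, M=sm.robust.norms.HuberT(t=HUBER_TUNING)).fit()
    return res.params, res.bse, res.pvalues


@dataclass
class GrowthFit:
    mu: float  # 1/h
    x0: float  # cells
    mu_se: float
    x0_se: float
    n_points: int
    outliers: np.ndarray | None = None

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.x0 * np.exp(self.mu * np.asarray(t, dtype=float))


@dataclass
class DegradationRate:
    metabolite: str
    k: float  # 1/h, positive = decay (dM/dt = -k M + v X)
    k_se: float
    p_value: float
    used: bool

    @property
    def effective_k(self) -> float:
        return self.k if self.used else 0.0


@dataclass
class FluxEstimate:
    metabolite: str
    v: float  # fmol/cell/h; negative = consumption
    se: float
    n_points: int
    k_used: float = 0.0


def mad_outliers(values: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Flag points farther than ``threshold`` times the MAD from the median."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values - med) > threshold * mad


def fit_growth_rate(times: np.ndarray, counts: np.ndarray) -> GrowthFit:
    """Robust linear fit of ln(cell count) against time.

    The slope is the growth rate mu and the exponentiated intercept the
    cell count at time zero.  Requires at least three distinct time points
    and strictly positive counts.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.unique(times).size < 3:
        raise ValueError("growth fit requires >= 3 distinct time points")
    if np.any(counts <= 0):
        raise ValueError("cell counts must be positive for the log transform")
    params, bse, _ = _robust_line(times, np.log(counts))
    x0 = float(np.exp(params[0]))
    return GrowthFit(
        mu=float(params[1]),
        x0=x0,
        mu_se=float(bse[1]),
        x0_se=float(x0 * bse[0]),  # delta method
        n_points=times.size,
    )


def estimate_evaporation(times: np.ndarray, weights_g: np.ndarray, density_g_per_ml: float = 1.0):
    """Volume function mL(t) from cell-free dish weighings.

    Piecewise-linear interpolation of the medium mass, converted to volume
    at the stated density; weight increases beyond 0.1% are clamped to
    monotone non-increasing with a warning.  Extrapolates linearly with the
    edge slopes.
    """
    times = np.asarray(times, dtype=float)
    weights = np.asarray(weights_g, dtype=float).copy()
    if times.size < 2:
        raise ValueError("evaporation estimate requires >= 2 weighings")
    order = np.argsort(times)
    times, weights = times[order], weights[order]
    increases = np.diff(weights) > 1e-3 * np.abs(weights[:-1])
    if np.any(increases):
        warnings.warn("dish weights increase over time; clamping to monotone", stacklevel=2)
    weights = np.minimum.accumulate(weights)

    def volume(t):
        t = np.asarray(t, dtype=float)
        slope_lo = (weights[1] - weights[0]) / (times[1] - times[0])
        slope_hi = (weights[-1] - weights[-2]) / (times[-1] - times[-2])
        w = np.interp(t, times, weights)
        w = np.where(t < times[0], weights[0] + slope_lo * (t - times[0]), w)
        w = np.where(t > times[-1], weights[-1] + slope_hi * (t - times[-1]), w)
        return w / density_g_per_ml

    return volume


def estimate_degradation(
    times: np.ndarray,
    masses: np.ndarray,
    metabolite: str = "",
    alpha: float = 0.05,
) -> DegradationRate:
    """First-order degradation/accumulation rate from cell-free medium.

    Robust fit of ln(mass) against time in unconditioned medium; the slope
    b gives k = -b (so positive k is decay).  The rate is applied downstream
    only when the slope differs from zero by a t-test at level ``alpha``.
    """
    times = np.asarray(times, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if np.unique(times).size < 3:
        raise ValueError("degradation fit requires >= 3 distinct time points")
    if np.any(masses <= 0):
        raise ValueError("metabolite masses must be positive for the log transform")
    params, bse, _ = _robust_line(times, np.log(masses))
    slope, slope_se = float(params[1]), float(bse[1])
    dof = max(times.size - 2, 1)
    if abs(slope) < 1e-12 and slope_se < 1e-12:
        p = 1.0  # numerically flat series
    elif slope_se == 0:
        p = 0.0
    else:
        p = float(2 * stats.t.sf(abs(slope / slope_se), dof))
    return DegradationRate(
        metabolite=metabolite, k=-slope, k_se=slope_se, p_value=p, used=p < alpha
    )


def estimate_flux(
    times: np.ndarray,
    masses_nmol: np.ndarray,
    growth: GrowthFit,
    k: float = 0.0,
    metabolite: str = "",
) -> FluxEstimate:
    """Extracellular flux from a metabolite mass time course.

    Regresses ``M exp(kt)`` on ``exp((mu+k)t) - 1`` (robustly); the slope s
    yields ``v = s (mu + k) / X0``.  When mu + k vanishes the model
    degenerates to ``M exp(kt) = v X0 t + M0`` and the regressor becomes t.
    Masses in nmol give v in fmol/cell/h.
    """
    times = np.asarray(times, dtype=float)
    masses = np.asarray(masses_nmol, dtype=float)
    if np.unique(times).size < 2:
        raise ValueError("flux estimate requires >= 2 distinct time points")
    mu_k = growth.mu + k
    y = masses * np.exp(k * times)
    if abs(mu_k) < 1e-12:
        x = times  # analytic limit of (exp((mu+k)t)-1)/(mu+k)
        scale = 1.0 / growth.x0
    else:
        x = np.expm1(mu_k * times)
        scale = mu_k / growth.x0
    params, bse, _ = _robust_line(x, y)
    v = float(params[1]) * scale * _NMOL_TO_FMOL
    se = float(bse[1]) * abs(scale) * _NMOL_TO_FMOL
    return FluxEstimate(metabolite=metabolite, v=v, se=se, n_points=times.size, k_used=k)


def estimate_fluxes_from_tables(
    timecourse: pd.DataFrame,
    dish_weights: pd.DataFrame,
    unconditioned: pd.DataFrame | None = None,
    alpha: float = 0.05,
    count_analyte: str = "cells",
) -> pd.DataFrame:
    """Run the full extracellular-flux stage on tidy long-format tables.

    ``timecourse`` columns: condition, replicate, time_h, analyte, value.
    The ``cells`` analyte is the per-well cell count; every other analyte is
    a medium concentration in mM.  ``dish_weights`` columns: time_h,
    weight_g.  ``unconditioned`` (optional) has the same layout as
    ``timecourse`` for cell-free medium, used for degradation rates.

    Returns a tidy table of per-condition growth rates and fluxes.
    """
    volume = estimate_evaporation(
        dish_weights["time_h"].to_numpy(), dish_weights["weight_g"].to_numpy()
    )
    k_rates: dict[str, DegradationRate] = {}
    if unconditioned is not None:
        for met, grp in unconditioned.groupby("analyte"):
            if met == count_analyte:
                continue
            t = grp["time_h"].to_numpy()
            mass = grp["value"].to_numpy() * volume(t)  # mM * mL = umol? see below
            k_rates[met] = estimate_degradation(t, mass, met, alpha=alpha)

    rows = []
    for cond, cgrp in timecourse.groupby("condition"):
        cells = cgrp[cgrp["analyte"] == count_analyte]
        growth = fit_growth_rate(cells["time_h"].to_numpy(), cells["value"].to_numpy())
        rows.append(
            {
                "condition": cond,
                "quantity": "growth_rate",
                "metabolite": "",
                "value": growth.mu,
                "se": growth.mu_se,
                "unit": "1/h",
            }
        )
        for met, grp in cgrp[cgrp["analyte"] != count_analyte].groupby("analyte"):
            t = grp["time_h"].to_numpy()
            masses_nmol = grp["value"].to_numpy() * volume(t) * 1000.0  # mM*mL = umol -> nmol
            k = k_rates[met].effective_k if met in k_rates else 0.0
            est = estimate_flux(t, masses_nmol, growth, k=k, metabolite=met)
            rows.append(
                {
                    "condition": cond,
                    "quantity": "flux",
                    "metabolite": met,
                    "value": est.v,
                    "se": est.se,
                    "unit": "fmol/cell/h",
                }
            )
    return pd.DataFrame(rows)
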