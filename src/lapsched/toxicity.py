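"""Clinical toxicity frontier: maximum tolerated dose vs. treatment days.

Three clinically observed dose-limiting points — continuous dosing at
3,000 mg/day (5 days/cycle), a tolerated 2-day pulse at 5,250 mg/day, and a
single-day limit of 7,000 mg/day — define how the maximum tolerated daily
oral dose (MTD) falls with the number of treatment days per 5-day cycle.
Both a linear curve ``dose = a0 + a1 * days`` and an exponential curve
``dose = exp(g0 + g1 * days)`` (ordinary least squares on the log scale)
are fitted and compared by AIC under the Gaussian maximum-likelihood
convention that counts the error variance as a parameter (k = 3).  The
exponential curve wins decisively and is used to extrapolate daily dose
limits for 3- and 4-day schedules; at the observed 1/2/5-day designs the
clinical doses themselves are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "ToxicityPoint",
    "ToxicityFit",
    "fit_toxicity_models",
    "aic",
    "mtd_for_days",
    "schedule_doses",
    "DegenerateFitError",
]


class DegenerateFitError(ValueError):
    """Raised when a fit has (numerically) zero residual variance."""


class ToxicityPoint(NamedTuple):
    days: int  # treatment days per 5-day cycle
    max_daily_oral_mg: float


@dataclass(frozen=True)
class ToxicityFit:
    """OLS fit of dose (or log dose) on treatment days."""

    model_form: str  # "linear" | "exponential"
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    aic: float
    residuals: np.ndarray

    def predict_dose(self, days):
        days = np.asarray(days, dtype=float)
        eta = self.intercept + self.slope * days
        return np.exp(eta) if self.model_form == "exponential" else eta


def _validate_points(points: Sequence[ToxicityPoint]) -> tuple[np.ndarray, np.ndarray]:
    if len(points) < 3:
        raise ValueError("need at least 3 toxicity points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("toxicity points must span at least 2 distinct day counts")
    if np.any(y <= 0):
        raise ValueError("doses must be positive")
    if np.any((x < 1) | (x > 5)):
        raise ValueError("treatment days must lie in 1..5")
    return x, y


def _gaussian_ml_aic(residuals: np.ndarray, k: int = 3) -> float:
    n = residuals.size
    rss = float(residuals @ residuals)
    if rss <= 0 or not math.isfinite(rss):
        raise DegenerateFitError("zero-residual fit: Gaussian ML AIC diverges to -inf")
    return 2 * k + n * (math.log(2 * math.pi * rss / n) + 1.0)


def aic(fit: ToxicityFit) -> float:
    """Gaussian maximum-likelihood AIC with k = 3 (intercept, slope, variance)."""
    return _gaussian_ml_aic(fit.residuals)


def _ols_fit(x: np.ndarray, y: np.ndarray, form: str) -> ToxicityFit:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ToxicityFit(
        model_form=form,
        intercept=float(res.params[0]), slope=float(res.params[1]),
        se_intercept=float(res.bse[0]), se_slope=float(res.bse[1]),
        aic=_gaussian_ml_aic(np.asarray(res.resid)),
        residuals=np.asarray(res.resid),
    )


def fit_toxicity_models(points: Sequence[ToxicityPoint]) -> tuple[ToxicityFit, ToxicityFit]:
    """Fit the linear and exponential MTD curves; returns (linear, exponential)."""
    x, y = _validate_points(points)
    return _ols_fit(x, y, "linear"), _ols_fit(x, np.log(y), "exponential")


def mtd_for_days(fit: ToxicityFit, days: int) -> float:
    """Daily oral dose limit (mg) for ``days`` treatment days per cycle."""
    if not 1 <= days <= 5:
        raise ValueError("days must lie in 1..5")
    if fit.model_form != "exponential":
        raise ValueError("dose extrapolation uses the exponential fit")
    return float(fit.predict_dose(days))


def schedule_doses(fit: ToxicityFit, points: Sequence[ToxicityPoint]) -> dict[int, float]:
    """Daily dose limits for 1..5 treatment days per cycle.

    Observed clinical MTDs take precedence at their day counts; the fitted
    exponential curve fills in the unobserved designs.
    """
    observed = {int(p[0]): float(p[1]) for p in points}
    return {k: observed.get(k, mtd_for_days(fit, k)) for k in range(1, 6)}
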