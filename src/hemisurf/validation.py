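"""Model-quality metrics: calculated-vs-actual regression and diagnostics.

When model-calculated resection parameters are compared with actual
(measured) ones, an ordinary least-squares line

    calculated = a + b * actual

summarizes the agreement.  Reported alongside the coefficients:

* S — residual standard deviation, sqrt(SSR / (n - 2));
* A-bar — average approximation error, the mean absolute relative
  deviation in percent, (100/n) * sum |e_i / y_i| over nonzero y_i
  (zeros are excluded and counted);
* R^2, the F statistic for regression significance, and t statistics
  for both coefficients.

A model is conventionally rated "good" when A-bar does not exceed 10%
(the threshold is configurable).  Residual diagnostics (mean, lag-1
autocorrelation, a runs count of residual signs) support the usual
visual randomness check of the residual plot.

The OLS fit itself is delegated to statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .errors import HemisurfError

__all__ = [
    "PairedObservations",
    "RegressionSummary",
    "ResidualDiagnostics",
    "AdequacyVerdicts",
    "fit_regression",
    "residual_diagnostics",
    "adequacy_tests",
    "rate_model",
]

GOOD_MODEL_THRESHOLD_PCT = 10.0


@dataclass(frozen=True)
class PairedObservations:
    """Actual (measured) vs calculated (model-predicted) value pairs."""

    actual: np.ndarray
    calculated: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.actual, dtype=float)
        c = np.asarray(self.calculated, dtype=float)
        if a.ndim != 1 or c.ndim != 1 or len(a) != len(c):
            raise HemisurfError("actual and calculated must be 1-D, equal length")
        if len(a) < 3:
            raise HemisurfError("need at least 3 pairs")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(c))):
            raise HemisurfError("non-finite observation")
        object.__setattr__(self, "actual", a)
        object.__setattr__(self, "calculated", c)

    def __len__(self) -> int:
        return len(self.actual)


@dataclass(frozen=True)
class RegressionSummary:
    intercept: float
    slope: float
    residual_sd: float  # S = sqrt(SSR / (n - 2))
    approx_error_pct: float  # A-bar, %
    n_excluded_zero: int  # pairs dropped from A-bar because y == 0
    r_squared: float
    f_statistic: float
    t_statistics: tuple  # (t_intercept, t_slope)
    residuals: np.ndarray
    fitted: np.ndarray
    x: np.ndarray
    y: np.ndarray

    @property
    def nobs(self) -> int:
        return len(self.residuals)


def fit_regression(obs: PairedObservations) -> RegressionSummary:
    """OLS of calculated on actual, with S, A-bar, R^2, F and t statistics."""
    x, y = obs.actual, obs.calculated
    if np.ptp(x) == 0:
        raise HemisurfError("actual values are constant; regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    e = np.asarray(res.resid)
    n = len(x)
    s = float(np.sqrt(res.ssr / (n - 2)))
    nz = y != 0
    n_excluded = int(np.sum(~nz))
    if n_excluded == n:
        raise HemisurfError("all calculated values are zero; A-bar undefined")
    abar = float(100.0 * np.mean(np.abs(e[nz] / y[nz])))
    return RegressionSummary(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        residual_sd=s,
        approx_error_pct=abar,
        n_excluded_zero=n_excluded,
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        t_statistics=(float(res.tvalues[0]), float(res.tvalues[1])),
        residuals=e,
        fitted=np.asarray(res.fittedvalues),
        x=x,
        y=y,
    )


@dataclass(frozen=True)
class ResidualDiagnostics:
    residuals: np.ndarray
    mean: float
    lag1_autocorr: float
    runs: int  # number of sign runs among nonzero residuals
    runs_expected: float  # n/2 + 1 under randomness
    plot_x: np.ndarray  # fitted values, for the residual plot
    plot_y: np.ndarray  # residuals


def residual_diagnostics(summary: RegressionSummary) -> ResidualDiagnostics:
    """Mean, lag-1 autocorrelation and a runs count of the residual signs."""
    e = summary.residuals
    mean = float(e.mean())
    de = e - mean
    denom = float(np.sum(de * de))
    lag1 = float(np.sum(de[:-1] * de[1:]) / denom) if denom > 0 else 0.0
    scale = float(np.max(np.abs(e))) if len(e) else 0.0
    nonzero = np.abs(e) > 1e-12 * max(scale, 1.0)  # exact fits leave fp dust
    signs = np.sign(e[nonzero])
    runs = int(1 + np.sum(signs[:-1] != signs[1:])) if len(signs) else 0
    return ResidualDiagnostics(
        residuals=e,
        mean=mean,
        lag1_autocorr=lag1,
        runs=runs,
        runs_expected=len(signs) / 2.0 + 1.0,
        plot_x=summary.fitted,
        plot_y=e,
    )


@dataclass(frozen=True)
class AdequacyVerdicts:
    f_statistic: float
    f_pvalue: float
    f_significant: bool
    t_intercept: float
    t_intercept_pvalue: float
    t_intercept_significant: bool
    t_slope: float
    t_slope_pvalue: float
    t_slope_significant: bool
    alpha: float


def adequacy_tests(summary: RegressionSummary, alpha: float = 0.05) -> AdequacyVerdicts:
    """F test for regression significance and t tests per coefficient."""
    if not 0.0 < alpha < 1.0:
        raise HemisurfError("alpha must lie in (0, 1)")
    n = summary.nobs
    df_resid = n - 2
    if df_resid < 1:
        raise HemisurfError("too few observations for adequacy tests")
    f_p = float(f_dist.sf(summary.f_statistic, 1, df_resid))
    t_int, t_slope = summary.t_statistics
    t_int_p = float(2 * t_dist.sf(abs(t_int), df_resid))
    t_slope_p = float(2 * t_dist.sf(abs(t_slope), df_resid))
    return AdequacyVerdicts(
        f_statistic=summary.f_statistic,
        f_pvalue=f_p,
        f_significant=f_p < alpha,
        t_intercept=t_int,
        t_intercept_pvalue=t_int_p,
        t_intercept_significant=t_int_p < alpha,
        t_slope=t_slope,
        t_slope_pvalue=t_slope_p,
        t_slope_significant=t_slope_p < alpha,
        alpha=alpha,
    )


def rate_model(approx_error_pct: float,
               threshold_pct: float = GOOD_MODEL_THRESHOLD_PCT) -> str:
    """'good' iff the average approximation error does not exceed the threshold."""
    return "good" if approx_error_pct <= threshold_pct else "inadequate"
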