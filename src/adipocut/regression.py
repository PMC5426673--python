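"""Sex-stratified simple linear regression with AIC, SEE and log-scale summaries.

The regression engine fits %FM (or ln VAT) on a single anthropometric index
by closed-form ordinary least squares and reports the quantities the
downstream model comparison and cut-point derivation consume: slope,
intercept, residual sum of squares, standard error of the estimate
SEE = sqrt(RSS / (n - 2)), adjusted R², and an AIC in the Gaussian
maximum-likelihood profile form

    AIC = n * ln(RSS / n) + 2k,        k = 3 (slope, intercept, residual variance).

Absolute AIC values are defined only up to an additive constant shared by
every candidate fitted to the same data, so only AIC *differences* within a
stratum are meaningful — which is all the comparison layer uses.

Log-normal outcomes (VAT mass) are summarised multiplicatively: a geometric
mean together with a "×/÷ factor SD" exp(SD of ln values), and the SEE of a
ln-scale fit is reportable as the factor exp(SEE).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    PerfectFitError,
)
from .indices import SubjectRecord

#: Number of estimated parameters in a simple regression with Gaussian errors.
AIC_N_PARAMS = 3

#: Relative tolerance below which RSS is treated as an exact fit.
_RSS_REL_TOL = 1e-12


@dataclass(frozen=True)
class FitResult:
    """One simple-regression fit for a (predictor, outcome, sex) stratum."""

    predictor: str
    outcome: str  # "fat_pct" or "log_vat"
    sex: str
    n: int
    slope: float
    intercept: float
    rss: float
    see: float
    adj_r2: float
    aic: float

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x

    @property
    def df(self) -> int:
        """Residual degrees of freedom, n - 2."""
        return self.n - 2

    @property
    def see_factor(self) -> float:
        """SEE expressed as a multiplicative ×/÷ factor (meaningful for ln-scale fits)."""
        return math.exp(self.see)


@dataclass(frozen=True)
class GeometricSummary:
    """Geometric mean with multiplicative ×/÷ factor SD of a positive variable."""

    geo_mean: float
    factor_sd: float
    n: int


def exclude_undetectable_vat(records: Sequence[SubjectRecord]) -> tuple[list[SubjectRecord], int]:
    """Drop subjects whose VAT was recorded as 0 g (undetectable).

    ln VAT is undefined at zero and zeros produce badly behaved residuals,
    so VAT models are fitted on detectable-VAT subjects only. %FM analyses
    never apply this filter.

    Returns the retained records and the number excluded.
    """
    retained = [r for r in records if r.vat_g > 0]
    return retained, len(records) - len(retained)


def compute_aic(n: int, rss: float, n_params: int = AIC_N_PARAMS) -> float:
    """Gaussian profile-likelihood AIC, n·ln(RSS/n) + 2k.

    Defined up to an additive constant common to all candidates fitted to
    the same n observations; RSS = 0 is rejected rather than returned as -inf.
    """
    if rss <= 0:
        raise PerfectFitError("AIC undefined for a zero residual sum of squares")
    return n * math.log(rss / n) + 2 * n_params


def fit_ols(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    *,
    predictor: str = "x",
    outcome: str = "y",
    sex: str = "M",
) -> FitResult:
    """Fit y = a + b·x by closed-form least squares.

    Uses the mean-centred normal equations b = Sxy/Sxx, a = ȳ − b·x̄;
    SEE = sqrt(RSS/(n−2)); adjusted R² = 1 − (1−R²)(n−1)/(n−2).

    Raises
    ------
    InsufficientDataError
        fewer than 4 observations or mismatched lengths.
    DegenerateDesignError
        x has zero variance.
    PerfectFitError
        residuals are numerically zero (SEE and AIC undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need at least 4 observations, got {n}")
    xbar = x.mean()
    ybar = y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        raise DegenerateDesignError(f"predictor {predictor!r} is constant; slope undefined")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))

    slope = sxy / sxx
    intercept = ybar - slope * xbar
    rss = float(np.sum((y - intercept - slope * x) ** 2))
    if syy == 0 or rss <= _RSS_REL_TOL * syy:
        raise PerfectFitError("residual sum of squares is numerically zero; SEE/AIC undefined")

    r2 = 1.0 - rss / syy
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    see = math.sqrt(rss / (n - 2))
    return FitResult(
        predictor=predictor,
        outcome=outcome,
        sex=sex,
        n=n,
        slope=slope,
        intercept=intercept,
        rss=rss,
        see=see,
        adj_r2=adj_r2,
        aic=compute_aic(n, rss),
    )


def see_ci_factor(df: int) -> float:
    """Symmetric ×/÷ 95% confidence factor for an SEE with ``df`` degrees of freedom.

    The residual variance follows SEE²·χ²_df/df in sampling, giving
    asymmetric bounds SEE·sqrt(df/χ²_{0.975,df}) and SEE·sqrt(df/χ²_{0.025,df});
    the single reported factor is the geometric mean of the up and down
    ratios, (χ²_{0.975,df}/χ²_{0.025,df})^{1/4}. At df = 39 it is 1.25, and
    it tends to 1 as df grows.
    """
    if df < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got {df}")
    lo, hi = see_ci_bounds(1.0, df)
    return math.sqrt((hi / 1.0) * (1.0 / lo))


def see_ci_bounds(see: float, df: int) -> tuple[float, float]:
    """Raw (lower, upper) 95% confidence bounds for an SEE, from the χ² distribution."""
    if df < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got {df}")
    if see <= 0:
        raise DomainError("see must be strictly positive")
    chi2_hi = stats.chi2.ppf(0.975, df)
    chi2_lo = stats.chi2.ppf(0.025, df)
    return see * math.sqrt(df / chi2_hi), see * math.sqrt(df / chi2_lo)


def geometric_summary(values: Iterable[float]) -> GeometricSummary:
    """Geometric mean exp(mean ln v) and ×/÷ factor SD exp(sample SD of ln v).

    All values must be strictly positive; undetectable (zero) VAT must be
    excluded by the caller first.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 positive values for a geometric summary")
    if np.any(arr <= 0):
        raise DomainError("geometric summary requires strictly positive values")
    logs = np.log(arr)
    return GeometricSummary(
        geo_mean=float(np.exp(logs.mean())),
        factor_sd=float(np.exp(logs.std(ddof=1))),
        n=int(arr.size),
    )


def with_metadata(fit: FitResult, **kwargs) -> FitResult:
    """Return a copy of a fit with replaced labelling fields."""
    return replace(fit, **kwargs)
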