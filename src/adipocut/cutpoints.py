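"""Probability-based obesity cut-points from a regression fit and its error.

Given a fitted prediction equation  outcome = a + b·index  with standard
error of the estimate SEE and residual degrees of freedom n − 2, the
cut-point is the index value at which an individual has probability ≥ p
(default 0.75, odds 3:1) of truly exceeding an obesity threshold. The chain:

1.  t* = the t-quantile with P(T ≤ t*) = p at n − 2 degrees of freedom;
2.  SEE is inflated for small-sample prediction-equation uncertainty by
    sqrt(1 + 1/n + 1/(n − 3));
3.  required predicted value = threshold + t*·SEE_adjusted;
4.  cut-point = (required predicted − a) / b, valid for b > 0.

For %FM the thresholds are fixed (25% men, 35% women). For VAT mass, which
has no established threshold, visceral obesity is defined distributionally:
the highest third of the detectable-VAT subjects, with the tertile boundary
taken on the gram scale and the whole derivation carried out on the natural
log scale the VAT regression uses.

``paper_mode`` replicates a hand calculation that rounds the t-value to 3
decimals and the adjusted SEE and required predicted value to 1 decimal
between steps; the default keeps full precision throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientDataError
from .regression import FitResult


@dataclass(frozen=True)
class CutpointResult:
    """Full audit trail of one cut-point derivation.

    ``threshold`` and the see/predicted fields are on the fit's outcome
    scale (percent fat, or ln grams for ln-VAT fits); ``cutpoint`` is in
    predictor units.
    """

    predictor: str
    outcome: str
    sex: str
    threshold: float
    probability: float
    df: int
    t_value: float
    see_raw: float
    see_adjusted: float
    required_predicted: float
    cutpoint: float
    paper_mode: bool


@dataclass(frozen=True)
class VatObesityDefinition:
    """Distributional definition of visceral obesity for one sex.

    ``tertile_boundary`` is the empirical 2/3 quantile (grams) of
    detectable-VAT subjects; the obese group is strictly above it.
    """

    sex: str
    tertile_boundary: float
    source_n: int


def t_quantile(p: float, df: int) -> float:
    """The t value with lower-tail area p at ``df`` degrees of freedom.

    t_quantile(0.75, 39) = 0.681 to 3 decimals; p = 0.5 gives 0 by symmetry.
    """
    if not 0 < p < 1:
        raise DomainError(f"probability must lie in (0, 1), got {p}")
    if df < 1:
        raise DomainError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf(p, df))


def inflate_see(see_raw: float, n: int, *, literal_factor: bool = False) -> float:
    """Adjust the SEE upward for prediction-equation sampling variability.

    The default multiplies by sqrt(1 + 1/n + 1/(n − 3)), the square-root
    form of the small-sample inflation (at n = 41 it takes 4.1 to 4.2).
    ``literal_factor=True`` applies the plain factor (1 + 1/n + 1/(n − 3))
    instead, which inflates roughly twice as much (4.1 to 4.3 at n = 41);
    the two conventions are discussed in the methods documentation.
    """
    if see_raw <= 0:
        raise DomainError(f"see_raw must be strictly positive, got {see_raw}")
    if n <= 3:
        raise DomainError(f"need n > 3 for the inflation factor, got {n}")
    factor = 1.0 + 1.0 / n + 1.0 / (n - 3)
    return see_raw * (factor if literal_factor else math.sqrt(factor))


def required_predicted(threshold: float, t_value: float, see_adjusted: float) -> float:
    """Predicted value at which P(true outcome > threshold) reaches the target.

    Inverts t = (predicted − threshold)/SEE: threshold + t·SEE_adjusted.
    """
    if see_adjusted <= 0:
        raise DomainError(f"see_adjusted must be strictly positive, got {see_adjusted}")
    return threshold + t_value * see_adjusted


def invert_regression(fit: FitResult, required: float) -> float:
    """Solve the prediction equation for the index: (required − intercept)/slope.

    Only defined for positively associated predictors (slope > 0), so that
    index ≥ cut-point implies predicted outcome ≥ required value.
    """
    if fit.slope <= 0:
        raise DomainError(
            f"cut-point derivation requires a positive slope, got {fit.slope} for {fit.predictor}"
        )
    return (required - fit.intercept) / fit.slope


def derive_cutpoint(
    fit: FitResult,
    threshold: float,
    p: float = 0.75,
    *,
    paper_mode: bool = False,
    literal_factor: bool = False,
) -> CutpointResult:
    """Chain t-quantile → SEE inflation → required predicted value → inversion.

    ``threshold`` must be on the fit's outcome scale (ln grams for ln-VAT
    fits). ``paper_mode`` rounds the t value to 3 decimals and the adjusted
    SEE and required predicted value to 1 decimal between steps, mirroring
    a desk calculation; otherwise full precision is kept.
    """
    t = t_quantile(p, fit.df)
    see_adj = inflate_see(fit.see, fit.n, literal_factor=literal_factor)
    if paper_mode:
        t = round(t, 3)
        see_adj = round(see_adj, 1)
    required = required_predicted(threshold, t, see_adj)
    if paper_mode:
        required = round(required, 1)
    cut = invert_regression(fit, required)
    return CutpointResult(
        predictor=fit.predictor,
        outcome=fit.outcome,
        sex=fit.sex,
        threshold=threshold,
        probability=p,
        df=fit.df,
        t_value=t,
        see_raw=fit.see,
        see_adjusted=see_adj,
        required_predicted=required,
        cutpoint=cut,
        paper_mode=paper_mode,
    )


def vat_tertile_threshold(vat_values: Sequence[float], sex: str) -> VatObesityDefinition:
    """Empirical 2/3 quantile (grams) of detectable VAT, defining the obese third.

    Uses the linear-interpolation empirical quantile; the obese group is
    the values strictly above the boundary. All-equal inputs are rejected
    (the tertile split is degenerate).
    """
    arr = np.asarray(list(vat_values), dtype=float)
    if arr.size < 3:
        raise InsufficientDataError(f"need at least 3 detectable-VAT subjects, got {arr.size}")
    if np.any(arr <= 0):
        raise DomainError("undetectable (zero) VAT must be excluded before tertile computation")
    boundary = float(np.quantile(arr, 2.0 / 3.0))
    if not np.any(arr > boundary):
        raise DomainError("degenerate tertiles: no subject strictly above the boundary")
    return VatObesityDefinition(sex=sex, tertile_boundary=boundary, source_n=int(arr.size))


def derive_vat_cutpoint(
    fit: FitResult,
    tertile: VatObesityDefinition,
    p: float = 0.75,
    *,
    paper_mode: bool = False,
    literal_factor: bool = False,
) -> CutpointResult:
    """Cut-point for membership of the obese VAT third, on the ln-gram scale.

    The tertile boundary (grams) becomes threshold ln(boundary) on the
    ln-VAT fit's outcome scale; the returned cut-point is in predictor units.
    """
    if fit.outcome != "log_vat":
        raise DomainError(f"expected a log_vat fit, got outcome {fit.outcome!r}")
    if fit.sex != tertile.sex:
        raise DomainError(f"fit sex {fit.sex!r} does not match tertile sex {tertile.sex!r}")
    return derive_cutpoint(
        fit,
        math.log(tertile.tertile_boundary),
        p,
        paper_mode=paper_mode,
        literal_factor=literal_factor,
    )
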