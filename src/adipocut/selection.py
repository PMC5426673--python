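"""AIC-based ranking of the five candidate predictors within a stratum.

Each candidate's AIC is referenced to the stratum minimum and the
difference mapped onto a qualitative support scale:

    Δ = 0            best
    0 < Δ < 2        essentially equivalent
    2 ≤ Δ ≤ 7        plausible alternative
    7 < Δ ≤ 14       weak support
    Δ > 14           unsupported

The printed scale's endpoints overlap ("<2", "2–7", "7–14", ">14"); the
half-open convention above resolves the overlap and is exercised by unit
tests at each boundary. Ties for the minimum are broken by the canonical
predictor order (BMI, WC, WHR, WHtR, WHT.5R): the first is labelled best,
the rest sit at Δ = 0 as equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import DomainError
from .indices import PREDICTORS
from .regression import FitResult, see_ci_bounds, see_ci_factor

LABELS = ("best", "equivalent", "plausible", "weak", "unsupported")


def label_for_delta(delta: float, is_best: bool = False) -> str:
    """Map an AIC difference (≥ 0) onto the qualitative support scale."""
    if delta < 0:
        raise DomainError(f"AIC difference must be non-negative, got {delta}")
    if is_best:
        return "best"
    if delta < 2:
        return "equivalent"
    if delta <= 7:
        return "plausible"
    if delta <= 14:
        return "weak"
    return "unsupported"


def format_delta(delta: float) -> str:
    """Table-style display: '0' for the best model, '<1' below one, else an integer."""
    if delta == 0:
        return "0"
    if delta < 1:
        return "<1"
    return str(round(delta))


@dataclass(frozen=True)
class ComparisonRow:
    predictor: str
    aic_delta: float
    label: str
    adj_r2: float
    see: float
    see_ci: tuple[float, float]


@dataclass(frozen=True)
class ComparisonTable:
    """Per-stratum model comparison; rows follow the canonical predictor order."""

    sex: str
    outcome: str
    n: int
    rows: tuple[ComparisonRow, ...]
    see_ci_factor: float

    @property
    def best_predictor(self) -> str:
        return next(r.predictor for r in self.rows if r.label == "best")

    def row(self, predictor: str) -> ComparisonRow:
        for r in self.rows:
            if r.predictor == predictor:
                return r
        raise DomainError(f"no row for predictor {predictor!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view mirroring the published comparison-table layout."""
        return pd.DataFrame(
            {
                "predictor": [r.predictor for r in self.rows],
                "aic_delta": [r.aic_delta for r in self.rows],
                "aic_delta_display": [format_delta(r.aic_delta) for r in self.rows],
                "inference": [r.label for r in self.rows],
                "adj_r2": [r.adj_r2 for r in self.rows],
                "see": [r.see for r in self.rows],
                "see_ci_low": [r.see_ci[0] for r in self.rows],
                "see_ci_high": [r.see_ci[1] for r in self.rows],
            }
        )


def compare_models(fits: Sequence[FitResult]) -> ComparisonTable:
    """Rank one stratum's five candidate fits by AIC and attach support labels.

    All fits must share sex, outcome and n (AIC comparison across different
    underlying data is invalid) and cover each canonical predictor exactly
    once.
    """
    if len(fits) != len(PREDICTORS):
        raise DomainError(f"expected {len(PREDICTORS)} fits, got {len(fits)}")
    sexes = {f.sex for f in fits}
    outcomes = {f.outcome for f in fits}
    ns = {f.n for f in fits}
    if len(sexes) != 1 or len(outcomes) != 1 or len(ns) != 1:
        raise DomainError(
            "fits are not comparable: they must share sex, outcome and n "
            f"(got sexes={sorted(sexes)}, outcomes={sorted(outcomes)}, n={sorted(ns)})"
        )
    by_predictor = {f.predictor: f for f in fits}
    if set(by_predictor) != set(PREDICTORS):
        raise DomainError(f"fits must cover predictors {PREDICTORS}, got {sorted(by_predictor)}")

    ordered = [by_predictor[p] for p in PREDICTORS]
    min_aic = min(f.aic for f in ordered)
    best_idx = next(i for i, f in enumerate(ordered) if f.aic == min_aic)

    n = ordered[0].n
    rows = tuple(
        ComparisonRow(
            predictor=f.predictor,
            aic_delta=f.aic - min_aic,
            label=label_for_delta(f.aic - min_aic, is_best=(i == best_idx)),
            adj_r2=f.adj_r2,
            see=f.see,
            see_ci=see_ci_bounds(f.see, f.n - 2),
        )
        for i, f in enumerate(ordered)
    )
    return ComparisonTable(
        sex=ordered[0].sex,
        outcome=ordered[0].outcome,
        n=n,
        rows=rows,
        see_ci_factor=see_ci_factor(n - 2),
    )
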