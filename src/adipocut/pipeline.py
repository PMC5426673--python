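"""End-to-end analysis: cohort → indices → fits → comparison → cut-points.

The report mirrors the three tables a sex-stratified adiposity-prediction
study presents — descriptives, %FM model comparison, ln-VAT model
comparison — plus the derived cut-points for the best predictor in each
stratum. Subjects with undetectable (0 g) VAT are excluded from the VAT
models only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import split_by_sex
from .cutpoints import (
    CutpointResult,
    VatObesityDefinition,
    derive_cutpoint,
    derive_vat_cutpoint,
    vat_tertile_threshold,
)
from .errors import InsufficientDataError
from .indices import (
    FM_OBESITY_THRESHOLD,
    PREDICTORS,
    SEXES,
    SubjectRecord,
    classify_bmi_obese,
    classify_fm_obese,
    compute_indices,
)
from .regression import (
    FitResult,
    exclude_undetectable_vat,
    fit_ols,
    geometric_summary,
)
from .selection import ComparisonTable, compare_models

OUTCOMES = ("fat_pct", "log_vat")


def indices_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-subject table of raw measurements plus the five derived indices."""
    rows = []
    for r in records:
        ix = compute_indices(r)
        rows.append(
            {
                "id": r.id,
                "sex": r.sex,
                "age_years": r.age,
                "mass_kg": r.mass,
                "height_cm": r.height * 100.0,
                "waist_cm": r.wc,
                "hip_cm": r.hc,
                "fat_pct": r.fat_pct,
                "vat_g": r.vat_g,
                "BMI": ix.bmi,
                "WC": ix.wc_cm,
                "WHR": ix.whr,
                "WHtR": ix.whtr,
                "WHT.5R": ix.wht5r,
            }
        )
    return pd.DataFrame(rows)


def fit_stratum(records: Sequence[SubjectRecord], outcome: str, sex: str) -> list[FitResult]:
    """Fit all five candidate predictors for one (outcome, sex) stratum.

    For ``log_vat`` the undetectable-VAT exclusion is applied first and the
    outcome is ln(VAT grams).
    """
    stratum = [r for r in records if r.sex == sex]
    if outcome == "log_vat":
        stratum, _ = exclude_undetectable_vat(stratum)
        y = np.log([r.vat_g for r in stratum])
    elif outcome == "fat_pct":
        y = np.asarray([r.fat_pct for r in stratum])
    else:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    if len(stratum) < 4:
        raise InsufficientDataError(
            f"stratum sex={sex} outcome={outcome} has only {len(stratum)} usable subjects"
        )
    index_sets = [compute_indices(r) for r in stratum]
    return [
        fit_ols(
            [ix.value(p) for ix in index_sets],
            y,
            predictor=p,
            outcome=outcome,
            sex=sex,
        )
        for p in PREDICTORS
    ]


def descriptives(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Sample-characteristics table: mean (SD) per sex, geometric mean ×/÷ for VAT."""
    frame = indices_frame(records)
    rows = []
    for sex in SEXES:
        sub = frame[frame.sex == sex]
        if sub.empty:
            continue
        row: dict[str, object] = {"sex": sex, "n": len(sub)}
        for col in ("age_years", "BMI", "WC", "WHR", "WHtR", "WHT.5R", "fat_pct"):
            row[f"{col}_mean"] = sub[col].mean()
            row[f"{col}_sd"] = sub[col].std(ddof=1)
        row["bmi_obese_n"] = int(
            sum(classify_bmi_obese(compute_indices(r)) for r in records if r.sex == sex)
        )
        row["fm_obese_n"] = int(
            sum(classify_fm_obese(r.sex, r.fat_pct) for r in records if r.sex == sex)
        )
        detectable = sub[sub.vat_g > 0].vat_g
        if len(detectable) >= 2:
            gs = geometric_summary(detectable)
            row["vat_geo_mean"] = gs.geo_mean
            row["vat_factor_sd"] = gs.factor_sd
            row["vat_detectable_n"] = gs.n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Report:
    """Everything the full pipeline produces for one cohort."""

    descriptives: pd.DataFrame
    comparisons: dict[tuple[str, str], ComparisonTable]  # (sex, outcome) -> table
    cutpoints: dict[tuple[str, str], CutpointResult]
    vat_definitions: dict[str, VatObesityDefinition]
    n_vat_excluded: dict[str, int]


def run_report(
    records: Sequence[SubjectRecord],
    probability: float = 0.75,
    *,
    paper_mode: bool = False,
) -> Report:
    """Run the full analysis on a cohort.

    For each sex and outcome, fits the five candidates, ranks them by AIC,
    and derives the obesity cut-point for the best-supported predictor:
    the fixed %FM thresholds (25% men / 35% women) for the fat outcome, and
    the sex-specific top-tertile VAT boundary (ln scale) for the VAT outcome.
    """
    by_sex = split_by_sex(records)
    comparisons: dict[tuple[str, str], ComparisonTable] = {}
    cutpoints: dict[tuple[str, str], CutpointResult] = {}
    vat_definitions: dict[str, VatObesityDefinition] = {}
    n_vat_excluded: dict[str, int] = {}

    for sex in SEXES:
        if not by_sex[sex]:
            continue
        detectable, n_excluded = exclude_undetectable_vat(by_sex[sex])
        n_vat_excluded[sex] = n_excluded

        for outcome in OUTCOMES:
            fits = fit_stratum(records, outcome, sex)
            table = compare_models(fits)
            comparisons[(sex, outcome)] = table
            best_fit = next(f for f in fits if f.predictor == table.best_predictor)
            if outcome == "fat_pct":
                cutpoints[(sex, outcome)] = derive_cutpoint(
                    best_fit, FM_OBESITY_THRESHOLD[sex], probability, paper_mode=paper_mode
                )
            else:
                tertile = vat_tertile_threshold([r.vat_g for r in detectable], sex)
                vat_definitions[sex] = tertile
                cutpoints[(sex, outcome)] = derive_vat_cutpoint(
                    best_fit, tertile, probability, paper_mode=paper_mode
                )

    return Report(
        descriptives=descriptives(records),
        comparisons=comparisons,
        cutpoints=cutpoints,
        vat_definitions=vat_definitions,
        n_vat_excluded=n_vat_excluded,
    )


def write_report(report: Report, outdir: str | Path) -> None:
    """Emit the report as CSVs (descriptives, comparisons) plus a cut-point JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.descriptives.to_csv(outdir / "descriptives.csv", index=False)
    for (sex, outcome), table in report.comparisons.items():
        table.to_frame().to_csv(outdir / f"comparison_{outcome}_{sex}.csv", index=False)
    payload = {
        "cutpoints": {
            f"{outcome}_{sex}": dataclasses.asdict(cp)
            for (sex, outcome), cp in report.cutpoints.items()
        },
        "vat_obesity_definitions": {
            sex: dataclasses.asdict(d) for sex, d in report.vat_definitions.items()
        },
        "n_vat_excluded": report.n_vat_excluded,
    }
    with open(outdir / "cutpoints.json", "w") as fh:
        json.dump(payload, fh, indent=2)


def simulate_cutpoint_distribution(
    make_config,
    n_replicates: int,
    base_seed: int,
    *,
    sex: str = "M",
    outcome: str = "fat_pct",
    predictor: str = "WHtR",
    probability: float = 0.75,
) -> np.ndarray:
    """Cut-points for one stratum across many independently seeded cohorts.

    ``make_config(seed)`` must return a ``SyntheticConfig``; each replicate
    generates a cohort, fits the requested predictor, and derives the
    cut-point at full precision. Returns the array of cut-points (useful
    for medians and sampling intervals).
    """
    from .cohort import generate_cohort  # local import to avoid cycle

    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    out = np.empty(n_replicates)
    for i, seed in enumerate(seeds):
        records = generate_cohort(make_config(int(seed)))
        fits = fit_stratum(records, outcome, sex)
        fit = next(f for f in fits if f.predictor == predictor)
        if outcome == "fat_pct":
            cp = derive_cutpoint(fit, FM_OBESITY_THRESHOLD[sex], probability)
        else:
            detectable, _ = exclude_undetectable_vat([r for r in records if r.sex == sex])
            tertile = vat_tertile_threshold([r.vat_g for r in detectable], sex)
            cp = derive_vat_cutpoint(fit, tertile, probability)
        out[i] = cp.cutpoint
    return out
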