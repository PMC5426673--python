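"""Anthropometric indices and binary obesity classifications.

Five candidate predictors of adiposity are computed from raw measurements:

- **BMI** — body mass index, mass / height² (kg/m²),
- **WC** — waist circumference (cm), carried through unchanged,
- **WHR** — waist-to-hip ratio, WC / HC (dimensionless),
- **WHtR** — waist-to-height ratio, WC / height in identical length units,
- **WHT.5R** — allometrically scaled waist, WC(m) / √height(m).

Internal canonical units are metres for height and centimetres for the
girths; conversions happen exactly once, at the CSV boundary (see
:mod:`adipocut.cohort`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InputDataError

SEXES = ("M", "F")

#: Canonical predictor order used everywhere a deterministic ordering matters.
PREDICTORS = ("BMI", "WC", "WHR", "WHtR", "WHT.5R")

#: WHO whole-body obesity criterion on BMI (kg/m²), boundary inclusive.
BMI_OBESITY_THRESHOLD = 30.0

#: Whole-body fat-percentage obesity thresholds, exceeded strictly.
FM_OBESITY_THRESHOLD = {"M": 25.0, "F": 35.0}


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's raw anthropometry and DXA outcomes.

    Attributes
    ----------
    id : str
        Opaque participant label.
    sex : str
        ``"M"`` or ``"F"``.
    age : float
        Age in years.
    mass : float
        Body mass, kg.
    height : float
        Standing height, metres (the cohort CSV carries centimetres).
    wc, hc : float
        Waist and hip circumference, cm.
    fat_pct : float
        DXA whole-body fat mass as a percentage of body mass, in (0, 100).
    vat_g : float
        DXA visceral adipose tissue mass, grams; 0 means undetectable.
    """

    id: str
    sex: str
    age: float
    mass: float
    height: float
    wc: float
    hc: float
    fat_pct: float
    vat_g: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise InputDataError(f"unknown sex code {self.sex!r} (expected M or F)")
        for name in ("mass", "height", "wc", "hc"):
            if not getattr(self, name) > 0:
                raise InputDataError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if not 0 < self.fat_pct < 100:
            raise InputDataError(f"fat_pct must lie in (0, 100), got {self.fat_pct}")
        if self.vat_g < 0:
            raise InputDataError(f"vat_g must be non-negative, got {self.vat_g}")


@dataclass(frozen=True)
class IndexSet:
    """The five derived indices for one subject (units as documented above)."""

    bmi: float
    wc_cm: float
    whr: float
    whtr: float
    wht5r: float

    def __post_init__(self) -> None:
        for name in ("bmi", "wc_cm", "whr", "whtr", "wht5r"):
            if not getattr(self, name) > 0:
                raise DomainError(f"index {name} must be strictly positive")

    def value(self, predictor: str) -> float:
        """Return one index by its canonical predictor name."""
        try:
            return {
                "BMI": self.bmi,
                "WC": self.wc_cm,
                "WHR": self.whr,
                "WHtR": self.whtr,
                "WHT.5R": self.wht5r,
            }[predictor]
        except KeyError:
            raise DomainError(f"unknown predictor {predictor!r}; expected one of {PREDICTORS}") from None


def compute_indices(record: SubjectRecord) -> IndexSet:
    """Compute all five indices for one subject.

    WHtR divides waist by height in identical length units; WHT.5R uses
    waist in metres over the square root of height in metres (the only unit
    convention consistent with typical adult values near 0.6-0.7).
    """
    if record.height <= 0 or record.hc <= 0:
        raise DomainError("height and hip circumference must be positive")
    height_cm = record.height * 100.0
    return IndexSet(
        bmi=record.mass / record.height**2,
        wc_cm=record.wc,
        whr=record.wc / record.hc,
        whtr=record.wc / height_cm,
        wht5r=(record.wc / 100.0) / math.sqrt(record.height),
    )


def classify_bmi_obese(indexset: IndexSet) -> bool:
    """True iff BMI ≥ 30 kg/m² (boundary inclusive, per the WHO criterion)."""
    return indexset.bmi >= BMI_OBESITY_THRESHOLD


def classify_fm_obese(sex: str, fat_pct: float) -> bool:
    """True iff fat percentage strictly exceeds the sex threshold (25% M, 35% F)."""
    try:
        threshold = FM_OBESITY_THRESHOLD[sex]
    except KeyError:
        raise InputDataError(f"unknown sex code {sex!r} (expected M or F)") from None
    return fat_pct > threshold
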