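"""Synthetic cohort generation and cohort CSV input/output.

The generator emulates the per-sex statistical structure the downstream
analysis assumes: the anthropometric indices (WHtR, BMI, WHR) and height are
drawn from normal distributions with configurable moments, the raw
measurements are back-derived from them (WC = WHtR x height, HC = WC / WHR,
mass = BMI x height^2), whole-body fat percentage follows a linear model in
WHtR with Gaussian residuals, and VAT mass follows a linear model in WHtR on
the natural-log scale with Gaussian residuals, zeroed out ("undetectable")
with a configurable probability.

The default parameters are the study conditions of the cohort the package
models: 41 men and 40 women, male WHtR 0.50 (SD 0.07), male %FM line
99.7 x WHtR - 24.7 with residual SD 4.1, a one-in-five rate of undetectable
VAT among women, and so on; see :data:`DEFAULT_CONFIG`.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, InputDataError
from .indices import SEXES, SubjectRecord

# Physiologic floors enforced by resampling; they keep back-derived
# measurements positive without distorting the bulk of the distribution.
_HEIGHT_FLOOR_M = 1.2
_WHTR_FLOOR = 0.25
_BMI_FLOOR = 13.0
_WHR_FLOOR = 0.4
_AGE_FLOOR = 18.0

CSV_COLUMNS = ("id", "sex", "age_years", "mass_kg", "height_cm", "waist_cm", "hip_cm", "fat_pct", "vat_g")


@dataclass(frozen=True)
class SexParams:
    """Generating parameters for one sex stratum.

    ``fm_*`` describe the linear model  %FM = fm_intercept + fm_slope*WHtR + N(0, fm_see);
    ``logvat_*`` the model  ln VAT(g) = logvat_intercept + logvat_slope*WHtR + N(0, logvat_see).
    ``p_zero_vat`` is the probability a subject's VAT is recorded as 0 g
    (undetectable by the densitometry software).
    """

    n_subjects: int
    height_mean_m: float
    height_sd_m: float
    whtr_mean: float
    whtr_sd: float
    bmi_mean: float
    bmi_sd: float
    whr_mean: float
    whr_sd: float
    age_mean: float
    age_sd: float
    fm_intercept: float
    fm_slope: float
    fm_see: float
    logvat_intercept: float
    logvat_slope: float
    logvat_see: float
    p_zero_vat: float

    def validate(self, label: str) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError(f"{label}.n_subjects must be >= 4, got {self.n_subjects}")
        for name in ("height_sd_m", "whtr_sd", "bmi_sd", "whr_sd", "age_sd"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{label}.{name} must be strictly positive, got {getattr(self, name)}")
        # Residual SDs may be exactly zero: the noiseless limit is well
        # defined and useful for testing the deterministic part of the model.
        for name in ("fm_see", "logvat_see"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{label}.{name} must be non-negative, got {getattr(self, name)}")
        for name in ("height_mean_m", "whtr_mean", "bmi_mean", "whr_mean"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{label}.{name} must be strictly positive, got {getattr(self, name)}")
        if not 0 <= self.p_zero_vat <= 1:
            raise ConfigurationError(f"{label}.p_zero_vat must lie in [0, 1], got {self.p_zero_vat}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generator configuration: one :class:`SexParams` block per sex plus a seed."""

    male: SexParams
    female: SexParams
    seed: int = 0

    def validate(self) -> None:
        self.male.validate("male")
        self.female.validate("female")


#: Male stratum defaults: marginal moments of the modelled cohort and its
#: fitted %FM / ln-VAT regression structure. Heights are chosen so that the
#: implied mean waist (WHtR x height) matches the cohort's 88.8 cm.
DEFAULT_MALE = SexParams(
    n_subjects=41,
    height_mean_m=1.78, height_sd_m=0.07,
    whtr_mean=0.50, whtr_sd=0.07,
    bmi_mean=26.2, bmi_sd=4.1,
    whr_mean=0.91, whr_sd=0.07,
    age_mean=40.5, age_sd=20.0,
    fm_intercept=-24.7, fm_slope=99.7, fm_see=4.1,
    logvat_intercept=-0.04, logvat_slope=12.9, logvat_see=math.log(1.8),
    p_zero_vat=0.0,
)

#: Female stratum defaults; the ln-VAT line is back-derived from the
#: geometric mean 204 g x// 4.9 and the fitted R^2/SEE, and one woman in
#: five has undetectable (0 g) VAT.
DEFAULT_FEMALE = SexParams(
    n_subjects=40,
    height_mean_m=1.64, height_sd_m=0.065,
    whtr_mean=0.48, whtr_sd=0.08,
    bmi_mean=24.8, bmi_sd=4.4,
    whr_mean=0.80, whr_sd=0.07,
    age_mean=36.3, age_sd=14.5,
    fm_intercept=-2.6, fm_slope=76.2, fm_see=5.0,
    logvat_intercept=-2.41, logvat_slope=16.1, logvat_see=math.log(2.6),
    p_zero_vat=0.2,
)

DEFAULT_CONFIG = SyntheticConfig(male=DEFAULT_MALE, female=DEFAULT_FEMALE, seed=0)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, floor: float, n: int) -> np.ndarray:
    """Draw n normal variates, resampling any at or below the floor."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= floor
    # With physiologic defaults the floor is many SDs below the mean, so the
    # loop almost never iterates; it is bounded for pathological configs.
    for _ in range(1000):
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= floor
    raise ConfigurationError(f"could not sample above floor {floor} from Normal({mean}, {sd})")


def _generate_sex(params: SexParams, sex: str, rng: np.random.Generator) -> list[SubjectRecord]:
    n = params.n_subjects
    whtr = _truncated_normal(rng, params.whtr_mean, params.whtr_sd, _WHTR_FLOOR, n)
    bmi = _truncated_normal(rng, params.bmi_mean, params.bmi_sd, _BMI_FLOOR, n)
    whr = _truncated_normal(rng, params.whr_mean, params.whr_sd, _WHR_FLOOR, n)
    height = _truncated_normal(rng, params.height_mean_m, params.height_sd_m, _HEIGHT_FLOOR_M, n)
    age = _truncated_normal(rng, params.age_mean, params.age_sd, _AGE_FLOOR, n)

    wc_cm = whtr * height * 100.0
    hc_cm = wc_cm / whr
    mass = bmi * height**2

    fat_mean = params.fm_intercept + params.fm_slope * whtr
    fat = fat_mean + (rng.normal(0.0, params.fm_see, size=n) if params.fm_see > 0 else 0.0)
    bad = (fat <= 0) | (fat >= 100)
    for _ in range(1000):
        if not bad.any():
            break
        if params.fm_see == 0:
            raise ConfigurationError("noiseless %FM model produces values outside (0, 100)")
        fat[bad] = fat_mean[bad] + rng.normal(0.0, params.fm_see, size=int(bad.sum()))
        bad = (fat <= 0) | (fat >= 100)
    else:
        raise ConfigurationError("%FM model rarely lands in (0, 100); check fm_* parameters")

    logvat = params.logvat_intercept + params.logvat_slope * whtr
    if params.logvat_see > 0:
        logvat = logvat + rng.normal(0.0, params.logvat_see, size=n)
    vat = np.exp(logvat)
    vat[rng.random(n) < params.p_zero_vat] = 0.0

    return [
        SubjectRecord(
            id=f"{sex}{i + 1:04d}",
            sex=sex,
            age=float(age[i]),
            mass=float(mass[i]),
            height=float(height[i]),
            wc=float(wc_cm[i]),
            hc=float(hc_cm[i]),
            fat_pct=float(fat[i]),
            vat_g=float(vat[i]),
        )
        for i in range(n)
    ]


def generate_cohort(config: SyntheticConfig = DEFAULT_CONFIG) -> list[SubjectRecord]:
    """Generate one synthetic cohort (all male records, then all female).

    The single seed is expanded deterministically into independent per-sex
    substreams, so the female stratum is unchanged by edits to male
    parameters and vice versa. Identical config implies identical output.
    """
    config.validate()
    male_seq, female_seq = np.random.SeedSequence(config.seed).spawn(2)
    records = _generate_sex(config.male, "M", np.random.default_rng(male_seq))
    records += _generate_sex(config.female, "F", np.random.default_rng(female_seq))
    return records


def write_cohort_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write records to the cohort CSV schema (height in cm on disk)."""
    if not records:
        raise InputDataError("refusing to write an empty cohort")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [r.id, r.sex]
                + [format(v, ".17g") for v in (r.age, r.mass, r.height * 100.0, r.wc, r.hc, r.fat_pct, r.vat_g)]
            )


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    """Read a cohort CSV, validating schema, sex codes and value ranges.

    Raises :class:`InputDataError` naming the offending column or row.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise InputDataError(f"cohort file missing column(s): {', '.join(missing)}")
        records: list[SubjectRecord] = []
        for rownum, row in enumerate(reader, start=2):
            try:
                values = {c: float(row[c]) for c in CSV_COLUMNS[2:]}
            except (TypeError, ValueError) as exc:
                raise InputDataError(f"row {rownum}: unparseable numeric value ({exc})") from None
            try:
                records.append(
                    SubjectRecord(
                        id=row["id"],
                        sex=row["sex"],
                        age=values["age_years"],
                        mass=values["mass_kg"],
                        height=values["height_cm"] / 100.0,
                        wc=values["waist_cm"],
                        hc=values["hip_cm"],
                        fat_pct=values["fat_pct"],
                        vat_g=values["vat_g"],
                    )
                )
            except InputDataError as exc:
                raise InputDataError(f"row {rownum}: {exc}") from None
    return records


def _params_from_mapping(block: dict, label: str) -> SexParams:
    fields = {f.name for f in dataclasses.fields(SexParams)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigurationError(f"{label}: unknown field(s) {sorted(unknown)}")
    missing = fields - set(block)
    if missing:
        raise ConfigurationError(f"{label}: missing field(s) {sorted(missing)}")
    return SexParams(**{k: (int(v) if k == "n_subjects" else float(v)) for k, v in block.items()})


def load_config(path: str | Path, seed: int | None = None) -> SyntheticConfig:
    """Load a :class:`SyntheticConfig` from a YAML file.

    The file mirrors the dataclass: top-level ``male:`` and ``female:``
    mappings plus an optional ``seed:``; a ``seed`` argument overrides the
    file's value.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "male" not in raw or "female" not in raw:
        raise ConfigurationError("config must contain 'male' and 'female' blocks")
    cfg = SyntheticConfig(
        male=_params_from_mapping(raw["male"], "male"),
        female=_params_from_mapping(raw["female"], "female"),
        seed=int(raw.get("seed", 0)) if seed is None else int(seed),
    )
    cfg.validate()
    return cfg


def dump_config(config: SyntheticConfig, path: str | Path) -> None:
    """Write a config as YAML (inverse of :func:`load_config`)."""
    payload = {
        "male": dataclasses.asdict(config.male),
        "female": dataclasses.asdict(config.female),
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def split_by_sex(records: Iterable[SubjectRecord]) -> dict[str, list[SubjectRecord]]:
    """Partition records into the two sex strata, preserving order."""
    out: dict[str, list[SubjectRecord]] = {s: [] for s in SEXES}
    for r in records:
        out[r.sex].append(r)
    return out
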