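"""Per-respondent smoking-burden indicators.

Five indicators quantify the burden of smoking for a survey respondent:

``is_current``
    1 if the respondent currently smokes, else 0.
``is_ever``
    1 if the respondent currently smokes or used to smoke, else 0.
``length_years``
    Years of regular smoking: current age minus starting age for current
    smokers, quitting age minus starting age for former smokers.
``pack_years``
    (cigarettes per day / 20) x years of smoking, assuming a constant
    intensity equal to the reported average and 20 cigarettes per pack.
``discounted_pack_years``
    Pack-years multiplied by a cessation discount that declines linearly
    from 1 to 0 over the first ``horizon`` (default 10) full years since
    quitting.  Current smokers keep their full pack-years; former smokers
    who quit ``horizon`` or more years ago score 0.

Never smokers score 0 on all five indicators, which lets population means
be taken over the entire population rather than over smokers only.

Ages are integer years, matching questionnaire granularity, so years since
cessation is integer-stepped; the discount still evaluates the linear
formula on that integer difference.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("smokeburden")

# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

SEX_LEVELS = ("male", "female")
EDUCATION_LEVELS = ("le15", "16_19", "ge20", "still_studying")
BILLS_LEVELS = ("most_of_time", "time_to_time", "almost_never")
RESIDENCE_LEVELS = ("rural", "small_town", "large_town")
OCCUPATION_LEVELS = ("employed", "unemployed", "not_working")
MARITAL_LEVELS = ("single_no_child", "single_child", "multi_no_child", "multi_child")
STATUS_LEVELS = ("current", "former", "never")
AGE_BANDS = ("15_24", "25_34", "35_44", "45_54", "55_64", "65_74", "75_plus")

#: Interview response meaning the respondent could not answer; such rows are
#: excluded from analysis (not a schema error).
DONT_KNOW = "dont_know"

CATEGORY_LEVELS: Mapping[str, tuple] = {
    "sex": SEX_LEVELS,
    "education_end": EDUCATION_LEVELS,
    "paying_bills": BILLS_LEVELS,
    "residence": RESIDENCE_LEVELS,
    "occupation": OCCUPATION_LEVELS,
    "marital": MARITAL_LEVELS,
    "smoking_status": STATUS_LEVELS,
}

COVARIATE_COLUMNS = (
    "sex",
    "education_end",
    "paying_bills",
    "residence",
    "occupation",
    "marital",
)

MICRODATA_COLUMNS = (
    "respondent_id",
    "country",
    "weight",
    "age",
    "sex",
    "education_end",
    "paying_bills",
    "residence",
    "occupation",
    "marital",
    "smoking_status",
    "start_age",
    "quit_age",
    "cigs_per_day",
)

INDICATOR_COLUMNS = (
    "is_current",
    "is_ever",
    "length_years",
    "pack_years",
    "discounted_pack_years",
)

DEFAULT_HORIZON = 10.0


class SchemaError(ValueError):
    """A field value that cannot be interpreted at all (wrong type, unknown
    category level).  Distinct from exclusion of an interpretable but
    unusable record."""


@dataclass(frozen=True)
class SmokingRecord:
    """One survey respondent.

    ``start_age``, ``quit_age`` and ``cigs_per_day`` are ``None`` when the
    question does not apply (never smokers; ``quit_age`` for current
    smokers) or was not answered.
    """

    respondent_id: str
    country: str
    weight: float
    age: int
    sex: str
    education_end: str
    paying_bills: str
    residence: str
    occupation: str
    marital: str
    smoking_status: str
    start_age: Optional[int] = None
    quit_age: Optional[int] = None
    cigs_per_day: Optional[float] = None


@dataclass(frozen=True)
class IndicatorSet:
    is_current: int
    is_ever: int
    length_years: float
    pack_years: float
    discounted_pack_years: float


@dataclass
class ValidationPolicy:
    """How raw records are screened before analysis.

    Observations with missing values or "don't know" responses are excluded.

    Parameters
    ----------
    cpd_cap:
        Optional upper cap applied to cigarettes/day.  Off by default: no
        truncation of extreme intensities.
    require_covariates:
        When True (default), a missing or "don't know" sociodemographic
        covariate excludes the record (listwise deletion, as used before
        model fitting).
    """

    cpd_cap: Optional[float] = None
    require_covariates: bool = True
    #: counts respondents flagged as smokers with 0 cigarettes/day
    #: (e.g. pipe-only users): they keep pack_years = 0 but still count in
    #: the prevalence indicators.
    zero_cpd_warnings: int = field(default=0, init=False)


@dataclass(frozen=True)
class ValidationResult:
    valid: bool
    reason: Optional[str] = None  # machine-readable exclusion reason


VALID = ValidationResult(True, None)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and (value == "" or value == DONT_KNOW):
        return True
    return False


def validate_record(r: SmokingRecord, policy: ValidationPolicy | None = None) -> ValidationResult:
    """Screen one record; return ``valid`` or an exclusion reason code.

    Raises :class:`SchemaError` for malformed values (unknown category
    level, non-numeric/negative quantities) — those are data defects, not
    analytic exclusions.
    """
    policy = policy if policy is not None else ValidationPolicy()

    for col in ("sex", "education_end", "paying_bills", "residence", "occupation", "marital"):
        value = getattr(r, col)
        if not _is_missing(value) and value not in CATEGORY_LEVELS[col]:
            raise SchemaError(f"unknown level {value!r} for field {col!r}")
    if not _is_missing(r.smoking_status) and r.smoking_status not in STATUS_LEVELS:
        raise SchemaError(f"unknown level {r.smoking_status!r} for field 'smoking_status'")
    for col in ("age", "start_age", "quit_age", "weight", "cigs_per_day"):
        value = getattr(r, col)
        if not _is_missing(value) and not isinstance(value, (int, float, np.integer, np.floating)):
            raise SchemaError(f"non-numeric value {value!r} for field {col!r}")
    if r.cigs_per_day is not None and not _is_missing(r.cigs_per_day) and r.cigs_per_day < 0:
        raise SchemaError("negative cigs_per_day")

    if _is_missing(r.weight) or r.weight <= 0:
        return ValidationResult(False, "nonpositive_weight")
    if _is_missing(r.age):
        return ValidationResult(False, "missing_age")
    if r.age < 15:
        return ValidationResult(False, "underage")

    if policy.require_covariates:
        for col in COVARIATE_COLUMNS:
            if _is_missing(getattr(r, col)):
                return ValidationResult(False, "missing_covariate")

    status = r.smoking_status
    if _is_missing(status):
        return ValidationResult(False, "missing_smoking_status")

    if status == "never":
        if not (_is_missing(r.start_age) and _is_missing(r.quit_age) and _is_missing(r.cigs_per_day)):
            return ValidationResult(False, "history_on_never_smoker")
        return VALID

    # current or former
    if _is_missing(r.start_age):
        return ValidationResult(False, "missing_start_age")
    if _is_missing(r.cigs_per_day):
        return ValidationResult(False, "missing_cpd")
    if r.start_age > r.age:
        return ValidationResult(False, "start_after_current_age")

    if status == "current":
        if not _is_missing(r.quit_age):
            return ValidationResult(False, "quit_age_on_current_smoker")
        if r.cigs_per_day == 0:
            policy.zero_cpd_warnings += 1
        return VALID

    # former
    if _is_missing(r.quit_age):
        return ValidationResult(False, "missing_quit_age")
    if r.quit_age < r.start_age:
        return ValidationResult(False, "quit_before_start")
    if r.quit_age > r.age:
        return ValidationResult(False, "quit_after_current_age")
    if r.cigs_per_day == 0:
        policy.zero_cpd_warnings += 1
    return VALID


def record_from_row(row) -> SmokingRecord:
    """Build a :class:`SmokingRecord` from a microdata frame row."""
    return SmokingRecord(
        respondent_id=str(row.respondent_id),
        country=row.country,
        weight=row.weight,
        age=None if pd.isna(row.age) else int(row.age),
        sex=_none_if_na(row.sex),
        education_end=_none_if_na(row.education_end),
        paying_bills=_none_if_na(row.paying_bills),
        residence=_none_if_na(row.residence),
        occupation=_none_if_na(row.occupation),
        marital=_none_if_na(row.marital),
        smoking_status=_none_if_na(row.smoking_status),
        start_age=None if pd.isna(row.start_age) else row.start_age,
        quit_age=None if pd.isna(row.quit_age) else row.quit_age,
        cigs_per_day=None if pd.isna(row.cigs_per_day) else row.cigs_per_day,
    )


def validation_reasons(df: pd.DataFrame, policy: ValidationPolicy | None = None) -> pd.Series:
    """Vectorized exclusion screening of a microdata frame.

    Returns one exclusion reason (or None) per row, applying exactly the
    same rules, in the same precedence order, as :func:`validate_record`.
    Raises :class:`SchemaError` on unknown category levels.
    """
    policy = policy if policy is not None else ValidationPolicy()
    n = len(df)
    for col, levels in CATEGORY_LEVELS.items():
        values = df[col]
        known = values.isna() | values.isin(levels) | (values == DONT_KNOW) | (values == "")
        if not known.all():
            bad = values[~known].iloc[0]
            raise SchemaError(f"unknown level {bad!r} for field {col!r}")
    cpd = df["cigs_per_day"].to_numpy(dtype=float)
    if np.nanmin(cpd, initial=0.0) < 0:
        raise SchemaError("negative cigs_per_day")

    def missing_cat(col):
        values = df[col]
        return (values.isna() | (values == DONT_KNOW) | (values == "")).to_numpy()

    weight = df["weight"].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    start = df["start_age"].to_numpy(dtype=float)
    quit = df["quit_age"].to_numpy(dtype=float)
    status = df["smoking_status"]
    current = (status == "current").to_numpy()
    former = (status == "former").to_numpy()
    never = (status == "never").to_numpy()
    smoker = current | former

    reason = np.full(n, None, dtype=object)

    def assign(mask, code):
        mask = mask & (reason == None)  # noqa: E711  (elementwise)
        reason[mask] = code

    assign(np.isnan(weight) | (weight <= 0), "nonpositive_weight")
    assign(np.isnan(age), "missing_age")
    assign(age < 15, "underage")
    if policy.require_covariates:
        missing_cov = np.zeros(n, dtype=bool)
        for col in COVARIATE_COLUMNS:
            missing_cov |= missing_cat(col)
        assign(missing_cov, "missing_covariate")
    assign(missing_cat("smoking_status"), "missing_smoking_status")
    assign(never & ~(np.isnan(start) & np.isnan(quit) & np.isnan(cpd)), "history_on_never_smoker")
    assign(smoker & np.isnan(start), "missing_start_age")
    assign(smoker & np.isnan(cpd), "missing_cpd")
    assign(smoker & (start > age), "start_after_current_age")
    assign(current & ~np.isnan(quit), "quit_age_on_current_smoker")
    assign(former & np.isnan(quit), "missing_quit_age")
    assign(former & (quit < start), "quit_before_start")
    assign(former & (quit > age), "quit_after_current_age")

    policy.zero_cpd_warnings += int((smoker & (cpd == 0) & (reason == None)).sum())  # noqa: E711
    return pd.Series(reason, index=df.index, dtype=object)


def validate_frame(
    df: pd.DataFrame, policy: ValidationPolicy | None = None
) -> tuple[pd.DataFrame, Counter]:
    """Screen a microdata frame; return (valid rows, exclusion counts by reason).

    Exclusion counts are also logged, one line per reason.
    """
    policy = policy if policy is not None else ValidationPolicy()
    reason_series = validation_reasons(df, policy)
    counts = Counter(r for r in reason_series if r is not None)
    for reason, count in sorted(counts.items()):
        logger.info("excluded %d records: %s", count, reason)
    if policy.zero_cpd_warnings:
        logger.warning(
            "%d smokers report 0 cigarettes/day (non-cigarette products); "
            "pack-years set to 0, prevalence indicators kept",
            policy.zero_cpd_warnings,
        )
    valid = df.loc[reason_series.isna()].copy()
    if policy.cpd_cap is not None and "cigs_per_day" in valid:
        valid["cigs_per_day"] = valid["cigs_per_day"].clip(upper=policy.cpd_cap)
    return valid, counts


def _none_if_na(value):
    return None if (value is None or (isinstance(value, float) and np.isnan(value))) else value


# ---------------------------------------------------------------------------
# Indicator arithmetic
# ---------------------------------------------------------------------------


def length_of_smoking(r: SmokingRecord) -> float:
    """Years of regular smoking; 0 for never smokers."""
    if r.smoking_status == "never":
        return 0.0
    if r.smoking_status == "current":
        return float(r.age - r.start_age)
    return float(r.quit_age - r.start_age)


def pack_years(r: SmokingRecord) -> float:
    """(cigarettes/day / 20) x years of smoking; 0 for never smokers."""
    if r.smoking_status == "never":
        return 0.0
    if r.cigs_per_day is not None and r.cigs_per_day < 0:
        raise SchemaError("negative cigs_per_day")
    return (r.cigs_per_day / 20.0) * length_of_smoking(r)


def cessation_discount(years_since_quit: float, horizon: float = DEFAULT_HORIZON) -> float:
    """Linear risk discount: 1 at quitting, 0 at ``horizon`` years or more."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    return max(0.0, 1.0 - years_since_quit / horizon)


def discounted_pack_years(r: SmokingRecord, horizon: float = DEFAULT_HORIZON) -> float:
    """Pack-years discounted linearly by full years since cessation.

    Equal to pack-years for current smokers; 0 for never smokers and for
    former smokers whose cessation reaches the horizon.  A respondent who
    quit within the current year (quit_age == age) keeps the full value:
    zero complete years of cessation means no discount yet.
    """
    if r.smoking_status == "never":
        return 0.0
    py = pack_years(r)
    if r.smoking_status == "current":
        return py
    return py * cessation_discount(float(r.age - r.quit_age), horizon)


def compute_indicator_set(r: SmokingRecord, horizon: float = DEFAULT_HORIZON) -> IndicatorSet:
    """Bundle the five burden indicators for one valid record."""
    is_current = 1 if r.smoking_status == "current" else 0
    is_ever = 1 if r.smoking_status in ("current", "former") else 0
    return IndicatorSet(
        is_current=is_current,
        is_ever=is_ever,
        length_years=length_of_smoking(r),
        pack_years=pack_years(r),
        discounted_pack_years=discounted_pack_years(r, horizon),
    )


def compute_indicators(df: pd.DataFrame, horizon: float = DEFAULT_HORIZON) -> pd.DataFrame:
    """Vectorized indicator computation over a validated microdata frame.

    Returns a copy of ``df`` with the five indicator columns appended.
    Identical, row for row, to applying :func:`compute_indicator_set` to
    each record.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = df.copy()
    status = out["smoking_status"]
    current = (status == "current").to_numpy()
    former = (status == "former").to_numpy()

    out["is_current"] = current.astype(int)
    out["is_ever"] = (current | former).astype(int)

    age = out["age"].to_numpy(dtype=float)
    start = out["start_age"].to_numpy(dtype=float)
    quit = out["quit_age"].to_numpy(dtype=float)
    cpd = out["cigs_per_day"].to_numpy(dtype=float)
    if np.nanmin(cpd, initial=0.0) < 0:
        raise SchemaError("negative cigs_per_day")

    length = np.zeros(len(out))
    length[current] = age[current] - start[current]
    length[former] = quit[former] - start[former]
    out["length_years"] = length

    py = np.zeros(len(out))
    ever = current | former
    py[ever] = cpd[ever] / 20.0 * length[ever]
    out["pack_years"] = py

    disc = np.zeros(len(out))
    disc[current] = 1.0
    disc[former] = np.maximum(0.0, 1.0 - (age[former] - quit[former]) / horizon)
    out["discounted_pack_years"] = py * disc
    return out
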