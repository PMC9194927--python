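"""Design-weighted prevalence and mean estimation.

Point estimates are Hajek estimators (weighted means).  The public
microdata schema carries a single design weight per respondent and no
PSU/stratum identifiers, so fully linearized design variances are not
attempted.  Instead, confidence intervals approximate the design effect of
unequal weighting through the Kish effective sample size

    n_eff = (sum w)^2 / sum w^2,

using a logit-transformed Wald interval for proportions and a t interval
with the weighted variance for means.  The method name is stamped into the
output so downstream consumers can see which approximation produced each
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PROPORTION_CI_METHOD = "logit_wald_kish"
MEAN_CI_METHOD = "t_kish"

#: binary indicators are estimated as proportions, the rest as means
PROPORTION_INDICATORS = ("is_current", "is_ever")


@dataclass(frozen=True)
class GroupEstimate:
    """Weighted estimate for one (group, indicator) cell."""

    group_key: Mapping[str, str]
    indicator: str
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    sum_weights: float
    method: str
    degenerate_ci: bool = False


def kish_effective_n(weights: np.ndarray) -> float:
    """(sum w)^2 / sum w^2 — effective sample size under unequal weights."""
    weights = np.asarray(weights, dtype=float)
    return weights.sum() ** 2 / (weights**2).sum()


def _weighted_mean_var(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, weighted variance of an observation, and Kish n_eff."""
    mean = float(np.average(values, weights=weights))
    n_eff = kish_effective_n(weights)
    var = float(np.average((values - mean) ** 2, weights=weights))
    if n_eff > 1:
        var *= n_eff / (n_eff - 1.0)  # small-sample correction
    return mean, var, n_eff


def _proportion_ci(p: float, n_eff: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    if p <= 0.0 or p >= 1.0:
        # logit undefined at the boundary: Wilson interval on n_eff
        denom = 1.0 + z**2 / n_eff
        centre = (p + z**2 / (2 * n_eff)) / denom
        half = z * np.sqrt(p * (1 - p) / n_eff + z**2 / (4 * n_eff**2)) / denom
        return max(0.0, centre - half), min(1.0, centre + half)
    logit = np.log(p / (1 - p))
    se = 1.0 / np.sqrt(n_eff * p * (1 - p))
    lo, hi = logit - z * se, logit + z * se
    return float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi)))


def _mean_ci(mean: float, var: float, n_eff: float, level: float) -> tuple[float, float, bool]:
    if n_eff <= 1 or var == 0.0:
        return np.nan, np.nan, True  # degenerate: a single (effective) observation
    t = stats.t.ppf(0.5 + level / 2.0, df=max(n_eff - 1.0, 1.0))
    half = t * np.sqrt(var / n_eff)
    return mean - half, mean + half, False


def _iter_strata(df: pd.DataFrame, strata: Optional[Sequence[str]]):
    if not strata:
        yield {}, df
        return
    for key, group in df.groupby(list(strata), observed=True, dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        yield dict(zip(strata, key)), group


def weighted_proportion(
    df: pd.DataFrame,
    indicator: str,
    strata: Optional[Sequence[str]] = None,
    level: float = 0.95,
    weight_col: str = "weight",
) -> list[GroupEstimate]:
    """Weighted proportion of a binary indicator, per stratum.

    An empty stratum yields an estimate of NaN (undefined), never 0.
    """
    out = []
    for key, group in _iter_strata(df, strata):
        if len(group) == 0:
            out.append(
                GroupEstimate(key, indicator, np.nan, np.nan, np.nan, 0, 0.0, PROPORTION_CI_METHOD)
            )
            continue
        y = group[indicator].to_numpy(dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError(f"indicator {indicator!r} is not binary")
        w = group[weight_col].to_numpy(dtype=float)
        p, _, n_eff = _weighted_mean_var(y, w)
        lo, hi = _proportion_ci(p, n_eff, level)
        out.append(
            GroupEstimate(key, indicator, p, lo, hi, len(group), float(w.sum()), PROPORTION_CI_METHOD)
        )
    return out


def weighted_mean(
    df: pd.DataFrame,
    indicator: str,
    strata: Optional[Sequence[str]] = None,
    population_scope: str = "all",
    level: float = 0.95,
    weight_col: str = "weight",
) -> list[GroupEstimate]:
    """Weighted mean of a continuous indicator, per stratum.

    ``population_scope="all"`` (the headline convention) keeps never
    smokers in the denominator with their indicator value of zero;
    ``"smokers_only"`` restricts to ever smokers, for diagnostics.
    """
    if population_scope not in ("all", "smokers_only"):
        raise ValueError(f"unknown population_scope {population_scope!r}")
    scoped = df if population_scope == "all" else df[df["is_ever"] == 1]
    method = f"{MEAN_CI_METHOD}:{population_scope}"
    out = []
    for key, group in _iter_strata(scoped, strata):
        if len(group) == 0:
            out.append(GroupEstimate(key, indicator, np.nan, np.nan, np.nan, 0, 0.0, method))
            continue
        values = group[indicator].to_numpy(dtype=float)
        w = group[weight_col].to_numpy(dtype=float)
        mean, var, n_eff = _weighted_mean_var(values, w)
        lo, hi, degenerate = _mean_ci(mean, var, n_eff, level)
        out.append(
            GroupEstimate(key, indicator, mean, lo, hi, len(group), float(w.sum()), method, degenerate)
        )
    return out


def relative_difference(e_a: GroupEstimate, e_b: GroupEstimate) -> float:
    """Signed percent difference of ``e_a`` relative to reference ``e_b``:
    100 x (a - b) / b.  NaN when the reference estimate is 0."""
    if e_a.indicator != e_b.indicator:
        raise ValueError("estimates compare different indicators")
    if e_b.estimate == 0 or np.isnan(e_b.estimate):
        return np.nan
    return 100.0 * (e_a.estimate - e_b.estimate) / e_b.estimate


def estimates_frame(estimates: Sequence[GroupEstimate]) -> pd.DataFrame:
    """Long-format table of estimates (group columns, indicator, estimate,
    ci bounds, n, sum of weights, CI method)."""
    rows = []
    for e in estimates:
        row = dict(e.group_key)
        row.update(
            indicator=e.indicator,
            estimate=e.estimate,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            n=e.n,
            sum_weights=e.sum_weights,
            method=e.method,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def estimate_all(
    df: pd.DataFrame,
    strata: Optional[Sequence[str]] = None,
    population_scope: str = "all",
    level: float = 0.95,
) -> pd.DataFrame:
    """All five indicators (proportions for binary, means for continuous),
    per stratum, as a long-format frame."""
    estimates: list[GroupEstimate] = []
    for indicator in PROPORTION_INDICATORS:
        estimates.extend(weighted_proportion(df, indicator, strata, level))
    for indicator in ("length_years", "pack_years", "discounted_pack_years"):
        estimates.extend(weighted_mean(df, indicator, strata, population_scope, level))
    return estimates_frame(estimates)
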