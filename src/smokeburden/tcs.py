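"""Tobacco Control Scale (TCS) aggregation.

The TCS scores national tobacco-control policy on a 0-100 scale, summing
six components (taxes 30, public-place smoking bans 22, information
campaigns 15, advertising bans 13, warning labels 10, cessation support
10).  Reports were published for 2005, 2007, 2010, 2013 and 2016; a
country's exposure over the period is summarized by the arithmetic mean of
the report years in which it appears (no imputation for absent years —
e.g. a country first scored in 2013 averages 2013 and 2016 only).

Averages are bucketed as low (< 40), moderate (40 to < 50) and high
(>= 50).  Boundary values go to the higher category: the published
intervals "40-49.9" and ">=50" have closed lower bounds.  A score of
exactly 0 is classified low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

TCS_REPORT_YEARS = (2005, 2007, 2010, 2013, 2016)
TCS_CATEGORIES = ("low", "moderate", "high")

MODERATE_THRESHOLD = 40.0
HIGH_THRESHOLD = 50.0


@dataclass(frozen=True)
class TCSRecord:
    country: str
    scores: Mapping[int, float]
    average: float
    category: str


def average_tcs(scores: Mapping[int, float]) -> float:
    """Mean TCS score over the report years present."""
    if not scores:
        raise ValueError("no TCS report years present")
    for year, score in scores.items():
        if not 0.0 <= score <= 100.0:
            raise ValueError(f"TCS score {score} for {year} outside [0, 100]")
    return sum(scores.values()) / len(scores)


def categorize_tcs(average: float) -> str:
    """low (< 40), moderate (40 to < 50), high (>= 50)."""
    if not 0.0 <= average <= 100.0:
        raise ValueError(f"TCS average {average} outside [0, 100]")
    if average >= HIGH_THRESHOLD:
        return "high"
    if average >= MODERATE_THRESHOLD:
        return "moderate"
    return "low"


def make_record(country: str, scores: Mapping[int, float]) -> TCSRecord:
    avg = average_tcs(scores)
    return TCSRecord(country=country, scores=dict(scores), average=avg, category=categorize_tcs(avg))


def aggregate_tcs(long_df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long (country, year, score) table to one row per country
    with the average score and its category."""
    required = {"country", "year", "score"}
    missing = required - set(long_df.columns)
    if missing:
        raise ValueError(f"TCS table missing columns: {sorted(missing)}")
    records = [
        make_record(country, dict(zip(group["year"], group["score"])))
        for country, group in long_df.groupby("country", sort=True)
    ]
    return pd.DataFrame(
        {
            "country": [r.country for r in records],
            "tcs_average": [r.average for r in records],
            "tcs_category": [r.category for r in records],
        }
    )
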