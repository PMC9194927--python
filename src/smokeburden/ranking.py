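"""Country league tables, rank discrepancies and indicator correlations.

Countries are ranked per indicator with rank 1 = highest burden.  Ties
share the minimum ("competition") rank and subsequent ranks skip
accordingly, matching how published league tables print shared ranks.
When reproducing a printed table the comparison is made on the printed
one-decimal values, since ties only arise after rounding.

Cross-indicator agreement is summarized by the Pearson correlation of the
country-level estimates (one point per country, countries unweighted) —
the same quantity behind country-level scatterplots.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

TABLE1_FIXTURE = "table1_eurobarometer2017.csv"

#: indicator columns in the bundled 2017 Eurobarometer country table
TABLE1_INDICATORS = ("prev_current", "pack_years", "disc_pack_years")


def load_table1() -> pd.DataFrame:
    """Bundled fixture: 2017 Eurobarometer country estimates (current-smoking
    prevalence, pack-years, discounted pack-years) with 95% CIs and printed
    ranks for the 27 EU member states plus the UK."""
    with resources.files("smokeburden.data").joinpath(TABLE1_FIXTURE).open() as fh:
        return pd.read_csv(fh)


def competition_rank(values: pd.Series) -> pd.Series:
    """Descending minimum-rank: ties share the lowest rank, next rank skips."""
    return values.rank(method="min", ascending=False).astype(int)


def rank_countries(
    estimates: pd.DataFrame,
    indicator: str,
    country_col: str = "country",
    ci_cols: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """League table for one indicator.

    ``estimates`` must hold one row per country with the indicator column;
    duplicate countries are an error.  Returns a frame sorted by descending
    estimate with columns country, estimate, (ci_low, ci_high when
    available) and rank.
    """
    if estimates[country_col].duplicated().any():
        dupes = estimates.loc[estimates[country_col].duplicated(), country_col].tolist()
        raise ValueError(f"duplicate countries in estimates: {dupes}")
    table = pd.DataFrame(
        {
            "country": estimates[country_col].to_numpy(),
            "indicator": indicator,
            "estimate": estimates[indicator].to_numpy(dtype=float),
        }
    )
    if ci_cols is not None:
        table["ci_low"] = estimates[ci_cols[0]].to_numpy(dtype=float)
        table["ci_high"] = estimates[ci_cols[1]].to_numpy(dtype=float)
    table["rank"] = competition_rank(table["estimate"])
    return table.sort_values(["rank", "country"]).reset_index(drop=True)


def indicator_correlation(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pearson r between country-level estimates for every indicator pair.

    All league tables must cover the same set of at least 3 countries.
    Computed on the estimates themselves, not on ranks.  An indicator with
    zero variance across countries yields NaN entries off the diagonal.
    """
    names = list(tables)
    if len(names) < 2:
        raise ValueError("need at least two indicators to correlate")
    country_sets = {name: frozenset(t["country"]) for name, t in tables.items()}
    reference = country_sets[names[0]]
    if len(reference) < 3:
        raise ValueError("need at least 3 countries")
    for name, countries in country_sets.items():
        if countries != reference:
            raise ValueError(f"country set of {name!r} differs from {names[0]!r}")
    wide = pd.DataFrame(
        {name: tables[name].set_index("country")["estimate"] for name in names}
    ).sort_index()
    matrix = np.eye(len(names))
    values = wide.to_numpy()
    sd = values.std(axis=0)
    for i in range(len(names)):
        for k in range(i + 1, len(names)):
            if sd[i] == 0 or sd[k] == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(values[:, i], values[:, k])[0, 1])
            matrix[i, k] = matrix[k, i] = r
    return pd.DataFrame(matrix, index=names, columns=names)


def discrepancy_report(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-country rank gaps across all indicator pairs.

    One row per (country, indicator pair) with both ranks and the absolute
    gap; countries ordered by their maximum gap (largest discrepancies
    first), pairs within a country by gap.
    """
    names = list(tables)
    ranks = pd.DataFrame({name: tables[name].set_index("country")["rank"] for name in names})
    rows = []
    for country, row in ranks.iterrows():
        for i in range(len(names)):
            for k in range(i + 1, len(names)):
                rows.append(
                    {
                        "country": country,
                        "indicator_a": names[i],
                        "indicator_b": names[k],
                        "rank_a": int(row[names[i]]),
                        "rank_b": int(row[names[k]]),
                        "rank_gap": int(abs(row[names[i]] - row[names[k]])),
                    }
                )
    report = pd.DataFrame(rows)
    max_gap = report.groupby("country")["rank_gap"].transform("max")
    report["max_gap"] = max_gap
    report = report.sort_values(
        ["max_gap", "country", "rank_gap"], ascending=[False, True, False]
    ).drop(columns="max_gap")
    return report.reset_index(drop=True)


def table1_league_tables() -> dict[str, pd.DataFrame]:
    """League tables recomputed from the bundled 2017 country estimates."""
    table1 = load_table1()
    return {
        indicator: rank_countries(
            table1, indicator, ci_cols=(f"{indicator}_lo", f"{indicator}_hi")
        )
        for indicator in TABLE1_INDICATORS
    }
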