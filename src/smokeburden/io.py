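"""Readers, writers, pipeline configuration and the end-to-end run.

CSV is the interchange format throughout: respondent-level microdata in
the documented schema (one row per respondent, missing answers as empty
cells, "don't know" as the literal ``dont_know``), tobacco-control scores
as a long (country, year, score) table, and every pipeline output as a
long-format CSV that the package's own readers can load back.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .indicators import (
    CATEGORY_LEVELS,
    DONT_KNOW,
    MICRODATA_COLUMNS,
    SchemaError,
    ValidationPolicy,
    compute_indicators,
    validate_frame,
)
from .models import ModelFit, ModelSpec, add_age_band, fit_two_level_linear, fit_two_level_logistic
from .ranking import indicator_correlation, rank_countries
from .survey import estimate_all, estimates_frame, weighted_mean, weighted_proportion
from .tcs import aggregate_tcs

logger = logging.getLogger("smokeburden")

_NUMERIC_COLUMNS = {"weight": float, "age": float, "start_age": float, "quit_age": float, "cigs_per_day": float}


def read_microdata(path) -> pd.DataFrame:
    """Read and schema-check a microdata CSV.

    Returns the frame with numeric columns parsed and missing answers as
    NaN.  Malformed rows (non-numeric quantities, unknown category levels)
    raise :class:`SchemaError` naming the 1-based data line number.
    An empty file yields an empty frame with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = set(MICRODATA_COLUMNS) - set(df.columns)
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {sorted(missing_cols)}")
    if df.empty:
        logger.warning("%s: empty microdata file", path)
    for col, typ in _NUMERIC_COLUMNS.items():
        raw = df[col].str.strip()
        blank = raw == ""
        parsed = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise SchemaError(f"{path}:{line}: non-numeric value {raw[bad].iloc[0]!r} in {col!r}")
        df[col] = parsed.astype(typ)
    for col, levels in CATEGORY_LEVELS.items():
        values = df[col].str.strip()
        ok = values.isin(levels) | (values == "") | (values == DONT_KNOW)
        if not ok.all():
            line = int(df.index[~ok][0]) + 2
            raise SchemaError(f"{path}:{line}: unknown level {values[~ok].iloc[0]!r} in {col!r}")
        df[col] = values.where(values != "", other=np.nan)
    return df


def write_microdata(df: pd.DataFrame, path) -> None:
    df.loc[:, list(MICRODATA_COLUMNS)].to_csv(path, index=False)


def read_tcs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("country", "year", "score"):
        if col not in df.columns:
            raise SchemaError(f"{path}: TCS table missing column {col!r}")
    return df


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs.

    Either ``microdata`` points at a CSV in the documented export schema,
    or ``simulate`` is True and a synthetic scenario is generated
    (``synthetic`` holding a scenario YAML path, or None for defaults).
    """

    output_dir: str = "smokeburden_out"
    microdata: Optional[str] = None
    tcs: Optional[str] = None
    simulate: bool = False
    synthetic: Optional[str] = None
    seed: int = 0
    horizon: float = 10.0
    cpd_cap: Optional[float] = None
    population_scope: str = "all"
    strata: Sequence[str] = ("sex", "paying_bills")
    model_outcomes: Sequence[str] = ("is_current", "is_ever", "length_years", "pack_years", "discounted_pack_years")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if not self.simulate and self.microdata is None:
            raise ValueError("either simulate: true or a microdata path is required")
        for p in (self.microdata, self.tcs, self.synthetic):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _fit_to_frame(fit: ModelFit, outcome: str) -> pd.DataFrame:
    frame = fit.frame()
    frame.insert(0, "outcome", outcome)
    frame["scale"] = fit.scale
    frame["random_intercept_sd"] = fit.random_intercept_sd
    frame["n_obs"] = fit.n_obs
    frame["n_groups"] = fit.n_groups
    frame["converged"] = fit.converged
    return frame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write all artifacts.

    Stages: load or simulate microdata -> validate/exclude -> derive
    indicators -> merge tobacco-control categories -> weighted estimates
    (overall, by country, and by the configured strata) -> country league
    tables and indicator correlations -> two-level models -> manifest.
    Any stage failure aborts with a stage-tagged message.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.simulate:
            from . import synth

            scenario = (
                synth.config_from_yaml(config.synthetic)
                if config.synthetic
                else synth.SyntheticConfig()
            )
            micro = synth.generate(scenario, seed=config.seed)
            write_microdata(micro, out / "microdata.csv")
            tcs_long = synth.tcs_long_table(scenario)
            tcs_long.to_csv(out / "tcs_scores.csv", index=False)
        else:
            micro = read_microdata(config.microdata)
            tcs_long = read_tcs(config.tcs) if config.tcs else None

        stage = "validate"
        policy = ValidationPolicy(cpd_cap=config.cpd_cap)
        valid, exclusions = validate_frame(micro, policy)

        stage = "indicators"
        ind = compute_indicators(valid, horizon=config.horizon)
        ind = add_age_band(ind)
        if tcs_long is not None:
            tcs_table = aggregate_tcs(tcs_long)
            ind = ind.merge(tcs_table[["country", "tcs_category"]], on="country", how="left")
            tcs_table.to_csv(out / "tcs_categories.csv", index=False)
        ind.to_csv(out / "indicators.csv", index=False)

        stage = "estimate"
        tables = [estimate_all(ind, strata=None, population_scope=config.population_scope)]
        tables.append(estimate_all(ind, strata=["country"], population_scope=config.population_scope))
        for stratum in config.strata:
            tables.append(estimate_all(ind, strata=[stratum], population_scope=config.population_scope))
        estimates = pd.concat(tables, ignore_index=True)
        estimates.to_csv(out / "estimates.csv", index=False)

        stage = "rank"
        by_country = estimates[estimates["country"].notna()] if "country" in estimates else pd.DataFrame()
        league = {}
        for indicator in ("is_current", "is_ever", "length_years", "pack_years", "discounted_pack_years"):
            rows = by_country[by_country["indicator"] == indicator]
            rows = rows.rename(columns={"estimate": indicator})
            league[indicator] = rank_countries(rows, indicator, ci_cols=("ci_low", "ci_high"))
            league[indicator].to_csv(out / f"league_{indicator}.csv", index=False)
        correlations = indicator_correlation(league)
        correlations.to_csv(out / "correlations.csv")

        stage = "fit"
        fits = []
        for outcome in config.model_outcomes:
            if outcome in ("is_current", "is_ever"):
                spec = ModelSpec(outcome=outcome, scale="odds_ratio")
                fit = fit_two_level_logistic(ind, spec)
            else:
                spec = ModelSpec(outcome=outcome, scale="beta")
                fit = fit_two_level_linear(ind, spec)
            fits.append(_fit_to_frame(fit, outcome))
        pd.concat(fits, ignore_index=True).to_csv(out / "model_fits.csv", index=False)

        stage = "manifest"
        artifacts = sorted(p.name for p in out.glob("*.csv"))
        manifest = {
            "package": "smokeburden",
            "version": __version__,
            "seed": config.seed,
            "horizon": config.horizon,
            "n_input": int(len(micro)),
            "n_valid": int(len(ind)),
            "exclusions": {k: int(v) for k, v in sorted(exclusions.items())},
            "artifacts": {name: _sha256(out / name) for name in artifacts},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
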