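"""Synthetic Eurobarometer-like microdata with analytically known truth.

The generator emulates a 28-country face-to-face smoking survey: one row
per respondent with design weight, sociodemographics, smoking status and
smoking history (start age, quit age, cigarettes/day).  Every pipeline
stage — validation, indicator derivation, weighted estimation, ranking and
two-level regression — can be exercised against closed-form expected
values, because the generating process is built from fully enumerable
discrete distributions:

* Sociodemographic covariates are drawn **mutually independently** with
  fixed marginals, and independently of country.  Under a product design
  the population least-squares coefficient of each factor level equals the
  marginal mean difference against the factor's reference level, whatever
  the interactions in the true mean surface; this is what makes the
  regression truths below exact rather than approximate.
* Smoking status follows an exactly specified two-level logistic model:
  P(current | x, country) = expit(a_j + x'b) with the configured log
  odds-ratios b, and country intercepts a_j solved by exact enumeration so
  that each country's marginal current-smoking probability equals its
  configured target.  Former smoking is modelled the same way among
  non-current respondents.
* Smoking history is age-driven: starting age from a truncated discrete
  bell on 12-35, and, for former smokers, integer years since quitting
  drawn from a mixture of a "recent quitter" binomial on 0-10 and a
  "long-quit" uniform on 11-30 (so a realistic majority of former smokers
  carry a fully discounted history).
* Cigarettes/day is gamma distributed (right-skewed, exact mean) with a
  mean that factorizes over country and covariate levels; the per-level
  multipliers for current and, separately, former smokers are calibrated
  by exact enumeration so that the marginal mean differences in pack-years
  and discounted pack-years reproduce the configured regression
  coefficients exactly, and country-level means follow the configured
  country pattern.

Weights are population-share over sample-share times mean-one lognormal
noise, so population-weighted estimates target the configured country
mixture.  A configurable fraction of rows is corrupted (missing answers,
inconsistent histories) to exercise the exclusion paths; corruption is
completely at random, leaving post-exclusion expectations unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats

from .indicators import DONT_KNOW, MICRODATA_COLUMNS

FACTORS = (
    "sex",
    "age_band",
    "education_end",
    "paying_bills",
    "residence",
    "occupation",
    "marital",
)

FACTOR_LEVELS: Mapping[str, tuple] = {
    "sex": ("male", "female"),
    "age_band": ("15_24", "25_34", "35_44", "45_54", "55_64", "65_74", "75_plus"),
    "education_end": ("le15", "16_19", "ge20", "still_studying"),
    "paying_bills": ("most_of_time", "time_to_time", "almost_never"),
    "residence": ("rural", "small_town", "large_town"),
    "occupation": ("employed", "unemployed", "not_working"),
    "marital": ("single_no_child", "single_child", "multi_no_child", "multi_child"),
}

_AGE_BAND_RANGES = {
    "15_24": (15, 24),
    "25_34": (25, 34),
    "35_44": (35, 44),
    "45_54": (45, 54),
    "55_64": (55, 64),
    "65_74": (65, 74),
    "75_plus": (75, 90),
}

#: default covariate marginals, loosely matching an adult EU sample
DEFAULT_MARGINALS: Mapping[str, Mapping[str, float]] = {
    "sex": {"male": 0.48, "female": 0.52},
    "age_band": {
        "15_24": 0.13, "25_34": 0.15, "35_44": 0.16, "45_54": 0.17,
        "55_64": 0.16, "65_74": 0.13, "75_plus": 0.10,
    },
    "education_end": {"le15": 0.18, "16_19": 0.42, "ge20": 0.32, "still_studying": 0.08},
    "paying_bills": {"most_of_time": 0.09, "time_to_time": 0.21, "almost_never": 0.70},
    "residence": {"rural": 0.32, "small_town": 0.39, "large_town": 0.29},
    "occupation": {"employed": 0.50, "unemployed": 0.07, "not_working": 0.43},
    "marital": {
        "single_no_child": 0.22, "single_child": 0.05,
        "multi_no_child": 0.45, "multi_child": 0.28,
    },
}

#: log odds-ratios of current smoking (reference levels 0)
DEFAULT_STATUS_LOG_OR: Mapping[str, Mapping[str, float]] = {
    "sex": {"female": np.log(0.57)},
    "age_band": {
        "25_34": np.log(1.00), "35_44": np.log(0.87), "45_54": np.log(0.86),
        "55_64": np.log(0.63), "65_74": np.log(0.31), "75_plus": np.log(0.13),
    },
    "education_end": {"16_19": np.log(1.01), "ge20": np.log(0.61), "still_studying": np.log(0.40)},
    "paying_bills": {"time_to_time": np.log(0.76), "almost_never": np.log(0.52)},
    "residence": {"small_town": np.log(1.06), "large_town": np.log(1.11)},
    "occupation": {"unemployed": np.log(1.38), "not_working": np.log(1.00)},
    "marital": {
        "single_child": np.log(1.22), "multi_no_child": np.log(0.78), "multi_child": np.log(0.67),
    },
}

#: log odds-ratios of former smoking among non-current respondents
#: (no published analogue; plausible pattern with a strong age gradient)
DEFAULT_FORMER_LOG_OR: Mapping[str, Mapping[str, float]] = {
    "sex": {"female": np.log(0.80)},
    "age_band": {
        "25_34": np.log(2.0), "35_44": np.log(3.0), "45_54": np.log(4.5),
        "55_64": np.log(7.0), "65_74": np.log(10.0), "75_plus": np.log(12.0),
    },
    "education_end": {"16_19": 0.10, "ge20": 0.20, "still_studying": -0.50},
    "paying_bills": {"time_to_time": 0.10, "almost_never": 0.30},
    "residence": {"small_town": 0.00, "large_town": 0.10},
    "occupation": {"unemployed": -0.10, "not_working": 0.30},
    "marital": {"single_child": 0.00, "multi_no_child": 0.20, "multi_child": 0.10},
}

#: additive effects on mean pack-years (exact regression estimands)
DEFAULT_PY_EFFECTS: Mapping[str, Mapping[str, float]] = {
    "sex": {"female": -7.5},
    "age_band": {"25_34": 3.1, "35_44": 6.1, "45_54": 9.7, "55_64": 12.4, "65_74": 9.2, "75_plus": 6.3},
    "education_end": {"16_19": -1.2, "ge20": -3.7, "still_studying": -5.9},
    "paying_bills": {"time_to_time": -1.9, "almost_never": -3.8},
    "residence": {"small_town": 0.0, "large_town": 0.5},
    "occupation": {"unemployed": 2.3, "not_working": 2.7},
    "marital": {"single_child": 0.4, "multi_no_child": -0.9, "multi_child": -1.3},
}

#: additive effects on mean discounted pack-years
DEFAULT_DPY_EFFECTS: Mapping[str, Mapping[str, float]] = {
    "sex": {"female": -4.1},
    "age_band": {"25_34": 3.0, "35_44": 6.3, "45_54": 8.1, "55_64": 8.7, "65_74": 4.7, "75_plus": 0.9},
    "education_end": {"16_19": -0.6, "ge20": -2.8, "still_studying": -3.6},
    "paying_bills": {"time_to_time": -2.1, "almost_never": -3.9},
    "residence": {"small_town": 0.2, "large_town": 0.6},
    "occupation": {"unemployed": 2.1, "not_working": 1.2},
    "marital": {"single_child": 0.0, "multi_no_child": -1.6, "multi_child": -2.0},
}

# The sex anchors tie the additive sex gaps to the corresponding relative
# gaps (49% of the male pack-years mean, 40% of the male discounted mean),
# which pins the male marginal means and hence the population level.
DEFAULT_PY_MALE_MEAN = 7.5 / 0.49
DEFAULT_DPY_MALE_MEAN = 4.1 / 0.40


@dataclass(frozen=True)
class CountryScenario:
    """Per-country targets: population share, status mix, burden levels and
    an (illustrative) tobacco-control score trajectory."""

    code: str
    pop_share: float
    p_current: float
    p_former: float
    pack_years: float  # relative country pattern; rescaled to the population level
    disc_pack_years: float
    tcs_scores: tuple[tuple[int, float], ...]


def _tcs(avg: float, croatia: bool = False) -> tuple[tuple[int, float], ...]:
    # deterministic per-year spread around the target average (mean exact)
    if croatia:
        return ((2013, avg - 1.0), (2016, avg + 1.0))
    offsets = (-4.0, -2.0, 0.0, 2.0, 4.0)
    return tuple(zip((2005, 2007, 2010, 2013, 2016), (avg + o for o in offsets)))


# population shares from 2017 country populations (millions, normalized in
# code); current smoking and the pack-years patterns follow the 2017
# Eurobarometer country estimates; former-smoking targets are synthetic,
# anchored so France/Ireland ever-smoking hit 57.4%/37.5% and the
# population-weighted EU ever prevalence is 46.5%.  TCS trajectories are
# synthetic illustrative values.
DEFAULT_COUNTRIES: tuple[CountryScenario, ...] = tuple(
    CountryScenario(code, pop, cur, fmr, py, dpy, _tcs(tcs_avg, code == "HR"))
    for code, pop, cur, fmr, py, dpy, tcs_avg in [
        ("AT", 8.80, 0.283, 0.204, 10.6, 7.4, 35.0),
        ("BE", 11.35, 0.192, 0.233, 7.8, 4.6, 49.0),
        ("BG", 7.10, 0.361, 0.117, 8.9, 7.0, 38.0),
        ("HR", 4.15, 0.353, 0.175, 11.9, 8.9, 39.0),
        ("CY", 0.85, 0.275, 0.155, 10.2, 6.7, 39.0),
        ("CZ", 10.59, 0.289, 0.175, 8.3, 6.1, 34.0),
        ("DK", 5.75, 0.186, 0.301, 8.2, 4.7, 46.0),
        ("EE", 1.32, 0.233, 0.194, 5.7, 4.1, 42.0),
        ("FI", 5.50, 0.201, 0.262, 6.7, 4.1, 52.0),
        ("FR", 67.00, 0.359, 0.215, 9.9, 7.0, 56.0),
        ("DE", 82.80, 0.258, 0.223, 8.8, 5.6, 36.0),
        ("EL", 10.77, 0.366, 0.214, 13.9, 10.0, 37.0),
        ("HU", 9.80, 0.266, 0.136, 8.1, 6.0, 44.0),
        ("IE", 4.78, 0.194, 0.181, 6.4, 4.2, 66.0),
        ("IT", 60.60, 0.246, 0.175, 7.6, 4.9, 47.0),
        ("LV", 1.95, 0.322, 0.155, 7.4, 5.7, 40.0),
        ("LT", 2.85, 0.291, 0.126, 5.8, 4.5, 41.0),
        ("LU", 0.59, 0.210, 0.243, 7.0, 4.6, 38.0),
        ("MT", 0.46, 0.240, 0.175, 10.3, 6.1, 52.0),
        ("NL", 17.08, 0.195, 0.291, 7.3, 4.2, 50.0),
        ("PL", 37.97, 0.298, 0.155, 8.7, 6.4, 43.0),
        ("PT", 10.31, 0.256, 0.146, 5.2, 4.8, 43.0),
        ("RO", 19.64, 0.280, 0.097, 7.2, 5.5, 45.0),
        ("SK", 5.44, 0.264, 0.136, 5.7, 4.3, 39.0),
        ("SI", 2.07, 0.279, 0.194, 9.4, 6.1, 44.0),
        ("ES", 46.53, 0.275, 0.185, 8.6, 5.0, 48.0),
        ("SE", 10.00, 0.072, 0.330, 6.5, 2.2, 51.0),
        ("UK", 65.80, 0.175, 0.253, 6.8, 4.2, 74.0),
    ]
)


@dataclass(frozen=True)
class SyntheticConfig:
    countries: tuple[CountryScenario, ...] = DEFAULT_COUNTRIES
    n_per_country: int = 1000
    seed: int = 0
    corrupt_fraction: float = 0.02
    covariate_marginals: Mapping = field(default_factory=lambda: DEFAULT_MARGINALS)
    status_log_or: Mapping = field(default_factory=lambda: DEFAULT_STATUS_LOG_OR)
    former_log_or: Mapping = field(default_factory=lambda: DEFAULT_FORMER_LOG_OR)
    py_effects: Mapping = field(default_factory=lambda: DEFAULT_PY_EFFECTS)
    dpy_effects: Mapping = field(default_factory=lambda: DEFAULT_DPY_EFFECTS)
    py_male_mean: float = DEFAULT_PY_MALE_MEAN
    dpy_male_mean: float = DEFAULT_DPY_MALE_MEAN
    # smoking-history distributions
    start_age_low: int = 12
    start_age_high: int = 35
    start_age_peak: float = 17.0
    start_age_spread: float = 4.5
    quit_recent_p: float = 0.5  # binomial parameter, recent quitters (0-10 y)
    long_quit_share: float = 0.55  # share of former smokers who quit > 10 y ago
    cpd_shape: float = 3.0  # gamma shape of cigarettes/day
    weight_noise_sd: float = 0.3  # lognormal sigma of within-country weight noise

    def validate(self) -> None:
        codes = [c.code for c in self.countries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate country codes")
        for c in self.countries:
            if not (0.0 <= c.p_current and 0.0 <= c.p_former and c.p_current + c.p_former <= 1.0):
                raise ValueError(f"{c.code}: P(current)+P(former) must lie in [0, 1]")
            if c.pop_share <= 0:
                raise ValueError(f"{c.code}: population share must be positive")
        for factor in FACTORS:
            probs = self.covariate_marginals[factor]
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"marginals of {factor!r} do not sum to 1")
        if not 0.0 <= self.corrupt_fraction < 1.0:
            raise ValueError("corrupt_fraction must be in [0, 1)")
        if not 0.0 < self.quit_recent_p < 1.0 or not 0.0 <= self.long_quit_share < 1.0:
            raise ValueError("quit distribution parameters out of range")
        if self.n_per_country < 1:
            raise ValueError("n_per_country must be positive")

    def cache_key(self) -> str:
        return yaml.safe_dump(_config_dict(self), sort_keys=True)


def _config_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["countries"] = [dataclasses.asdict(c) for c in config.countries]
    for c in d["countries"]:
        c["tcs_scores"] = [[int(y), float(s)] for y, s in c["tcs_scores"]]
    for key in ("covariate_marginals", "status_log_or", "former_log_or", "py_effects", "dpy_effects"):
        d[key] = {f: {lvl: float(v) for lvl, v in levels.items()} for f, levels in d[key].items()}
    return d


def config_to_yaml(config: SyntheticConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)


def config_from_yaml(path) -> SyntheticConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["countries"] = tuple(
        CountryScenario(
            code=c["code"], pop_share=c["pop_share"], p_current=c["p_current"],
            p_former=c["p_former"], pack_years=c["pack_years"],
            disc_pack_years=c["disc_pack_years"],
            tcs_scores=tuple((int(y), float(s)) for y, s in c["tcs_scores"]),
        )
        for c in d["countries"]
    )
    return SyntheticConfig(**d)


def tcs_long_table(config: SyntheticConfig) -> pd.DataFrame:
    """Long-format (country, year, score) table from the configured trajectories."""
    rows = [
        {"country": c.code, "year": year, "score": score}
        for c in config.countries
        for year, score in c.tcs_scores
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact enumeration machinery
# ---------------------------------------------------------------------------


def _effect_vector(config_effects: Mapping, factor: str) -> np.ndarray:
    levels = FACTOR_LEVELS[factor]
    table = config_effects.get(factor, {})
    return np.array([table.get(level, 0.0) for level in levels])


class Calibration:
    """Exact enumeration over the covariate cell grid x countries.

    Solves (i) country intercepts of the status models against the
    configured prevalence targets, and (ii) per-level and per-country
    cigarettes/day multipliers against the configured pack-years and
    discounted pack-years marginal means, by iterative proportional
    fitting.  All quantities are exact expectations of the sampling
    process, so a converged calibration makes the configured regression
    effects exact estimands.
    """

    MAX_SWEEPS = 400
    TOL = 1e-11

    def __init__(self, config: SyntheticConfig):
        config.validate()
        self.config = config
        self.codes = [c.code for c in config.countries]
        self.J = len(self.codes)
        self._build_cells()
        self._build_history_tables()
        self._calibrate_status()
        self._calibrate_intensity()

    # -- cell grid ----------------------------------------------------------

    def _build_cells(self):
        config = self.config
        shapes = [len(FACTOR_LEVELS[f]) for f in FACTORS]
        grids = np.meshgrid(*[np.arange(s) for s in shapes], indexing="ij")
        self.cell_levels = {f: g.ravel() for f, g in zip(FACTORS, grids)}
        self.n_cells = self.cell_levels["sex"].size

        prob = np.ones(self.n_cells)
        lp_cur = np.zeros(self.n_cells)
        lp_fmr = np.zeros(self.n_cells)
        for factor in FACTORS:
            levels = FACTOR_LEVELS[factor]
            marg = np.array([config.covariate_marginals[factor][lvl] for lvl in levels])
            idx = self.cell_levels[factor]
            prob *= marg[idx]
            lp_cur += _effect_vector(config.status_log_or, factor)[idx]
            lp_fmr += _effect_vector(config.former_log_or, factor)[idx]
        self.cell_prob = prob
        self.lp_cur = lp_cur
        self.lp_fmr = lp_fmr
        self.band_of_cell = self.cell_levels["age_band"]

    # -- smoking-history expectations ----------------------------------------

    def _build_history_tables(self):
        config = self.config
        lo, hi = config.start_age_low, config.start_age_high
        support = np.arange(lo, hi + 1)
        w = np.exp(-0.5 * ((support - config.start_age_peak) / config.start_age_spread) ** 2)
        self._start_support = support
        self._start_w = w / w.sum()
        self._start_cdf = np.cumsum(self._start_w)

        max_age = max(b for _, b in _AGE_BAND_RANGES.values())
        # mean starting age given the cap min(hi, cap)
        e_start = {}
        for cap in range(lo + 1, max_age + 1):
            m = support <= min(hi, cap)
            e_start[cap] = float(np.average(support[m], weights=self._start_w[m]))
        self._e_start = e_start

        ages = np.arange(15, max_age + 1)
        el_cur = np.array([a - e_start[min(hi, a)] for a in ages])
        el_fmr = np.zeros(len(ages))
        el_disc = np.zeros(len(ages))
        for i, a in enumerate(ages):
            pmf = self._quit_pmf(a)
            q = np.arange(len(pmf))
            lengths = np.array([(a - qq) - e_start[min(hi, a - qq)] for qq in q])
            disc = np.maximum(0.0, 1.0 - q / 10.0)
            el_fmr[i] = pmf @ lengths
            el_disc[i] = pmf @ (disc * lengths)
        self._ages = ages
        self._el_cur_age, self._el_fmr_age, self._el_disc_age = el_cur, el_fmr, el_disc

        bands = list(FACTOR_LEVELS["age_band"])
        self.el_cur_band = np.zeros(len(bands))
        self.el_fmr_band = np.zeros(len(bands))
        self.el_disc_band = np.zeros(len(bands))
        for b, band in enumerate(bands):
            a0, a1 = _AGE_BAND_RANGES[band]
            m = (ages >= a0) & (ages <= a1)
            self.el_cur_band[b] = el_cur[m].mean()  # age uniform within band
            self.el_fmr_band[b] = el_fmr[m].mean()
            self.el_disc_band[b] = el_disc[m].mean()

    def _quit_pmf(self, age: int) -> np.ndarray:
        """Distribution of integer years since quitting, age ``age``.

        Support 0..min(30, age-13): quitting age stays >= 13 so a starting
        age >= 12 always exists.  Mixture of a truncated Binomial(10, p)
        (recent quitters) and a uniform 11-30 block (long quit), the latter
        only available from age 24.
        """
        config = self.config
        cut = min(30, age - 13)
        pmf = np.zeros(cut + 1)
        short_cut = min(10, cut)
        short = stats.binom.pmf(np.arange(short_cut + 1), 10, config.quit_recent_p)
        short /= short.sum()
        if cut >= 11:
            pmf[: short_cut + 1] = (1.0 - config.long_quit_share) * short
            pmf[11 : cut + 1] = config.long_quit_share / (cut - 10)
        else:
            pmf[: short_cut + 1] = short
        return pmf

    # -- status calibration ---------------------------------------------------

    def _calibrate_status(self):
        config = self.config
        self.a_country = np.full(self.J, -np.inf)
        self.c_country = np.full(self.J, -np.inf)
        prob = self.cell_prob
        for j, country in enumerate(config.countries):
            if country.p_current > 0:
                target = country.p_current
                self.a_country[j] = optimize.brentq(
                    lambda a: prob @ special.expit(a + self.lp_cur) - target, -40, 40, xtol=1e-13
                )
        self.p_cur = special.expit(self.a_country[None, :] + self.lp_cur[:, None])  # (C, J)
        for j, country in enumerate(config.countries):
            if country.p_former > 0:
                not_cur = prob * (1.0 - self.p_cur[:, j])
                target = country.p_former
                self.c_country[j] = optimize.brentq(
                    lambda c: not_cur @ special.expit(c + self.lp_fmr) - target, -40, 40, xtol=1e-13
                )
        self.p_fmr = (1.0 - self.p_cur) * special.expit(
            self.c_country[None, :] + self.lp_fmr[:, None]
        )

    # -- intensity calibration -------------------------------------------------

    def _level_targets(self) -> tuple[dict, dict]:
        """Absolute marginal-mean targets per (factor, level) and country."""
        config = self.config
        py, dpy = {}, {}
        female_share = config.covariate_marginals["sex"]["female"]
        py_female = config.py_male_mean + config.py_effects["sex"]["female"]
        dpy_female = config.dpy_male_mean + config.dpy_effects["sex"]["female"]
        py["sex"] = np.array([config.py_male_mean, py_female])
        dpy["sex"] = np.array([config.dpy_male_mean, dpy_female])
        pop_py = (1 - female_share) * config.py_male_mean + female_share * py_female
        pop_dpy = (1 - female_share) * config.dpy_male_mean + female_share * dpy_female
        self.pop_py, self.pop_dpy = pop_py, pop_dpy
        for factor in FACTORS:
            if factor == "sex":
                continue
            levels = FACTOR_LEVELS[factor]
            marg = np.array([config.covariate_marginals[factor][lvl] for lvl in levels])
            for name, store, effects, pop in (
                ("py", py, config.py_effects, pop_py),
                ("dpy", dpy, config.dpy_effects, pop_dpy),
            ):
                beta = _effect_vector(effects, factor)
                ref = pop - marg @ beta
                store[factor] = ref + beta
        # country targets: configured pattern rescaled so the equal-weight
        # mean across countries matches the population mean
        table_py = np.array([c.pack_years for c in config.countries])
        table_dpy = np.array([c.disc_pack_years for c in config.countries])
        ever = np.array([c.p_current + c.p_former for c in config.countries])
        py["country"] = np.where(ever > 0, table_py, 0.0)
        dpy["country"] = np.where(ever > 0, table_dpy, 0.0)
        if py["country"].mean() > 0:
            py["country"] = py["country"] * (pop_py / py["country"].mean())
        if dpy["country"].mean() > 0:
            dpy["country"] = dpy["country"] * (pop_dpy / dpy["country"].mean())
        return py, dpy

    def _calibrate_intensity(self):
        targets_py, targets_dpy = self._level_targets()
        self.targets_py, self.targets_dpy = targets_py, targets_dpy
        prob = self.cell_prob
        band = self.band_of_cell
        # fixed per (cell, country) building blocks, already weighted by the
        # cell probability
        cur_block = prob[:, None] * self.p_cur * self.el_cur_band[band][:, None] / 20.0
        fmr_len = prob[:, None] * self.p_fmr * self.el_fmr_band[band][:, None] / 20.0
        fmr_disc = prob[:, None] * self.p_fmr * self.el_disc_band[band][:, None] / 20.0

        g = {f: np.ones(len(FACTOR_LEVELS[f])) for f in FACTORS}  # cpd multipliers
        r = {f: np.ones(len(FACTOR_LEVELS[f])) for f in FACTORS}  # former/current ratio
        k_country = np.ones(self.J)
        r_country = np.ones(self.J)

        def cellG():
            out = np.ones(self.n_cells)
            for f in FACTORS:
                out *= g[f][self.cell_levels[f]]
            return out

        def cellR():
            out = np.ones(self.n_cells)
            for f in FACTORS:
                out *= r[f][self.cell_levels[f]]
            return out

        dpy_infeasible = set()

        def solve(A, B, C, t_py, t_dpy, r_old, margin):
            # PY = g (A + r B), DPY = g (A + r C): closed form per level
            if A + B <= 0 or t_py <= 0:
                return 1.0, r_old  # margin carries no smokers or no burden
            if A <= 1e-10 * B:
                # no current smokers in this margin: the former/current
                # intensity ratio cannot steer the discount mix, so only the
                # pack-years margin is matched
                dpy_infeasible.add(margin)
                return float(t_py / (A + B)), 1.0
            R = t_py / max(t_dpy, 1e-12)
            denom = B - R * C
            if denom <= 0:
                r_new = 1e4  # target ratio at (or beyond) the feasible edge
            else:
                r_new = A * (R - 1.0) / denom
            r_new = float(np.clip(r_new, 1e-6, 1e4))
            g_new = t_py / (A + r_new * B)
            return float(g_new), r_new

        for sweep in range(self.MAX_SWEEPS):
            max_change = 0.0
            G, Rc = cellG(), cellR()
            for f in FACTORS:
                idx = self.cell_levels[f]
                for lvl in range(len(FACTOR_LEVELS[f])):
                    mask = idx == lvl
                    p_lvl = prob[mask].sum()
                    Gm = G[mask] / g[f][lvl]
                    GRm = Gm * Rc[mask] / r[f][lvl]
                    scale = 1.0 / (self.J * p_lvl)
                    A = scale * (Gm @ (cur_block[mask] @ k_country))
                    B = scale * (GRm @ (fmr_len[mask] @ (k_country * r_country)))
                    C = scale * (GRm @ (fmr_disc[mask] @ (k_country * r_country)))
                    g_new, r_new = solve(
                        A, B, C, targets_py[f][lvl], targets_dpy[f][lvl], r[f][lvl], (f, lvl)
                    )
                    max_change = max(
                        max_change, abs(g_new - g[f][lvl]) / g[f][lvl], abs(r_new - r[f][lvl]) / r[f][lvl]
                    )
                    G[mask] *= g_new / g[f][lvl]
                    Rc[mask] *= r_new / r[f][lvl]
                    g[f][lvl], r[f][lvl] = g_new, r_new
            GR = G * Rc
            for j in range(self.J):
                # country update: PY_j = k (A + r B0), former part B0/C0 at r=1
                A = G @ cur_block[:, j]
                B0 = GR @ fmr_len[:, j]
                C0 = GR @ fmr_disc[:, j]
                k_new, r_new = solve(
                    A, B0, C0, targets_py["country"][j], targets_dpy["country"][j],
                    r_country[j], ("country", j),
                )
                max_change = max(
                    max_change,
                    abs(k_new - k_country[j]) / k_country[j],
                    abs(r_new - r_country[j]) / r_country[j],
                )
                k_country[j], r_country[j] = k_new, r_new
            if max_change < self.TOL:
                break
        self.g, self.r = g, r
        self.k_country, self.r_country = k_country, r_country
        self.sweeps = sweep + 1
        self.dpy_infeasible = dpy_infeasible
        self.dpy_exact = not dpy_infeasible
        self._verify()

    def _verify(self):
        py, dpy = self.level_means()
        err = 0.0
        for f in FACTORS:
            t = self.targets_py[f]
            active = t > 1e-9
            err = max(err, np.max(np.abs(py[f][active] - t[active]) / t[active], initial=0.0))
            if not self.dpy_exact:
                continue  # degenerate scenario: only pack-years margins pinned
            t = self.targets_dpy[f]
            active = t > 1e-9
            err = max(err, np.max(np.abs(dpy[f][active] - t[active]) / t[active], initial=0.0))
        self.max_rel_error = err
        if err > 1e-6:
            raise RuntimeError(
                f"intensity calibration did not converge (max rel error {err:.2e}); "
                "the configured effect pattern is infeasible for this scenario"
            )

    # -- exact expectations ----------------------------------------------------

    def _cell_arrays(self):
        G = np.ones(self.n_cells)
        Rc = np.ones(self.n_cells)
        for f in FACTORS:
            G *= self.g[f][self.cell_levels[f]]
            Rc *= self.r[f][self.cell_levels[f]]
        return G, Rc

    def cpd_mean(self, cells: Mapping[str, np.ndarray], country_idx: np.ndarray, former: np.ndarray):
        """Mean cigarettes/day for sampled respondents (vectorized)."""
        kappa = self.k_country[country_idx]
        rho = self.r_country[country_idx]
        for f in FACTORS:
            kappa = kappa * self.g[f][cells[f]]
            rho = rho * self.r[f][cells[f]]
        return np.where(former, kappa * rho, kappa)

    def indicator_means(self) -> pd.DataFrame:
        """Exact per-country expectations of the five indicators."""
        G, Rc = self._cell_arrays()
        prob, band = self.cell_prob, self.band_of_cell
        rows = []
        for j, code in enumerate(self.codes):
            pc, pf = self.p_cur[:, j], self.p_fmr[:, j]
            kappa = G * self.k_country[j]
            rho = Rc * self.r_country[j]
            length = prob @ (pc * self.el_cur_band[band] + pf * self.el_fmr_band[band])
            py = prob @ (kappa * (pc * self.el_cur_band[band] + rho * pf * self.el_fmr_band[band])) / 20.0
            dpy = prob @ (kappa * (pc * self.el_cur_band[band] + rho * pf * self.el_disc_band[band])) / 20.0
            rows.append(
                {
                    "country": code,
                    "is_current": prob @ pc,
                    "is_ever": prob @ (pc + pf),
                    "length_years": length,
                    "pack_years": py,
                    "discounted_pack_years": dpy,
                }
            )
        return pd.DataFrame(rows)

    def level_means(self) -> tuple[dict, dict]:
        """Exact equal-country-weight marginal means of pack-years and
        discounted pack-years per factor level."""
        G, Rc = self._cell_arrays()
        prob, band = self.cell_prob, self.band_of_cell
        cur = (prob * G * self.el_cur_band[band])[:, None] * self.p_cur / 20.0
        fl = (prob * G * Rc * self.el_fmr_band[band])[:, None] * self.p_fmr / 20.0
        fd = (prob * G * Rc * self.el_disc_band[band])[:, None] * self.p_fmr / 20.0
        kr = self.k_country * self.r_country
        py_cell = cur @ self.k_country + fl @ kr
        dpy_cell = cur @ self.k_country + fd @ kr
        py, dpy = {}, {}
        for f in FACTORS:
            idx = self.cell_levels[f]
            n_lvl = len(FACTOR_LEVELS[f])
            p_lvl = np.bincount(idx, weights=prob, minlength=n_lvl)
            py[f] = np.bincount(idx, weights=py_cell, minlength=n_lvl) / (self.J * p_lvl)
            dpy[f] = np.bincount(idx, weights=dpy_cell, minlength=n_lvl) / (self.J * p_lvl)
        return py, dpy


_CALIBRATION_CACHE: dict[str, Calibration] = {}


def calibrate(config: SyntheticConfig) -> Calibration:
    key = config.cache_key()
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = Calibration(config)
    return _CALIBRATION_CACHE[key]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def generate(config: SyntheticConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw a microdata frame from the configured scenario.

    Reproducible: the same config and seed give identical output.  ``seed``
    overrides ``config.seed`` when given.
    """
    cal = calibrate(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_per_country
    total = n * cal.J

    country_idx = np.repeat(np.arange(cal.J), n)
    cells = {}
    for f in FACTORS:
        levels = FACTOR_LEVELS[f]
        p = np.array([config.covariate_marginals[f][lvl] for lvl in levels])
        cells[f] = rng.choice(len(levels), size=total, p=p)

    band_lo = np.array([_AGE_BAND_RANGES[b][0] for b in FACTOR_LEVELS["age_band"]])
    band_hi = np.array([_AGE_BAND_RANGES[b][1] for b in FACTOR_LEVELS["age_band"]])
    lo, hi = band_lo[cells["age_band"]], band_hi[cells["age_band"]]
    age = lo + (rng.random(total) * (hi - lo + 1)).astype(int)

    lp_cur = cal.a_country[country_idx].copy()
    lp_fmr = cal.c_country[country_idx].copy()
    for f in FACTORS:
        lp_cur += _effect_vector(config.status_log_or, f)[cells[f]]
        lp_fmr += _effect_vector(config.former_log_or, f)[cells[f]]
    with np.errstate(over="ignore"):
        current = rng.random(total) < special.expit(lp_cur)
        former = ~current & (rng.random(total) < special.expit(lp_fmr))
    ever = current | former

    # years since quitting (former smokers)
    quit_years = np.zeros(total, dtype=int)
    if former.any():
        af = age[former]
        cut = np.minimum(30, af - 13)
        long_ok = cut >= 11
        is_long = long_ok & (rng.random(former.sum()) < config.long_quit_share)
        # long quit: uniform integers on 11..cut
        q = np.zeros(former.sum(), dtype=int)
        if is_long.any():
            span = cut[is_long] - 11 + 1
            q[is_long] = 11 + (rng.random(is_long.sum()) * span).astype(int)
        # recent quit: truncated Binomial(10, p) via inverse CDF
        short = ~is_long
        if short.any():
            pmf = stats.binom.pmf(np.arange(11), 10, config.quit_recent_p)
            cdf = np.cumsum(pmf)
            caps = np.minimum(10, cut[short])
            u = rng.random(short.sum()) * cdf[caps]
            q[short] = np.searchsorted(cdf, u, side="right")
        quit_years[former] = q

    # starting age: base bell truncated at min(start_age_high, latest possible)
    start_age = np.full(total, np.nan)
    if ever.any():
        cap_age = np.where(former, age - quit_years, age)[ever]
        caps = np.minimum(config.start_age_high, cap_age)
        cap_cdf = cal._start_cdf[np.searchsorted(cal._start_support, caps)]
        u = rng.random(ever.sum()) * cap_cdf
        start_age[ever] = cal._start_support[np.searchsorted(cal._start_cdf, u, side="right")]

    quit_age = np.full(total, np.nan)
    quit_age[former] = age[former] - quit_years[former]

    cpd = np.full(total, np.nan)
    if ever.any():
        mean = cal.cpd_mean({f: cells[f][ever] for f in FACTORS}, country_idx[ever], former[ever])
        cpd[ever] = rng.gamma(config.cpd_shape, mean / config.cpd_shape)

    shares = np.array([c.pop_share for c in config.countries])
    shares = shares / shares.sum()
    sd = config.weight_noise_sd
    weight = shares[country_idx] * cal.J * np.exp(rng.normal(-0.5 * sd**2, sd, total))

    status = np.where(current, "current", np.where(former, "former", "never"))
    df = pd.DataFrame(
        {
            "respondent_id": [f"{cal.codes[j]}{i:06d}" for i, j in enumerate(country_idx)],
            "country": np.array(cal.codes)[country_idx],
            "weight": weight,
            "age": age,
            "sex": np.array(FACTOR_LEVELS["sex"])[cells["sex"]],
            "education_end": np.array(FACTOR_LEVELS["education_end"])[cells["education_end"]],
            "paying_bills": np.array(FACTOR_LEVELS["paying_bills"])[cells["paying_bills"]],
            "residence": np.array(FACTOR_LEVELS["residence"])[cells["residence"]],
            "occupation": np.array(FACTOR_LEVELS["occupation"])[cells["occupation"]],
            "marital": np.array(FACTOR_LEVELS["marital"])[cells["marital"]],
            "smoking_status": status,
            "start_age": start_age,
            "quit_age": quit_age,
            "cigs_per_day": cpd,
            "age_band": np.array(FACTOR_LEVELS["age_band"])[cells["age_band"]],
        }
    )

    if config.corrupt_fraction > 0:
        corrupt = rng.random(total) < config.corrupt_fraction
        flip = rng.random(total) < 0.5
        idx = df.index[corrupt]
        for i in idx:
            s = df.at[i, "smoking_status"]
            if s == "never":
                df.at[i, "paying_bills"] = DONT_KNOW
            elif s == "current":
                if flip[i]:
                    df.at[i, "start_age"] = np.nan
                else:
                    df.at[i, "cigs_per_day"] = np.nan
            else:
                if flip[i]:
                    df.at[i, "quit_age"] = max(11.0, df.at[i, "start_age"] - 1.0)
                else:
                    df.at[i, "start_age"] = np.nan
    return df[list(MICRODATA_COLUMNS) + ["age_band"]]


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------


def truth_table(config: SyntheticConfig) -> dict:
    """Exact (analytic, enumeration-based) expectations of the scenario.

    Returns a mapping with:

    ``country``
        per-country expected values of the five indicators;
    ``eu_weighted``
        population-share-weighted EU expectations of the five indicators;
    ``sex_weighted``
        population-share-weighted expectations by sex (for descriptive
        male/female gap checks);
    ``regression``
        the exact estimands of the two-level models: odds ratios of
        current smoking and additive effects on pack-years and discounted
        pack-years, keyed by model term name (e.g. ``sex[female]``).
    """
    cal = calibrate(config)
    country = cal.indicator_means()
    shares = np.array([c.pop_share for c in config.countries])
    shares = shares / shares.sum()
    eu = {
        col: float(shares @ country[col].to_numpy())
        for col in ("is_current", "is_ever", "length_years", "pack_years", "discounted_pack_years")
    }

    # weighted sex marginals: same enumeration, pop-share country weights
    G, Rc = cal._cell_arrays()
    prob, band = cal.cell_prob, cal.band_of_cell
    sex_idx = cal.cell_levels["sex"]
    sex_rows = []
    for s, sex in enumerate(FACTOR_LEVELS["sex"]):
        m = sex_idx == s
        p_s = prob[m].sum()
        w_cell = prob[m] / p_s
        pc, pf = cal.p_cur[m], cal.p_fmr[m]
        kappa = G[m][:, None] * cal.k_country[None, :]
        rho = Rc[m][:, None] * cal.r_country[None, :]
        elc = cal.el_cur_band[band[m]][:, None]
        elf = cal.el_fmr_band[band[m]][:, None]
        eld = cal.el_disc_band[band[m]][:, None]
        per_country_py = w_cell @ (kappa * (pc * elc + rho * pf * elf)) / 20.0
        per_country_dpy = w_cell @ (kappa * (pc * elc + rho * pf * eld)) / 20.0
        sex_rows.append(
            {
                "sex": sex,
                "is_current": float(shares @ (w_cell @ pc)),
                "is_ever": float(shares @ (w_cell @ (pc + pf))),
                "length_years": float(shares @ (w_cell @ (pc * elc + pf * elf))),
                "pack_years": float(shares @ per_country_py),
                "discounted_pack_years": float(shares @ per_country_dpy),
            }
        )

    regression = {"or_current": {}, "beta_pack_years": {}, "beta_disc_pack_years": {}}
    for f in FACTORS:
        for lvl in FACTOR_LEVELS[f][1:]:
            term = f"{f}[{lvl}]"
            regression["or_current"][term] = float(
                np.exp(config.status_log_or.get(f, {}).get(lvl, 0.0))
            )
            regression["beta_pack_years"][term] = float(config.py_effects.get(f, {}).get(lvl, 0.0))
            regression["beta_disc_pack_years"][term] = float(
                config.dpy_effects.get(f, {}).get(lvl, 0.0)
            )

    return {
        "country": country,
        "eu_weighted": eu,
        "sex_weighted": pd.DataFrame(sex_rows),
        "regression": regression,
        "dpy_effects_exact": cal.dpy_exact,
        "calibration_sweeps": cal.sweeps,
        "calibration_max_rel_error": cal.max_rel_error,
    }
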