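# Methods

## Indicators

Five per-respondent quantities summarize smoking burden: current smoking,
ever smoking (current or former), length of smoking, pack-years, and
discounted pack-years.  Pack-years assume one pack = 20 cigarettes and
that the reported average daily consumption applied over the whole smoking
history (constant-intensity assumption).  Discounted pack-years multiply
pack-years by a factor that falls linearly from 1 to 0 over the first
`horizon` years since quitting (default 10, reflecting the common finding
that former smokers' excess mortality risk approaches never smokers' about
a decade after cessation).  Current smokers keep their full pack-years;
never smokers score 0 on everything, so all means are population means.

Ages are integer years, as questionnaires collect them, so years since
cessation is integer-stepped; the linear discount is evaluated on that
integer difference.  A respondent who quit within the current interview
year (quit age = current age) has zero complete years of cessation and is
not yet discounted.  Alternative decay shapes are out of scope; the
horizon is the only tunable.

Validation excludes, with machine-readable reasons, records with missing
or "don't know" answers, inconsistent histories (start after current age,
quitting before starting), non-positive weights, and under-15 respondents.
Smokers reporting 0 cigarettes/day (e.g. pipe-only users: the status
question covers all combustibles, the intensity question cigarettes only)
stay in the prevalence indicators with pack-years 0 and are counted in a
warning.  Extreme cigarettes/day values are not truncated by default; a
configurable cap exists but is off, since no principled cut-point is
known.

## Survey-weighted estimation

Point estimates are Hajek (weighted-mean) estimators.  The public
microdata schema has one design weight per respondent and no PSU or
stratum identifiers, so linearized design variances cannot be formed;
intervals instead inflate for unequal weighting via the Kish effective
sample size n_eff = (Σw)²/Σw².  Proportions get logit-transformed Wald
intervals on n_eff (Wilson at the 0/1 boundary); means get t intervals
with the weighted variance and n_eff − 1 degrees of freedom.  The method
name is stamped into every output row.  These are approximations: with a
real multi-stage design they understate clustering, which is why interval
bounds carry looser guarantees than point estimates throughout the tests.
All estimates are invariant to rescaling the weights by a positive
constant.  Continuous indicators are reported for the entire population
(never smokers as zeros) by default; a smokers-only scope exists for
diagnostics and is recorded in the output metadata.

## Ranking and correlation

League tables sort countries by descending estimate; rank 1 is the
highest burden.  Ties take the minimum ("competition") rank and the next
rank skips.  Published tables show ties only at the printed precision, so
when reproducing a printed table the ranking runs on the printed
one-decimal values.  Cross-indicator agreement is the Pearson correlation
of country-level estimates, one unweighted point per country — the same
quantity a country-level scatterplot shows.  Correlations use estimates,
never ranks.

## Tobacco Control Scale

Country policy scores (0–100, six components) from the 2005–2016 report
rounds are averaged over the rounds in which a country appears (no
imputation; a country first scored in 2013 averages two rounds) and
bucketed as low < 40 ≤ moderate < 50 ≤ high, with boundary values going to
the higher category because the published intervals have closed lower
bounds.  A score of exactly 0 is classified low.  The packaged default
score table used by the synthetic scenario is an illustrative synthetic
trajectory per country, not a transcription of the published reports.

## Two-level models

Respondents nest in countries via a normal random intercept.  Continuous
indicators use y_ij = x'β + u_j + ε_ij, fitted by REML: for a fixed
variance ratio ψ = σ_u²/σ_ε² the GLS solution reduces to OLS on partially
group-centred data (centring factor 1 − (1 + ψ n_j)^−½), so the REML
criterion is profiled and optimized in one dimension, with the ψ = 0
boundary checked explicitly.  This specialization keeps a full fit on
28 000 rows under 0.3 s, which the simulation studies rely on; unit tests
verify agreement with statsmodels MixedLM (coefficients and SEs) on
correctly specified data.

Binary indicators use logit P(y=1) = x'β + u_j, fitted by maximum
likelihood with the per-country integral evaluated by adaptive
Gauss–Hermite quadrature: 13 nodes centred at each country's conditional
mode and scaled by the local curvature (a Newton inner loop, warm-started
across evaluations).  Thirteen adaptive nodes agree with 25 to ~1e-10 at
these cluster sizes.  The same quadrature rule applied to the derivative
integrands gives an analytic gradient; L-BFGS-B optimizes (β, log σ) and
the observed information comes from central differences of that gradient.
Oracles: the σ→0 limit against single-level logistic regression, a 2×2
contingency-table odds ratio, and R lme4::glmer (nAGQ=13) on
single-covariate data.

Wald 95% CIs are formed on the link scale and exponentiated to odds
ratios.  An estimate exceeding |β| > 15 raises a separation error naming
the offending term.  Fixed-effect factors are treatment-coded with fixed
reference levels (male; 15–24; education ≤15; bills most of the time;
rural; employed; single without children; low TCS); levels absent from the
data get no column.  Models are unweighted by default — design weights
serve the descriptive estimates, models are fit on raw observations — with
a weighted pseudo-likelihood option behind a flag.  Missing covariates
must be excluded listwise upstream; the model refuses data with missing
factor values.

## Synthetic scenario design

The generator's purpose is an end-to-end testbed whose truth is known
exactly, under realistic study conditions: 28 countries, 1000 respondents
per country, population-share design weights with mean-one lognormal
within-country noise, and ~2% deliberately corrupted rows (missing
answers, inconsistent histories) to exercise the exclusion paths;
corruption is completely at random so post-exclusion expectations are
unchanged.

Three structural choices make the truth analytic rather than simulated:

1. **Product covariate design.**  Sociodemographic factors are drawn
   mutually independently, and independently of country.  Under a product
   measure, the population least-squares coefficient of a factor level in
   an additive (dummy) regression equals the marginal mean difference
   against the reference level — regardless of interactions in the true
   mean surface, and also under the mixed model's GLS weighting with
   balanced clusters.  Exact effect calibration therefore only requires
   matching marginal means, which are enumerable: the covariate grid has
   6048 cells, all discrete.
2. **Exactly specified status model.**  P(current | x, country) =
   expit(a_j + x'b) with b the configured log odds-ratios (female
   ln 0.57, unemployed ln 1.38, ...); the country intercepts a_j are
   solved by root-finding on the exact enumeration so each country's
   marginal prevalence hits its target (the 2017 country estimates).
   Former smoking among non-current respondents is modelled the same way
   with a plausible default effect pattern (strong age gradient).
   Country-level tobacco-policy effects are absorbed into the per-country
   prevalence targets rather than modelled separately, so TCS terms have
   no defined truth in the scenario and are excluded from recovery checks.
3. **Calibrated intensity.**  Smoking history is age-driven: starting age
   from a truncated discrete bell on 12–35 (peak 17); for former smokers,
   integer years-since-quit from a mixture of a Binomial(10, 0.5) recent
   block and a uniform 11–30 long-quit block (share 0.55), truncated so
   quitting age stays ≥ 13.  Cigarettes/day is Gamma(shape 3) with a mean
   that factorizes over country and covariate levels, with separate
   multipliers for current and former smokers.  Because pack-years and
   discounted pack-years are both linear in these two multipliers, each
   margin's pair of targets has a closed-form solution, and iterative
   proportional fitting over factors and countries converges to machine
   precision in a few sweeps.  The result: every configured regression
   coefficient (the published effect estimates) is the exact estimand of
   the fitted model, and country-level means follow the configured
   country pattern.

The sex anchors tie the additive sex gaps to the published relative gaps
(pack-years 49% lower among women, discounted pack-years 40% lower), which
fixes the male marginal means at 7.5/0.49 ≈ 15.3 and 4.1/0.40 ≈ 10.25 and
hence the synthetic population mean pack-years at ≈ 11.4 — inside the
observed 2017 country range (5.2–13.9) though above its population mean.
This is deliberate: with independent covariates the additive and relative
gaps must cohere exactly, and these anchors are the only pair that honours
both published magnitudes.  Country-level continuous targets are the
published country pattern proportionally rescaled to that population
level, so the synthetic league-table order matches the published order.
The implied mean cigarettes/day among smokers (~20) is consequently higher
than typical survey values — intensity is derived from the target means,
not set directly.

What the generator does **not** emulate: household/PSU sampling and
nonresponse (weights are noise around population shares), covariate
dependence (real age and education are correlated; independence is what
buys exact truths), item-level missingness patterns (corruption is MCAR),
intensity–duration dependence (cigarettes/day is independent of length
given the cell, with a correlated option available), non-cigarette
products, and any real country's microdata.  Passing recovery tests
therefore demonstrates estimator correctness under a faithful two-level
structure, not agreement with any particular survey's numbers —
reproducing those requires the original microdata deposit, which is not
redistributable with the package.

Degenerate scenarios (e.g. a country with no current smokers) leave too
few degrees of freedom to pin the discounted-pack-years margins; the
calibration then matches pack-years exactly, keeps the former/current
intensity ratio at 1, and flags `dpy_effects_exact = False` in the truth
table rather than failing.

## Numerical choices and test sizes

- Enumeration tolerances: status intercepts to 1e-13 (Brent), intensity
  fitting to relative 1e-11, verified below 1e-6 before any sampling.
- REML profile optimized on log ψ over [−15, 12]; boundary ψ = 0 compared
  explicitly; residual variance below 1e-12 (outcome fits exactly) is
  treated as zero.
- Logistic mode search: damped Newton, step cap 4, tolerance 1e-10;
  log σ bounded in [−7, 3] so the σ→0 boundary is representable.
- Unit and property tests run on a 6-country × 500 scenario (seconds);
  the module-level recovery study uses 30 seeds with a family-wise
  4-MC-SE bound per term (a 2-SE bound across ~40 simultaneous terms
  would false-alarm in most runs); the acceptance recovery study uses the
  full 28 × 1000 scenario over 100 seeds (~4 minutes) and checks the
  three female terms at 2 MC SE with ≥ 90/100 CI coverage.
- The discrete inverse-CDF samplers (start age, years since quit) draw
  from exactly the distributions the enumeration integrates, which is
  what keeps sampled moments and analytic truths consistent.

## Known limitations

- Confidence intervals for weighted estimates ignore multi-stage
  clustering (no PSU information in the schema) and so are approximate.
- The logistic fit treats country intercepts as normal; the scenario's
  calibrated intercepts are fixed values with a roughly symmetric spread,
  a mild misspecification that fixed-effect recovery tests show is
  immaterial at these sizes.
- Model-based (non-robust) standard errors are used in the linear models;
  the two-part outcome is heteroscedastic, which nudges CI coverage
  slightly below nominal (observed 91–96% across terms at n = 28 000).
- The former-smoking effect pattern and the TCS score trajectories are
  plausible defaults, not published estimates; they are configuration,
  not conclusions.
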