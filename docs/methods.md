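# Methods

This note records the statistical model the package implements, the
conventions and numerical choices behind it, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
more than one defensible convention exists.

## Mortality model

For one sex/race stratum within an area (state, region or national), county
death counts D and populations P at single ages 30–84 are modeled as
D ~ Poisson(P·λ) with

    ln λ(i, age, year) = f(age) + g(year) + Σⱼ βⱼ 1{SESQᵢ=j} + Σⱼ γⱼ 1{SESQᵢ=j}·age

where f and g are restricted (natural) cubic splines and SES enters either
as five population-weighted quintiles or as a two-level low (Q1–Q3) / high
(Q4–Q5) factor. Key conventions:

- **Spline basis.** Harrell parameterization with the knot-range
  normalization: k knots give one linear column plus k−2 nonlinear columns
  that vanish at and below the first knot and make the function linear at
  and beyond the last. Default knots: age 32, 40, 55, 70, 77, 82; year
  1992, 1997, 2002, 2007, 2012. Extrapolation outside the knot span is
  therefore log-linear.
- **Interaction uses linear age**, not the age spline — the SES effect on
  log mortality is a level shift plus a linear tilt in age. This keeps the
  SES terms interpretable and the design small.
- **Reference SES level** is the lowest (Q1, or "low"), matching the model
  equations (quintile effects for j = 2..5; a high-SES indicator in the
  two-level form); it is configurable via `ModelSpec.ses_reference`. Fitted
  rates are invariant to this choice.
- **Grouped rates.** Deaths and populations are summed over a centered
  3-year window labeled by its middle year (1991–93 → 1992). Windows at the
  panel edge sum whatever years exist, which slightly biases the year trend
  at the edges; the standing studies use interior centers only.
- **Estimation.** Maximum likelihood via a log-link Poisson GLM with
  log-population offset (statsmodels); IRLS tolerance 1e−8, 100 iterations,
  non-convergence is an error. Rows sharing (age, year, SES) are collapsed
  before fitting — the Poisson likelihood is invariant to this, and it makes
  fits on large county panels cheap. SES levels absent from the data are
  dropped from the design (their dummies would be identically zero); if the
  reference level itself is absent, the lowest/highest observed level takes
  its place.
- **Deviance** is reported against the saturated model on the *input* rows,
  not the collapsed cells, so deviances of nested specs with different SES
  groupings are comparable (collapsing changes the saturated likelihood).
- **Model ladder.** Candidates in decreasing detail — state+quintiles,
  state+2-level, state only, region+quintiles, national+2-level, national —
  with a candidate feasible when every area×SES design cell holds at least
  `min_cell_deaths` (default 25) and the stratum at least `min_total_deaths`
  (default 10,000). The thresholds are configurable because no published
  values exist; the defaults are round numbers at which Poisson log-rate
  cells are stable.

## SES index and quintiles

The county SES index is taken as given at anchor years (default 1990, 2000,
2007, 2008, 2009). Between anchors it is linearly interpolated; outside the
anchor span it is linearly extrapolated from the two nearest anchors;
single-anchor counties carry their value constant. County populations are
interpolated the same way (clipped at zero) because quintile assignment
needs per-year weights.

Each year, counties are ranked by index (ties broken by county ID) and cut
into five bands of ~20% of national population. A county straddling a band
boundary is assigned the band containing the *midpoint* of its
cumulative-population interval: deterministic, order-independent, and the
resulting shares deviate from 20% by at most one county's population share.
Quintile labels are invariant under any strictly monotone transform of the
index (only ranks and populations matter). Cut-points are national and
per-year, not frozen to a single census.

## Life tables

- **Scale discipline.** The boundary adjustment is defined on central rates
  m; reference-table probabilities are converted with m = −ln(1−q) before
  any ratio is taken, and rates convert back with q = 1 − e^(−m). Mixing the
  two scales would make the ratio formulas ambiguous exactly where q is
  large (old ages).
- **Boundary adjustment.** Modeled rates pass through unchanged on ages
  35–84. Below 35 and above 84 the output is the reference table's age
  shape scaled to the modeled level at the anchors: m(a) =
  m(35)·m_US(a)/m_US(35) for a < 35 and m(a) = m(84)·m_US(a)/m_US(84) for
  a > 84. The scale factor is computed first, so modeled ≡ reference is an
  exact floating-point identity. Ages 30–34 of the fit are not used; the
  reference shape takes over below the age-35 anchor.
- **Table construction.** Radix 100,000; l_{x+1} = l_x(1−q_x); person-years
  L_x = l_x − ½d_x (a_x = ½ at every age, infancy included — young-age
  shape comes from the reference table, so a refined infant separation
  factor would add nothing testable). The table closes at exact age 99:
  life expectancy is the truncated (temporary) expectancy
  Σ_{x}^{98} L_x / l_x, i.e. expected years lived before exact age 99.
  Under q ≡ 0 this gives 99.0 from birth; under q ≡ 1, 0.5.
- **Library lookup** carries the last available calendar year forward (and
  the first backward) and clips attained ages at 99, matching how
  expected-survival software treats follow-up beyond the final table year.

## Survival estimators

Interval convention throughout: interval k covers months ((k−1)L, kL]; a
patient is at risk at the interval start when follow-up time exceeds the
start, so an exit at exactly kL belongs to interval k.

- **Cohort filters.** Autopsy/DCO-only cases and zero-follow-up cases are
  removed; follow-up is truncated (status → censored) at the month attained
  age reaches 99; optionally patients with more than one primary are
  removed. Patients map to a life-table stratum through county → SES
  quintile at diagnosis, fixed over follow-up.
- **Ederer II expected survival.** For interval k, the conditional expected
  survival is the mean over patients still under follow-up at the start of
  k of (1−q)^(L/12), with q read from the patient's matched table at
  attained age (diagnosis age + elapsed whole years, capped at 99) and
  calendar year (diagnosis year + elapsed whole years, capped at the last
  table year). Cumulative expected survival is the running product. If the
  risk set empties early the curve truncates.
- **Observed survival** uses the actuarial (life-table) estimator with
  half-interval credit for within-interval censorings: conditional survival
  1 − d_k/(n_k − c_k/2), Greenwood-type standard errors. Monthly intervals
  are the default; the standing studies use annual intervals for 10-year
  quantities. The actuarial form (rather than Kaplan–Meier) matches
  registry-software convention for grouped follow-up.
- **Relative survival** is the pointwise ratio observed/expected and may
  exceed 1; expected survival is treated as fixed (population tables carry
  no sampling error on the cohort's scale), so SE(RS) = SE(OS)/ES.
- **Cause-specific survival** is Kaplan–Meier with cancer death as the
  event; other-cause deaths and administrative/age-99 exits censor.
  Greenwood variance, log-log 95% intervals. Deaths with unknown cause
  count as non-cancer by default (configurable) — the conservative reading
  when a cause algorithm leaves residual ambiguity. The in-package
  estimator is cross-checked against lifelines in the test suite.
- **Suppression.** Groups with fewer than 50 patients at diagnosis emit no
  estimates (NaN + flag); exactly 50 is reported.

## Synthetic data

The generator plants a ground truth of the same functional form the models
fit, which is what recovery testing requires:

- `TrueSurface` is an exact log-mortality surface: a natural cubic spline
  through specified log rates at the age knots (linear beyond them), a
  linear calendar trend, and per-SES-level offsets β and linear-age tilts
  γ with a mandatory zero reference level. Defaults give adult mortality
  rising from ~1e−3 at age 30 to ~4e−2 at 84, a −1%/year trend — levels a
  demographer would call unremarkable for a recent US-like population.
- County populations and SES indexes are drawn from a seed-derived stream
  separate from the death-count stream, so the panel and its companion SES
  table are mutually consistent and bit-reproducible. Deaths are Poisson
  with mean P·exp(surface) (matching the fitted likelihood); draws
  exceeding the cell population are redrawn.
- Cohorts: integer diagnosis ages (default 55–84) and years (default
  2000–2012, diagnoses mid-year, administrative censoring at end 2012, so
  maximum follow-up ≈ 12.5 years and 10-year survival is estimable). The
  all-cause hazard on annual follow-up segments is the life-table
  background rate at attained age plus a configurable excess rate per
  follow-up year; event times come from exact piecewise-constant hazard
  inversion, and deaths are labeled "cancer" with probability
  excess/(excess+background) at the death segment — the standard
  competing-risks construction, giving a known truth for cause-specific
  survival (exp(−Λ_excess)).
- Not emulated: real county population-size distributions, migration,
  cohort (generation) effects, race-specific mortality levels, CHSDA
  geography, within-county SES heterogeneity, or dependence between SES
  and population size. Passing recovery tests therefore demonstrates
  correctness of the estimators under the model, not robustness to
  violations of it.

## Standing studies and their sizes

Problem sizes were chosen so Monte-Carlo noise is small against each
study's tolerance:

- *Null-excess calibration*: 100 cohorts of 20,000 patients, zero excess
  hazard, relative survival at 5 and 10 years against the generating
  table; the observed spread (SD ≈ 0.005 at 10 years) sits well inside the
  ±0.02 band checked.
- *Gradient reduction*: 250,000 patients per SES stratum, diagnosis ages
  70–84 (where background differences bite), excess 0.05/yr on both
  strata. Matched tables leave a |RS_low − RS_high| of pure noise
  (SD ≈ 0.2 points); the pooled-average table opens a ~23-point gap,
  biased against the low-SES stratum.
- *Model recovery*: 100 replicates of 200-county panels with cell
  populations ≥ 1e5, national 5-level-SES spec, interior grouping centers
  1994–2010. Coverage of true coefficients by estimate ± 3 SE is pooled
  over (replicate, coefficient) pairs against a 99% floor — the reading
  consistent with the 3σ nominal level of ~99.7%, since requiring all ~18
  coefficients jointly inside 3σ in 99% of replicates would fail even for
  a perfectly calibrated estimator (0.9973¹⁸ ≈ 0.95). End-to-end life
  expectancy (fit → boundary adjustment → expectancy) is checked to 0.2
  years against the exact surface; observed errors are ~0.005 years.

## Known limitations

- The linear-age SES interaction cannot represent SES effects that bend
  with age; the spline×SES alternative was deliberately excluded.
- Boundary adjustment assumes the reference table's age shape applies
  below 35 and above 84 up to a level shift; where a stratum's old-age
  shape truly differs, adjusted tables inherit the reference's shape.
- Ederer II here uses annual attained-age/year steps; sub-annual hazard
  variation within a year of age is averaged out.
- The fallback ladder checks death counts only; it does not penalize
  model complexity or check fit quality.
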