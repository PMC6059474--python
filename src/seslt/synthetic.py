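"""Synthetic county mortality panels and cancer cohorts with known truth.

Every downstream stage (SES quintiles, Poisson spline fits, boundary-adjusted
life tables, expected/relative/cause-specific survival) is testable by
recovery against the ground truth planted here:

* :class:`TrueSurface` — an exact log mortality surface of the same
  functional form the models fit: a natural cubic spline over age (specified
  by its values at the age knots), a linear calendar-year trend, and per-SES
  level and SES x age offsets with a zero-effect reference level.
* :func:`generate_mortality_panel` — county x age x year death counts drawn
  Poisson around population x exp(surface), with county populations and SES
  indexes drawn from seed-derived streams so the panel and its companion SES
  table are mutually consistent.
* :func:`generate_cohort` — patient follow-up simulated from a background
  hazard read off a known life table plus a configurable excess cancer
  hazard, by exact piecewise-constant hazard inversion on annual segments;
  cause-of-death labels drawn Bernoulli with the hazard ratio at death.
* :func:`true_life_expectancy` — the oracle expectancy computed from the
  exact surface through the same life-table algebra the pipeline uses.

The generator makes no attempt to imitate real US county population sizes,
CHSDA geography, or race-specific mortality levels; it emulates the data
*structure* and the model family, which is what recovery tests need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lifetable as ltmod
from . import ses as sesmod
from .lifetable import AGE_MAX, LifeTable, build_life_table, rate_to_q
from .ltmodel import ModelSpec, rcs_basis

__all__ = [
    "TrueSurface",
    "SimConfig",
    "county_frame",
    "ses_index_table",
    "quintile_assignment",
    "generate_mortality_panel",
    "generate_cohort",
    "true_life_expectancy",
    "true_coefficients",
]


@dataclass(frozen=True)
class TrueSurface:
    """Exact log mortality surface: ln m(age, year, SES).

    ``age_knot_values`` are log rates at ``age_knots``; the surface between
    and beyond the knots is the unique restricted cubic spline interpolant
    (linear outside the boundary knots).  ``ses_effects``/``ses_age_slopes``
    map SES levels to log-rate offsets beta and linear-age interaction slopes
    gamma; the reference level (absent or zero) must carry both zero.
    """

    age_knots: tuple = (32, 40, 55, 70, 77, 82)
    age_knot_values: tuple = (-6.9, -6.4, -5.4, -4.2, -3.6, -3.2)
    year_ref: float = 2000.0
    year_slope: float = -0.01
    ses_effects: dict = field(default_factory=dict)
    ses_age_slopes: dict = field(default_factory=dict)
    sex: str = "male"
    race: str = "all"

    def __post_init__(self):
        if len(self.age_knots) != len(self.age_knot_values):
            raise ValueError("one log-rate value per age knot required")
        if self.levels and self.reference_level is None:
            raise ValueError(
                "one SES level must carry zero offset and zero slope (the reference)"
            )

    @property
    def base_stratum(self) -> str:
        return f"{self.sex}/{self.race}"

    @property
    def levels(self) -> tuple:
        lv = set(self.ses_effects) | set(self.ses_age_slopes)
        return tuple(sorted(lv)) if lv else ()

    @property
    def reference_level(self):
        levels = self.levels
        if not levels:
            return None
        zero = [l for l in levels if self.ses_effects.get(l, 0.0) == 0.0
                and self.ses_age_slopes.get(l, 0.0) == 0.0]
        return zero[0] if zero else None

    def _age_coeffs(self) -> np.ndarray:
        # natural-spline interpolation through the knot values: with k knots the
        # intercept + (k-1)-column restricted basis is a square, invertible system
        knots = np.asarray(self.age_knots, dtype=float)
        A = np.column_stack([np.ones(len(knots)), rcs_basis(knots, knots)])
        return np.linalg.solve(A, np.asarray(self.age_knot_values, dtype=float))

    def log_rate(self, age, year, ses_level=None):
        """ln m at (age, year, SES level); vectorized over age/year."""
        age = np.asarray(age, dtype=float)
        year = np.asarray(year, dtype=float)
        c = self._age_coeffs()
        B = np.column_stack([np.ones(np.atleast_1d(age).shape), np.atleast_2d(rcs_basis(np.atleast_1d(age), self.age_knots))])
        out = B @ c + self.year_slope * (np.atleast_1d(year) - self.year_ref)
        if ses_level is not None:
            out = out + self.ses_effects.get(ses_level, 0.0)
            out = out + self.ses_age_slopes.get(ses_level, 0.0) * np.atleast_1d(age)
        return out if age.ndim or year.ndim else float(out[0])

    def rates(self, ages, year, ses_level=None) -> np.ndarray:
        return np.exp(self.log_rate(np.asarray(ages, dtype=float), year, ses_level))


@dataclass(frozen=True)
class SimConfig:
    """Shape of a simulated county mortality panel."""

    n_counties: int = 100
    population_range: tuple = (5_000, 100_000)
    years: tuple = (1992, 2012)
    age_range: tuple = (30, 84)
    quintile_scheme: str = "quintile5"
    seed: int = 0

    def __post_init__(self):
        if self.n_counties < 1:
            raise ValueError("need at least one county")
        lo, hi = self.population_range
        if lo <= 0 or hi < lo:
            raise ValueError("population range must be positive with min <= max")
        if self.years[1] < self.years[0]:
            raise ValueError("year span must cover at least one year")
        if self.quintile_scheme not in ("quintile5", "level2"):
            raise ValueError("quintile scheme must be 'quintile5' or 'level2'")

    @property
    def year_list(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    @property
    def age_list(self) -> np.ndarray:
        return np.arange(self.age_range[0], self.age_range[1] + 1)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def county_frame(config: SimConfig) -> pd.DataFrame:
    """Counties with seed-deterministic populations and SES index values."""
    rng = _rng(config, 0)
    n = config.n_counties
    lo, hi = config.population_range
    return pd.DataFrame(
        {
            "county": [f"C{i:04d}" for i in range(n)],
            "population": rng.integers(lo, hi + 1, size=n),
            "index": rng.uniform(-2.0, 2.0, size=n),
        }
    )


def ses_index_table(config: SimConfig) -> pd.DataFrame:
    """County SES index table over the simulated years (index held constant)."""
    counties = county_frame(config)
    years = pd.DataFrame({"year": config.year_list})
    return counties.merge(years, how="cross")[["county", "year", "index", "population"]]


def quintile_assignment(config: SimConfig) -> pd.DataFrame:
    """Population-weighted quintile (and 2-level) labels for the simulated counties."""
    return sesmod.assign_quintiles(ses_index_table(config))


def _surface_level(scheme: str, quintile, level2):
    return level2 if scheme == "level2" else quintile


def generate_mortality_panel(config: SimConfig, surface: TrueSurface) -> pd.DataFrame:
    """County x age x year death and population counts around the true surface.

    Deaths are Poisson with mean population x exp(surface at the county's SES
    level); draws exceeding the cell population (essentially impossible at
    realistic rates) are redrawn.  Identical config + surface + seed give a
    bit-identical panel.
    """
    ages = config.age_list
    if surface.levels:
        missing = [l for l in _scheme_levels(config) if l not in surface.levels]
        if missing:
            raise ValueError(f"surface lacks SES levels {missing}")
    quint = quintile_assignment(config)
    panel = quint.rename(columns={"population": "base_pop"})[
        ["county", "year", "quintile", "level2", "base_pop"]
    ]
    panel = panel.merge(pd.DataFrame({"age": ages}), how="cross")
    rng = _rng(config, 1)
    lo, hi = config.population_range
    pop = rng.integers(lo, hi + 1, size=len(panel))
    level_col = "level2" if config.quintile_scheme == "level2" else "quintile"
    level = panel[level_col].to_numpy()
    age = panel["age"].to_numpy(float)
    year = panel["year"].to_numpy(float)
    # vectorized surface: base age spline on unique ages + linear year + SES terms
    uniq_ages = np.unique(age)
    base_by_age = dict(zip(uniq_ages, np.asarray(surface.log_rate(uniq_ages, surface.year_ref))))
    base = np.array([base_by_age[a] for a in age])
    beta = np.array([surface.ses_effects.get(l, 0.0) for l in level])
    gamma = np.array([surface.ses_age_slopes.get(l, 0.0) for l in level])
    lograte = base + surface.year_slope * (year - surface.year_ref) + beta + gamma * age
    mean = pop * np.exp(lograte)
    deaths = rng.poisson(mean)
    bad = deaths > pop
    while bad.any():
        deaths[bad] = rng.poisson(mean[bad])
        bad = deaths > pop
    out = panel[["county", "age", "year"]].copy()
    out["sex"] = surface.sex
    out["race"] = surface.race
    out["deaths"] = deaths
    out["population"] = pop
    return out.sort_values(["county", "year", "age"], ignore_index=True)


def _scheme_levels(config: SimConfig):
    return (1, 2, 3, 4, 5) if config.quintile_scheme == "quintile5" else ("low", "high")


def generate_cohort(
    lt: LifeTable,
    excess_hazard,
    n: int,
    seed: int,
    diag_years: tuple = (2000, 2012),
    diag_ages: tuple = (55, 84),
    study_end_year: int = 2012,
    county: str = "C0000",
    frac_dco: float = 0.0,
    frac_autopsy: float = 0.0,
    frac_multiprimary: float = 0.0,
) -> pd.DataFrame:
    """Simulate a patient cohort with background + excess cancer hazard.

    The all-cause hazard on annual segments since diagnosis is the life-table
    background rate at the attained age, m = -ln(1 - q), plus the excess rate
    for that follow-up year (``excess_hazard``: scalar, or a sequence of
    per-follow-up-year rates with the last carried forward).  Event times are
    drawn by exact inversion of the piecewise-constant cumulative hazard;
    deaths are labeled "cancer" with probability excess/total at the death
    segment.  Diagnoses fall mid-year, uniformly over ``diag_years``;
    administrative censoring is at the end of ``study_end_year``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    excess = np.atleast_1d(np.asarray(excess_hazard, dtype=float))
    if np.any(excess < 0):
        raise ValueError("excess hazard rates must be non-negative")
    rng = np.random.default_rng([int(seed), 2])
    diag_year = rng.integers(diag_years[0], diag_years[1] + 1, size=n)
    diag_age = rng.integers(diag_ages[0], diag_ages[1] + 1, size=n)
    censor_years = (study_end_year - diag_year) + 0.5
    max_seg = int(np.ceil(censor_years.max()))

    with np.errstate(divide="ignore"):
        bg_by_age = -np.log1p(-lt.qx)  # index = attained age, inf where q = 1
    E = rng.exponential(size=n)
    t = np.full(n, np.inf)
    frac_excess = np.zeros(n)
    cum = np.zeros(n)
    for j in range(max_seg):
        age_j = np.minimum(diag_age + j, AGE_MAX)
        e_j = excess[min(j, len(excess) - 1)]
        h_j = bg_by_age[age_j] + e_j
        hit = (t == np.inf) & (E < cum + h_j)
        if hit.any():
            t[hit] = j + (E[hit] - cum[hit]) / h_j[hit]
            with np.errstate(invalid="ignore"):
                frac_excess[hit] = np.where(h_j[hit] > 0, e_j / h_j[hit], 0.0)
        cum = cum + h_j
    dead = t <= censor_years
    time_years = np.where(dead, t, censor_years)
    cancer = rng.random(n) < frac_excess
    cause = np.where(dead, np.where(cancer, "cancer", "other"), "")
    u = rng.random(n)
    source = np.select(
        [u < frac_dco, u < frac_dco + frac_autopsy], ["DCO", "autopsy"], default="registry"
    )
    n_primaries = 1 + (rng.random(n) < frac_multiprimary).astype(int)
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "diag_year": diag_year,
            "diag_age": diag_age,
            "sex": lt.stratum.split("/")[0] if "/" in lt.stratum else lt.stratum,
            "race": lt.stratum.split("/")[1] if "/" in lt.stratum else "all",
            "county": county,
            "stratum": lt.stratum,
            "time_months": time_years * 12.0,
            "status": np.where(dead, "dead", "alive"),
            "cause": cause,
            "source": source,
            "n_primaries": n_primaries,
        }
    )


def true_life_expectancy(surface: TrueSurface, ses_level=None, year: float = 2000.0,
                         from_age: int = 0) -> float:
    """Oracle expectancy: exact surface rates 0-99 through the life-table algebra."""
    ages = np.arange(AGE_MAX + 1)
    m = surface.rates(ages, year, ses_level)
    if not np.all(np.isfinite(m)):
        raise ValueError("surface rates must be finite over ages 0-99")
    lt = build_life_table(rate_to_q(m), stratum=surface.base_stratum, year=int(year))
    return ltmod.life_expectancy(lt, from_age)


def true_surface_life_table(surface: TrueSurface, ses_level=None, year: float = 2000.0,
                            stratum: str | None = None) -> LifeTable:
    """Exact life table implied by the surface at one SES level and year."""
    ages = np.arange(AGE_MAX + 1)
    m = surface.rates(ages, year, ses_level)
    return build_life_table(
        rate_to_q(m), stratum=stratum or surface.base_stratum, year=int(year)
    )


def true_coefficients(surface: TrueSurface, spec: ModelSpec) -> dict:
    """The surface's exact coefficients in the fitted model's parameterization.

    Valid when the fitted spec uses the surface's age knots, the surface's
    SES levels with the same (lowest) reference, and year knots spanning the
    linear trend (the trend loads the linear year column; nonlinear year
    coefficients are exactly zero).  Used by recovery tests to check
    coefficient coverage.
    """
    if tuple(spec.age_knots) != tuple(surface.age_knots):
        raise ValueError("spec age knots must match the surface age knots")
    c = surface._age_coeffs()
    out = {"intercept": float(c[0] - surface.year_slope * surface.year_ref)}
    for i, v in enumerate(c[1:]):
        out[f"age_{i}"] = float(v)
    if len(spec.year_knots):
        out["year_0"] = float(surface.year_slope)
        for i in range(1, len(spec.year_knots) - 1):
            out[f"year_{i}"] = 0.0
    if spec.ses_form != "none":
        ref = spec.reference_level
        if surface.ses_effects.get(ref, 0.0) != 0.0 or surface.ses_age_slopes.get(ref, 0.0) != 0.0:
            raise ValueError("surface reference level must match the spec reference")
        for lvl in spec.ses_levels:
            if lvl == ref:
                continue
            out[f"ses[{lvl}]"] = float(surface.ses_effects.get(lvl, 0.0))
            out[f"ses[{lvl}]:age"] = float(surface.ses_age_slopes.get(lvl, 0.0))
    return out
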