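"""Poisson spline models for county mortality rates with SES covariates.

The mortality surface for one sex/race stratum within an area (state, region
or national) is modeled on grouped county counts as

    D ~ Poisson(P * lambda),
    ln(lambda) = f(age) + g(year) + sum_j beta_j I(SES=j) + sum_j gamma_j I(SES=j) * age

with f and g restricted (natural) cubic splines, SES entering as a 5-level
quintile or a 2-level (low Q1-Q3 / high Q4-Q5) factor, and the SES x age
interaction using linear age.  Fitting is by maximum likelihood via a
log-link Poisson GLM with log-population offset; identical design rows are
collapsed first (the Poisson likelihood is invariant to this aggregation).

Models are fit to 3-year grouped rates at ages 30-84; the ``lifetable``
module extends predictions to the full 0-99 age range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FittedLTModel",
    "LadderConfig",
    "DEFAULT_AGE_KNOTS",
    "DEFAULT_YEAR_KNOTS",
    "DEFAULT_LADDER",
    "rcs_basis",
    "aggregate_rates",
    "fit_poisson_lt",
    "predict_log_rate",
    "select_model_spec",
]

DEFAULT_AGE_KNOTS = (32, 40, 55, 70, 77, 82)
DEFAULT_YEAR_KNOTS = (1992, 1997, 2002, 2007, 2012)

FIT_AGE_MIN = 30
FIT_AGE_MAX = 84


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (Harrell parameterization).

    k strictly increasing knots t_1 < ... < t_k give k-1 columns: the first is
    x itself, and for j = 1..k-2 the nonlinear columns

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which vanish for x <= t_1 and are linear for x >= t_k, so the fitted
    function is linear beyond the boundary knots.  The (t_k-t_1)^2 divisor is
    the standard knot-range normalization keeping columns on the scale of x.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(knots)
    t = knots
    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    plus3 = lambda u: np.clip(u, 0.0, None) ** 3
    last = plus3(x - t[-1])
    second_last = plus3(x - t[-2])
    denom = t[-1] - t[-2]
    for j in range(k - 2):
        col = (
            plus3(x - t[j])
            - second_last * (t[-1] - t[j]) / denom
            + last * (t[-2] - t[j]) / denom
        ) / norm
        cols.append(col)
    return np.column_stack(cols)


@dataclass(frozen=True)
class ModelSpec:
    """Design of one mortality model: area granularity, SES form, knots.

    ``ses_form`` is "quintile5", "level2" or "none".  Empty knot tuples drop
    the corresponding spline entirely (used for degenerate/intercept-only
    designs in calibration checks).  ``ses_reference`` picks the SES level
    carrying beta = gamma = 0; "lowest" matches the model equations (quintile
    effects for Q2..Q5, a high-SES indicator in the 2-level form).
    """

    area_level: str = "state"
    ses_form: str = "quintile5"
    age_knots: tuple = DEFAULT_AGE_KNOTS
    year_knots: tuple = DEFAULT_YEAR_KNOTS
    grouping_window: int = 3
    ses_reference: str = "lowest"

    def __post_init__(self):
        if self.area_level not in ("state", "region", "national"):
            raise ValueError(f"unknown area level {self.area_level!r}")
        if self.ses_form not in ("quintile5", "level2", "none"):
            raise ValueError(f"unknown SES form {self.ses_form!r}")
        for knots in (self.age_knots, self.year_knots):
            if len(knots) and (len(knots) < 3 or np.any(np.diff(knots) <= 0)):
                raise ValueError("knot sequences must be empty or >=3 strictly increasing values")
        if self.grouping_window < 1 or self.grouping_window % 2 == 0:
            raise ValueError("grouping window must be odd and >= 1")
        if self.ses_reference not in ("lowest", "highest"):
            raise ValueError("ses_reference must be 'lowest' or 'highest'")

    @property
    def ses_levels(self) -> tuple:
        if self.ses_form == "quintile5":
            return (1, 2, 3, 4, 5)
        if self.ses_form == "level2":
            return ("low", "high")
        return ()

    @property
    def reference_level(self):
        levels = self.ses_levels
        if not levels:
            return None
        return levels[0] if self.ses_reference == "lowest" else levels[-1]


def aggregate_rates(panel: pd.DataFrame, center_year: int, window: int = 3) -> pd.DataFrame:
    """Sum deaths and populations over a centered window of calendar years.

    The 3-year default pools [center-1, center+1] and labels the result with
    the center year (1991-1993 -> 1992, etc.).  Years absent from the panel
    contribute nothing, so windows at the panel edges are truncated sums.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = (window - 1) // 2
    sub = panel[(panel["year"] >= center_year - half) & (panel["year"] <= center_year + half)]
    if sub.empty:
        raise ValueError(f"no panel years fall in window around {center_year}")
    keys = [c for c in ("county", "age", "sex", "race", "area") if c in sub.columns]
    out = sub.groupby(keys, as_index=False)[["deaths", "population"]].sum()
    out.insert(keys.index("age") + 1 if "age" in keys else len(keys), "year", center_year)
    return out


@dataclass
class FittedLTModel:
    """Maximum-likelihood fit of one mortality model.

    Holds the coefficient vector in design order (intercept, age spline, year
    spline, SES mains, SES x age slopes), its covariance, and enough of the
    spec to rebuild the design row for any (age, year, SES level).
    """

    spec: ModelSpec
    params: np.ndarray
    cov: np.ndarray
    colnames: list
    stratum: str = ""
    deviance: float = float("nan")
    n_cells: int = 0
    converged: bool = True
    _ses_levels: tuple = field(default=())

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    def _coef_block(self, prefix: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.colnames) if c.startswith(prefix)]
        return self.params[idx]

    @property
    def f_coeffs(self) -> np.ndarray:
        return self._coef_block("age_")

    @property
    def g_coeffs(self) -> np.ndarray:
        return self._coef_block("year_")

    @property
    def beta(self) -> dict:
        out = {lvl: 0.0 for lvl in self._ses_levels}
        for i, c in enumerate(self.colnames):
            if c.startswith("ses[") and not c.endswith(":age"):
                out[_parse_level(c)] = float(self.params[i])
        return out

    @property
    def gamma(self) -> dict:
        out = {lvl: 0.0 for lvl in self._ses_levels}
        for i, c in enumerate(self.colnames):
            if c.startswith("ses[") and c.endswith(":age"):
                out[_parse_level(c)] = float(self.params[i])
        return out

    def design(self, age, year, ses_level=None) -> np.ndarray:
        age = np.atleast_1d(np.asarray(age, dtype=float))
        year = np.broadcast_to(np.atleast_1d(np.asarray(year, dtype=float)), age.shape)
        return _design_matrix(self.spec, age, year, ses_level, self._ses_levels)[0]

    def predict_log_rate(self, age, year, ses_level=None):
        X = self.design(age, year, ses_level)
        out = X @ self.params
        return float(out[0]) if np.isscalar(age) or np.ndim(age) == 0 else out

    def predict_rate(self, age, year, ses_level=None):
        return np.exp(self.predict_log_rate(age, year, ses_level))

    def modeled_rates(self, year, ses_level=None, ages=None) -> np.ndarray:
        """Predicted central rates at single ages 35-84 (boundary-adjust input)."""
        if ages is None:
            ages = np.arange(35, 85)
        return np.exp(self.predict_log_rate(np.asarray(ages), year, ses_level))

    def coef_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame({"term": self.colnames, "coef": self.params, "se": se})


def _parse_level(col: str):
    lvl = col.split("[", 1)[1].split("]", 1)[0]
    return int(lvl) if lvl.isdigit() else lvl


def _design_matrix(spec: ModelSpec, age, year, ses, ses_levels):
    """Design matrix and column names for the model equation.

    ``ses_levels`` are the levels the model carries (reference first or last
    per the spec); levels absent from a fit are excluded so the design stays
    full rank.
    """
    n = len(age)
    cols, names = [np.ones(n)], ["intercept"]
    if len(spec.age_knots):
        B = rcs_basis(age, spec.age_knots)
        cols.extend(B.T)
        names.extend(f"age_{i}" for i in range(B.shape[1]))
    if len(spec.year_knots):
        B = rcs_basis(year, spec.year_knots)
        cols.extend(B.T)
        names.extend(f"year_{i}" for i in range(B.shape[1]))
    if spec.ses_form != "none":
        ref = ses_levels[0] if spec.ses_reference == "lowest" else ses_levels[-1]
        if ses is None:
            raise ValueError("SES level required for this model spec")
        ses = np.broadcast_to(np.atleast_1d(np.asarray(ses, dtype=object)), (n,))
        known = set(ses_levels)
        bad = {v for v in ses if v not in known}
        if bad:
            raise ValueError(f"unknown SES level(s) {sorted(map(str, bad))!r}; expected {ses_levels}")
        for lvl in ses_levels:
            if lvl == ref:
                continue
            ind = (ses == lvl).astype(float)
            cols.append(ind)
            names.append(f"ses[{lvl}]")
        for lvl in ses_levels:
            if lvl == ref:
                continue
            ind = (ses == lvl).astype(float)
            cols.append(ind * age)
            names.append(f"ses[{lvl}]:age")
    return np.column_stack(cols), names


def _ses_column(spec: ModelSpec, grouped: pd.DataFrame, quintiles) -> pd.Series | None:
    if spec.ses_form == "none":
        return None
    if quintiles is None:
        raise ValueError("quintile assignment required when ses_form != 'none'")
    col = "quintile" if spec.ses_form == "quintile5" else "level2"
    merged = grouped.merge(
        quintiles[["county", "year", col]], on=["county", "year"], how="left", validate="m:1"
    )
    if merged[col].isna().any():
        missing = merged.loc[merged[col].isna(), ["county", "year"]].drop_duplicates()
        raise ValueError(f"no quintile assignment for {len(missing)} county-year(s)")
    return merged[col]


def fit_poisson_lt(
    grouped: pd.DataFrame,
    quintiles: pd.DataFrame | None,
    spec: ModelSpec,
    stratum: str = "",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> FittedLTModel:
    """Fit the Poisson mortality model to a grouped county panel.

    ``grouped`` needs columns county, age, year, deaths, population (e.g. the
    concatenated output of :func:`aggregate_rates` over center years);
    ``quintiles`` supplies county-year SES labels when the spec includes SES.
    Cells with zero population are dropped; zero total deaths is an error
    (the log rate level is unidentifiable).
    """
    panel = grouped.copy()
    ses = _ses_column(spec, panel, quintiles)
    panel["_ses"] = ses if ses is not None else "all"
    panel = panel[panel["population"] > 0]
    if panel.empty:
        raise ValueError("no cells with positive population")
    if panel["deaths"].sum() <= 0:
        raise ValueError("zero total deaths: log mortality level is unidentifiable")
    # collapse counties sharing (age, year, SES): likelihood-equivalent, much smaller
    cells = panel.groupby(["age", "year", "_ses"], as_index=False)[["deaths", "population"]].sum()
    if spec.ses_form != "none":
        observed = set(cells["_ses"])
        fit_levels = tuple(l for l in spec.ses_levels if l in observed)
        if not fit_levels:
            raise ValueError("no known SES levels present in the data")
    else:
        fit_levels = ()
    X, names = _design_matrix(
        spec,
        cells["age"].to_numpy(float),
        cells["year"].to_numpy(float),
        cells["_ses"].to_numpy() if spec.ses_form != "none" else None,
        fit_levels,
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient ({rank} < {X.shape[1]} columns)")
    model = sm.GLM(
        cells["deaths"].to_numpy(float),
        X,
        family=sm.families.Poisson(),
        offset=np.log(cells["population"].to_numpy(float)),
    )
    res = model.fit(maxiter=maxiter, tol=tol)
    if not res.converged:
        raise RuntimeError(f"Poisson fit did not converge in {maxiter} iterations")
    # deviance against the saturated model on the input rows (not the collapsed
    # cells), so nested specs with different SES groupings stay comparable
    X_rows, _ = _design_matrix(
        spec,
        panel["age"].to_numpy(float),
        panel["year"].to_numpy(float),
        panel["_ses"].to_numpy() if spec.ses_form != "none" else None,
        fit_levels,
    )
    d = panel["deaths"].to_numpy(float)
    mu = panel["population"].to_numpy(float) * np.exp(X_rows @ np.asarray(res.params))
    pos = d > 0
    deviance = 2.0 * (np.sum(d[pos] * np.log(d[pos] / mu[pos])) - np.sum(d - mu))
    logger.info(
        "fit %s/%s: %d cells, deviance %.3f", stratum, spec.ses_form, len(cells), deviance
    )
    return FittedLTModel(
        spec=spec,
        params=np.asarray(res.params, dtype=float),
        cov=np.asarray(res.cov_params(), dtype=float),
        colnames=names,
        stratum=stratum,
        deviance=float(deviance),
        n_cells=len(cells),
        converged=bool(res.converged),
        _ses_levels=fit_levels,
    )


def predict_log_rate(model: FittedLTModel, age, year, ses_level=None):
    """Linear predictor ln(lambda) at (age, year, SES level)."""
    return model.predict_log_rate(age, year, ses_level)


@dataclass(frozen=True)
class LadderConfig:
    """Fallback ladder: ordered candidate specs with sufficiency thresholds.

    A candidate is feasible when every area x SES design cell holds at least
    ``min_cell_deaths`` deaths and the stratum holds ``min_total_deaths`` in
    all.  Candidates run from most to least detailed.
    """

    candidates: tuple = (
        ("state", "quintile5"),
        ("state", "level2"),
        ("state", "none"),
        ("region", "quintile5"),
        ("national", "level2"),
        ("national", "none"),
    )
    min_cell_deaths: float = 25.0
    min_total_deaths: float = 10_000.0


DEFAULT_LADDER = LadderConfig()

_AREA_COL = {"state": "state", "region": "region", "national": None}
_SES_KEY = {
    "quintile5": lambda q: q,
    "level2": lambda q: np.where(np.asarray(q, dtype=float) <= 3, "low", "high"),
    "none": None,
}


def select_model_spec(
    stratum_totals: pd.DataFrame,
    ladder: LadderConfig = DEFAULT_LADDER,
    **spec_kwargs,
) -> ModelSpec:
    """Pick the most detailed feasible model for one sex/race stratum.

    ``stratum_totals`` has one row per county-level unit with columns
    state, region, quintile, deaths, population.  The first ladder candidate
    whose every design cell meets the death threshold wins.
    """
    required = {"state", "region", "quintile", "deaths"}
    missing = required - set(stratum_totals.columns)
    if missing:
        raise ValueError(f"stratum totals missing columns {sorted(missing)}")
    total = stratum_totals["deaths"].sum()
    for area_level, ses_form in ladder.candidates:
        df = stratum_totals.copy()
        keys = []
        area_col = _AREA_COL[area_level]
        if area_col:
            keys.append(area_col)
        ses_fn = _SES_KEY[ses_form]
        if ses_fn is not None:
            df["_ses"] = ses_fn(df["quintile"])
            keys.append("_ses")
        cell_deaths = df.groupby(keys)["deaths"].sum() if keys else pd.Series([total])
        if total >= ladder.min_total_deaths and (cell_deaths >= ladder.min_cell_deaths).all():
            return ModelSpec(area_level=area_level, ses_form=ses_form, **spec_kwargs)
    raise ValueError("no ladder candidate is feasible for these totals")
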