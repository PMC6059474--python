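"""Observed, expected (Ederer II), relative, and cause-specific survival.

Relative survival — the registry-standard net-survival measure — is the ratio
of a cancer cohort's observed all-cause survival to the expected survival of
a matched, cancer-free population.  Expected survival uses the Ederer II
estimator: within each follow-up interval, average the matched life-table
probability of surviving the interval over the patients still under
follow-up at the interval's start, then multiply the conditional averages
across intervals.  Cause-specific survival is the Kaplan-Meier complement
using cancer death as the event and other deaths as censorings.

Interval convention: interval k (1-based) covers months ((k-1)L, kL].  A
patient is at risk at the interval's start when their follow-up time exceeds
the start; a death or censoring at exactly kL months belongs to interval k.

Patients are matched to life tables through a ``stratum`` column fixed at
diagnosis (county -> SES quintile -> stratum); within follow-up the matched
probability is read at attained age (diagnosis age + elapsed whole years,
capped at 99) and calendar year (capped at the library's last year).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lifetable import AGE_MAX, LifeTableLibrary

__all__ = [
    "SurvivalCurve",
    "apply_cohort_filters",
    "attach_stratum",
    "expected_survival_ederer2",
    "observed_survival_actuarial",
    "relative_survival",
    "cause_specific_survival",
    "suppress_small_groups",
]

Z95 = 1.959963984540054


@dataclass
class SurvivalCurve:
    """Interval survival estimates of one kind on a regular month grid.

    ``table`` has one row per interval with columns interval, months (interval
    end), n_risk, events, estimate (cumulative survival), se; cause-specific
    curves add log-log 95% CI columns.  Relative survival may exceed 1.
    """

    kind: str
    interval_months: float
    table: pd.DataFrame
    suppressed: bool = False

    def estimate_at(self, months: float) -> float:
        """Cumulative estimate at the interval whose end is ``months``."""
        if self.suppressed:
            return float("nan")
        row = self.table[np.isclose(self.table["months"], months)]
        if row.empty:
            raise KeyError(f"no interval ends at {months} months")
        return float(row["estimate"].iloc[0])

    @property
    def estimates(self) -> np.ndarray:
        return self.table["estimate"].to_numpy()


def apply_cohort_filters(cohort: pd.DataFrame, single_primary_only: bool = False) -> pd.DataFrame:
    """Registry-style cohort exclusions and age-99 truncation.

    Removes cases known only from autopsy or death certificate (DCO) and
    cases with no follow-up (zero survival time); truncates follow-up at the
    month attained age reaches 99 (status becomes alive/censored there); with
    ``single_primary_only``, removes patients with more than one primary.
    """
    out = cohort.copy()
    if "source" in out.columns:
        out = out[~out["source"].isin(["autopsy", "DCO"])]
    out = out[out["time_months"] > 0]
    if single_primary_only and "n_primaries" in out.columns:
        out = out[out["n_primaries"] <= 1]
    months_to_99 = (AGE_MAX - out["diag_age"].to_numpy(float)) * 12.0
    over = out["time_months"].to_numpy(float) > months_to_99
    out = out.copy()
    out.loc[over, "time_months"] = months_to_99[over]
    out.loc[over, "status"] = "alive"
    return out.reset_index(drop=True)


def attach_stratum(
    cohort: pd.DataFrame,
    quintiles: pd.DataFrame | None = None,
    scheme: str = "quintile5",
    template: str = "{sex}/{race}/{level}",
) -> pd.DataFrame:
    """Label each patient with their life-table stratum at diagnosis.

    The county of residence at diagnosis maps to its SES level for the
    diagnosis year; the label is fixed over follow-up.  With no quintile
    table the stratum is sex/race only.
    """
    out = cohort.copy()
    if quintiles is None:
        out["stratum"] = [
            template.replace("/{level}", "").format(sex=s, race=r)
            for s, r in zip(out["sex"], out["race"])
        ]
        return out
    col = "quintile" if scheme == "quintile5" else "level2"
    merged = out.merge(
        quintiles[["county", "year", col]].rename(columns={"year": "diag_year"}),
        on=["county", "diag_year"],
        how="left",
        validate="m:1",
    )
    if merged[col].isna().any():
        raise ValueError("some patients' county-year has no quintile assignment")
    out["stratum"] = [
        template.format(sex=s, race=r, level=l)
        for s, r, l in zip(merged["sex"], merged["race"], merged[col])
    ]
    return out


def _interval_grid(n_intervals: int, interval_months: float) -> np.ndarray:
    if n_intervals < 1 or interval_months <= 0:
        raise ValueError("need n_intervals >= 1 and a positive interval length")
    return np.arange(n_intervals + 1) * float(interval_months)


def expected_survival_ederer2(
    cohort: pd.DataFrame,
    lt_library: LifeTableLibrary,
    n_intervals: int,
    interval_months: float = 12.0,
) -> SurvivalCurve:
    """Ederer II expected survival for a cohort matched to life tables.

    For interval k the conditional expected survival p*_k is the mean, over
    patients under follow-up at the start of k, of their matched table's
    probability of surviving the interval, (1 - q)^(L/12) read at current
    attained age and calendar year.  Cumulative expected survival is the
    running product of the p*_k.  If the risk set empties before
    ``n_intervals``, the curve truncates there.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    grid = _interval_grid(n_intervals, interval_months)
    time = cohort["time_months"].to_numpy(float)
    diag_age = cohort["diag_age"].to_numpy(float)
    diag_year = cohort["diag_year"].to_numpy(int)
    strata = cohort["stratum"].to_numpy()
    for s in np.unique(strata):
        if s not in lt_library.strata:
            raise KeyError(f"no life table for stratum {s!r}")
    rows = []
    cum = 1.0
    frac = interval_months / 12.0
    for k in range(n_intervals):
        start = grid[k]
        at_risk = time > start
        n_k = int(at_risk.sum())
        if n_k == 0:
            break
        elapsed = int(start // 12)
        ages = np.minimum(diag_age[at_risk] + elapsed, AGE_MAX).astype(int)
        years = diag_year[at_risk] + elapsed
        q = np.empty(n_k)
        sub = strata[at_risk]
        for s in np.unique(sub):
            m = sub == s
            q[m] = lt_library.annual_q(s, years[m], ages[m])
        p_star = float(np.mean((1.0 - q) ** frac))
        cum *= p_star
        rows.append((k + 1, grid[k + 1], n_k, np.nan, cum, np.nan))
    table = pd.DataFrame(rows, columns=["interval", "months", "n_risk", "events", "estimate", "se"])
    return SurvivalCurve(kind="expected", interval_months=interval_months, table=table)


def observed_survival_actuarial(
    cohort: pd.DataFrame, n_intervals: int, interval_months: float = 12.0
) -> SurvivalCurve:
    """Actuarial (life-table) all-cause observed survival.

    Within-interval censorings get half-interval credit: the effective
    denominator is n_k - c_k/2, the conditional survival 1 - d_k/(n_k - c_k/2),
    multiplied cumulatively, with Greenwood-type standard errors.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    grid = _interval_grid(n_intervals, interval_months)
    time = cohort["time_months"].to_numpy(float)
    dead = cohort["status"].to_numpy() == "dead"
    rows = []
    cum = 1.0
    var_sum = 0.0
    for k in range(n_intervals):
        start, end = grid[k], grid[k + 1]
        at_risk = time > start
        n_k = int(at_risk.sum())
        if n_k == 0:
            break
        in_int = at_risk & (time <= end)
        d_k = int((in_int & dead).sum())
        c_k = int((in_int & ~dead).sum())
        n_eff = n_k - c_k / 2.0
        p_k = 1.0 - d_k / n_eff if n_eff > 0 else 0.0
        cum *= p_k
        if d_k > 0 and n_eff > d_k:
            var_sum += d_k / (n_eff * (n_eff - d_k))
        rows.append((k + 1, end, n_k, d_k, cum, cum * np.sqrt(var_sum)))
    table = pd.DataFrame(rows, columns=["interval", "months", "n_risk", "events", "estimate", "se"])
    return SurvivalCurve(kind="observed", interval_months=interval_months, table=table)


def relative_survival(observed: SurvivalCurve, expected: SurvivalCurve) -> SurvivalCurve:
    """Relative survival: pointwise observed / expected (may exceed 1).

    The expected curve is treated as fixed (population tables carry no
    sampling error on the cohort's scale), so SE(RS) = SE(OS)/ES.
    """
    n = min(len(observed.table), len(expected.table))
    obs, exp = observed.table.iloc[:n], expected.table.iloc[:n]
    if not np.allclose(obs["months"].to_numpy(), exp["months"].to_numpy()):
        raise ValueError("observed and expected curves are on different interval grids")
    es = exp["estimate"].to_numpy()
    if np.any(es <= 0):
        raise ValueError("expected survival reaches zero; relative survival undefined")
    table = pd.DataFrame(
        {
            "interval": obs["interval"].to_numpy(),
            "months": obs["months"].to_numpy(),
            "n_risk": obs["n_risk"].to_numpy(),
            "events": obs["events"].to_numpy(),
            "estimate": obs["estimate"].to_numpy() / es,
            "se": obs["se"].to_numpy() / es,
        }
    )
    return SurvivalCurve(kind="relative", interval_months=observed.interval_months, table=table)


def _km_step(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier at distinct event times with Greenwood variance terms."""
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    event_times = np.unique(times[events])
    n = len(times)
    S, var = [], []
    s, g = 1.0, 0.0
    for t in event_times:
        n_t = int((times >= t).sum())  # deaths at t count as at risk at t
        d_t = int(((times == t) & events).sum())
        s *= 1.0 - d_t / n_t
        if n_t > d_t:
            g += d_t / (n_t * (n_t - d_t))
        else:
            g = np.inf
        S.append(s)
        var.append(s * s * g if np.isfinite(g) else 0.0)
    return event_times, np.asarray(S), np.asarray(var)


def cause_specific_survival(
    cohort: pd.DataFrame,
    n_intervals: int,
    interval_months: float = 12.0,
    unknown_cause_as_cancer: bool = False,
) -> SurvivalCurve:
    """Kaplan-Meier survival with cancer death as the event.

    Deaths from other causes, end-of-study exits, and the age-99 truncation
    (already applied by the filters) are censorings.  Unknown causes count as
    non-cancer by default.  Greenwood standard errors; log-log 95% CI.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    grid = _interval_grid(n_intervals, interval_months)
    time = cohort["time_months"].to_numpy(float)
    dead = cohort["status"].to_numpy() == "dead"
    cause = cohort["cause"].to_numpy()
    is_cancer = dead & ((cause == "cancer") | (unknown_cause_as_cancer & (cause == "unknown")))
    ev_times, S_step, var_step = _km_step(time, is_cancer)
    rows = []
    for k in range(n_intervals):
        end = grid[k + 1]
        n_k = int((time > grid[k]).sum())
        if n_k == 0:
            break
        idx = np.searchsorted(ev_times, end, side="right") - 1
        s = float(S_step[idx]) if idx >= 0 else 1.0
        v = float(var_step[idx]) if idx >= 0 else 0.0
        d_k = int(((time > grid[k]) & (time <= end) & is_cancer).sum())
        se = np.sqrt(v)
        if 0.0 < s < 1.0 and se > 0:
            sig = se / (s * abs(np.log(s)))
            lo = s ** np.exp(Z95 * sig)
            hi = s ** np.exp(-Z95 * sig)
        else:
            lo = hi = s
        rows.append((k + 1, end, n_k, d_k, s, se, lo, hi))
    table = pd.DataFrame(
        rows,
        columns=["interval", "months", "n_risk", "events", "estimate", "se", "ci_low", "ci_high"],
    )
    return SurvivalCurve(kind="cause-specific", interval_months=interval_months, table=table)


def suppress_small_groups(curves: dict, group_sizes: dict, min_n: int = 50) -> dict:
    """Withhold estimates for groups with fewer than ``min_n`` patients at diagnosis.

    Suppressed curves keep their grid but carry NaN estimates and the
    ``suppressed`` flag; a group of exactly ``min_n`` is reported.
    """
    out = {}
    for group, curve in curves.items():
        if group_sizes.get(group, 0) < min_n:
            table = curve.table.copy()
            for col in ("estimate", "se"):
                table[col] = np.nan
            out[group] = replace(curve, table=table, suppressed=True)
        else:
            out[group] = curve
    return out
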