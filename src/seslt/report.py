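"""Summary surfaces: survival comparison tables and life-expectancy summaries.

The central comparison is between three 10-year survival measures per
patient group: (a) relative survival computed with national-average life
tables, (b) relative survival computed with county-SES-matched tables, and
(c) cause-specific survival.  Whichever relative-survival variant sits
closer to cause-specific survival better captured the cohort's background
mortality, so the table reports |a-c|, |b-c| and their difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lifetable import LifeTable, LifeTableLibrary, adjusted_life_table
from .ltmodel import FittedLTModel

__all__ = [
    "comparison_table",
    "life_expectancy_summary",
    "life_tables_from_model",
]


def comparison_table(values: pd.DataFrame, display_rounding: bool = True) -> pd.DataFrame:
    """Per-group comparison of relative vs cause-specific survival percentages.

    ``values`` has columns group, a (relative survival, reference-average
    tables, %), b (relative survival, SES-matched tables, %), c
    (cause-specific survival, %).  Returns those columns plus diff_a = |a-c|,
    diff_b = |b-c| and closer_by = diff_a - diff_b (positive when the
    SES-matched tables sit closer to cause-specific survival).

    With ``display_rounding`` (default) inputs are rounded to one decimal —
    the publication display scale — before differencing, so the output
    reproduces a printed table's difference columns; otherwise differences
    use the inputs at full precision.
    """
    required = {"group", "a", "b", "c"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    for col in ("a", "b", "c"):
        v = values[col].to_numpy(float)
        if np.any((v < 0) | (v > 200)):
            raise ValueError(f"column {col!r} must hold survival percentages in [0, 200]")
    out = values[["group", "a", "b", "c"]].copy()
    a, b, c = (out[col].to_numpy(float) for col in ("a", "b", "c"))
    if display_rounding:
        a, b, c = np.round(a, 1), np.round(b, 1), np.round(c, 1)
    out["diff_a"] = np.round(np.abs(a - c), 10)
    out["diff_b"] = np.round(np.abs(b - c), 10)
    out["closer_by"] = out["diff_a"] - out["diff_b"]
    return out


def life_expectancy_summary(
    lt_library: LifeTableLibrary,
    groups: pd.DataFrame,
    weighted: bool = True,
) -> pd.DataFrame:
    """Per-group life expectancy with the low/high SES-quintile range.

    ``groups`` has one row per (group, quintile) with columns group, quintile,
    stratum, year and optionally population (quintile weights).  For each
    group the summary holds the mean expectancy over quintiles
    (population-weighted when ``weighted`` and weights are present, else
    unweighted), and the expectancies of the lowest and highest quintile —
    the left and right ends of a disparity bar.  Missing strata are reported
    as gaps (NaN rows), not failures.
    """
    rows = []
    for group, grp in groups.groupby("group", sort=True):
        recs = []
        for _, r in grp.iterrows():
            try:
                lt = lt_library.get(r["stratum"], int(r["year"]))
            except KeyError:
                continue
            w = float(r["population"]) if "population" in grp.columns and weighted else 1.0
            recs.append((r["quintile"], lt.life_expectancy(), w))
        if not recs:
            rows.append((group, np.nan, np.nan, np.nan, 0))
            continue
        recs.sort(key=lambda t: t[0])
        e = np.array([r[1] for r in recs])
        w = np.array([r[2] for r in recs])
        rows.append((group, float(np.average(e, weights=w)), e[0], e[-1], len(recs)))
    return pd.DataFrame(
        rows, columns=["group", "mean_e0", "e0_lowest_q", "e0_highest_q", "n_quintiles"]
    )


def life_tables_from_model(
    model: FittedLTModel,
    reference: LifeTable,
    years,
    ses_levels=None,
    stratum_template: str = "{base}/{level}",
    base: str = "",
) -> LifeTableLibrary:
    """Build complete boundary-adjusted life tables from a fitted model.

    For each year and SES level, predicts central rates at ages 35-84,
    extends them to 0-99 against the reference table's age shape, and builds
    the standard columns.  Strata are labeled by ``stratum_template``.
    """
    levels = list(ses_levels) if ses_levels is not None else (list(model.spec.ses_levels) or [None])
    lib = LifeTableLibrary()
    for year in np.atleast_1d(years):
        for lvl in levels:
            rates = model.modeled_rates(float(year), lvl)
            label = (
                stratum_template.format(base=base or model.stratum, level=lvl)
                if lvl is not None
                else (base or model.stratum)
            )
            lib.add(adjusted_life_table(rates, reference, stratum=label, year=int(year)))
    return lib
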