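"""County SES index interpolation and population-weighted quintile assignment.

A composite county socioeconomic index is observed only at anchor years
(census years and survey midpoints; default 1990, 2000, 2007, 2008, 2009).
Intermediate years are filled by straight-line interpolation between the two
bracketing anchors; years outside the anchor span are linearly extrapolated
from the two nearest anchors; a county with a single anchor carries its value
constant.  Counties are then ranked nationally each year and cut into five
bands each holding ~20% of the national population (Q1 = lowest SES), with a
coarser 2-level grouping low = Q1-Q3 vs high = Q4-Q5.

Because counties have unequal populations, a county can straddle a 20%
boundary; the quintile is the band containing the *midpoint* of the county's
cumulative-population interval, which keeps the assignment deterministic and
the population shares as close to equal as single counties allow.  Ties in
the index are broken by county ID ascending.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ANCHOR_YEARS",
    "interpolate_ses_index",
    "assign_quintiles",
    "collapse_two_level",
]

DEFAULT_ANCHOR_YEARS = (1990, 2000, 2007, 2008, 2009)

_N_QUINTILES = 5


def _interp_county(years: np.ndarray, values: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Piecewise-linear with linear extrapolation from the two nearest anchors."""
    if len(years) == 1:
        return np.full(len(targets), values[0])
    out = np.interp(targets, years, values)
    lo = targets < years[0]
    if lo.any():
        slope = (values[1] - values[0]) / (years[1] - years[0])
        out[lo] = values[0] + slope * (targets[lo] - years[0])
    hi = targets > years[-1]
    if hi.any():
        slope = (values[-1] - values[-2]) / (years[-1] - years[-2])
        out[hi] = values[-1] + slope * (targets[hi] - years[-1])
    return out


def interpolate_ses_index(anchors: pd.DataFrame, target_years) -> pd.DataFrame:
    """Fill an SES index table at ``target_years`` from anchor-year records.

    ``anchors`` has columns county, year, index, population with at least one
    record per county.  Populations are interpolated the same way as the
    index and clipped at zero (quintile assignment needs per-year weights).
    """
    required = {"county", "year", "index", "population"}
    if not required <= set(anchors.columns):
        raise ValueError(f"anchor table must have columns {sorted(required)}")
    targets = np.asarray(sorted(set(int(y) for y in np.atleast_1d(target_years))))
    frames = []
    for county, grp in anchors.sort_values("year").groupby("county", sort=True):
        if grp["year"].duplicated().any():
            raise ValueError(f"duplicate anchor year for county {county!r}")
        yrs = grp["year"].to_numpy(float)
        frames.append(
            pd.DataFrame(
                {
                    "county": county,
                    "year": targets,
                    "index": _interp_county(yrs, grp["index"].to_numpy(float), targets),
                    "population": np.clip(
                        _interp_county(yrs, grp["population"].to_numpy(float), targets), 0, None
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def assign_quintiles(ses: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted national quintiles per calendar year.

    Counties are sorted ascending by index (ties by county ID); each county
    falls in the quintile band containing the midpoint of its cumulative
    national-population interval.  Returns the input columns plus ``quintile``
    (1 = lowest SES) and ``level2``.
    """
    if ses["index"].isna().any():
        raise ValueError("missing SES index values")
    out = []
    for year, grp in ses.groupby("year", sort=True):
        total = grp["population"].sum()
        if total <= 0:
            raise ValueError(f"year {year} has non-positive total population")
        grp = grp.sort_values(["index", "county"], kind="mergesort").copy()
        pop = grp["population"].to_numpy(float)
        mid_frac = (np.cumsum(pop) - 0.5 * pop) / total
        grp["quintile"] = np.minimum(
            (mid_frac * _N_QUINTILES).astype(int) + 1, _N_QUINTILES
        )
        out.append(grp)
    result = pd.concat(out, ignore_index=True)
    return collapse_two_level(result)


def collapse_two_level(q: pd.DataFrame) -> pd.DataFrame:
    """Attach the 2-level grouping: low = Q1-Q3, high = Q4-Q5."""
    quintile = q["quintile"].to_numpy()
    if np.any((quintile < 1) | (quintile > _N_QUINTILES)):
        raise ValueError("quintile labels must lie in 1..5")
    out = q.copy()
    out["level2"] = np.where(quintile <= 3, "low", "high")
    return out
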