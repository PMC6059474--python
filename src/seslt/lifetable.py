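"""Complete period life tables from modeled adult mortality rates.

Mortality models are fit on ages 30-84 only; a complete table on single ages
0-99 is obtained by keeping the modeled level at the anchor ages 35 and 84 and
borrowing the age *shape* of a reference (national decennial-style) life table
below 35 and above 84.  All boundary arithmetic is done on the central-rate
scale (m), converting the reference table's death probabilities to rates with
m = -ln(1-q) and back with q = 1 - exp(-m), so the ratio adjustment is applied
on one declared scale throughout.

Tables are closed at exact age 99: the age-99 row contributes person-years
L_99 = l_99 - 0.5 d_99 and nothing beyond, and truncated ("temporary") life
expectancy measures years lived between an age and exact age 99.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGE_MAX",
    "ANCHOR_LOW",
    "ANCHOR_HIGH",
    "RADIX",
    "LifeTable",
    "LifeTableLibrary",
    "rate_to_q",
    "q_to_rate",
    "boundary_adjust",
    "build_life_table",
    "life_expectancy",
    "adjusted_life_table",
]

AGE_MAX = 99
ANCHOR_LOW = 35
ANCHOR_HIGH = 84
RADIX = 100_000.0
AGES = np.arange(AGE_MAX + 1)


def rate_to_q(m):
    """Annual death probability from a central death rate: q = 1 - exp(-m)."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("central death rates must be non-negative")
    return -np.expm1(-m)


def q_to_rate(q):
    """Central death rate from an annual death probability: m = -ln(1-q).

    q = 1 maps to +inf; ratios of rates at q = 1 are handled by callers.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("death probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        return -np.log1p(-q)


@dataclass
class LifeTable:
    """Single-age period life table for one population stratum and year.

    Columns follow standard demographic notation: ``q_x`` conditional death
    probability, ``l_x`` survivorship from radix 100,000, ``L_x`` person-years
    lived in [x, x+1) with a_x = 0.5, and ``e_x`` the truncated expectancy —
    expected years lived between exact age x and exact age 99.
    """

    stratum: str
    year: int
    qx: np.ndarray
    lx: np.ndarray = field(repr=False)
    Lx: np.ndarray = field(repr=False)
    ex: np.ndarray = field(repr=False)

    @property
    def ages(self) -> np.ndarray:
        return AGES

    def life_expectancy(self, from_age: int = 0) -> float:
        return life_expectancy(self, from_age)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "year": self.year,
                "age": AGES,
                "q_x": self.qx,
                "l_x": self.lx,
                "L_x": self.Lx,
                "e_x": self.ex,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        frame = frame.sort_values("age")
        if len(frame) != AGE_MAX + 1 or not np.array_equal(frame["age"].to_numpy(), AGES):
            raise ValueError("life-table frame must have one row per single age 0-99")
        return build_life_table(
            frame["q_x"].to_numpy(),
            stratum=str(frame["stratum"].iloc[0]),
            year=int(frame["year"].iloc[0]),
        )

    @classmethod
    def read_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))


def build_life_table(q, stratum: str = "", year: int = 0) -> LifeTable:
    """Build the standard columns from per-age death probabilities 0-99.

    l_0 = 100,000; l_{x+1} = l_x (1 - q_x); L_x = l_x - 0.5 d_x (a_x = 0.5
    at every age, infancy included — young-age shape comes from the reference
    table, so a refined infant separation factor would be spurious precision).
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (AGE_MAX + 1,):
        raise ValueError(f"expected {AGE_MAX + 1} single-age probabilities, got shape {q.shape}")
    if np.any((q < 0) | (q > 1)) or not np.all(np.isfinite(q)):
        raise ValueError("death probabilities must lie in [0, 1]")
    surv = np.cumprod(1.0 - q)
    lx = RADIX * np.concatenate(([1.0], surv[:-1]))
    dx = lx * q
    Lx = lx - 0.5 * dx
    # e_x = years lived between exact age x and exact age 99
    tail = np.concatenate((np.cumsum(Lx[:-1][::-1])[::-1], [0.0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, tail / lx, 0.0)
    return LifeTable(stratum=stratum, year=year, qx=q, lx=lx, Lx=Lx, ex=ex)


def life_expectancy(lt: LifeTable, from_age: int = 0) -> float:
    """Truncated (temporary) expectancy between ``from_age`` and exact age 99."""
    if not 0 <= from_age <= AGE_MAX:
        raise ValueError("from_age must be in 0..99")
    if lt.lx[from_age] <= 0:
        raise ValueError(f"no survivors at age {from_age}")
    return float(lt.Lx[from_age:AGE_MAX].sum() / lt.lx[from_age])


def boundary_adjust(modeled_rates, reference: LifeTable) -> np.ndarray:
    """Extend modeled central rates on ages 35-84 to 0-99 with a reference shape.

    Ages 35-84 pass through unchanged.  Below 35 and above 84 the output takes
    the reference table's age shape, scaled so that the adjusted series equals
    the modeled level at the anchor ages:

        m(a) = m(35) * m_US(a) / m_US(35)   for a < 35
        m(a) = m(84) * m_US(a) / m_US(84)   for a > 84

    where m_US = -ln(1 - q_US) is the reference table on the rate scale.

    Parameters
    ----------
    modeled_rates
        Central death rates at single ages 35..84 (length 50) on the
        per-person-year scale.
    reference
        Complete reference life table whose q_x at the anchors is positive.
    """
    modeled = np.asarray(modeled_rates, dtype=float)
    n_model = ANCHOR_HIGH - ANCHOR_LOW + 1
    if modeled.shape != (n_model,):
        raise ValueError(f"modeled rates must cover ages {ANCHOR_LOW}-{ANCHOR_HIGH} (length {n_model})")
    if np.any(modeled < 0) or not np.all(np.isfinite(modeled)):
        raise ValueError("modeled rates must be finite and non-negative")
    ref_m = q_to_rate(reference.qx)
    if ref_m[ANCHOR_LOW] <= 0 or ref_m[ANCHOR_HIGH] <= 0 or not np.isfinite(ref_m[ANCHOR_HIGH]):
        raise ValueError("reference table must have positive, finite rates at the anchor ages")
    out = np.empty(AGE_MAX + 1)
    out[ANCHOR_LOW : ANCHOR_HIGH + 1] = modeled
    # scale factor computed first so modeled == reference is an exact identity
    out[:ANCHOR_LOW] = (modeled[0] / ref_m[ANCHOR_LOW]) * ref_m[:ANCHOR_LOW]
    out[ANCHOR_HIGH + 1 :] = (modeled[-1] / ref_m[ANCHOR_HIGH]) * ref_m[ANCHOR_HIGH + 1 :]
    return out


def adjusted_life_table(
    modeled_rates, reference: LifeTable, stratum: str = "", year: int = 0
) -> LifeTable:
    """Boundary-adjust modeled adult rates and build the complete table."""
    rates = boundary_adjust(modeled_rates, reference)
    return build_life_table(rate_to_q(rates), stratum=stratum, year=year)


class LifeTableLibrary:
    """Collection of life tables keyed by stratum and calendar year.

    Lookup carries the last available year forward (and the first backward)
    when a requested calendar year is outside the stored span, matching how
    expected-survival software treats follow-up beyond the final table year.
    """

    def __init__(self, tables=()):
        self._tables: dict[tuple[str, int], LifeTable] = {}
        self._qgrid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for lt in tables:
            self.add(lt)

    def add(self, lt: LifeTable) -> None:
        self._tables[(lt.stratum, lt.year)] = lt
        self._qgrid.pop(lt.stratum, None)

    def __len__(self) -> int:
        return len(self._tables)

    @property
    def strata(self) -> list[str]:
        return sorted({s for s, _ in self._tables})

    def years(self, stratum: str) -> list[int]:
        return sorted(y for s, y in self._tables if s == stratum)

    def get(self, stratum: str, year: int) -> LifeTable:
        years = self.years(stratum)
        if not years:
            raise KeyError(f"no life tables for stratum {stratum!r}")
        year = min(max(year, years[0]), years[-1])
        eligible = [y for y in years if y <= year]
        return self._tables[(stratum, eligible[-1])]

    def _grid(self, stratum: str):
        if stratum not in self._qgrid:
            years = np.asarray(self.years(stratum))
            if years.size == 0:
                raise KeyError(f"no life tables for stratum {stratum!r}")
            q = np.stack([self._tables[(stratum, y)].qx for y in years])
            self._qgrid[stratum] = (years, q)
        return self._qgrid[stratum]

    def annual_q(self, stratum: str, years, ages) -> np.ndarray:
        """Vectorized q_x lookup with year carry-forward and ages clipped to 0-99."""
        yrs, q = self._grid(stratum)
        years = np.atleast_1d(np.asarray(years, dtype=int))
        ages = np.atleast_1d(np.asarray(ages, dtype=int))
        yi = np.clip(np.searchsorted(yrs, years, side="right") - 1, 0, len(yrs) - 1)
        ai = np.clip(ages, 0, AGE_MAX)
        return q[yi, ai]
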