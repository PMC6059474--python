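"""Reproducible simulation studies exercising the full pipeline.

These are the package's standing experiments: each function runs a complete
study — generate synthetic data with known truth, push it through the
pipeline, measure recovery — and returns plain numbers.  They back both the
test suite and the results-reproduction script, so study conditions (sample
sizes, effect sizes, replicate counts) are defined once, here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic
from .lifetable import LifeTableLibrary, adjusted_life_table, build_life_table
from .ltmodel import ModelSpec, aggregate_rates, fit_poisson_lt
from .report import comparison_table
from .survival import (
    apply_cohort_filters,
    expected_survival_ederer2,
    observed_survival_actuarial,
    relative_survival,
)
from .synthetic import SimConfig, TrueSurface, true_coefficients, true_life_expectancy

__all__ = [
    "seer18_survival_75_84",
    "published_comparison",
    "null_excess_calibration",
    "gradient_reduction_study",
    "model_recovery_study",
]


def seer18_survival_75_84() -> pd.DataFrame:
    """Published 10-year survival percentages for SEER-18 patients aged 75-84.

    Input data for the comparison-table arithmetic: per race group, 10-year
    relative survival computed with national-average life tables (a), with
    county-SES-matched life tables (b), and 10-year cause-specific survival
    (c), for patients diagnosed with any cancer in 2000-2012, both sexes,
    ages 75-84 at diagnosis.
    """
    return pd.DataFrame(
        {
            "group": ["NH Whites", "NH Blacks", "NH AI/AN", "NH API", "Hispanics"],
            "a": [48.5, 39.5, 21.8, 42.6, 51.3],
            "b": [48.7, 38.2, 35.2, 43.1, 41.4],
            "c": [44.8, 37.9, 32.2, 43.7, 43.0],
        }
    )


def published_comparison() -> pd.DataFrame:
    """Comparison table computed from the published survival percentages."""
    return comparison_table(seer18_survival_75_84(), display_rounding=True)


def _rs_at(cohort, library, months):
    filtered = apply_cohort_filters(cohort)
    n_int = int(max(months) // 12)
    expected = expected_survival_ederer2(filtered, library, n_int, 12.0)
    observed = observed_survival_actuarial(filtered, n_int, 12.0)
    rs = relative_survival(observed, expected)
    return [rs.estimate_at(m) for m in months]


def null_excess_calibration(
    n_runs: int = 100,
    n_patients: int = 20_000,
    seed: int = 0,
    band: tuple = (0.98, 1.02),
) -> dict:
    """Zero-excess cohorts matched to their generating tables: RS should be 1.

    Simulates ``n_runs`` cohorts with no excess hazard from a known life
    table, computes 5- and 10-year relative survival against that same table,
    and reports the fraction of runs with both inside ``band``.
    """
    surface = TrueSurface()
    lt = synthetic.true_surface_life_table(surface, None, 2006, stratum="all")
    library = LifeTableLibrary([lt])
    rs5, rs10 = [], []
    base = int(seed) % (2**20)
    for run in range(n_runs):
        cohort = synthetic.generate_cohort(lt, 0.0, n_patients, seed=base * 1000 + run)
        r5, r10 = _rs_at(cohort, library, (60.0, 120.0))
        rs5.append(r5)
        rs10.append(r10)
    rs5, rs10 = np.asarray(rs5), np.asarray(rs10)
    in_band = (rs5 >= band[0]) & (rs5 <= band[1]) & (rs10 >= band[0]) & (rs10 <= band[1])
    return {
        "frac_in_band": float(in_band.mean()),
        "rs5_mean": float(rs5.mean()),
        "rs10_mean": float(rs10.mean()),
        "rs10_sd": float(rs10.std()),
        "n_runs": n_runs,
        "n_patients": n_patients,
    }


def gradient_reduction_study(
    n_per_stratum: int = 250_000,
    excess: float = 0.05,
    seed: int = 0,
) -> dict:
    """The pooled-table bias mechanism, on two SES strata with one excess hazard.

    Low- and high-SES strata share the same excess cancer hazard but differ
    in background mortality.  With stratum-matched tables, 10-year relative
    survival is the same net quantity in both strata (difference is pure
    Monte-Carlo noise).  With a single pooled-average table, the expected
    survival is too high for the low-SES stratum and too low for the high-SES
    one, so relative survival is biased low in the low-SES stratum and high
    in the high-SES stratum — the bias the SES-matched tables remove.

    Diagnosis ages 70-84 (where background differences bite); returns the
    matched-table |RS_low - RS_high| and the pooled-table RS_high - RS_low,
    both in survival points (percent).
    """
    surface = TrueSurface(
        age_knot_values=tuple(v - 0.30 for v in TrueSurface().age_knot_values),
        ses_effects={"low": 0.85, "high": 0.0},
        ses_age_slopes={"low": 0.0, "high": 0.0},
    )
    lt_low = synthetic.true_surface_life_table(surface, "low", 2006, stratum="low")
    lt_high = synthetic.true_surface_life_table(surface, "high", 2006, stratum="high")
    pooled_q = 0.5 * (lt_low.qx + lt_high.qx)
    pooled = LifeTableLibrary(
        [build_life_table(pooled_q, s, 2006) for s in ("low", "high")]
    )
    matched = LifeTableLibrary([lt_low, lt_high])
    base = int(seed) % (2**20)
    coh_low = synthetic.generate_cohort(
        lt_low, excess, n_per_stratum, seed=base * 100 + 1, diag_ages=(70, 84)
    )
    coh_high = synthetic.generate_cohort(
        lt_high, excess, n_per_stratum, seed=base * 100 + 2, diag_ages=(70, 84)
    )
    (rs_low_m,) = _rs_at(coh_low, matched, (120.0,))
    (rs_high_m,) = _rs_at(coh_high, matched, (120.0,))
    (rs_low_p,) = _rs_at(coh_low, pooled, (120.0,))
    (rs_high_p,) = _rs_at(coh_high, pooled, (120.0,))
    return {
        "matched_abs_diff_points": abs(rs_low_m - rs_high_m) * 100.0,
        "pooled_gap_points": (rs_high_p - rs_low_p) * 100.0,
        "rs_matched_low": rs_low_m * 100.0,
        "rs_matched_high": rs_high_m * 100.0,
        "rs_pooled_low": rs_low_p * 100.0,
        "rs_pooled_high": rs_high_p * 100.0,
        "true_net_survival": float(np.exp(-excess * 10.0)) * 100.0,
        "n_per_stratum": n_per_stratum,
    }


RECOVERY_SURFACE = TrueSurface(
    ses_effects={1: 0.0, 2: -0.06, 3: -0.12, 4: -0.18, 5: -0.25},
    ses_age_slopes={1: 0.0, 2: -0.0005, 3: -0.001, 4: -0.0015, 5: -0.002},
)
RECOVERY_CENTERS = (1994, 1998, 2002, 2006, 2010)


def model_recovery_study(
    n_replicates: int = 100,
    n_counties: int = 200,
    seed: int = 0,
) -> dict:
    """Coefficient and life-expectancy recovery of the Poisson spline fit.

    Each replicate simulates a county panel (populations >= 1e5 per cell)
    from a known quintile surface, fits the national 5-level-SES model on
    3-year grouped rates, and checks each true coefficient against its
    estimate +/- 3 SE.  Also rebuilds the quintile-5 life table end to end
    (fit -> boundary adjustment against the exact reference -> expectancy)
    and records the absolute error versus the exact surface expectancy.
    Reports pooled (replicate x coefficient) coverage, worst per-coefficient
    coverage, and the maximum life-expectancy error in years.
    """
    surface = RECOVERY_SURFACE
    spec = ModelSpec(area_level="national", ses_form="quintile5")
    truth = true_coefficients(surface, spec)
    reference = synthetic.true_surface_life_table(surface, 5, 2002)
    true_e0 = true_life_expectancy(surface, 5, 2002)
    base = int(seed) % (2**20)
    hits = {}
    le_errors = []
    for rep in range(n_replicates):
        config = SimConfig(
            n_counties=n_counties,
            population_range=(100_000, 200_000),
            years=(1992, 2012),
            seed=base * 1000 + rep,
        )
        panel = synthetic.generate_mortality_panel(config, surface)
        quintiles = synthetic.quintile_assignment(config)
        grouped = pd.concat(
            [aggregate_rates(panel, c, spec.grouping_window) for c in RECOVERY_CENTERS],
            ignore_index=True,
        )
        model = fit_poisson_lt(grouped, quintiles, spec)
        se = np.sqrt(np.diag(model.cov))
        for i, name in enumerate(model.colnames):
            hits.setdefault(name, []).append(
                abs(model.params[i] - truth[name]) <= 3.0 * se[i]
            )
        lt = adjusted_life_table(model.modeled_rates(2002.0, 5), reference, "fit", 2002)
        le_errors.append(abs(lt.life_expectancy() - true_e0))
    per_coef = {k: float(np.mean(v)) for k, v in hits.items()}
    pooled = float(np.mean([h for v in hits.values() for h in v]))
    return {
        "pooled_coverage": pooled,
        "min_coef_coverage": min(per_coef.values()),
        "per_coef_coverage": per_coef,
        "max_le_error_years": float(np.max(le_errors)),
        "mean_le_error_years": float(np.mean(le_errors)),
        "true_e0": float(true_e0),
        "n_replicates": n_replicates,
        "n_counties": n_counties,
    }
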