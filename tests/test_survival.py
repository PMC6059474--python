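import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from seslt import (
    LifeTableLibrary,
    apply_cohort_filters,
    attach_stratum,
    build_life_table,
    cause_specific_survival,
    expected_survival_ederer2,
    observed_survival_actuarial,
    relative_survival,
    suppress_small_groups,
)

from conftest import make_cohort


def ederer2_oracle(patients, annual_q, n_intervals, interval_months):
    """Brute-force Ederer II: explicit loops, no shared code with the package.

    ``patients``: (time_months, diag_age, diag_year, stratum) tuples;
    ``annual_q``: {stratum: q_list_by_age} with year-constant tables.
    """
    results = []
    cum = 1.0
    for k in range(n_intervals):
        start = k * interval_months
        at_risk = [p for p in patients if p[0] > start]
        if not at_risk:
            break
        total = 0.0
        for time, age, year, stratum in at_risk:
            attained = min(int(age) + int(start // 12), 99)
            q = annual_q[stratum][attained]
            total += (1.0 - q) ** (interval_months / 12.0)
        cum *= total / len(at_risk)
        results.append(cum)
    return results


class TestCohortFilters:
    def test_autopsy_and_dco_removed(self):
        cohort = make_cohort(
            [
                {"time_months": 10, "status": "dead", "source": "DCO"},
                {"time_months": 10, "status": "dead", "source": "autopsy"},
                {"time_months": 10, "status": "dead", "source": "registry"},
            ]
        )
        out = apply_cohort_filters(cohort)
        assert len(out) == 1 and out["source"].iloc[0] == "registry"

    def test_zero_survival_time_removed(self):
        cohort = make_cohort(
            [{"time_months": 0.0, "status": "dead"}, {"time_months": 5.0, "status": "alive"}]
        )
        assert len(apply_cohort_filters(cohort)) == 1

    def test_age_99_truncation(self):
        # diagnosed at 97, died at 30 months -> censored alive at 24 months
        cohort = make_cohort([{"time_months": 30.0, "status": "dead", "diag_age": 97}])
        out = apply_cohort_filters(cohort)
        assert out["time_months"].iloc[0] == 24.0
        assert out["status"].iloc[0] == "alive"

    def test_death_before_age_99_untouched(self):
        cohort = make_cohort([{"time_months": 20.0, "status": "dead", "diag_age": 97}])
        out = apply_cohort_filters(cohort)
        assert out["time_months"].iloc[0] == 20.0 and out["status"].iloc[0] == "dead"

    def test_single_primary_flag(self):
        cohort = make_cohort(
            [{"time_months": 5, "status": "alive", "n_primaries": 2},
             {"time_months": 5, "status": "alive", "n_primaries": 1}]
        )
        assert len(apply_cohort_filters(cohort, single_primary_only=True)) == 1
        assert len(apply_cohort_filters(cohort, single_primary_only=False)) == 2

    def test_attach_stratum_via_quintiles(self):
        cohort = make_cohort([{"time_months": 5, "status": "alive", "county": "C1"}])
        quintiles = pd.DataFrame(
            {"county": ["C1"], "year": [2000], "quintile": [4], "level2": ["high"]}
        )
        out = attach_stratum(cohort, quintiles, scheme="quintile5")
        assert out["stratum"].iloc[0] == "m/all/4"


class TestEderer2:
    def test_single_patient_constant_survival(self, toy_tables):
        library = LifeTableLibrary([toy_tables["A"]])
        cohort = make_cohort([{"time_months": 200.0, "status": "alive", "stratum": "A"}])
        curve = expected_survival_ederer2(cohort, library, 5, 12.0)
        assert curve.estimate_at(60.0) == pytest.approx(0.9**5, abs=1e-12)

    def test_zero_mortality_tables_give_unity(self):
        lt = build_life_table(np.zeros(100), stratum="Z", year=2000)
        cohort = make_cohort(
            [{"time_months": t, "status": "dead", "stratum": "Z"} for t in (5.0, 30.0, 80.0)]
        )
        curve = expected_survival_ederer2(cohort, LifeTableLibrary([lt]), 8, 12.0)
        assert np.allclose(curve.estimates, 1.0)

    def test_staggered_cohort_matches_oracle(self, toy_tables):
        library = LifeTableLibrary(toy_tables.values())
        rows = [
            {"time_months": 18.0, "status": "dead", "stratum": "A", "diag_age": 60},
            {"time_months": 30.0, "status": "dead", "stratum": "B", "diag_age": 75},
            {"time_months": 48.0, "status": "alive", "stratum": "C", "diag_age": 80},
        ]
        cohort = make_cohort(rows)
        curve = expected_survival_ederer2(cohort, library, 4, 12.0)
        annual_q = {s: lt.qx for s, lt in toy_tables.items()}
        patients = [(r["time_months"], r["diag_age"], 2000, r["stratum"]) for r in rows]
        oracle = ederer2_oracle(patients, annual_q, 4, 12.0)
        assert np.allclose(curve.estimates, oracle, atol=1e-12)

    def test_attained_age_moves_through_the_table(self):
        q = np.zeros(100)
        q[61] = 0.5  # only age 61 is risky
        lt = build_life_table(q, stratum="S", year=2000)
        cohort = make_cohort([{"time_months": 100.0, "status": "alive", "stratum": "S",
                               "diag_age": 60}])
        curve = expected_survival_ederer2(cohort, LifeTableLibrary([lt]), 3, 12.0)
        assert curve.estimates == pytest.approx([1.0, 0.5, 0.5], abs=1e-12)

    def test_unmatched_stratum_rejected(self, toy_tables):
        library = LifeTableLibrary([toy_tables["A"]])
        cohort = make_cohort([{"time_months": 10, "status": "alive", "stratum": "X"}])
        with pytest.raises(KeyError):
            expected_survival_ederer2(cohort, library, 5, 12.0)

    def test_risk_set_exhaustion_truncates_curve(self, toy_tables):
        library = LifeTableLibrary([toy_tables["A"]])
        cohort = make_cohort([{"time_months": 14.0, "status": "dead", "stratum": "A"}])
        curve = expected_survival_ederer2(cohort, library, 5, 12.0)
        assert len(curve.table) == 2  # nobody under follow-up after month 24


class TestObservedActuarial:
    def test_no_events_stays_at_one(self):
        cohort = make_cohort([{"time_months": 130.0, "status": "alive"}] * 4)
        curve = observed_survival_actuarial(cohort, 10, 12.0)
        assert np.allclose(curve.estimates, 1.0)

    def test_two_deaths_out_of_ten(self):
        rows = [{"time_months": 6.0, "status": "dead"}] * 2 + [
            {"time_months": 130.0, "status": "alive"}
        ] * 8
        curve = observed_survival_actuarial(make_cohort(rows), 1, 12.0)
        assert curve.estimate_at(12.0) == pytest.approx(0.8)

    def test_half_interval_censoring_credit(self):
        rows = (
            [{"time_months": 6.0, "status": "dead"}]
            + [{"time_months": 6.0, "status": "alive"}] * 2
            + [{"time_months": 130.0, "status": "alive"}] * 7
        )
        curve = observed_survival_actuarial(make_cohort(rows), 1, 12.0)
        assert curve.estimate_at(12.0) == pytest.approx(8.0 / 9.0)

    def test_boundary_death_belongs_to_earlier_interval(self):
        rows = [{"time_months": 12.0, "status": "dead"}] + [
            {"time_months": 130.0, "status": "alive"}
        ] * 3
        curve = observed_survival_actuarial(make_cohort(rows), 2, 12.0)
        assert curve.estimate_at(12.0) == pytest.approx(0.75)
        assert curve.estimate_at(24.0) == pytest.approx(0.75)


class TestRelativeSurvival:
    def _curves(self, obs_rows, toy_tables):
        cohort = make_cohort(obs_rows)
        library = LifeTableLibrary(toy_tables.values())
        observed = observed_survival_actuarial(cohort, 5, 12.0)
        expected = expected_survival_ederer2(cohort, library, 5, 12.0)
        return observed, expected

    def test_ratio_of_point_values(self):
        obs = observed_survival_actuarial(
            make_cohort([{"time_months": 130.0, "status": "alive"}] * 2), 1, 12.0
        )
        table = obs.table.copy()
        table["estimate"] = 0.8
        expected = type(obs)(kind="expected", interval_months=12.0, table=table)
        obs.table["estimate"] = 0.5
        rs = relative_survival(obs, expected)
        assert rs.estimate_at(12.0) == pytest.approx(0.625)

    def test_unity_expected_returns_observed(self, toy_tables):
        lt = build_life_table(np.zeros(100), stratum="A", year=2000)
        rows = [{"time_months": 30.0, "status": "dead", "stratum": "A"}] + [
            {"time_months": 130.0, "status": "alive", "stratum": "A"}
        ] * 3
        cohort = make_cohort(rows)
        observed = observed_survival_actuarial(cohort, 5, 12.0)
        expected = expected_survival_ederer2(cohort, LifeTableLibrary([lt]), 5, 12.0)
        rs = relative_survival(observed, expected)
        assert np.allclose(rs.estimates, observed.estimates)

    def test_relative_survival_may_exceed_one(self, toy_tables):
        rows = [{"time_months": 130.0, "status": "alive", "stratum": "B"}] * 5
        observed, expected = self._curves(rows, toy_tables)
        rs = relative_survival(observed, expected)
        assert np.all(rs.estimates > 1.0)

    def test_zero_expected_rejected(self):
        obs = observed_survival_actuarial(
            make_cohort([{"time_months": 130.0, "status": "alive"}]), 1, 12.0
        )
        bad = type(obs)(kind="expected", interval_months=12.0, table=obs.table.assign(estimate=0.0))
        with pytest.raises(ValueError):
            relative_survival(obs, bad)

    def test_mismatched_grids_rejected(self):
        cohort = make_cohort([{"time_months": 130.0, "status": "alive"}] * 2)
        a = observed_survival_actuarial(cohort, 2, 12.0)
        b = observed_survival_actuarial(cohort, 2, 6.0)
        with pytest.raises(ValueError):
            relative_survival(a, b)


class TestCauseSpecific:
    def test_no_cancer_deaths_stays_at_one(self):
        rows = [{"time_months": 30.0, "status": "dead", "cause": "other"}] * 3 + [
            {"time_months": 130.0, "status": "alive"}
        ] * 3
        curve = cause_specific_survival(make_cohort(rows), 5, 12.0)
        assert np.allclose(curve.estimates, 1.0)

    def test_km_product_over_two_event_times(self):
        rows = (
            [{"time_months": 10.0, "status": "dead", "cause": "cancer"}]
            + [{"time_months": 20.0, "status": "dead", "cause": "cancer"}]
            + [{"time_months": 130.0, "status": "alive"}] * 8
        )
        curve = cause_specific_survival(make_cohort(rows), 2, 12.0)
        assert curve.estimate_at(12.0) == pytest.approx(0.9)
        assert curve.estimate_at(24.0) == pytest.approx(0.9 * (1 - 1 / 9))

    def test_other_cause_death_is_censoring(self):
        rows = (
            [{"time_months": 5.0, "status": "dead", "cause": "other"}]
            + [{"time_months": 10.0, "status": "dead", "cause": "cancer"}]
            + [{"time_months": 130.0, "status": "alive"}] * 8
        )
        curve = cause_specific_survival(make_cohort(rows), 1, 12.0)
        # risk set at the cancer death is 9, not 10
        assert curve.estimate_at(12.0) == pytest.approx(1 - 1 / 9)

    def test_unknown_cause_configurable(self):
        rows = [{"time_months": 10.0, "status": "dead", "cause": "unknown"}] + [
            {"time_months": 130.0, "status": "alive"}
        ] * 4
        default = cause_specific_survival(make_cohort(rows), 1, 12.0)
        strict = cause_specific_survival(make_cohort(rows), 1, 12.0, unknown_cause_as_cancer=True)
        assert default.estimate_at(12.0) == 1.0
        assert strict.estimate_at(12.0) == pytest.approx(0.8)

    def test_matches_lifelines_kaplan_meier(self):
        rng = np.random.default_rng(12)
        n = 300
        times = rng.exponential(60.0, n)
        cens = rng.uniform(0, 120.0, n)
        observed_time = np.minimum(times, cens)
        is_cancer = times <= cens
        rows = [
            {"time_months": float(t), "status": "dead" if e else "alive",
             "cause": "cancer" if e else ""}
            for t, e in zip(observed_time, is_cancer)
        ]
        curve = cause_specific_survival(make_cohort(rows), 10, 12.0)
        kmf = KaplanMeierFitter().fit(observed_time, is_cancer)
        grid = curve.table["months"].to_numpy()
        ours = curve.table["estimate"].to_numpy()
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        assert np.allclose(ours, theirs, atol=1e-10)
        # log-log confidence intervals agree with lifelines' exponential Greenwood CI
        ci = kmf.confidence_interval_survival_function_
        idx = np.searchsorted(ci.index.to_numpy(), grid, side="right") - 1
        assert np.allclose(curve.table["ci_low"], ci.iloc[idx, 0].to_numpy(), atol=5e-3)
        assert np.allclose(curve.table["ci_high"], ci.iloc[idx, 1].to_numpy(), atol=5e-3)


class TestSuppression:
    def _curve(self):
        return observed_survival_actuarial(
            make_cohort([{"time_months": 130.0, "status": "alive"}] * 3), 2, 12.0
        )

    def test_below_threshold_suppressed(self):
        curves = suppress_small_groups({"g": self._curve()}, {"g": 49})
        assert curves["g"].suppressed and np.isnan(curves["g"].estimates).all()

    def test_at_threshold_reported(self):
        curves = suppress_small_groups({"g": self._curve()}, {"g": 50})
        assert not curves["g"].suppressed

    def test_zero_threshold_suppresses_nothing(self):
        curves = suppress_small_groups({"g": self._curve()}, {"g": 1}, min_n=0)
        assert not curves["g"].suppressed
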