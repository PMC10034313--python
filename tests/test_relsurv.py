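import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from misseddeaths.lifetable import LifeTable, make_constant_lifetable
from misseddeaths.relsurv import (
    PeriodWindow,
    SurvivalCurve,
    age_standardize,
    conditional_rs,
    estimate_period_rs,
    expected_survival_ederer2,
    observed_survival,
    period_contributions,
    relative_survival,
)
from misseddeaths import CohortConfig

from conftest import brute_force_actuarial, cohort_frame, constant_lt, make_patient


WINDOW_2011_2016 = PeriodWindow(dt.date(2011, 12, 31), dt.date(2016, 12, 31))


class TestPeriodContributions:
    def test_recent_patient_full_contribution(self):
        # diagnosed within the window, death in year 2
        df = cohort_frame(
            [make_patient("a", status="dead", dx="2012-01-01", exit="2013-12-31")]
        )
        c = period_contributions(df, WINDOW_2011_2016, horizon=5)
        frame = c.to_frame()
        assert list(frame["interval"]) == [1, 2]
        assert list(frame["death"]) == [False, True]
        assert not frame["late_entry"].any()

    def test_no_calendar_overlap_means_no_contribution(self):
        df = cohort_frame(
            [make_patient("a", status="dead", dx="1990-01-01", exit="1995-01-01")]
        )
        c = period_contributions(df, WINDOW_2011_2016, horizon=35)
        assert c.to_frame().empty

    def test_late_entry_contributes_window_intervals_only(self):
        df = cohort_frame(
            [make_patient("a", status="alive", dx="2005-12-29", exit="2016-12-26")]
        )
        c = period_contributions(df, WINDOW_2011_2016, horizon=35)
        frame = c.to_frame()
        assert list(frame["interval"]) == [7, 8, 9, 10, 11]
        assert not frame["death"].any()
        assert bool(frame.loc[frame["interval"] == 7, "late_entry"].iloc[0])

    def test_attained_age_and_year_advance_together(self):
        df = cohort_frame(
            [make_patient("a", age=70, status="alive", dx="2012-06-01", exit="2016-06-01")]
        )
        c = period_contributions(df, WINDOW_2011_2016, horizon=4)
        frame = c.to_frame()
        assert list(frame["age_start"]) == [70, 71, 72, 73]
        assert list(frame["year_start"]) == [2012, 2013, 2014, 2015]


class TestObservedSurvival:
    def test_simple_first_year_probability(self, wide_window):
        records = [
            make_patient(f"d{i}", status="dead", dx="2000-01-01", exit="2000-06-01")
            for i in range(2)
        ] + [
            make_patient(f"a{i}", status="alive", dx="2000-01-01", exit="2005-01-01")
            for i in range(8)
        ]
        c = period_contributions(cohort_frame(records), wide_window, horizon=1)
        curve = observed_survival(c)
        assert curve.s_obs[0] == pytest.approx(0.8)

    def test_no_deaths_gives_unit_survival_zero_se(self, wide_window):
        records = [
            make_patient(f"a{i}", status="alive", dx="2000-01-01", exit="2006-01-01")
            for i in range(5)
        ]
        c = period_contributions(cohort_frame(records), wide_window, horizon=5)
        curve = observed_survival(c)
        np.testing.assert_allclose(curve.s_obs, 1.0)
        np.testing.assert_allclose(curve.se_obs, 0.0)

    def test_three_person_hand_table(self, toy3, wide_window):
        # interval 1: n=3, 1 death -> p=2/3; interval 2: n=2, both withdraw
        # within the interval -> n'=1, p=1.  Greenwood se = S*sqrt(1/6).
        c = period_contributions(toy3, wide_window, horizon=2)
        curve = observed_survival(c)
        np.testing.assert_allclose(curve.s_obs, [2 / 3, 2 / 3])
        np.testing.assert_allclose(curve.n_risk, [3, 2])
        np.testing.assert_allclose(curve.deaths, [1, 0])
        se = (2 / 3) * np.sqrt(1 / (3 * 2))
        np.testing.assert_allclose(curve.se_obs, [se, se])

    def test_matches_brute_force_oracle_on_random_cohort(self, wide_window):
        rng = np.random.default_rng(7)
        records = []
        for i in range(120):
            dx = dt.date(2000, 1, 1) + dt.timedelta(days=int(rng.integers(0, 4000)))
            fu_days = int(rng.integers(1, 5000))
            records.append(
                make_patient(
                    i,
                    status="dead" if rng.random() < 0.5 else "alive",
                    dx=dx.isoformat(),
                    exit=(dx + dt.timedelta(days=fu_days)).isoformat(),
                )
            )
        df = cohort_frame(records)
        window = PeriodWindow(dt.date(2008, 1, 1), dt.date(2013, 1, 1))
        c = period_contributions(df, window, horizon=12)
        curve = observed_survival(c)
        n, d, n_eff, s = brute_force_actuarial(df, window, 12)
        np.testing.assert_allclose(curve.n_risk, n[: len(curve)])
        np.testing.assert_allclose(curve.deaths, d[: len(curve)])
        np.testing.assert_allclose(curve.s_obs, s[: len(curve)])


class TestEdererII:
    def test_homogeneous_cohort_reproduces_power(self, wide_window):
        records = [
            make_patient(f"a{i}", age=60, status="alive", dx="2000-01-01", exit="2010-01-01")
            for i in range(4)
        ]
        c = period_contributions(cohort_frame(records), wide_window, horizon=3)
        s_exp = expected_survival_ederer2(c, constant_lt(0.95))
        np.testing.assert_allclose(s_exp, [0.95, 0.95**2, 0.95**3])

    def test_unit_lifetable_means_rs_equals_observed(self, toy3, wide_window, unit_lt):
        c = period_contributions(toy3, wide_window, horizon=2)
        curve = relative_survival(
            observed_survival(c), expected_survival_ederer2(c, unit_lt, length=2)
        )
        np.testing.assert_allclose(curve.rs, curve.s_obs)

    def test_mixed_ages_average_hand_mean(self, wide_window):
        rows = [
            {"sex": s, "age": a, "year": 2000, "px": 0.9 if a < 65 else 0.8}
            for s in ("male", "female")
            for a in range(100)
        ]
        lt = LifeTable(pd.DataFrame(rows))
        records = [
            make_patient("y", age=60, status="alive", dx="2000-01-01", exit="2002-01-01"),
            make_patient("o", age=70, status="alive", dx="2000-01-01", exit="2002-01-01"),
        ]
        c = period_contributions(cohort_frame(records), wide_window, horizon=1)
        s_exp = expected_survival_ederer2(c, lt)
        assert s_exp[0] == pytest.approx(0.85)


class TestRelativeSurvival:
    def test_equal_curves_give_100_percent(self, toy3, wide_window, unit_lt):
        c = period_contributions(toy3, wide_window, horizon=2)
        obs = observed_survival(c)
        curve = relative_survival(obs, obs.s_obs.copy())
        np.testing.assert_allclose(curve.rs_percent, 100.0)

    def test_quotient_can_exceed_100(self):
        curve = SurvivalCurve(
            years=np.array([20]),
            n_risk=np.array([10]),
            deaths=np.array([0]),
            s_obs=np.array([0.6]),
            se_obs=np.array([0.05]),
        )
        rel = relative_survival(curve, np.array([0.5]))
        assert rel.rs_percent[0] == pytest.approx(120.0)
        assert rel.se_rs[0] == pytest.approx(0.1)

    def test_outliving_population_gives_rs_above_100_everywhere(self, wide_window):
        records = [
            make_patient(f"a{i}", age=80, status="alive", dx="2000-01-01", exit="2010-01-01")
            for i in range(10)
        ]
        df = cohort_frame(records)
        cfg = CohortConfig()
        curve = estimate_period_rs(df, constant_lt(0.9), cfg, horizon=5, window=wide_window)
        assert (curve.rs > 1.0).all()


class TestConditionalRS:
    def test_flat_curve(self):
        curve = _rs_curve(np.full(4, 0.8))
        np.testing.assert_allclose(conditional_rs(curve), [0.8, 1, 1, 1])

    def test_geometric_curve(self):
        curve = _rs_curve(np.array([0.9, 0.81]))
        np.testing.assert_allclose(conditional_rs(curve), [0.9, 0.9])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.2), min_size=1, max_size=30)
    )
    def test_product_telescopes_back_to_cumulative(self, rs_values):
        curve = _rs_curve(np.array(rs_values))
        np.testing.assert_allclose(np.cumprod(conditional_rs(curve)), curve.rs)


def _rs_curve(rs, se=None):
    J = len(rs)
    se = np.zeros(J) if se is None else np.asarray(se, dtype=float)
    return SurvivalCurve(
        years=np.arange(1, J + 1),
        n_risk=np.full(J, 100),
        deaths=np.zeros(J, dtype=int),
        s_obs=np.asarray(rs, dtype=float),
        se_obs=se,
        s_exp=np.ones(J),
        rs=np.asarray(rs, dtype=float),
        se_rs=se,
    )


class TestAgeStandardize:
    WEIGHTS = {"15-54": 0.19, "55-74": 0.52, "75+": 0.29}

    def test_identical_groups_unchanged(self):
        curves = {k: _rs_curve(np.full(3, 0.5)) for k in self.WEIGHTS}
        std = age_standardize(curves, self.WEIGHTS)
        np.testing.assert_allclose(std.rs, 0.5)

    def test_hand_dot_product(self):
        curves = {
            "15-54": _rs_curve(np.array([1.0])),
            "55-74": _rs_curve(np.array([0.5])),
            "75+": _rs_curve(np.array([0.0001])),
        }
        curves["75+"].rs[:] = 0.0
        std = age_standardize(curves, self.WEIGHTS)
        assert std.rs_percent[0] == pytest.approx(0.19 * 100 + 0.52 * 50 + 0.29 * 0)

    def test_single_group_weight_one_is_identity(self):
        curves = {"all": _rs_curve(np.array([0.7, 0.6]), se=np.array([0.1, 0.2]))}
        std = age_standardize(curves, {"all": 1.0})
        np.testing.assert_allclose(std.rs, [0.7, 0.6])
        np.testing.assert_allclose(std.se_rs, [0.1, 0.2])

    def test_se_combines_weighted_variances(self):
        curves = {
            k: _rs_curve(np.array([0.5]), se=np.array([0.1])) for k in self.WEIGHTS
        }
        std = age_standardize(curves, self.WEIGHTS)
        expected = np.sqrt(sum(w**2 * 0.01 for w in self.WEIGHTS.values()))
        assert std.se_rs[0] == pytest.approx(expected)


class TestPeriodVsCohort:
    def test_all_time_window_equals_cohort_estimate(self, wide_window):
        # with no calendar trend, a window covering all person-time gives the
        # plain cohort life-table estimate (computed by the brute-force oracle
        # with the window disabled)
        rng = np.random.default_rng(11)
        records = []
        for i in range(200):
            fu_days = int(rng.integers(30, 3000))
            records.append(
                make_patient(
                    i,
                    status="dead" if rng.random() < 0.6 else "alive",
                    dx="2000-01-01",
                    exit=(dt.date(2000, 1, 1) + dt.timedelta(days=fu_days)).isoformat(),
                )
            )
        df = cohort_frame(records)
        c = period_contributions(df, wide_window, horizon=8)
        curve = observed_survival(c)
        _, _, _, s = brute_force_actuarial(df, wide_window, 8)
        np.testing.assert_allclose(curve.s_obs, s[: len(curve)])

    def test_removing_late_entrant_does_not_change_earlier_intervals(self, wide_window):
        base = [
            make_patient(i, status="dead", dx="2000-01-01", exit="2001-06-01")
            for i in range(3)
        ] + [
            make_patient("s", status="alive", dx="2000-01-01", exit="2009-01-01")
        ]
        extra = make_patient("late", status="alive", dx="1995-01-01", exit="2009-01-01")
        window = PeriodWindow(dt.date(2000, 1, 1), dt.date(2010, 1, 1))
        c_with = period_contributions(cohort_frame(base + [extra]), window, horizon=3)
        c_without = period_contributions(cohort_frame(base), window, horizon=3)
        with_curve = observed_survival(c_with)
        without_curve = observed_survival(c_without)
        # the late entrant (enters at fu year 6) cannot alter years 1-3
        np.testing.assert_allclose(with_curve.s_obs, without_curve.s_obs)
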