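"""Cohort statistics: thresholds, correlation, survival analysis, report."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plasmacnv as pc
from plasmacnv.cohort_stats import (
    SampleRecord,
    build_report,
    km_estimate,
    load_plasma_cohort,
    logrank_test,
    median_value,
    r_squared,
    stratify_and_test,
    threshold_count,
)
from plasmacnv.fish_oncoscan import load_fish_table, load_oncoscan_table


@pytest.fixture(scope="module")
def cohort():
    return load_plasma_cohort()


class TestScalarStats:
    def test_bundled_z_column_statistics(self, cohort):
        z = [r.gw_z for r in cohort]
        assert median_value(z) == pytest.approx(2.2)
        assert max(z) == 31.5
        assert threshold_count(z, 3.0) == 8

    def test_bundled_tumor_fraction_statistics(self, cohort):
        itf = [r.itf_percent for r in cohort]
        assert median_value(itf) == pytest.approx(4.6)
        assert threshold_count(itf, 3.0) == 12

    def test_bundled_z_itf_correlation(self, cohort):
        z = [r.gw_z for r in cohort]
        itf = [r.itf_percent for r in cohort]
        assert r_squared(z, itf) == pytest.approx(0.81, abs=0.01)

    def test_perfect_linear_relation_gives_unity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert r_squared(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_r_squared_matches_covariance_formula(self):
        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 9.0]
        mx, my = sum(x) / 3, sum(y) / 3
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        vx = sum((a - mx) ** 2 for a in x)
        vy = sum((b - my) ** 2 for b in y)
        assert r_squared(x, y) == pytest.approx(cov * cov / (vx * vy))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_empty_inputs(self):
        assert threshold_count([], 3.0) == 0
        with pytest.raises(ValueError):
            median_value([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_median_matches_sort_based_oracle(self, values):
        s = sorted(values)
        n = len(s)
        oracle = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
        assert median_value(values) == pytest.approx(oracle)

    @given(
        st.lists(st.floats(-100, 100), min_size=0, max_size=50),
        st.floats(-100, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_threshold_count_matches_exhaustive_oracle(self, values, cutoff):
        assert threshold_count(values, cutoff) == sum(1 for v in values if v > cutoff)


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([3.0, 5.0, 9.0], [False, False, False])
        assert np.all(km.survival == 1.0)
        assert km.median == math.inf

    def test_no_censoring_matches_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0) == pytest.approx(1 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_interleaved_worked_example(self):
        # hand-computed product-limit values:
        # t=1 (event, n=6): S=5/6; t=2 censored; t=3 (event, n=4): S=5/8;
        # t=4 censored; t=5 (event, n=2): S=5/16; t=6 censored
        times = [1, 2, 3, 4, 5, 6]
        events = [True, False, True, False, True, False]
        km = km_estimate(times, events)
        assert km.survival_at(1) == pytest.approx(5 / 6)
        assert km.survival_at(3) == pytest.approx(5 / 8)
        assert km.survival_at(5) == pytest.approx(5 / 16)
        assert km.median == 5.0

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 40)
        e = rng.random(40) < 0.7
        km = km_estimate(t, e)
        inside = (km.ci_lower - 1e-9 <= km.survival) & (
            km.survival <= km.ci_upper + 1e-9
        )
        assert inside.all()

    def test_survival_is_non_increasing(self):
        rng = np.random.default_rng(6)
        km = km_estimate(rng.exponential(5, 50), rng.random(50) < 0.5)
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetric_in_group_order(self):
        rng = np.random.default_rng(7)
        t1, t2 = rng.exponential(5, 30), rng.exponential(9, 30)
        e1, e2 = rng.random(30) < 0.8, rng.random(30) < 0.8
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t2, e2, t1, e1)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(8)
        t1, t2 = rng.exponential(5, 25), rng.exponential(9, 25)
        e1, e2 = rng.random(25) < 0.8, rng.random(25) < 0.8
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(7.3 * t1, e1, 7.3 * t2, e2)
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [False], [2.0], [False])

    def test_detects_tumor_fraction_hazard_link(self):
        sheet, _ = pc.simulate_patient_cohort(200, seed=321)
        recs = _records(sheet)
        res = stratify_and_test(recs, "itf_percent").test
        assert res.p_value < 0.05

    def test_power_above_80_percent(self):
        hits = 0
        for rep in range(100):
            sheet, _ = pc.simulate_patient_cohort(200, seed=3_000 + rep)
            res = stratify_and_test(_records(sheet), "itf_percent").test
            hits += res.p_value < 0.05
        assert hits > 80

    def test_type_one_error_near_nominal(self):
        hits = 0
        n_rep = 400
        for rep in range(n_rep):
            sheet, _ = pc.simulate_patient_cohort(
                120, seed=100_000 + rep, hazard_slope=0.0
            )
            res = stratify_and_test(_records(sheet), "itf_percent").test
            hits += res.p_value < 0.05
        assert 0.02 <= hits / n_rep <= 0.08


def _records(sheet):
    return [
        SampleRecord(
            r.case_id,
            itf_percent=min(100.0, r.true_tf * 100),
            os_months=r.os_months,
            event=bool(r.event),
        )
        for r in sheet.itertuples()
    ]


class TestStratification:
    def test_high_tumor_fraction_group_has_lower_survival(self):
        sheet, _ = pc.simulate_patient_cohort(300, seed=55)
        strat = stratify_and_test(_records(sheet), "itf_percent")
        grid = np.linspace(5, 60, 12)
        lo = [strat.low.survival_at(t) for t in grid]
        hi = [strat.high.survival_at(t) for t in grid]
        assert np.mean(np.array(lo) > np.array(hi)) > 0.9
        assert strat.high_median_os < strat.low_median_os

    def test_median_ties_go_to_low_group(self):
        recs = [
            SampleRecord(str(i), gw_z=v, os_months=10.0 + i, event=True)
            for i, v in enumerate([1.0, 2.0, 2.0, 3.0, 4.0])
        ]
        strat = stratify_and_test(recs, "gw_z")  # median 2.0; ties -> low
        assert (strat.test.n1, strat.test.n2) == (3, 2)

    def test_too_few_records_rejected(self):
        recs = [
            SampleRecord(str(i), gw_z=float(i), os_months=10.0, event=True)
            for i in range(3)
        ]
        with pytest.raises(ValueError):
            stratify_and_test(recs, "gw_z")

    def test_constant_variable_rejected(self):
        recs = [
            SampleRecord(str(i), gw_z=1.0, os_months=10.0, event=True)
            for i in range(6)
        ]
        with pytest.raises(ValueError):
            stratify_and_test(recs, "gw_z")


class TestReport:
    def test_headline_numbers(self, cohort):
        report = build_report(
            fish=load_fish_table(), array=load_oncoscan_table(), records=cohort
        )
        assert report["fish"]["amplified"] == 17
        assert report["fish"]["low_amplified"] == 3
        assert report["fish"]["positive"] == 20
        assert report["concordance"]["percent"] == 91
        assert report["plasma"]["n_gw_z_above_cutoff"] == 8
        assert report["plasma"]["n_itf_above_cutoff"] == 12
        assert report["plasma"]["n_itf_above_cutoff_fish_positive"] == 7
        assert report["plasma"]["gw_z_median"] == pytest.approx(2.2)
        assert report["plasma"]["itf_median_percent"] == pytest.approx(4.6)
        assert report["plasma"]["r_squared_z_vs_itf"] == pytest.approx(0.81, abs=0.01)

    def test_report_deterministic(self, cohort):
        a = build_report(fish=load_fish_table(), records=cohort)
        b = build_report(fish=load_fish_table(), records=cohort)
        assert a == b

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_report()
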