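import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from melrisk.imaging_io import CohortTable, PatientRecord, ValidationError, table1_fixture
from melrisk.survival_stats import (
    assign_risk,
    dichotomize_marker,
    gehan_wilcoxon_test,
    holm_bonferroni,
    km_curve,
    marker_screen,
    welch_t_test,
)


def brute_force_km(times, events):
    """Product-limit estimator computed from first principles."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in np.sort(np.unique(times[events])):
        at_risk = (times >= t).sum()
        d = ((times == t) & events).sum()
        s *= 1.0 - d / at_risk
        out[float(t)] = s
    return out


def brute_force_cut(values, min_group):
    """Exhaustive search over all cuts maximising between-group SS."""
    x = np.sort(np.asarray(values, float))
    n = len(x)
    best, best_k = None, None
    for k in range(min_group, n - min_group + 1):
        if x[k - 1] == x[k]:
            continue
        lo, hi = x[:k], x[k:]
        bss = k * (lo.mean() - x.mean()) ** 2 + (n - k) * (hi.mean() - x.mean()) ** 2
        if best is None or bss > best + 1e-12:
            best, best_k = bss, k
    if best_k is None:
        return None
    return (x[best_k - 1] + x[best_k]) / 2.0, best


class TestAssignRisk:
    @pytest.mark.parametrize(
        "os_days,response,expected",
        [(1266, "PR", "low"), (1456, "PD", "high"), (243, "PR", "high"),
         (549, "CR", "low"), (548, "CR", "high"), (1000, "SD", "low")],
    )
    def test_rule(self, os_days, response, expected):
        assert assign_risk(os_days, response) == expected

    def test_reproduces_printed_risk_column(self):
        table = table1_fixture()
        agree = [assign_risk(r.os_days, r.response) == r.risk for r in table]
        assert all(agree)

    def test_unknown_response_rejected(self):
        with pytest.raises(ValidationError):
            assign_risk(100, "XX")


class TestKMCurve:
    def test_uncensored_steps(self):
        curve = km_curve([1, 2, 3, 4], [True] * 4)
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2

    def test_all_censored(self):
        curve = km_curve([5, 10, 15], [False] * 3)
        assert curve.median is None
        assert curve.times.size == 0

    def test_hand_computed_mixed_censoring(self):
        # times 2, 4+, 6, 8+, 10: S(2)=0.8, S(6)=0.8*(2/3)=0.533, S(10)=0
        curve = km_curve([2, 4, 6, 8, 10], [True, False, True, False, True])
        np.testing.assert_allclose(curve.survival, [0.8, 0.8 * 2 / 3, 0.0], atol=1e-9)
        np.testing.assert_array_equal(curve.at_risk, [5, 3, 1])
        # S first drops to <= 0.5 at the last event time
        assert curve.median == 10

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            km_curve([], [])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 50), st.booleans()), min_size=1, max_size=30))
    def test_matches_brute_force_product_limit(self, data):
        times = [t for t, _ in data]
        events = [e for _, e in data]
        curve = km_curve(times, events)
        expected = brute_force_km(times, events)
        got = dict(zip(curve.times.tolist(), curve.survival.tolist()))
        assert set(got) == set(expected)
        for t in expected:
            assert got[t] == pytest.approx(expected[t], abs=1e-9)
        assert np.all(np.diff(curve.survival) <= 1e-12)


class TestDichotomize:
    def test_maximal_gap(self):
        values = list(range(1, 11)) + list(range(101, 111))
        threshold, upper = dichotomize_marker(values, min_group=10)
        assert 10 < threshold < 101
        assert upper.sum() == 10

    def test_outliers_forced_to_min_group(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 34), [50.0, 55.0, 60.0]])
        threshold, upper = dichotomize_marker(values, min_group=10)
        assert upper.sum() >= 10 and (~upper).sum() >= 10
        expected_threshold, _ = brute_force_cut(values, 10)
        assert threshold == pytest.approx(expected_threshold)

    def test_constant_values_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize_marker([3.0] * 25, min_group=10)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize_marker(list(range(15)), min_group=10)

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False, width=32), min_size=8, max_size=60
        )
    )
    def test_matches_exhaustive_search(self, values):
        expected = brute_force_cut(values, 4)
        if expected is None:
            with pytest.raises(ValidationError):
                dichotomize_marker(values, min_group=4)
            return
        threshold, upper = dichotomize_marker(values, min_group=4)
        x = np.asarray(values)
        bss_got = _bss(x, x > threshold)
        bss_exp = _bss(x, x > expected[0])
        assert bss_got == pytest.approx(bss_exp, rel=1e-9, abs=1e-9)


def _bss(x, upper):
    n = len(x)
    return (
        (~upper).sum() * (x[~upper].mean() - x.mean()) ** 2
        + upper.sum() * (x[upper].mean() - x.mean()) ** 2
    )


class TestGehanWilcoxon:
    def test_identical_groups_p_one(self):
        t = [3, 5, 8, 13]
        e = [True, True, False, True]
        stat, p = gehan_wilcoxon_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_no_events_flagged(self):
        stat, p = gehan_wilcoxon_test([5, 6], [False, False], [7, 8], [False, False])
        assert (stat, p) == (0.0, 1.0)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.tuples(st.integers(1, 60), st.booleans()), min_size=3, max_size=15),
        st.lists(st.tuples(st.integers(1, 60), st.booleans()), min_size=3, max_size=15),
    )
    def test_matches_lifelines_weighted_logrank(self, g1, g2):
        """The in-house Gehan statistic agrees with the lifelines Wilcoxon-
        weighted log-rank on random censored samples."""
        from lifelines.statistics import logrank_test

        t1 = [t for t, _ in g1]; e1 = [e for _, e in g1]
        t2 = [t for t, _ in g2]; e2 = [e for _, e in g2]
        if sum(e1) + sum(e2) == 0:
            return
        stat, p = gehan_wilcoxon_test(t1, e1, t2, e2)
        ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2,
                           weightings="wilcoxon")
        assert stat == pytest.approx(float(ref.test_statistic), rel=1e-6, abs=1e-9)
        assert p == pytest.approx(float(ref.p_value), rel=1e-6, abs=1e-9)

    def test_chi_square_close_to_permutation(self):
        rng = np.random.default_rng(0)
        t1 = rng.exponential(300, 10).round() + 1
        t2 = rng.exponential(900, 10).round() + 1
        e1 = np.ones(10, bool)
        e2 = rng.random(10) < 0.7
        stat, p_chi = gehan_wilcoxon_test(t1, e1, t2, e2)
        _, p_perm = gehan_wilcoxon_test(t1, e1, t2, e2, permutation=20000, seed=1)
        assert abs(p_chi - p_perm) < 0.02

    def test_power_on_separated_groups(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t1 = rng.exponential(200, 20).round() + 1  # hazard ratio 5
            t2 = rng.exponential(1000, 20).round() + 1
            _, p = gehan_wilcoxon_test(t1, np.ones(20, bool), t2, np.ones(20, bool))
            hits += p < 0.05
        assert hits >= 9

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            gehan_wilcoxon_test([], [], [1], [True])


class TestWelch:
    def test_identical_samples(self):
        stat, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_example_matches_formula(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0])
        x2 = np.array([5.0, 6.0, 7.0, 8.0])
        stat, p = welch_t_test(x1, x2)
        se = np.sqrt(x1.var(ddof=1) / 4 + x2.var(ddof=1) / 4)
        assert stat == pytest.approx((x1.mean() - x2.mean()) / se)
        assert p < 0.01

    def test_large_shift_small_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        _, p = welch_t_test(x, x + 50)
        assert p < 1e-10

    def test_degenerate_zero_variance(self):
        stat, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert p == 1.0


class TestHolm:
    def test_worked_example(self):
        rejected = holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        np.testing.assert_array_equal(rejected, [True, False, False])

    def test_all_ones_none_rejected(self):
        assert not holm_bonferroni([1.0, 1.0, 1.0]).any()

    def test_single_p_plain_alpha(self):
        assert holm_bonferroni([0.04]).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_between_bonferroni_and_unadjusted(self, pvals):
        alpha = 0.05
        holm = holm_bonferroni(pvals, alpha)
        p = np.asarray(pvals)
        bonf = p <= alpha / len(p)
        raw = p <= alpha
        assert np.all(holm[bonf])  # Holm rejects everything Bonferroni does
        assert np.all(raw[holm])  # Holm rejects only unadjusted-significant


def _null_features(rng, n=37):
    rows = []
    for i in range(n):
        rows.append(
            {
                "patient_id": f"p{i}",
                "tmtv_ml": rng.lognormal(3, 1),
                "tlg_total": rng.lognormal(4, 1),
                "n_lesions": int(rng.integers(1, 60)),
                "n_organ_regions": int(rng.integers(1, 8)),
                "dm_max": rng.normal(40, 15),
                "sul_peak_min": rng.lognormal(0.5, 0.5),
                "adc_mean_range": rng.normal(600, 200),
                "blr": rng.normal(0.76, 0.19),
                "slr": rng.normal(0.9, 0.08),
                "region_bone": int(rng.random() < 0.35),
                "region_liver": int(rng.random() < 0.4),
                "region_brain": int(rng.random() < 0.27),
                "region_lung": int(rng.random() < 0.45),
                "region_spleen": int(rng.random() < 0.14),
            }
        )
    return pd.DataFrame(rows)


def _null_cohort(rng, n=37):
    recs = []
    for i in range(n):
        os_days = int(rng.exponential(600)) + 1
        died = os_days < 1500
        recs.append(
            PatientRecord(
                patient_id=f"p{i}", sex="f", age=60,
                response=str(rng.choice(["CR", "PR", "SD", "PD"], p=[0.1, 0.2, 0.08, 0.62])),
                os_days=min(os_days, 1500) if not died else os_days,
                died=died,
            )
        )
    return CohortTable(recs)


class TestMarkerScreen:
    def test_planted_effect_detected(self):
        """A marker that strongly drives the hazard survives Holm correction
        in most seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            feats = _null_features(rng, n=60)
            # plant: high TMTV -> short OS (hazard scales 8x over TMTV range)
            tm = feats["tmtv_ml"].to_numpy()
            z = (tm - tm.mean()) / tm.std()
            recs = []
            for i in range(60):
                scale = 900 * np.exp(-1.8 * z[i])
                os_days = int(rng.exponential(scale)) + 1
                died = os_days <= 1500
                recs.append(
                    PatientRecord(
                        patient_id=f"p{i}", sex="m", age=60,
                        response="PD", os_days=min(os_days, 1500), died=died,
                    )
                )
            results = marker_screen(feats, CohortTable(recs))
            by_name = {r.marker: r for r in results}
            hits += by_name["tmtv_ml"].os_rejected
        assert hits >= 8

    def test_degenerate_indicator_skipped(self):
        rng = np.random.default_rng(5)
        feats = _null_features(rng)
        feats["region_spleen"] = 0
        feats.loc[0, "region_spleen"] = 1  # only one affected patient
        results = marker_screen(feats, _null_cohort(np.random.default_rng(6)))
        assert "region_spleen" not in {r.marker for r in results}

    # family-wise error calibration over 200 null replicates runs in
    # tests/test_acceptance.py (TestStatisticalCalibration)

    def test_group_sizes_partition_cohort(self):
        rng = np.random.default_rng(8)
        feats = _null_features(rng)
        cohort = _null_cohort(np.random.default_rng(9))
        for r in marker_screen(feats, cohort):
            assert r.n_low + r.n_high == 37
            assert 0 <= r.os_p <= 1
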