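import numpy as np
import pytest
from scipy import stats as sps

from btmbkit.survival import (cox_hr, greenwood_landmark_ci, km_fit,
                              km_median_ci, logrank_power, logrank_test)
from oracles import (brute_force_km, golden_section_cox,
                     permutation_logrank_p)


def _random_censored(rng, n, scale=5.0):
    t = rng.exponential(scale, n)
    c = rng.uniform(1, 3 * scale, n)
    return np.minimum(t, c), t <= c


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = km_fit([3.0, 5.0, 8.0], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_complete_data_closed_form(self):
        curve = km_fit([1.0, 2.0, 3.0], [True, True, True])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_censoring_processed_after_same_time_events(self):
        # event and censoring at t=2: the censored subject is still at risk
        curve = km_fit([1.0, 2.0, 2.0, 4.0],
                       [True, True, False, True])
        assert np.allclose(curve.survival, [3 / 4, 3 / 4 * 2 / 3, 0.0])

    def test_matches_brute_force_risk_set_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(1, 31))
            t, e = _random_censored(rng, n)
            t = np.round(t, 1)  # force ties
            curve = km_fit(t, e)
            ot, os_ = brute_force_km(t, e)
            assert np.allclose(curve.event_times, ot)
            assert np.allclose(curve.survival, os_)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_fit([], [])


class TestMedianCI:
    def test_all_censored_median_not_estimable(self):
        curve = km_fit([3.0, 5.0], [False, False])
        res = km_median_ci(curve)
        assert res.median is None

    def test_complete_odd_n_median_is_middle_order_statistic(self):
        times = [1.0, 4.0, 2.0, 9.0, 5.0]
        curve = km_fit(times, [True] * 5)
        assert km_median_ci(curve).median == 4.0

    def test_median_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(5)
        for _ in range(20):
            t, e = _random_censored(rng, 80)
            res = km_median_ci(km_fit(t, e), 0.95)
            kmf = KaplanMeierFitter().fit(t, e)
            assert res.median == pytest.approx(
                float(kmf.median_survival_time_))

    def test_interval_matches_test_inversion_oracle(self):
        # invert (S - 0.5)^2 / Var <= chi2 over event times, computed from
        # the brute-force product-limit path with naive accumulations
        rng = np.random.default_rng(15)
        crit = sps.chi2.ppf(0.95, 1)
        for _ in range(30):
            t, e = _random_censored(rng, 60)
            curve = km_fit(t, e)
            res = km_median_ci(curve, 0.95)
            ot, os_ = brute_force_km(t, e)
            gw = []
            acc = 0.0
            for tt, s in zip(ot, os_):
                n_risk = sum(1 for x in t if x >= tt)
                d = sum(1 for x, ev in zip(t, e) if ev and x == tt)
                acc += d / (n_risk * (n_risk - d)) if n_risk > d else 0.0
                gw.append(s * s * acc)
            ok = [i for i, (s, v) in enumerate(zip(os_, gw))
                  if v > 0 and (s - 0.5) ** 2 / v <= crit]
            if not ok:
                assert res.ci_low is None
                continue
            assert res.ci_low == pytest.approx(ot[ok[0]])
            if ok[-1] == len(ot) - 1:
                assert res.ci_high is None
            else:
                assert res.ci_high == pytest.approx(ot[ok[-1] + 1])


class TestLandmark:
    def test_time_zero_is_degenerate_at_one(self):
        curve = km_fit([1.0, 2.0], [True, True])
        res = greenwood_landmark_ci(curve, 0.0)
        assert (res.estimate, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_no_events_before_landmark_degenerate(self):
        curve = km_fit([1.0, 5.0], [False, True])
        res = greenwood_landmark_ci(curve, 0.5)
        assert res.ci_low == res.ci_high == 1.0

    def test_landmark_beyond_follow_up_rejected(self):
        curve = km_fit([1.0, 2.0], [True, True])
        with pytest.raises(ValueError, match="follow-up"):
            greenwood_landmark_ci(curve, 3.0)

    def test_loglog_interval_inside_unit_interval(self):
        rng = np.random.default_rng(2)
        t, e = _random_censored(rng, 50)
        curve = km_fit(t, e)
        res = greenwood_landmark_ci(curve, 4.0, transform="loglog")
        assert 0 <= res.ci_low <= res.estimate <= res.ci_high <= 1


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        t1, e1 = _random_censored(rng, 30)
        t2, e2 = _random_censored(rng, 25, scale=8)
        assert logrank_test(t1, e1, t2, e2) == pytest.approx(
            logrank_test(t2, e2, t1, e1))

    def test_agrees_with_exact_permutation_reference(self):
        def package_stat(times, events, labels):
            m = np.array(labels, bool)
            t, e = np.asarray(times), np.asarray(events)
            return logrank_test(t[m], e[m], t[~m], e[~m])[0]

        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(12):
            n1, n2 = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            t1 = np.round(rng.exponential(3, n1), 1) + 0.1
            t2 = np.round(rng.exponential(6, n2), 1) + 0.1
            e1 = rng.uniform(size=n1) < 0.8
            e2 = rng.uniform(size=n2) < 0.8
            if not (e1.any() or e2.any()):
                continue
            # the permutation law of the implemented statistic must be
            # identical to that of the enumeration-based oracle statistic
            p_impl = permutation_logrank_p(t1, e1, t2, e2,
                                           statistic=package_stat)
            p_oracle = permutation_logrank_p(t1, e1, t2, e2)
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)
            _, p_chi2 = logrank_test(t1, e1, t2, e2)
            diffs.append(abs(p_chi2 - p_oracle))
        # the chi-square reference is only an approximation of the exact
        # law at these sizes; it should track it, not equal it
        assert np.median(diffs) < 0.15

    def test_no_events_warns_and_returns_null(self):
        with pytest.warns(UserWarning, match="no events"):
            stat, p = logrank_test([1.0], [False], [2.0], [False])
        assert (stat, p) == (0.0, 1.0)


class TestCox:
    def test_identical_groups_hazard_ratio_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 0], bool)
        g = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        # symmetric data: every event time alternates groups
        res = cox_hr(np.concatenate([t, t]), np.concatenate([e, e]),
                     np.concatenate([g, 1 - g]))
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-8)

    def test_matches_golden_section_maximizer_without_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = 40
            t = rng.exponential(5, n) * np.where(
                rng.uniform(size=n) < 0.5, 1.0, 1.8)
            g = (np.arange(n) % 2).astype(float)
            e = rng.uniform(size=n) < 0.8
            if e.sum() < 3 or not (e[g == 1].any() and e[g == 0].any()):
                continue
            res = cox_hr(t, e, g)
            beta_star = golden_section_cox(t, e, g)
            assert res.log_hr == pytest.approx(beta_star, abs=1e-4)

    def test_matches_lifelines_with_efron_ties(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(8)
        t = np.round(rng.exponential(5, 120), 0) + 1
        g = (rng.uniform(size=120) < 0.5).astype(float)
        t = t * np.where(g == 1, 0.7, 1.0)
        e = rng.uniform(size=120) < 0.85
        res = cox_hr(t, e, g, conf=0.90)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "g": g}), "t", "e")
        assert res.log_hr == pytest.approx(float(cph.params_.iloc[0]),
                                           abs=1e-6)
        assert res.se == pytest.approx(
            float(cph.standard_errors_.iloc[0]), abs=1e-6)

    def test_no_events_in_one_group_flagged_monotone(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([0, 0, 1, 1], bool)
        g = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="monotone"):
            res = cox_hr(t, e, g)
        assert res.monotone
        assert res.ci_high == np.inf


class TestPower:
    def test_null_hazard_ratio_gives_alpha_level_power(self):
        power = logrank_power(150, 0.24, 1.0, alpha_two_sided=0.10)
        assert power == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_effect_size(self):
        powers = [logrank_power(150, 0.24, hr) for hr in
                  (0.9, 0.75, 0.6, 0.45)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_design_point_reaches_80_percent(self):
        assert logrank_power(150, 0.24, 0.6, 0.10, 0.87) >= 0.80
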