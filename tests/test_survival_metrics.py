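"""KM, log-rank, IPCW time-dependent ROC and calibration statistics."""

import numpy as np
import pytest

from adgfs import (
    compare_auc,
    confusion_at_time,
    dagostino_nam,
    expected_events,
    km_estimate,
    logrank_test,
    time_dependent_auc,
)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert km.predict(2.5) == pytest.approx(0.5)
        assert km.predict(0.5) == 1.0

    def test_all_censored_is_flat_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.predict(3.0) == 1.0

    def test_hand_product_limit_with_censoring(self):
        # t=1 event (6 at risk), t=2 event+censor (5), t=3 event (3),
        # t=4 censor, t=5 event (1 at risk)
        km = km_estimate([1, 2, 2, 3, 4, 5], [1, 0, 1, 1, 0, 1])
        hand = {1: 5 / 6, 2: 5 / 6 * 4 / 5, 3: 5 / 6 * 4 / 5 * 2 / 3, 5: 0.0}
        for t, s in hand.items():
            assert km.predict(t) == pytest.approx(s, abs=1e-12)

    def test_survival_is_monotone_nonincreasing(self):
        rng = np.random.default_rng(0)
        km = km_estimate(rng.exponential(5, 80), rng.uniform(size=80) < 0.6)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km.survival[0] <= 1.0

    def test_greenwood_variance_positive_under_events(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        assert km.se(2.5) > 0

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimate([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2, 3, 4])
        d = np.array([1, 1, 0, 1])
        chi2, df, p = logrank_test([(t, d), (t, d)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(1)
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            a = rng.exponential(1.0, 100)
            b = rng.exponential(5.0, 100)  # hazard ratio 5
            _, _, p = logrank_test([(a, np.ones(100)), (b, np.ones(100))])
            hits += p < 0.001
        assert hits >= 9

    def test_four_groups_have_three_degrees_of_freedom(self):
        rng = np.random.default_rng(2)
        groups = [(rng.exponential(k + 1, 30), np.ones(30)) for k in range(4)]
        _, df, _ = logrank_test(groups)
        assert df == 3


class TestTimeDependentAUC:
    def test_null_marker_near_half(self):
        rng = np.random.default_rng(3)
        n = 1000
        t = rng.exponential(8, n)
        c = rng.uniform(0, 15, n)
        time, event = np.minimum(t, c), t <= c
        marker = rng.normal(size=n)  # independent of outcome
        r = time_dependent_auc(marker, time, event, 10.0)
        assert r.auc == pytest.approx(0.5, abs=0.04)

    def test_perfect_marker_is_one(self):
        t = np.r_[np.linspace(0.5, 5, 20), np.linspace(11, 20, 20)]
        marker = (t <= 10).astype(float)
        r = time_dependent_auc(marker, t, np.ones(40, bool), 10.0)
        assert r.auc == 1.0

    def test_equals_mann_whitney_without_censoring(self):
        rng = np.random.default_rng(4)
        n = 50
        t = rng.exponential(8, n)
        marker = -t + rng.normal(0, 4, n)
        r = time_dependent_auc(marker, t, np.ones(n, bool), 6.0)
        case, ctrl = t <= 6.0, t > 6.0
        brute = np.mean([
            (marker[i] > marker[j]) + 0.5 * (marker[i] == marker[j])
            for i in np.where(case)[0] for j in np.where(ctrl)[0]
        ])
        assert r.auc == pytest.approx(brute, abs=1e-12)

    def test_matches_scikit_survival_under_censoring(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(5)
        n = 300
        t = rng.exponential(8, n)
        c = rng.uniform(0, 15, n)
        time, event = np.minimum(t, c), t <= c
        marker = -t + rng.normal(0, 3, n)
        y = np.array(list(zip(event, time)),
                     dtype=[("event", bool), ("time", float)])
        ref, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, marker, [8.0])
        ours = time_dependent_auc(marker, time, event, 8.0)
        assert ours.auc == pytest.approx(float(ref[0]), abs=1e-9)

    def test_no_cases_is_undefined(self):
        t = np.full(20, 15.0)
        with pytest.raises(ValueError, match="undefined"):
            time_dependent_auc(np.arange(20.0), t, np.zeros(20, bool), 10.0)

    def test_binary_marker_matches_km_closed_form(self):
        """For a binary marker without censoring, AUC(t) has the closed form
        in the group event fractions."""
        rng = np.random.default_rng(6)
        n = 200
        g = rng.uniform(size=n) < 0.4
        t = np.where(g, rng.exponential(3, n), rng.exponential(12, n))
        r = time_dependent_auc(g.astype(float), t, np.ones(n, bool), 8.0)
        case, ctrl = t <= 8.0, t > 8.0
        p1 = g[case].mean()  # P(marker=1 | case)
        q1 = g[ctrl].mean()  # P(marker=1 | control)
        closed = p1 * (1 - q1) + 0.5 * (p1 * q1 + (1 - p1) * (1 - q1))
        assert r.auc == pytest.approx(closed, abs=1e-12)


class TestCompareAUC:
    def test_identical_markers_p_one(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(8, 100)
        m = rng.normal(size=100)
        a1, a2, p = compare_auc(m, m, t, np.ones(100, bool), 5.0)
        assert a1 == a2 and p == 1.0

    def test_null_p_values_roughly_uniform(self):
        """Adding pure noise to a marker: the difference test's p-values are
        uniform under the null (KS on replicate p-values)."""
        from scipy import stats

        ps = []
        for s in range(120):
            rng = np.random.default_rng(9000 + s)
            n = 200
            t = rng.exponential(8, n)
            m1 = -t + rng.normal(0, 4, n)
            m2 = m1 + rng.normal(0, 0.8, n)  # same information + noise
            _, _, p = compare_auc(m1, m2, t, np.ones(n, bool), 6.0)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_designed_degradation(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            n = 1000
            t = rng.exponential(8, n)
            good = -t + rng.normal(0, 2, n)
            bad = -t + rng.normal(0, 12, n)
            _, _, p = compare_auc(good, bad, t, np.ones(n, bool), 6.0)
            hits += p < 0.05
        assert hits >= 8


class TestConfusion:
    def test_reduces_to_classical_table_without_censoring(self):
        rng = np.random.default_rng(8)
        n = 40
        t = rng.exponential(8, n)
        score = rng.integers(0, 13, n).astype(float)
        conf = confusion_at_time(score, t, np.ones(n, bool), 4.0, 10.0)
        case = t <= 10.0
        assert conf.se_sensitivity[0] == pytest.approx((score[case] > 4).mean())
        assert conf.sp_specificity[0] == pytest.approx((score[~case] <= 4).mean())
        pos = score > 4
        assert conf.ppv[0] == pytest.approx(case[pos].mean())
        assert conf.npv[0] == pytest.approx((~case)[~pos].mean())
        assert conf.n_positive + conf.n_negative == n

    def test_extreme_cutpoints(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(5, 30)
        score = rng.integers(2, 9, 30).astype(float)
        low = confusion_at_time(score, t, np.ones(30, bool), 0.0, 8.0)
        assert low.se_sensitivity[0] == 1.0 and low.sp_specificity[0] == 0.0
        high = confusion_at_time(score, t, np.ones(30, bool), 99.0, 8.0)
        assert high.se_sensitivity[0] == 0.0 and high.sp_specificity[0] == 1.0
        assert np.isnan(high.ppv[0])  # no positive tests: flagged, not zero

    def test_sensitivity_monotone_in_cutpoint(self):
        rng = np.random.default_rng(10)
        n = 150
        t = rng.exponential(8, n)
        c = rng.uniform(0, 15, n)
        time, event = np.minimum(t, c), t <= c
        score = rng.integers(0, 13, n).astype(float)
        cuts = [0, 2, 4, 6, 8]
        se = [confusion_at_time(score, time, event, c, 8.0).se_sensitivity[0]
              for c in cuts]
        sp = [confusion_at_time(score, time, event, c, 8.0).sp_specificity[0]
              for c in cuts]
        assert np.all(np.diff(se) <= 1e-12)
        assert np.all(np.diff(sp) >= -1e-12)


class TestCalibration:
    def test_published_validation_cells(self):
        """The four printed observed/expected pairs give chi2 close to the
        reported 2.39 on 2 df (p ~ 0.30)."""
        groups = [(328, 14, 14.9), (333, 47, 53.8),
                  (203, 57, 58.3), (32, 18, 14.8)]
        res = dagostino_nam(groups)
        assert res.df == 2
        assert res.chi2 == pytest.approx(2.39, abs=0.05)
        assert res.p_value == pytest.approx(0.30, abs=0.02)

    def test_self_calibration_is_exact_zero(self):
        rng = np.random.default_rng(11)
        groups, refs = [], []
        for lam in (0.02, 0.05, 0.1):
            t = rng.exponential(1 / lam, 150)
            c = rng.uniform(0, 15, 150)
            time, event = np.minimum(t, c), t <= c
            groups.append((time, event))
            refs.append(float(km_estimate(time, event).predict(10.0)))
        res = dagostino_nam(groups, horizon=10.0, reference_km=refs)
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_group_order(self):
        groups = [(328, 14, 14.9), (333, 47, 53.8),
                  (203, 57, 58.3), (32, 18, 14.8)]
        a = dagostino_nam(groups).chi2
        b = dagostino_nam(groups[::-1]).chi2
        assert a == pytest.approx(b)

    def test_degenerate_group_merged_with_warning(self):
        groups = [(100, 10, 12.0), (100, 8, 9.0), (100, 20, 18.0),
                  (50, 0, 0.0)]
        with pytest.warns(UserWarning, match="merged"):
            res = dagostino_nam(groups)
        assert res.df == 1  # 3 groups after merging

    def test_null_distribution_of_statistic(self):
        """Under an exact external-reference null the statistic behaves as a
        chi-square with as many degrees of freedom as groups (the printed
        df = groups - 2 convention is anti-conservative for external
        validation; see the methods note)."""
        from scipy import stats

        rng = np.random.default_rng(13)
        lams = (0.015, 0.03, 0.06, 0.12)
        ps = [1 - np.exp(-lam * 10.0) for lam in lams]
        vals, rej_g = [], 0
        reps = 500
        for _ in range(reps):
            groups = [(120, rng.binomial(120, p), 120 * p) for p in ps]
            res = dagostino_nam(groups)
            vals.append(res.chi2)
            rej_g += stats.chi2.sf(res.chi2, len(ps)) < 0.05
        assert np.mean(vals) == pytest.approx(len(ps), abs=0.5)
        assert rej_g / reps == pytest.approx(0.05, abs=0.025)


class TestExpectedEvents:
    def test_closed_forms(self):
        assert expected_events(100, 0.9) == pytest.approx(10.0)
        assert expected_events(328, 1.0) == 0.0

    def test_against_simulated_counting(self):
        rng = np.random.default_rng(12)
        lam = 0.05
        t = rng.exponential(1 / lam, 4000)
        observed = (t <= 10.0).sum()
        exp = expected_events(4000, float(np.exp(-lam * 10.0)))
        assert observed == pytest.approx(exp, rel=0.05)

    def test_invalid_survival_rejected(self):
        with pytest.raises(ValueError):
            expected_events(10, 1.2)
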