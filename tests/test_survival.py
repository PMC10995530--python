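import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from pethotspot.survival import (
    _admissible_splits,
    concordance_index,
    km_estimate,
    logrank,
    maxstat_cutoff,
    risk_categories,
    wilcoxon_ranksum,
)


def hand_logrank_chi2(time_a, event_a, time_b, event_b):
    """Independent O-E log-rank computed time point by time point."""
    t = np.concatenate([time_a, time_b])
    e = np.concatenate([event_a, event_b]).astype(bool)
    g = np.concatenate([np.zeros(len(time_a)), np.ones(len(time_b))])
    o_minus_e, var = 0.0, 0.0
    for tj in np.unique(t[e]):
        at = t >= tj
        d = ((t == tj) & e).sum()
        n = at.sum()
        n1 = (at & (g == 1)).sum()
        d1 = ((t == tj) & e & (g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * n1 / n * (1 - n1 / n)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_distinct_events_no_censoring_closed_form(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4)
        curve = km_estimate(time, event)
        surv_at = dict(zip(curve.times, curve.survival))
        for k, t in enumerate([1.0, 2.0, 3.0, 4.0], start=1):
            assert surv_at[t] == pytest.approx((4 - k) / 4)

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([2.0, 5.0, 9.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)
        assert np.isnan(curve.median)

    def test_mixed_toy_set_matches_hand_product_limit(self):
        # 6 subjects: events at 2, 4, 7; censored at 3, 5, 8
        # S(2) = 5/6; S(4) = 5/6 * 3/4 = 0.625; S(7) = 0.625 * 1/2 = 0.3125
        time = np.array([2.0, 3.0, 4.0, 5.0, 7.0, 8.0])
        event = np.array([1, 0, 1, 0, 1, 0])
        curve = km_estimate(time, event)
        surv_at = dict(zip(curve.times, curve.survival))
        assert surv_at[2.0] == pytest.approx(5 / 6)
        assert surv_at[4.0] == pytest.approx(5 / 6 * 3 / 4)
        assert surv_at[7.0] == pytest.approx(5 / 6 * 3 / 4 * 1 / 2)

    def test_curve_non_increasing_and_starts_at_one(self, rng):
        time = rng.exponential(10, 50) + 0.01
        event = rng.random(50) < 0.6
        curve = km_estimate(time, event)
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_no_censoring_equals_empirical_survival(self, rng):
        time = np.sort(rng.exponential(5, 30)) + 0.01
        curve = km_estimate(time, np.ones(30))
        for t, s in zip(curve.times[1:], curve.survival[1:]):
            assert s == pytest.approx((time > t).mean(), abs=1e-12)

    def test_non_positive_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation_on_toy_sets(self, rng):
        for _ in range(10):
            ta = rng.exponential(8, 12) + 0.1
            tb = rng.exponential(4, 10) + 0.1
            ea = rng.random(12) < 0.8
            eb = rng.random(10) < 0.8
            if not (ea.any() or eb.any()):
                continue
            chi2, _ = logrank(ta, ea, tb, eb)
            assert chi2 == pytest.approx(hand_logrank_chi2(ta, ea, tb, eb), rel=1e-9)

    def test_symmetric_in_group_order(self, rng):
        ta, tb = rng.exponential(5, 15) + 0.1, rng.exponential(9, 15) + 0.1
        ea, eb = np.ones(15), np.ones(15)
        assert logrank(ta, ea, tb, eb)[0] == pytest.approx(logrank(tb, eb, ta, ea)[0])

    def test_power_under_strong_hazard_ratio(self):
        # exponential groups with hazard ratio 3, n = 200/arm
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(7000 + s)
            ta = rng.exponential(30.0, 200) + 1e-6
            tb = rng.exponential(10.0, 200) + 1e-6
            _, p = logrank(ta, np.ones(200), tb, np.ones(200))
            hits += p < 0.001
        assert hits >= 95

    def test_no_events_flagged_degenerate(self):
        chi2, p = logrank([1.0, 2.0], [0, 0], [3.0], [0])
        assert (chi2, p) == (0.0, 1.0)


class TestMaxstat:
    def test_separating_feature_selects_exhaustive_scan_maximum(self):
        # values 10-12 die early, values 1-3 survive long; the selected
        # cutoff is whatever the exhaustive standardized-statistic scan
        # maximizes (the standardized log-rank statistic can peak at an
        # unbalanced split, not necessarily inside the value gap)
        time = np.array([1.0, 1.5, 2.0, 2.5, 30.0, 31.0, 32.0, 33.0])
        event = np.ones(8)
        feat = np.array([12.0, 11.0, 10.5, 10.0, 3.0, 2.0, 1.5, 1.0])
        res = maxstat_cutoff(time, event, feat, minprop=0.1, n_perm=200, seed=0)
        order = np.argsort(feat, kind="stable")
        fs = feat[order]
        best_z, best_cut = -1.0, None
        for k in _admissible_splits(fs, 8, 0.1):
            cut = (fs[k - 1] + fs[k]) / 2
            low = feat < cut
            r = logrank_test(
                time[low], time[~low],
                event_observed_A=event[low], event_observed_B=event[~low],
            )
            z = float(np.sqrt(r.test_statistic))
            if z > best_z:
                best_z, best_cut = z, cut
        assert res.statistic == pytest.approx(best_z, abs=1e-10)
        assert res.cutoff == pytest.approx(best_cut)
        assert res.direction == "+"  # high values still mean poor survival
        assert res.c_index == pytest.approx(1.0)

    def test_statistic_equals_exhaustive_lifelines_scan(self, rng):
        for trial in range(25):
            n = 30 + (trial % 3) * 10
            time = rng.exponential(12, n) + 0.1
            event = rng.random(n) < 0.7
            if not event.any():
                continue
            feat = rng.normal(0, 1, n)
            res = maxstat_cutoff(time, event, feat, n_perm=0)
            order = np.argsort(feat, kind="stable")
            fs = feat[order]
            ks = _admissible_splits(fs, n, 0.10)
            best = 0.0
            for k in ks:
                cut = (fs[k - 1] + fs[k]) / 2
                low = feat < cut
                r = logrank_test(
                    time[low], time[~low],
                    event_observed_A=event[low], event_observed_B=event[~low],
                )
                best = max(best, float(np.sqrt(r.test_statistic)))
            assert res.statistic == pytest.approx(best, abs=1e-10)

    def test_ties_in_survival_times_still_match_scan(self, rng):
        time = np.round(rng.exponential(6, 40)) + 1.0  # many tied times
        event = rng.random(40) < 0.8
        feat = rng.normal(0, 1, 40)
        res = maxstat_cutoff(time, event, feat, n_perm=0)
        order = np.argsort(feat, kind="stable")
        fs = feat[order]
        best = 0.0
        for k in _admissible_splits(fs, 40, 0.10):
            cut = (fs[k - 1] + fs[k]) / 2
            low = feat < cut
            r = logrank_test(
                time[low], time[~low],
                event_observed_A=event[low], event_observed_B=event[~low],
            )
            best = max(best, float(np.sqrt(r.test_statistic)))
        assert res.statistic == pytest.approx(best, abs=1e-10)

    def test_minprop_keeps_group_sizes(self, rng):
        time = rng.exponential(10, 50) + 0.1
        event = np.ones(50)
        feat = rng.normal(0, 1, 50)
        res = maxstat_cutoff(time, event, feat, minprop=0.2, n_perm=0)
        assert min(res.n_low, res.n_high) >= 10

    def test_errors(self):
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutoff([1.0, 2.0, 3.0], [1, 1, 1], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="event"):
            maxstat_cutoff([1.0, 2.0, 3.0], [0, 0, 0], [1.0, 2.0, 3.0])


class TestConcordance:
    def test_perfect_risk_score(self):
        time = np.array([5.0, 3.0, 9.0, 1.0])
        res = concordance_index(time, np.ones(4), -time)  # higher score, earlier death
        assert res.c_index == pytest.approx(1.0)

    def test_perfectly_wrong_risk_score(self):
        time = np.array([5.0, 3.0, 9.0, 1.0])
        res = concordance_index(time, np.ones(4), time)
        assert res.c_index == pytest.approx(0.0)

    def test_matches_pair_enumeration_with_censoring(self, rng):
        def oracle(time, event, risk):
            num = den = 0.0
            n = len(time)
            for i in range(n):
                for j in range(n):
                    if time[i] < time[j] and event[i]:
                        den += 1
                        if risk[i] > risk[j]:
                            num += 1
                        elif risk[i] == risk[j]:
                            num += 0.5
            return num / den

        for _ in range(25):
            n = 8 + int(rng.integers(0, 8))
            time = rng.exponential(10, n) + 0.1  # continuous: no time ties
            event = rng.random(n) < 0.6
            risk = rng.normal(0, 1, n)
            if not event.any():
                continue
            res = concordance_index(time, event, risk)
            assert res.c_index == pytest.approx(oracle(time, event, risk), abs=1e-12)


class TestRiskCategories:
    def test_all_favorable_gives_category_zero(self):
        time = np.array([5.0, 6.0, 7.0, 8.0])
        event = np.ones(4)
        fa = np.array([0.1, 0.2, 0.1, 0.3])  # "+": unfavorable above 0.5
        fb = np.array([0.9, 0.8, 0.9, 0.7])  # "-": unfavorable below 0.5
        cat, table = risk_categories(time, event, fa, 0.5, "+", fb, 0.5, "-")
        assert np.all(cat == 0)
        assert table["skipped"].all()

    def test_bh_adjustment_closed_form(self, monkeypatch):
        # p = (0.01, 0.02, 0.03) -> (0.03, 0.03, 0.03)
        import pethotspot.survival as surv

        raw = iter([(1.0, 0.01), (2.0, 0.02), (3.0, 0.03)])
        monkeypatch.setattr(surv, "logrank", lambda *a, **k: next(raw))
        time = np.arange(1.0, 10.0)
        event = np.ones(9)
        fa = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1.0])
        fb = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1.0])
        cat, table = risk_categories(time, event, fa, 0.5, "+", fb, 0.5, "+")
        np.testing.assert_allclose(table["p_adjusted"], [0.03, 0.03, 0.03])

    def test_additive_risk_orders_km_medians(self):
        rng = np.random.default_rng(99)
        n = 300
        fa = rng.normal(0, 1, n)
        fb = rng.normal(0, 1, n)
        hazard = (1 / 20.0) * np.exp(0.8 * (fa > 0) + 0.8 * (fb > 0))
        time = rng.exponential(1 / hazard) + 1e-6
        event = np.ones(n)
        cat, _ = risk_categories(time, event, fa, 0.0, "+", fb, 0.0, "+")
        med0 = np.median(time[cat == 0])
        med2 = np.median(time[cat == 2])
        assert med2 < med0


class TestWilcoxon:
    def test_extreme_small_sample_exact_p(self):
        stat, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1)  # 2/20 partitions as extreme, two-sided

    def test_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        _, p = wilcoxon_ranksum(a, list(a))
        assert p == pytest.approx(1.0, abs=0.01)

    def test_power_for_one_sd_shift(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(8800 + s)
            a = rng.normal(0, 1, 100)
            b = rng.normal(1, 1, 100)
            _, p = wilcoxon_ranksum(a, b)
            hits += p < 0.01
        assert hits >= 95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])
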