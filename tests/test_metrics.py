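"""Diagnostic statistics: AUC/DeLong, cutoff, exact CIs, calibration, trend."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fragdecipher.metrics import (
    bh_adjust,
    calibration,
    choose_cutoff,
    confusion_metrics,
    delong_test,
    jonckheere_trend,
    prevalence_adjusted,
    roc_auc,
    wilcoxon_effect,
)


def brute_force_auc(scores, labels):
    """Fraction of positive-negative pairs ranked correctly (ties 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_worked_example_three_quarters(self):
        out = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert out["auc"] == pytest.approx(0.75)
        assert out["auc"] == brute_force_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])

    def test_perfect_separation_is_one(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])["auc"] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.random(2000)
        y = rng.integers(0, 2, 2000)
        assert roc_auc(s, y)["auc"] == pytest.approx(0.5, abs=0.05)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_small_instances(self, data):
        n = data.draw(st.integers(4, 20))
        y = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)
                      .filter(lambda v: 0 < sum(v) < len(v)))
        s = data.draw(st.lists(st.sampled_from([0.1, 0.2, 0.3, 0.5, 0.7, 0.9]),
                               min_size=len(y), max_size=len(y)))
        assert roc_auc(s, y)["auc"] == pytest.approx(brute_force_auc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 40)
        s = y * 0.3 + rng.random(80) * 0.7
        out = roc_auc(s, y)
        assert out["ci"][0] <= out["auc"] <= out["ci"][1]


class TestDeLong:
    def test_identical_scores_give_p_one(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.7, 0.4, 0.6, 0.3, 0.1]
        out = delong_test(s, s, y)
        assert out["diff"] == 0.0
        assert out["p"] == 1.0

    def test_argument_order_symmetry(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        a = y * 0.4 + rng.random(60)
        b = y * 0.2 + rng.random(60)
        assert delong_test(a, b, y)["p"] == pytest.approx(delong_test(b, a, y)["p"])

    def test_agrees_with_bootstrap_of_auc_difference(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.repeat([0, 1], n // 2)
        a = y * 0.8 + rng.random(n) * 0.8
        b = y * 0.1 + rng.random(n)
        out = delong_test(a, b, y)
        # bootstrap the AUC difference, compare the two-sided p
        diffs = []
        idx = np.arange(n)
        for _ in range(4000):
            bs = rng.choice(idx, n, replace=True)
            if 0 < y[bs].sum() < n:
                diffs.append(roc_auc(a[bs], y[bs])["auc"] - roc_auc(b[bs], y[bs])["auc"])
        diffs = np.array(diffs)
        se = diffs.std()
        z = out["diff"] / se
        from scipy import stats as ss

        p_boot = 2 * ss.norm.sf(abs(z))
        assert out["p"] == pytest.approx(p_boot, abs=0.02)


class TestChooseCutoff:
    def brute(self, scores, labels, target):
        cand = sorted(set(scores), reverse=True)
        pos = [s for s, y in zip(scores, labels) if y == 1]
        feasible = [t for t in cand
                    if sum(s >= t for s in pos) / len(pos) >= target]
        return max(feasible)

    def test_worked_example(self):
        s = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        y = [1, 1, 1, 1, 0, 0]
        t = choose_cutoff(s, y, 0.95)
        assert t == 0.6 == self.brute(s, y, 0.95)
        rep = confusion_metrics(s, y, t)
        assert rep.metrics["sensitivity"][0] == 1.0
        assert rep.metrics["specificity"][0] == 1.0

    def test_zero_target_returns_max_score(self):
        assert choose_cutoff([0.2, 0.9, 0.5], [0, 1, 1], 0.0) == 0.9

    def test_negative_above_cutoff_leaves_cutoff_unchanged(self):
        s = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        y = [1, 1, 1, 1, 0, 0]
        t0 = choose_cutoff(s, y, 0.95)
        t1 = choose_cutoff(s + [0.95], y + [0], 0.95)
        assert t0 == t1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        y = rng.integers(0, 2, n)
        if not 0 < y.sum() < n:
            y[0], y[-1] = 0, 1
        s = rng.choice(np.linspace(0, 1, 11), n)
        target = float(rng.choice([0.5, 0.8, 0.9, 0.95]))
        assert choose_cutoff(s, y, target) == self.brute(list(s), list(y), target)

    def test_cutoff_then_metrics_meets_target(self):
        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 100)
        s = y * 0.3 + rng.random(100) * 0.8
        t = choose_cutoff(s, y, 0.95)
        rep = confusion_metrics(s, y, t)
        assert rep.metrics["sensitivity"][0] >= 0.95


class TestConfusionMetrics:
    def test_counts_api_matches_scores_api(self):
        s = [0.9, 0.2, 0.6, 0.4]
        y = [1, 0, 0, 1]
        a = confusion_metrics(s, y, 0.5)
        b = confusion_metrics(counts=(a.tp, a.fp, a.tn, a.fn))
        assert a.metrics == b.metrics

    def test_all_correct_gives_ones(self):
        rep = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        for name in ("sensitivity", "specificity", "accuracy"):
            assert rep.metrics[name][0] == 1.0

    def test_ci_contains_estimate(self):
        rep = confusion_metrics(counts=(92, 11, 88, 5))
        for est, lo, hi in rep.metrics.values():
            assert lo <= est <= hi


class TestPrevalence:
    def test_perfect_test_everywhere(self):
        tab = prevalence_adjusted(1.0, 1.0, (0.01, 0.1, 0.5))
        assert (tab["ppv"] == 1.0).all() and (tab["npv"] == 1.0).all()

    def test_rare_disease_ppv_collapses(self):
        tab = prevalence_adjusted(0.842, 0.906, (0.001,))
        assert tab["ppv"].iloc[0] == pytest.approx(0.009, abs=0.002)

    def test_monotone_in_prevalence(self):
        tab = prevalence_adjusted(0.842, 0.906, (0.001, 0.01, 0.1, 0.2, 0.5))
        assert tab["ppv"].is_monotonic_increasing
        assert tab["npv"].is_monotonic_decreasing

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            prevalence_adjusted(0.9, 0.9, (1.5,))


class TestWilcoxonEffect:
    def test_exact_p_on_fully_separated_triplets(self):
        # 2 of the C(6,3)=20 label arrangements are at least this extreme
        out = wilcoxon_effect([1, 2, 3], [4, 5, 6])
        assert out["p"] == pytest.approx(0.1)

    def test_identical_groups_have_zero_effect(self):
        out = wilcoxon_effect([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert out["r"] == 0.0
        assert out["p"] == 1.0

    def test_ci_brackets_point_estimate_within_unit_interval(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 1.0, 30)
        b = rng.normal(0.0, 1.0, 30)
        out = wilcoxon_effect(a, b, seed=1)
        lo, hi = out["ci"]
        assert 0.0 <= lo <= hi <= 1.0
        assert lo - 0.1 <= out["r"] <= hi + 0.1


class TestBH:
    def test_worked_example(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_equal_ps_map_to_themselves(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCalibration:
    def test_perfect_probabilities_zero_brier(self):
        rep = calibration([1.0, 0.0, 1.0, 0.0], [1, 0, 1, 0])
        assert rep.brier == 0.0

    def test_constant_half_on_balanced_labels(self):
        rep = calibration([0.5] * 10, [1, 0] * 5)
        assert rep.brier == pytest.approx(0.25)

    def test_two_point_arithmetic(self):
        rep = calibration([0.8, 0.2], [1, 0])
        assert rep.brier == pytest.approx(0.04)

    def test_well_calibrated_scores_have_unit_slope(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.05, 0.95, 4000)
        y = rng.binomial(1, p)
        rep = calibration(p, y)
        assert rep.slope == pytest.approx(1.0, abs=0.15)
        assert rep.intercept == pytest.approx(0.0, abs=0.15)
        assert not rep.degenerate

    def test_single_class_flagged_degenerate(self):
        rep = calibration([0.4, 0.6], [1, 1])
        assert rep.degenerate and np.isnan(rep.slope)


class TestJonckheere:
    def test_maximum_statistic_on_increasing_groups(self):
        # 3 ordered pairs x 4 strictly concordant comparisons each
        out = jonckheere_trend([[1, 2], [3, 4], [5, 6]], seed=0)
        assert out["statistic"] == 12.0
        assert out["p"] < 0.05

    def test_reversed_groups_give_zero(self):
        out = jonckheere_trend([[5, 6], [3, 4], [1, 2]], seed=0)
        assert out["statistic"] == 0.0

    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(60):
            g = [rng.normal(size=12) for _ in range(3)]
            ps.append(jonckheere_trend(g, n_perm=400, seed=int(rng.integers(1 << 30)))["p"])
        ps = np.array(ps)
        assert 0.3 < ps.mean() < 0.7
        assert (ps < 0.05).mean() < 0.2

    def test_monotone_trend_detected_with_normal_approximation(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(loc, 1.0, 80) for loc in (0.0, 0.4, 0.8)]
        out = jonckheere_trend(groups, method="normal")
        assert out["p"] < 1e-4

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_trend([[1, 2, 3]])
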