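"""Statistical layer: each test checks against an independent oracle or a
hand-computed value."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import spindlespa as sp


# --- independent oracles -----------------------------------------------------

def mw_oracle(a, b):
    """Exhaustive two-sided Mann-Whitney p by direct pair counting over all
    label assignments of the pooled sample."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_of(group_a, group_b):
        u = 0.0
        for x in group_a:
            for z in group_b:
                u += 1.0 if x > z else (0.5 if x == z else 0.0)
        return u

    mu = n1 * (len(pooled) - n1) / 2.0
    obs = abs(u_of(a, b) - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_of(ga, gb) - mu) >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


def auc_oracle(scores, labels, positive_low=True):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    conc = 0.0
    for p in pos:
        for n in neg:
            win = p < n if positive_low else p > n
            conc += 1.0 if win else (0.5 if p == n else 0.0)
    return conc / (len(pos) * len(neg))


# --- univariate tests --------------------------------------------------------

class TestShapiroWilk:
    def test_gaussian_rarely_rejected(self):
        rng = np.random.default_rng(0)
        hits = sum(sp.shapiro_wilk(rng.normal(size=40))[1] > 0.05
                   for _ in range(100))
        assert hits >= 90

    def test_bimodal_rejected(self):
        x = np.concatenate([np.zeros(20), np.full(20, 10.0)])
        x += np.linspace(0, 1e-6, 40)  # break exact ties, keep bimodality
        assert sp.shapiro_wilk(x)[1] < 0.01

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            sp.shapiro_wilk(np.ones(10))

    def test_sample_size_gate(self):
        with pytest.raises(ValueError):
            sp.shapiro_wilk(np.arange(60))


class TestMannWhitney:
    def test_complete_separation(self):
        c = sp.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert c.u == 0.0

    def test_identical_groups(self):
        c = sp.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert c.u == pytest.approx(4.5)
        assert c.p == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sp.mann_whitney_u([], [1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=1, max_size=6),
           st.lists(st.integers(0, 5), min_size=1, max_size=6))
    def test_exact_p_matches_enumeration_oracle(self, a, b):
        c = sp.mann_whitney_u(a, b)
        assert c.method == "exact"
        assert c.p == pytest.approx(mw_oracle(a, b), abs=1e-9)

    def test_large_sample_matches_scipy_asymptotic(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        a, b = rng.normal(size=13), rng.normal(size=27)
        c = sp.mann_whitney_u(a, b)
        assert c.method == "normal"
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert c.p == pytest.approx(ref.pvalue, rel=1e-6)


class TestChiSquare:
    def test_equal_proportions(self):
        chi2, p = sp.chi_square_binary([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_computed(self):
        chi2, _ = sp.chi_square_binary([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)

    def test_cohort_sex_split_not_significant(self):
        # 6/13 female in UCP vs 13/27 in typical outcome
        chi2, p = sp.chi_square_binary([[6, 7], [13, 14]])
        assert p > 0.05

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            sp.chi_square_binary([[0, 0], [5, 5]])


# --- logistic selection ------------------------------------------------------

def _frame(cols: dict, y):
    d = pd.DataFrame(cols)
    d["y"] = y
    return d


class TestForwardLogistic:
    def test_perfect_separator_selected_with_warning(self):
        y = np.array([0] * 10 + [1] * 10)
        x = np.where(y == 1, 0.5, 1.0) + np.linspace(0, 0.05, 20)
        res = sp.forward_conditional_logistic(_frame({"x": x}, y), ["x"], "y")
        assert res.selected == ["x"]
        assert res.separation_warning
        assert res.classification_accuracy == 1.0

    def test_pure_noise_rarely_enters(self):
        rng = np.random.default_rng(3)
        empty = 0
        runs = 40
        for _ in range(runs):
            y = np.array([0] * 14 + [1] * 7)
            cols = {f"x{j}": rng.normal(size=21) for j in range(3)}
            res = sp.forward_conditional_logistic(_frame(cols, y),
                                                  list(cols), "y")
            empty += not res.selected
        # three independent null candidates: P(empty) = 0.95**3 ~ 0.86
        assert empty >= 0.78 * runs

    def test_strong_predictor_beats_correlated_noise(self):
        rng = np.random.default_rng(4)
        first = 0
        runs = 25
        for _ in range(runs):
            y = np.array([1] * 13 + [0] * 27)
            strong = np.where(y == 1, 0.56, 1.0) * np.exp(
                rng.normal(0, 0.25, 40))
            cols = {"strong": strong}
            for j in range(6):
                cols[f"weak{j}"] = strong * np.exp(rng.normal(0, 0.6, 40))
            res = sp.forward_conditional_logistic(_frame(cols, y),
                                                  list(cols), "y")
            first += bool(res.selected) and res.selected[0] == "strong"
        assert first >= 0.9 * runs

    def test_listwise_deletion_of_missing_rows(self):
        y = np.array([0] * 10 + [1] * 10, dtype=float)
        x = y + np.linspace(-0.2, 0.2, 20)
        d = _frame({"x": x}, y)
        d.loc[0, "x"] = np.nan
        res = sp.forward_conditional_logistic(d, ["x"], "y")
        assert res.n == 19

    def test_one_class_rejected(self):
        d = _frame({"x": np.arange(5.0)}, np.zeros(5))
        with pytest.raises(ValueError):
            sp.forward_conditional_logistic(d, ["x"], "y")


class TestNagelkerke:
    def test_null_model_is_zero(self):
        assert sp.nagelkerke_r2(-27.0, -27.0, 40) == 0.0

    def test_perfect_model_approaches_one(self):
        n = 40
        ll0 = n * math.log(0.5)
        assert sp.nagelkerke_r2(ll0, -1e-9, n) == pytest.approx(1.0, abs=1e-6)

    def test_toy_fit_matches_formula(self):
        ll0, ll1, n = -6.730116670092563, -4.0, 10
        cs = 1 - math.exp(2 * (ll0 - ll1) / n)
        expected = cs / (1 - math.exp(2 * ll0 / n))
        assert sp.nagelkerke_r2(ll0, ll1, n) == pytest.approx(expected)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            sp.nagelkerke_r2(-5, -4, 0)


# --- ROC and diagnostics -----------------------------------------------------

class TestRocAuc:
    def test_perfect_separation(self):
        r = sp.roc_auc([0.5, 0.6, 1.0, 1.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert sp.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_eight_subject_toy_matches_pair_oracle(self):
        scores = [0.4, 0.55, 0.6, 0.65, 0.7, 0.9, 1.0, 1.1]
        labels = [1, 1, 1, 0, 1, 0, 0, 0]
        r = sp.roc_auc(scores, labels)
        assert r.auc == pytest.approx(auc_oracle(scores, labels))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 8), min_size=2, max_size=12),
           st.data())
    def test_pair_oracle_and_orientation_reversal(self, scores, data):
        n = len(scores)
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        r = sp.roc_auc(scores, labels)
        assert r.auc == pytest.approx(auc_oracle(scores, labels), abs=1e-9)
        rev = sp.roc_auc(scores, labels, positive_low=False)
        assert rev.auc == pytest.approx(1.0 - r.auc, abs=1e-9)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            sp.roc_auc([1.0, 2.0], [1, 1])


class TestDiagnosticMetrics:
    def test_separated_toy(self):
        d = sp.diagnostic_metrics([0.56, 0.60, 1.00, 0.92], [1, 1, 0, 0])
        assert (d.sensitivity, d.specificity, d.ppv, d.npv) == (1, 1, 1, 1)

    def test_boundary_value_is_negative_class(self):
        d = sp.diagnostic_metrics([0.65, 0.64], [1, 0])
        assert d.fn == 1 and d.fp == 1

    def test_metrics_consistent_with_counts(self):
        d = sp.DiagnosticMetrics(cutoff=0.65, tp=13, fp=0, tn=25, fn=2)
        assert d.sensitivity == pytest.approx(13 / 15)
        assert d.ppv == 1.0
        assert d.npv == pytest.approx(25 / 27)
        assert d.tp + d.fp + d.tn + d.fn == 40

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0.3, 1.3, size=30)
        y = (s < 0.7).astype(int)
        y[:3] = 1 - y[:3]
        d = sp.diagnostic_metrics(s, y)
        assert d.tp + d.fp + d.tn + d.fn == 30


class TestGrubbs:
    def test_obvious_outlier_flagged(self):
        r = sp.grubbs_test([1, 1, 1, 1, 10], ids=list("abcde"))
        assert r.outlier_id == "e"
        assert r.g > r.critical

    def test_symmetric_sample_no_outlier(self):
        r = sp.grubbs_test([-1.0, 0.0, 1.0])
        assert r.outlier_id is None

    @pytest.mark.parametrize("n,expected", [(5, 1.715), (10, 2.290),
                                            (20, 2.709)])
    def test_critical_values_match_published_table(self, n, expected):
        assert sp.grubbs_critical_value(n) == pytest.approx(expected, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sp.grubbs_test([2.0, 2.0, 2.0])


class TestHolm:
    def test_monotone_and_bounded(self):
        p = [0.001, 0.04, 0.2, 0.9]
        adj = sp.holm_adjust(p)
        assert adj == sorted(adj)
        assert all(0 <= a <= 1 for a in adj)
        assert adj[0] == pytest.approx(0.004)
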