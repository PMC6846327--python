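"""Evaluation layer: confusion metrics, ROC/AUC, combined rule, t-tests.

The ROC implementation is checked against an exhaustive pair-concordance
oracle (the Mann-Whitney interpretation of AUC, ties counted half) and
against scikit-learn; the t-test p-value against a direct quadrature of the
t density.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import norm

from varstab.stats import (
    ConfusionCounts,
    EmptyClassError,
    StatsError,
    combined_rule,
    confusion,
    group_summary,
    metrics,
    roc,
    t_test_two_sample,
)


def pair_concordance_auc(scores):
    """Brute-force AUC: P(pos > neg) + 0.5*P(pos == neg) over all pairs."""
    pos = [v for v, lab in scores if lab == "pathogenic"]
    neg = [v for v, lab in scores if lab == "benign"]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def random_scored_set(rng, n_max=12, tie_prob=0.4):
    n_pos = int(rng.integers(1, n_max))
    n_neg = int(rng.integers(1, n_max))
    pool = rng.normal(0, 1, size=4)      # small pool forces frequent ties
    def draw(n, shift):
        if rng.random() < tie_prob:
            return rng.choice(pool, size=n) + shift * rng.integers(0, 2)
        return rng.normal(shift, 1, size=n)
    return ([(float(v), "pathogenic") for v in draw(n_pos, 1.0)]
            + [(float(v), "benign") for v in draw(n_neg, 0.0)])


class TestConfusion:
    def test_basic_counts(self):
        c = confusion([(5.0, "pathogenic"), (1.0, "benign")], 3.0)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_all_below_threshold(self):
        c = confusion([(1.0, "pathogenic"), (0.5, "benign")], 3.0)
        assert (c.tp, c.fp) == (0, 0)
        assert (c.fn, c.tn) == (1, 1)

    def test_matches_brute_force_scan(self, default_cohort):
        truth = default_cohort.truth
        scores = list(zip(truth.true_ddg, truth.group))
        c = confusion(scores, 3.0)
        tp = sum(1 for v, g in scores if g == "pathogenic" and v > 3.0)
        fp = sum(1 for v, g in scores if g == "benign" and v > 3.0)
        assert (c.tp, c.fp) == (tp, fp)
        assert c.tp + c.fn == sum(1 for _, g in scores if g == "pathogenic")
        assert c.fp + c.tn == sum(1 for _, g in scores if g == "benign")

    def test_boundary_is_strict_by_default(self):
        c = confusion([(3.0, "pathogenic"), (3.0, "benign")], 3.0)
        assert (c.tp, c.fp) == (0, 0)
        c = confusion([(3.0, "pathogenic"), (3.0, "benign")], 3.0,
                      direction="greater_equal")
        assert (c.tp, c.fp) == (1, 1)

    def test_empty_class_rejected(self):
        with pytest.raises(EmptyClassError):
            confusion([(5.0, "pathogenic")], 3.0)


class TestMetrics:
    def test_printed_cohort_counts(self):
        # 108/161 pathogenic and 17/161 benign called destabilizing
        m = metrics(ConfusionCounts(tp=108, fn=53, fp=17, tn=144))
        assert round(m["sensitivity"], 3) == 0.671
        assert round(m["specificity"], 3) == 0.894
        assert round(m["ppv"], 3) == 0.864

    def test_balanced_counts(self):
        m = metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert all(v == 0.5 for v in m.values())

    def test_undefined_ppv_is_none(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert m["ppv"] is None
        assert m["specificity"] == 1.0

    def test_sensitivity_complements_miss_rate(self):
        c = ConfusionCounts(tp=7, fn=3, fp=2, tn=8)
        m = metrics(c)
        assert m["sensitivity"] + c.fn / (c.tp + c.fn) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(StatsError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestRoc:
    def test_perfect_separation(self):
        scores = [(v, "pathogenic") for v in (5, 6, 7)] + \
                 [(v, "benign") for v in (1, 2)]
        assert roc(scores).auc == 1.0

    def test_constant_scores(self):
        scores = [(1.0, "pathogenic")] * 3 + [(1.0, "benign")] * 4
        assert roc(scores).auc == 0.5

    def test_curve_endpoints_and_monotonicity(self, default_cohort):
        truth = default_cohort.truth
        curve = roc(list(zip(truth.true_ddg, truth.group)))
        assert curve.points[0] == (0.0, 0.0)
        assert curve.points[-1] == (1.0, 1.0)
        fpr = [p[0] for p in curve.points]
        tpr = [p[1] for p in curve.points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_auc_equals_pair_concordance_on_many_fixtures(self):
        rng = np.random.default_rng(17)
        for _ in range(120):
            scores = random_scored_set(rng)
            assert roc(scores).auc == pytest.approx(
                pair_concordance_auc(scores), abs=1e-12)

    def test_matches_sklearn(self, default_cohort):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        truth = default_cohort.truth
        scores = list(zip(truth.true_ddg, truth.group))
        expected = sklearn_metrics.roc_auc_score(
            [g == "pathogenic" for _, g in scores], [v for v, _ in scores])
        assert roc(scores).auc == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        scores = random_scored_set(rng, tie_prob=0.0)
        base = roc(scores).auc
        for f in (lambda x: 3 * x - 7, math.exp, lambda x: x ** 3):
            transformed = [(f(v), lab) for v, lab in scores]
            assert roc(transformed).auc == pytest.approx(base, abs=1e-12)

    def test_gaussian_closed_form_at_large_n(self):
        """Empirical AUC of two Gaussian groups approaches
        Phi((mu1-mu2)/sqrt(s1^2+s2^2))."""
        rng = np.random.default_rng(29)
        n = 100_000
        mu1, s1, mu2, s2 = 5.06, 4.25, 1.13, 1.46
        scores = ([(v, "pathogenic") for v in rng.normal(mu1, s1, n)]
                  + [(v, "benign") for v in rng.normal(mu2, s2, n)])
        expected = norm.cdf((mu1 - mu2) / math.hypot(s1, s2))
        assert roc(scores).auc == pytest.approx(expected, abs=0.01)

    def test_one_class_rejected(self):
        with pytest.raises(EmptyClassError):
            roc([(1.0, "benign"), (2.0, "benign")])


class TestCombinedRule:
    @pytest.mark.parametrize("ddg, revel, mode, expected", [
        (5.0, 0.9, "and", True),
        (5.0, 0.5, "and", False),
        (2.0, 0.9, "and", False),
        (2.0, 0.9, "or", True),
        (5.0, 0.7, "and", True),        # REVEL cutoff is inclusive
        (3.0, 0.9, "and", False),       # ddg threshold is strict
    ])
    def test_modes(self, ddg, revel, mode, expected):
        assert combined_rule(ddg, revel, 3.0, mode=mode) is expected

    def test_missing_revel_falls_back_to_ddg(self):
        assert combined_rule(5.0, None, 3.0) is True
        assert combined_rule(2.0, float("nan"), 3.0) is False

    def test_conjunction_raises_ppv_on_cohort(self, default_cohort):
        """With a score correlated with pathogenicity, requiring both calls
        trades sensitivity for precision."""
        truth = default_cohort.truth
        def ppv(calls):
            tp = sum(c and g == "pathogenic" for c, g in zip(calls, truth.group))
            fp = sum(c and g == "benign" for c, g in zip(calls, truth.group))
            return tp / (tp + fp)
        ddg_only = [d > 3.0 for d in truth.true_ddg]
        combined = [combined_rule(d, r, 3.0)
                    for d, r in zip(truth.true_ddg, truth.revel)]
        assert ppv(combined) >= ppv(ddg_only)


def t_tail_by_quadrature(t_stat, df):
    """Two-sided tail of the t distribution by direct numerical integration."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    tail, _ = integrate.quad(pdf, abs(t_stat), math.inf)
    return 2 * tail


class TestTTest:
    def test_identical_groups(self):
        t, df, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_large_shift_is_significant(self):
        _, _, p = t_test_two_sample([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_pooled_df(self):
        _, df, _ = t_test_two_sample([1.0, 2.0, 4.0], [2.0, 5.0], "student")
        assert df == 3

    def test_p_matches_quadrature_oracle(self):
        a, b = [2.1, 2.5, 1.9, 2.4], [3.0, 3.4, 2.9]
        for variant in ("student", "welch"):
            t, df, p = t_test_two_sample(a, b, variant)
            assert p == pytest.approx(t_tail_by_quadrature(t, df), abs=1e-6)

    def test_welch_satterthwaite_df(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0]
        _, df, _ = t_test_two_sample(a, b, "welch")
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        expected = (va + vb) ** 2 / (va ** 2 / (len(a) - 1)
                                     + vb ** 2 / (len(b) - 1))
        assert df == pytest.approx(expected)

    def test_degenerate_equal_constant_groups(self):
        t, _, p = t_test_two_sample([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_too_small_groups_rejected(self):
        with pytest.raises(StatsError):
            t_test_two_sample([1.0], [2.0, 3.0])


class TestGroupSummary:
    def test_type7_quartiles(self):
        gs = group_summary({"g": [1, 2, 3, 4]}, compare=None)
        assert gs.groups["g"]["median"] == 2.5
        assert gs.groups["g"]["q1"] == 1.75
        assert gs.groups["g"]["q3"] == 3.25

    def test_single_value_quantiles_collapse(self):
        gs = group_summary({"g": [7.0]}, compare=None)
        g = gs.groups["g"]
        assert g["q1"] == g["median"] == g["q3"] == 7.0

    def test_quartile_ordering_invariant(self, default_cohort):
        truth = default_cohort.truth
        gs = group_summary({g: truth.loc[truth.group == g, "true_ddg"]
                            for g in ("pathogenic", "benign")})
        for g in gs.groups.values():
            assert g["q1"] <= g["median"] <= g["q3"]
        assert gs.p_value is not None and gs.p_value < 0.001

    def test_generator_mean_recovered_at_large_n(self):
        rng = np.random.default_rng(31)
        values = rng.normal(5.06, 4.25, 10_000)
        gs = group_summary({"pathogenic": values}, compare=None)
        assert abs(gs.groups["pathogenic"]["mean"] - 5.06) < 0.2


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.lists(st.floats(-50, 50), min_size=1, max_size=15),
       st.lists(st.floats(-50, 50), min_size=1, max_size=15))
def test_roc_pair_concordance_property(pos_values, neg_values):
    """AUC equals exhaustive pair concordance for arbitrary score sets."""
    scores = ([(v, "pathogenic") for v in pos_values]
              + [(v, "benign") for v in neg_values])
    assert roc(scores).auc == pytest.approx(pair_concordance_auc(scores),
                                            abs=1e-12)
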