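import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from riskpattern.errors import ValidationError
from riskpattern.evaluate import (
    ConfusionCounts,
    auc,
    compare_cohorts,
    confusion,
    evaluate_pattern,
    evaluate_scores,
    metrics_from_confusion,
    optimal_roc_point,
    roc_curve,
)
from riskpattern.pattern import Condition, Pattern
from riskpattern.synth import generate_cohort, planted_signal_config

from conftest import make_table


def concordance_auc(scores, labels):
    """Brute-force Mann-Whitney pairwise concordance, ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_all_correct_positive(self):
        c = confusion([1] * 5, [1] * 5)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 0, 0)

    def test_complement_predictions(self):
        c = confusion([0, 1, 0, 1], [1, 0, 1, 0])
        assert c.tp == 0 and c.tn == 0 and c.fp == 2 and c.fn == 2

    def test_hand_counted_vector(self):
        preds = [1, 1, 0, 0, 1, 0, 1, 0, 0, 1]
        labels = [1, 0, 0, 1, 1, 0, 0, 0, 1, 1]
        c = confusion(preds, labels)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 2, 3, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            confusion([1], [1, 0])


class TestMetrics:
    @pytest.mark.parametrize(
        "counts,expect",
        [
            # sens 0.6, spec 0.88 → G-mean 0.73 at two decimals
            (ConfusionCounts(tp=60, fn=40, tn=88, fp=12), 0.73),
            # sens 0.83, spec 0.57 → G-mean 0.69
            (ConfusionCounts(tp=83, fn=17, tn=57, fp=43), 0.69),
        ],
    )
    def test_g_mean_from_sensitivity_specificity(self, counts, expect):
        rep = metrics_from_confusion(counts)
        assert round(rep.g_mean, 2) == expect
        assert rep.g_mean == pytest.approx(
            math.sqrt(rep.sensitivity * rep.specificity)
        )

    def test_f_zero_when_no_true_positives(self):
        rep = metrics_from_confusion(ConfusionCounts(tp=0, fp=5, tn=10, fn=3))
        assert rep.f_score == 0.0

    def test_precision_zero_when_nothing_predicted(self):
        rep = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, tn=10, fn=3))
        assert rep.precision == 0.0 and rep.f_score == 0.0

    def test_f_is_harmonic_mean(self):
        rep = metrics_from_confusion(ConfusionCounts(tp=30, fp=10, tn=50, fn=10))
        expect = 2 * rep.precision * rep.sensitivity / (
            rep.precision + rep.sensitivity
        )
        assert rep.f_score == pytest.approx(expect)


class TestRoc:
    def test_perfect_separation(self):
        c = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc(c) == pytest.approx(1.0)

    def test_constant_scores_diagonal(self):
        c = roc_curve([0.5] * 6, [1, 0, 1, 0, 0, 0])
        assert auc(c) == pytest.approx(0.5)
        assert len(c.fpr) == 2  # single vertex plus the origin

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 8), 50)  # heavy ties
        labels = rng.integers(0, 2, 50)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        c = roc_curve(scores, labels)
        assert auc(c) == pytest.approx(concordance_auc(scores, labels))

    def test_cross_check_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, 200) + rng.integers(0, 2, 200)
        labels = rng.integers(0, 2, 200)
        c = roc_curve(scores, labels)
        assert auc(c) == pytest.approx(roc_auc_score(labels, scores))

    def test_monotone_vertices(self):
        rng = np.random.default_rng(1)
        c = roc_curve(rng.random(60), rng.integers(0, 2, 60))
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([0.1, 0.2], [1, 1])

    @given(
        seed=st.integers(min_value=0, max_value=50),
        scale=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_increasing_transform(self, seed, scale):
        rng = np.random.default_rng(seed)
        scores = rng.normal(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a1 = auc(roc_curve(scores, labels))
        a2 = auc(roc_curve(np.exp(scale * scores), labels))
        assert a1 == pytest.approx(a2)


class TestOptimalRocPoint:
    def test_perfect_separator_j_one(self):
        c = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        cut, counts = optimal_roc_point(c)
        rep = metrics_from_confusion(counts)
        assert rep.sensitivity + rep.specificity - 1 == pytest.approx(1.0)
        assert cut == pytest.approx(0.8)

    def test_constant_scores_j_zero(self):
        c = roc_curve([0.5] * 6, [1, 0, 1, 0, 0, 0])
        _, counts = optimal_roc_point(c)
        rep = metrics_from_confusion(counts)
        assert rep.sensitivity + rep.specificity - 1 == pytest.approx(0.0)

    def test_agrees_with_exhaustive_vertex_scan(self):
        scores = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        labels = [0, 0, 1, 0, 1, 0, 1, 1]
        c = roc_curve(scores, labels)
        js = c.tpr - c.fpr
        _, counts = optimal_roc_point(c)
        got_j = (
            counts.tp / (counts.tp + counts.fn)
            - counts.fp / (counts.fp + counts.tn)
        )
        assert got_j == pytest.approx(js.max())

    def test_tie_prefers_higher_specificity(self):
        # vertices (0,0), (0.5, 0.5), (1,1) all have J = 0 … pick fpr 0
        c = roc_curve([3, 3, 2, 2, 1, 1], [1, 0, 1, 0, 1, 0])
        _, counts = optimal_roc_point(c)
        assert counts.fp == 0


class TestEvaluatePattern:
    def test_always_positive_pattern(self):
        t = make_table({"x": [1.0, 2.0, 3.0, 4.0]}, [1, 0, 0, 1])
        pat = Pattern("outcome", "Yes", [Condition("x", ">", -10.0)], 1)
        rep = evaluate_pattern(pat, t)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_unsatisfiable_conjunction(self):
        t = make_table(
            {"x": [1.0, 2.0, 3.0, 4.0], "y": [1.0, 1.0, 2.0, 2.0]}, [1, 0, 0, 1]
        )
        pat = Pattern("outcome", "Yes",
                      [Condition("x", ">", 100.0), Condition("y", ">", 100.0)], 2)
        rep = evaluate_pattern(pat, t)
        assert rep.f_score == 0.0 and rep.sensitivity == 0.0

    def test_planted_signal_auc_high(self):
        cfg = planted_signal_config(3, n_train=2000, n_test=2000)
        _, test = generate_cohort(cfg, seed=0)
        rep = evaluate_pattern(cfg.planted_pattern, test)
        assert rep.auc > 0.95


class TestEvaluateScores:
    def test_labels_as_scores(self):
        labels = [1, 0, 1, 0, 0]
        rep = evaluate_scores(labels, labels, cutoff=0.5)
        assert rep.sensitivity == rep.specificity == rep.f_score == 1.0
        assert rep.auc == pytest.approx(1.0)

    def test_optimal_cutoff_matches_youden_point(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 100) + 0.8 * rng.integers(0, 2, 100)
        labels = rng.integers(0, 2, 100)
        rep = evaluate_scores(scores, labels, cutoff="optimal")
        curve = roc_curve(scores, labels)
        cut, counts = optimal_roc_point(curve)
        direct = metrics_from_confusion(counts)
        assert rep.sensitivity == pytest.approx(direct.sensitivity)
        assert rep.specificity == pytest.approx(direct.specificity)
        assert rep.threshold == pytest.approx(cut)

    def test_twelve_patient_hand_computation(self):
        # published-threshold style: score ≥ 8 predicts the event
        scores = [2, 4, 9, 11, 5, 8, 1, 12, 7, 3, 10, 6]
        labels = [0, 0, 1, 1, 0, 0, 0, 1, 1, 0, 0, 0]
        rep = evaluate_scores(scores, labels, cutoff=8, comparator=">=")
        # by hand: predictions {9,11,8,12,10} → TP=3 (9,11,12), FP=2 (8,10),
        # FN=1 (7), TN=6
        assert rep.sensitivity == pytest.approx(3 / 4)
        assert rep.specificity == pytest.approx(6 / 8)
        assert rep.precision == pytest.approx(3 / 5)


class TestCompareCohorts:
    def test_identical_groups_chi2_zero(self):
        t = make_table({"flag": ["Yes", "No"] * 20}, [1, 0] * 20)
        df = compare_cohorts(t, t)
        row = df[df["variable"] == "flag"].iloc[0]
        assert row["p_value"] == pytest.approx(1.0)

    def test_published_categorical_p_values(self):
        # outcome 149/1791 vs 40/769 → p 0.007; anemia 33 vs 27 → 0.016;
        # urgent PCI 204 vs 114 → 0.019 (Yates-corrected chi-square)
        def cohort(n, n_outcome, n_anemia, n_urgent):
            return make_table(
                {
                    "anemia": ["Yes"] * n_anemia + ["No"] * (n - n_anemia),
                    "urgent_pci": ["Yes"] * n_urgent + ["No"] * (n - n_urgent),
                },
                [1] * n_outcome + [0] * (n - n_outcome),
                target_name="AKI",
            )

        train = cohort(1791, 149, 33, 204)
        test = cohort(769, 40, 27, 114)
        df = compare_cohorts(train, test).set_index("variable")
        assert round(df.loc["AKI", "p_value"], 3) == 0.007
        assert round(df.loc["anemia", "p_value"], 3) == 0.016
        assert round(df.loc["urgent_pci", "p_value"], 3) == 0.019

    def test_numeric_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(8)
        a = make_table({"x": rng.normal(0, 1, 60).tolist()}, [0] * 60)
        a.target[0] = True  # keep both classes formally representable
        b = make_table({"x": rng.normal(0.4, 1, 50).tolist()}, [0] * 50)
        df = compare_cohorts(a, b)
        p_anova = df[df["variable"] == "x"].iloc[0]["p_value"]
        p_t = stats.ttest_ind(
            a.data["x"], b.data["x"], equal_var=True
        ).pvalue
        assert p_anova == pytest.approx(p_t)

    def test_schema_mismatch_rejected(self):
        a = make_table({"x": [1.0, 2.0]}, [0, 1])
        b = make_table({"y": [1.0, 2.0]}, [0, 1])
        with pytest.raises(ValidationError):
            compare_cohorts(a, b)
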