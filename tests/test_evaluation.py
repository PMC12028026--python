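"""Tests of relative-risk gold standards, rank AUC, and LR combination."""

import math

import numpy as np
import pandas as pd
import pytest

from gscomod import (
    CohortTable,
    auc,
    bonferroni_threshold,
    label_pairs,
    lr_combine,
    relative_risk,
)
from gscomod.evaluation import RRResult


def _cohort_from_counts(a, b, c, d):
    """Build a cohort realising the 2x2 table (A+B+, A+B-, A-B+, A-B-)."""
    rows = (
        [[1, 1]] * a + [[1, 0]] * b + [[0, 1]] * c + [[0, 0]] * d
    )
    df = pd.DataFrame(rows, columns=["A", "B"], index=[f"s{i}" for i in range(len(rows))])
    return CohortTable(data=df)


def chi2_oracle(a, b, c, d):
    """Textbook Pearson chi-square on a 2x2 table, no continuity correction."""
    n = a + b + c + d
    obs = [a, b, c, d]
    exp = [
        (a + b) * (a + c) / n,
        (a + b) * (b + d) / n,
        (c + d) * (a + c) / n,
        (c + d) * (b + d) / n,
    ]
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


class TestRelativeRisk:
    def test_worked_example(self):
        # 100 exposed, 30 with outcome; 200 unexposed, 20 with outcome
        c = _cohort_from_counts(30, 70, 20, 180)
        res = relative_risk(c, "A", "B")
        assert res.rr == pytest.approx(3.0)
        assert (res.a, res.b, res.c, res.d) == (30, 70, 20, 180)
        assert res.ci_low <= res.rr <= res.ci_high

    def test_equal_rates_give_rr_one(self):
        c = _cohort_from_counts(10, 90, 20, 180)
        assert relative_risk(c, "A", "B").rr == pytest.approx(1.0)

    def test_chi_square_matches_direct_formula(self):
        from scipy.stats import chi2

        c = _cohort_from_counts(30, 70, 20, 180)
        res = relative_risk(c, "A", "B")
        stat = chi2_oracle(30, 70, 20, 180)
        assert res.p == pytest.approx(chi2.sf(stat, df=1), rel=1e-10)

    def test_wald_ci_formula(self):
        c = _cohort_from_counts(30, 70, 20, 180)
        res = relative_risk(c, "A", "B")
        se = math.sqrt(1 / 30 - 1 / 100 + 1 / 20 - 1 / 200)
        assert res.ci_low == pytest.approx(3.0 * math.exp(-1.96 * se), rel=1e-9)
        assert res.ci_high == pytest.approx(3.0 * math.exp(1.96 * se), rel=1e-9)

    def test_exhaustive_small_tables_match_hand_ratio(self):
        """RR equals the directly computed risk ratio on a grid of small
        tables with non-zero outcome counts in both arms."""
        for a in range(1, 8):
            for b in range(0, 8):
                for c in range(1, 8):
                    for d in range(0, 8):
                        cohort = _cohort_from_counts(a, b, c, d)
                        res = relative_risk(cohort, "A", "B")
                        expected = (a / (a + b)) / (c / (c + d))
                        assert res.rr == pytest.approx(expected, rel=1e-12)

    def test_zero_outcome_arm_applies_continuity_correction(self):
        c = _cohort_from_counts(0, 50, 10, 40)
        res = relative_risk(c, "A", "B")
        assert "continuity_corrected" in res.flags
        expected = (0.5 / 51.0) / (10.5 / 51.0)
        assert res.rr == pytest.approx(expected, rel=1e-12)

    def test_missing_code_and_empty_arm_raise(self):
        c = _cohort_from_counts(5, 5, 5, 5)
        with pytest.raises(KeyError):
            relative_risk(c, "A", "ZZ")
        df = pd.DataFrame({"A": [1, 1], "B": [0, 1]}, index=["s0", "s1"])
        with pytest.raises(ValueError, match="unexposed group is empty"):
            relative_risk(CohortTable(data=df), "A", "B")


class TestBonferroni:
    def test_printed_thresholds(self):
        assert bonferroni_threshold(0.05, 3828) == pytest.approx(1.31e-5, rel=5e-3)
        assert bonferroni_threshold(0.05, 7658) == pytest.approx(6.53e-6, rel=5e-3)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_m_raises(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _rr(rr, p, a="X", b="Y"):
    return RRResult(a, b, 1, 1, 1, 1, rr=rr, ci_low=rr, ci_high=rr, p=p)


class TestLabelPairs:
    def test_three_threshold_gates(self):
        # M = 100 tested pairs -> Bonferroni threshold 5e-4
        results = [_rr(12.0, 1e-9), _rr(3.0, 1e-9), _rr(12.0, 0.01)]
        results += [_rr(1.0, 1.0) for _ in range(97)]
        labels = label_pairs(results, alpha=0.05, thresholds=(1.0, 5.0, 10.0))
        by_thr = {t: [l.label for l in labs[:3]] for t, labs in labels.items()}
        assert by_thr[1.0] == [1, 1, 0]
        assert by_thr[5.0] == [1, 0, 0]
        assert by_thr[10.0] == [1, 0, 0]

    def test_rr_gate_is_strict(self):
        labels = label_pairs([_rr(5.0, 1e-9)] + [_rr(1.0, 1.0)] * 9, thresholds=(5.0,))
        assert labels[5.0][0].label == 0  # rr must strictly exceed the threshold


def auc_oracle(scores, labels):
    """O(n^2) enumeration of positive-negative pairs with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_pure_ties_give_half(self):
        r = auc(np.zeros(10), np.array([0, 1] * 5))
        assert r.auc == 0.5 and r.n_pos == 5 and r.n_neg == 5

    def test_perfect_separation_gives_one(self):
        assert auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])).auc == 1.0

    def test_matches_brute_force_with_ties(self):
        scores = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        labels = np.array([0, 0, 1, 1, 1])
        assert auc(scores, labels).auc == pytest.approx(
            auc_oracle(scores, labels), abs=1e-12
        )

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels).auc == pytest.approx(
                auc_oracle(scores, labels), abs=1e-12
            )

    def test_complement_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)
        labels = np.array([0, 1] * 20)
        assert auc(scores, labels).auc + auc(-scores, labels).auc == pytest.approx(
            1.0, abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc(np.arange(4.0), np.ones(4, dtype=int))

    def test_agrees_with_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = rng.integers(0, 5, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestLrCombine:
    def test_single_measure_auc_equals_raw_auc(self):
        rng = np.random.default_rng(5)
        score = rng.normal(size=100)
        labels = (score + rng.normal(0, 1, 100) > 0).astype(int)
        raw = auc(score, labels).auc
        res = lr_combine(pd.DataFrame({"m": score}), labels, model_spec=[("m",)])
        assert res.best_auc == pytest.approx(raw, abs=1e-12)

    def test_random_labels_give_null_auc(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"m1": rng.normal(size=200), "m2": rng.normal(size=200)})
        labels = rng.integers(0, 2, 200)
        res = lr_combine(X, labels, model_spec=[("m1",)])
        assert abs(res.best_auc - 0.5) < 0.1

    def test_search_is_monotone_in_subset_inclusion(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(size=150)
        x2 = rng.normal(size=150)
        labels = (x1 + 0.5 * x2 + rng.normal(0, 1, 150) > 0).astype(int)
        X = pd.DataFrame({"m1": x1, "m2": x2})
        small = lr_combine(X, labels, model_spec=[("m1",)])
        full = lr_combine(X, labels, model_spec=[("m1",), ("m2",), ("m1", "m2")])
        assert full.best_auc >= small.best_auc - 1e-12
        assert full.per_subset[("m1",)] == pytest.approx(small.best_auc, abs=1e-12)

    def test_perfect_separation_still_reports_auc_one(self):
        X = pd.DataFrame({"m": np.r_[np.zeros(20), np.ones(20)]})
        labels = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
        res = lr_combine(X, labels)
        assert res.best_auc == 1.0

    def test_missing_scores_are_zero_filled(self):
        X = pd.DataFrame({"m": [np.nan, 1.0, np.nan, 2.0]})
        labels = np.array([0, 1, 0, 1])
        res = lr_combine(X, labels, model_spec=[("m",)])
        assert res.best_auc == 1.0  # zeros sit below both positives

    def test_unknown_measure_raises(self):
        X = pd.DataFrame({"m": np.arange(12.0)})
        with pytest.raises(ValueError, match="unknown measure"):
            lr_combine(X, np.array([0, 1] * 6), model_spec=[("zz",)])


def test_no_overlap_benchmark_reproduces_overlap_blindness(no_overlap_benchmark):
    """On gene-disjoint disease pairs, overlap measures are identically
    zero (AUC exactly 0.5) while the profile-similarity score still
    separates comorbid from independent pairs."""
    from gscomod import gs_sim, jaccard, overlap_coefficient

    collection, diseases, pairs, labels, profiles = no_overlap_benchmark
    jac = np.array([jaccard(diseases[a].genes, diseases[b].genes) for a, b in pairs])
    oc = np.array(
        [overlap_coefficient(diseases[a].genes, diseases[b].genes) for a, b in pairs]
    )
    assert np.all(jac == 0.0) and np.all(oc == 0.0)
    assert auc(jac, labels).auc == 0.5
    assert auc(oc, labels).auc == 0.5
    gs = np.array([gs_sim(profiles[a], profiles[b]).value for a, b in pairs])
    assert auc(gs, labels).auc > 0.5
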