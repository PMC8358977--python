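"""Fold construction, AUC, significance thresholds, rank-sum test, reports."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from rhythmdecode.containers import EpochSet
from rhythmdecode.evaluation import (
    CVSummary,
    cohort_report,
    kfold_split,
    rank_sum_test,
    robustness_experiment,
    run_cv,
    significance_threshold,
)
from rhythmdecode.metrics import auc


class TestKFold:
    def test_balanced_sizes(self):
        groups = kfold_split(800, 5, seed=0)
        assert [len(g) for g in groups] == [160] * 5

    def test_remainder_rule(self):
        assert sorted(len(g) for g in kfold_split(7, 5, seed=1)) == [1, 1, 1, 2, 2]

    def test_deterministic(self):
        a = kfold_split(40, 5, seed=3)
        b = kfold_split(40, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(4, 5, seed=0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(n=st.integers(5, 200), k=st.integers(2, 5), seed=st.integers(0, 10))
    def test_partition_invariants(self, n, k, seed):
        groups = kfold_split(n, k, seed)
        sizes = [len(g) for g in groups]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(np.concatenate(groups)) == list(range(n))


class TestAUC:
    def test_hand_enumerated_example(self):
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_matches_trapezoidal_roc_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # forces ties
            assert abs(auc(y, scores) - roc_auc_score(y, scores)) < 1e-12

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_negation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        y = np.concatenate([[0, 1], rng.integers(0, 2, 10)])
        s = rng.normal(size=12).round(1)  # rounding creates ties
        assert auc(y, s) + auc(y, -s) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 1], [0.2, 0.3])


class TestSignificanceThreshold:
    @pytest.mark.parametrize(
        "n,alpha,expected_pct",
        [(100, 0.05, 58.0), (100, 1e-4, 68.0), (10, 0.05, 80.0)],
    )
    def test_reference_values(self, n, alpha, expected_pct):
        assert significance_threshold(n, alpha).threshold_pct == pytest.approx(expected_pct)

    def test_matches_exact_enumeration(self):
        # brute force with integer arithmetic: P(X >= c) = sum C(n,i) / 2^n
        for n in [1, 2, 7, 10, 33, 100, 250, 1000]:
            for alpha in [Fraction(1, 20), Fraction(1, 10_000)]:
                tail = 0
                c_star = n + 1
                for c in range(n, -1, -1):
                    tail += math.comb(n, c)
                    if Fraction(tail, 2**n) >= alpha:
                        break
                    c_star = c
                got = significance_threshold(n, float(alpha))
                assert got.critical_count == c_star, (n, alpha)
                assert got.threshold_pct == pytest.approx(100 * (c_star - 1) / n)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(0, 0.05)
        with pytest.raises(ValueError):
            significance_threshold(10, 1.5)


class TestRankSum:
    def test_small_sample_exact(self):
        W, Z, p = rank_sum_test([1, 2], [3, 4])
        assert W == 3.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        W, Z, p = rank_sum_test([5.0] * 10, [5.0] * 10)
        assert Z == 0.0
        assert p == pytest.approx(1.0)

    def test_null_calibration(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, _, p = rank_sum_test(rng.normal(size=50), rng.normal(size=50))
            rejections += p <= 0.05
        assert rejections <= 2  # >= 90% of null runs non-significant

    def test_detects_shift(self):
        rng = np.random.default_rng(0)
        _, z, p = rank_sum_test(rng.normal(size=30), rng.normal(size=30) + 2.0)
        assert p < 1e-4
        assert abs(z) > 4

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class _ConstantModel:
    """Scores every epoch identically - AUC must be exactly 1/2 by ties."""

    def fit(self, X, y):
        return self

    def predict_score(self, X):
        return np.zeros(len(X))


def _noise_epochs(n=60, seed=0, reject=None):
    rng = np.random.default_rng(seed)
    labels = np.array(["drum", "syllable"] * (n // 2), dtype=object)
    return EpochSet(
        rng.standard_normal((n, 8, 200)), labels, 100.0, 2.0, reject_mask=reject
    )


class TestRunCV:
    def test_constant_model_gives_exact_half(self):
        summary = run_cv(lambda seed: _ConstantModel(), _noise_epochs(), k=5, seed=1,
                         condition="all_epochs")
        assert summary.fold_aucs == [0.5] * 5
        assert summary.mean_auc == 0.5
        assert summary.sd_auc == 0.0

    def test_svm_on_noise_is_chance(self):
        summary = run_cv("svm", _noise_epochs(n=120, seed=5), k=5, seed=2,
                         condition="all_epochs")
        assert len(summary.fold_aucs) == 5
        assert 0.35 <= summary.mean_auc <= 0.65

    def test_clean_condition_applies_mask(self):
        reject = np.zeros(60, bool)
        reject[:10] = True
        eps = _noise_epochs(reject=reject)
        s = run_cv(lambda seed: _ConstantModel(), eps, k=5, seed=0, condition="clean")
        assert s.n_epochs == 50

    def test_single_class_rejected(self):
        eps = _noise_epochs()
        eps.labels[:] = "drum"
        with pytest.raises(ValueError, match="both classes"):
            run_cv("svm", eps, k=5, seed=0, condition="all_epochs")


class TestRobustness:
    def test_requires_mask_and_returns_pair(self):
        eps = _noise_epochs()
        with pytest.raises(ValueError, match="reject mask"):
            robustness_experiment(eps, "svm", seed=0)
        reject = np.zeros(60, bool)
        reject[::6] = True
        eps = _noise_epochs(reject=reject)
        out = robustness_experiment(eps, lambda seed: _ConstantModel(), seed=0)
        assert set(out) == {"clean", "all_epochs", "degradation"}
        assert out["degradation"] == pytest.approx(
            out["clean"].mean_auc - out["all_epochs"].mean_auc
        )


def _mk_summary(subject, model, condition, mean, site="A"):
    return CVSummary([mean] * 5, mean, 0.0, subject_id=subject, model=model,
                     condition=condition, site=site)


class TestCohortReport:
    def test_row_counts_and_cohort_mean(self):
        summaries = [
            _mk_summary(f"S{i:03d}", m, c, 0.6 + 0.01 * i)
            for i in range(4)
            for m in ("cnn", "svm")
            for c in ("clean", "all_epochs")
        ]
        table, stats = cohort_report(summaries)
        assert len(table) == 16
        grp = stats["groups"]["cnn:clean"]
        assert grp["mean_auc"] == pytest.approx(np.mean([0.6, 0.61, 0.62, 0.63]))
        assert stats["thresholds"][0.05] == pytest.approx(58.0)
        assert stats["thresholds"][1e-4] == pytest.approx(68.0)

    def test_identical_site_noise_null(self):
        non_sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            summaries = [
                _mk_summary(f"S{i:03d}", "cnn", "clean", float(rng.normal(0.8, 0.05)),
                            site="A" if i < 12 else "B")
                for i in range(20)
            ]
            _, stats = cohort_report(summaries)
            non_sig += stats["site_comparison"]["cnn:clean"]["p"] > 0.05
        assert non_sig >= 18

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_report([])
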