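"""Metrics, the conservative SD adjustment, and replication comparisons."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import treedistill as td
from treedistill.evaluation import (
    METRIC_NAMES,
    ConfusionMatrix,
    confusion,
    metric_set,
    replicate,
    sd_adjustment_factor,
    significance_flags,
)


def brute_force_auc(y, s):
    wins = ties = total = 0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            total += 1
            if s[i] > s[j]:
                wins += 1
            elif s[i] == s[j]:
                ties += 1
    return (wins + 0.5 * ties) / total


def brute_force_average_precision(y, s):
    """Precision-recall step construction with tie blocks."""
    n_pos = int(np.sum(y))
    ap = 0.0
    prev_tp = 0
    seen = 0
    for value in sorted(set(s), reverse=True):
        block = [i for i in range(len(s)) if s[i] == value]
        seen += len(block)
        tp = prev_tp + sum(int(y[i]) for i in block)
        ap += (tp - prev_tp) * (tp / seen)
        prev_tp = tp
    return ap / n_pos


labeled_scores = st.integers(2, 10).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
        st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n),
    )
)


class TestConfusion:
    def test_perfect_scorer(self):
        cm = confusion([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (cm.fp, cm.fn) == (0, 0)

    def test_all_zero_scores(self):
        cm = confusion([1, 0, 1], [0.0, 0.0, 0.0])
        assert (cm.tp, cm.fp) == (0, 0)

    def test_hand_example(self):
        cm = confusion([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 0], [0.5])


class TestAucRoc:
    def test_perfect_separation(self):
        assert td.auc_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_identical_scores_are_chance(self):
        assert td.auc_roc([0, 1, 0, 1], [0.4] * 4) == 0.5

    def test_worked_example(self):
        # 3 of 4 positive-negative pairs won, 1 lost
        assert td.auc_roc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            td.auc_roc([1, 1], [0.4, 0.5])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(labeled_scores)
    def test_matches_pairwise_count(self, case):
        y, s = np.array(case[0]), np.array(case[1])
        if 0 < y.sum() < y.size:
            assert td.auc_roc(y, s) == pytest.approx(brute_force_auc(y, s))


class TestAuprc:
    def test_positives_on_top(self):
        assert td.auprc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_worked_example(self):
        assert td.auprc([1, 0, 1], [0.9, 0.8, 0.7]) == pytest.approx((1.0 + 2 / 3) / 2)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            td.auprc([0, 0], [0.4, 0.5])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(labeled_scores)
    def test_matches_step_construction(self, case):
        y, s = np.array(case[0]), np.array(case[1])
        if y.sum() > 0:
            assert td.auprc(y, s) == pytest.approx(brute_force_average_precision(y, s))

    def test_random_scorer_baseline_tends_to_prevalence(self, rng):
        y = (rng.random(5000) < 0.25).astype(float)
        values = [td.auprc(y, rng.random(5000)) for _ in range(40)]
        assert np.mean(values) == pytest.approx(y.mean(), abs=0.01)


class TestMcc:
    def test_perfect(self):
        assert td.mcc(ConfusionMatrix(5, 0, 0, 5)) == 1.0

    def test_one_class_prediction_is_zero(self):
        assert td.mcc(ConfusionMatrix(0, 0, 5, 5)) == 0.0

    def test_hand_arithmetic(self):
        assert td.mcc(ConfusionMatrix(6, 1, 2, 3)) == pytest.approx(16 / np.sqrt(1120))


class TestMetricSet:
    def test_f_value_consistency(self, rng):
        y = (rng.random(200) < 0.3).astype(float)
        s = np.clip(y * 0.6 + rng.random(200) * 0.4, 0, 1)
        ms = metric_set(y, s)
        if ms.precision + ms.recall > 0:
            assert ms.f_value == pytest.approx(
                2 * ms.precision * ms.recall / (ms.precision + ms.recall)
            )
        cm = confusion(y, s)
        assert ms.acc == pytest.approx((cm.tp + cm.tn) / cm.n)

    def test_cross_check_against_sklearn(self, rng):
        from sklearn.metrics import average_precision_score, matthews_corrcoef, roc_auc_score

        y = (rng.random(500) < 0.2).astype(float)
        s = np.clip(y * 0.3 + rng.random(500) * 0.7, 0, 1)
        ms = metric_set(y, s)
        assert ms.auc == pytest.approx(roc_auc_score(y, s))
        assert ms.auprc == pytest.approx(average_precision_score(y, s))
        assert ms.mcc == pytest.approx(matthews_corrcoef(y, s >= 0.5))


class TestSdAdjustment:
    def test_paper_printed_factor(self):
        assert round(sd_adjustment_factor(50, 0.05), 4) == 1.2017

    def test_small_sample_value(self):
        from scipy.stats import chi2

        assert sd_adjustment_factor(10, 0.05) == pytest.approx(np.sqrt(9 / chi2.ppf(0.05, 9)))
        assert sd_adjustment_factor(10, 0.05) == pytest.approx(1.645, abs=5e-4)

    def test_limits_and_monotonicity(self):
        assert sd_adjustment_factor(5000, 0.05) < 1.02
        values = [sd_adjustment_factor(r, 0.05) for r in (3, 5, 10, 50, 200, 1000)]
        assert (np.diff(values) < 0).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            sd_adjustment_factor(1, 0.05)
        with pytest.raises(ValueError, match="alpha"):
            sd_adjustment_factor(50, 1.5)


@pytest.fixture(scope="module")
def tiny_problem():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(300, 3))
    y = (X[:, 0] + rng.normal(0, 1.5, 300) > 0.8).astype(float)
    return X, y


def logistic_builder(X, y, seed):
    return td.fit_logistic(X, y, seed=seed)


class TestReplicate:
    def test_summary_shapes_and_adjustment(self, tiny_problem):
        X, y = tiny_problem
        summary = replicate(X, y, logistic_builder, R=10, base_seed=0)
        factor = sd_adjustment_factor(10, 0.05)
        for m in METRIC_NAMES:
            assert summary.adjusted_se[m] == pytest.approx(factor * summary.sds[m])
        assert len(summary.per_replication) == 10

    def test_test_split_is_stratified_and_sized(self, tiny_problem):
        X, y = tiny_problem
        captured = []

        def builder(X_tr, y_tr, seed):
            captured.append(len(y_tr))
            return td.fit_logistic(X_tr, y_tr, seed=seed)

        summary = replicate(X, y, builder, R=3, rebalance_mode=None, base_seed=1)
        assert len(summary.per_replication) == 3
        # per-class rounding keeps the test size within one row of 30%
        n_test = round(0.30 * len(y))
        assert all(abs((len(y) - n) - n_test) <= 1 for n in captured)

    def test_identical_seeds_give_zero_sd(self, tiny_problem):
        X, y = tiny_problem
        a = replicate(X, y, logistic_builder, R=5, base_seed=9)
        b = replicate(X, y, logistic_builder, R=5, base_seed=9)
        assert a.means == b.means

    def test_builder_failures_are_isolated(self, tiny_problem):
        X, y = tiny_problem
        calls = []

        def flaky(X_tr, y_tr, seed):
            calls.append(seed)
            if seed == 1:
                raise RuntimeError("boom")
            return td.fit_logistic(X_tr, y_tr, seed=seed)

        summary = replicate(X, y, flaky, R=4, base_seed=0)
        assert any("boom" in w for w in summary.warnings)
        assert len(summary.per_replication) == 3

    def test_validation(self, tiny_problem):
        X, y = tiny_problem
        with pytest.raises(ValueError, match="R"):
            replicate(X, y, logistic_builder, R=1)
        with pytest.raises(ValueError, match="class"):
            replicate(X, np.zeros_like(y), logistic_builder, R=3)


class TestSignificanceFlags:
    def make(self, means, sds, R=50):
        factor = sd_adjustment_factor(R, 0.05)
        return td.ReplicationSummary(
            means=means, sds=sds,
            adjusted_se={k: factor * v for k, v in sds.items()},
            R=R, split=0.7, seeds=(),
        )

    def base(self, auc_sd=0.0088):
        means = {m: 0.5 for m in METRIC_NAMES}
        sds = {m: auc_sd for m in METRIC_NAMES}
        return self.make(means, sds)

    def test_boundary_is_not_significant(self):
        # baseline mean 0 keeps the difference float-exact at 2 adjusted SEs
        means = {m: 0.0 for m in METRIC_NAMES}
        sds = {m: 0.0088 for m in METRIC_NAMES}
        base = self.make(means, sds)
        cand_means = dict(means)
        cand_means["auc"] = 2 * base.adjusted_se["auc"]
        cand = self.make(cand_means, dict(sds))
        assert significance_flags(cand, base)["auc"] == "ns"

    def test_star_thresholds_match_printed_auc_rule(self):
        # with the printed baseline AUC SD 0.0088 a single star needs > 0.0212
        base = self.base()
        just_over = self.make({**base.means, "auc": 0.5 + 0.0213}, dict(base.sds))
        just_under = self.make({**base.means, "auc": 0.5 + 0.0211}, dict(base.sds))
        assert significance_flags(just_over, base)["auc"] == "*"
        assert significance_flags(just_under, base)["auc"] == "ns"

    def test_double_star_beyond_three_se(self):
        base = self.base()
        cand = self.make({**base.means, "auc": 0.5 + 0.04}, dict(base.sds))
        assert significance_flags(cand, base)["auc"] == "**"

    def test_one_sided(self):
        base = self.base()
        worse = self.make({**base.means, "auc": 0.3}, dict(base.sds))
        assert significance_flags(worse, base)["auc"] == "ns"

    def test_mismatched_R_rejected(self):
        base = self.base()
        other = dataclasses.replace(base, R=10)
        with pytest.raises(ValueError, match="replications"):
            significance_flags(other, base)

    def test_paired_mode_uses_difference_series(self, tiny_problem):
        X, y = tiny_problem

        def noisy_builder(X_tr, y_tr, seed):
            return td.fit_logistic(X_tr, y_tr, seed=seed, C=0.01)

        base = replicate(X, y, noisy_builder, R=6, base_seed=0)
        better = replicate(
            X, y, lambda X_tr, y_tr, s: td.fit_logistic(X_tr, y_tr, seed=s), R=6, base_seed=0
        )
        flags = significance_flags(better, base, paired=True)
        assert set(flags.values()) <= {"ns", "*", "**"}
        with pytest.raises(ValueError, match="shared seeds"):
            significance_flags(
                better, dataclasses.replace(base, seeds=(9, 9, 9, 9, 9, 9)), paired=True
            )
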