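"""Small-sample nonparametric statistics: exact Mann-Whitney, ROC/AUC,
Youden cutoffs and confusion matrices, checked against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from cartdegen import (
    classify_three_groups,
    group_summary,
    mann_whitney_u,
    per_iteration_significance,
    roc_curve,
)


def enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p by enumerating every group labeling."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x, y):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi in x for yi in y
        )

    u_obs = u_stat(a, b)
    mid = n1 * len(b) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            count += 1
        total += 1
    return count / total


def pairwise_auc(pos, neg):
    """AUC as the fraction of (positive, negative) pairs correctly ordered."""
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        u, p = mann_whitney_u([3.0] * 5, [3.0] * 5, mode="auto")
        assert u == pytest.approx(12.5)
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        """{1,2,3} vs {4,5,6}: U = 0 wins, exact two-sided p = 2/20."""
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_exact_matches_full_enumeration_n7(self):
        """The exact p equals brute-force enumeration of all C(14,7) = 3432
        labelings on tie-free random data."""
        rng = np.random.default_rng(0)
        for _ in range(3):
            a = rng.normal(0.0, 1.0, 7)
            b = rng.normal(0.7, 1.0, 7)
            _, p = mann_whitney_u(a, b, mode="exact")
            assert p == pytest.approx(enumeration_p(a, b), abs=1e-12)

    def test_auto_switches_on_ties(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 4.0, 6.0]
        _, p_auto = mann_whitney_u(a, b, mode="auto")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p_auto == pytest.approx(float(res.pvalue))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestRocCurve:
    def _labels(self, n_neg, n_pos):
        return np.array([False] * n_neg + [True] * n_pos)

    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.9, 1.0])
        roc = roc_curve(scores, self._labels(3, 3))
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_index == pytest.approx(1.0)
        # cutoff separates the classes
        assert 0.3 < roc.youden_cutoff <= 0.8

    def test_uninformative_scores(self):
        scores = np.full(8, 2.0)
        roc = roc_curve(scores, self._labels(4, 4))
        assert roc.auc == pytest.approx(0.5)

    def test_auc_equals_pairwise_count_and_u_identity(self):
        """Trapezoidal AUC = pairwise-ordering fraction = U/(n1 n2) on
        random data with and without ties."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            neg = np.round(rng.normal(0, 1, 9), 1)  # rounding creates ties
            pos = np.round(rng.normal(0.8, 1, 7), 1)
            scores = np.concatenate([neg, pos])
            roc = roc_curve(scores, self._labels(9, 7))
            oracle = pairwise_auc(pos, neg)
            assert roc.auc == pytest.approx(oracle, abs=1e-12)
            u, _ = mann_whitney_u(pos, neg, mode="normal_approx")
            assert roc.auc * len(pos) * len(neg) == pytest.approx(u, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=12)
        labels = self._labels(6, 6)
        a1 = roc_curve(scores, labels).auc
        a2 = roc_curve(np.exp(scores), labels).auc
        a3 = roc_curve(3.0 * scores + 10.0, labels).auc
        assert a1 == pytest.approx(a2) == pytest.approx(a3)

    def test_matches_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        scores = rng.normal(size=16)
        labels = self._labels(8, 8)
        ours = roc_curve(scores, labels).auc
        ref = sklearn.roc_auc_score(labels, scores)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_youden_matches_brute_force_scan(self):
        """The Youden cutoff maximizes sens + spec - 1 over every threshold;
        among ties it takes the highest-specificity (largest) threshold."""
        rng = np.random.default_rng(4)
        neg = rng.normal(0, 1, 10)
        pos = rng.normal(1.0, 1, 8)
        scores = np.concatenate([neg, pos])
        roc = roc_curve(scores, self._labels(10, 8))
        best_j, best_thr = -np.inf, -np.inf
        for thr in np.concatenate([[scores.min() - 1], np.unique(scores), [scores.max() + 1]]):
            sens = np.mean(pos >= thr)
            spec = np.mean(neg < thr)
            j = sens + spec - 1
            if j > best_j or (j == best_j and thr > best_thr):
                best_j, best_thr = j, thr
        assert roc.youden_index == pytest.approx(best_j, abs=1e-12)
        assert roc.youden_cutoff == pytest.approx(best_thr, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.arange(4.0), np.array([True] * 4))

    def test_roc_points_monotone(self):
        rng = np.random.default_rng(5)
        roc = roc_curve(rng.normal(size=14), self._labels(7, 7))
        # thresholds ascend: sensitivity falls, specificity rises
        assert np.all(np.diff(roc.sensitivities) <= 1e-15)
        assert np.all(np.diff(roc.specificities) >= -1e-15)


class TestThreeGroupClassification:
    def test_perfectly_separated_clusters_give_diagonal(self):
        feats = [0.1, 0.2, 1.1, 1.2, 2.1, 2.2]
        labels = ["KL0", "KL0", "KL2", "KL2", "KL3", "KL3"]
        cm = classify_three_groups(feats, labels, 0.5, 1.5)
        assert np.array_equal(cm.counts, 2 * np.eye(3, dtype=int))

    def test_all_below_low_cutoff(self):
        feats = [0.0, 0.1, 0.2]
        labels = ["KL0", "KL2", "KL3"]
        cm = classify_three_groups(feats, labels, 5.0, 6.0)
        assert cm.counts[:, 0].sum() == 3 and cm.counts[:, 1:].sum() == 0

    def test_row_sums_equal_group_sizes(self):
        rng = np.random.default_rng(6)
        feats = rng.normal(size=21)
        labels = ["KL0"] * 7 + ["KL2"] * 7 + ["KL3"] * 7
        cm = classify_three_groups(feats, labels, -0.5, 0.5)
        assert np.array_equal(cm.row_sums(), [7, 7, 7])
        assert cm.counts.sum() == 21

    def test_swapped_cutoffs_normalized(self):
        feats = [0.1, 1.1, 2.1]
        labels = ["KL0", "KL2", "KL3"]
        a = classify_three_groups(feats, labels, 0.5, 1.5)
        b = classify_three_groups(feats, labels, 1.5, 0.5)
        assert np.array_equal(a.counts, b.counts)


class TestPerIterationSignificance:
    def test_identical_groups_have_p_one(self):
        traj = np.tile(np.linspace(1, 0.5, 10), (4, 1))
        p = per_iteration_significance(traj, traj.copy())
        assert np.allclose(p, 1.0)

    def test_fully_separated_n7_gives_extreme_exact_p(self):
        """Tie-free full separation at n = 7 per group pins the exact
        two-sided p at 2/3432 in every iteration."""
        rng = np.random.default_rng(7)
        n_iter = 5
        a = 1.0 + rng.uniform(0.01, 0.5, size=(7, n_iter))
        b = -rng.uniform(0.01, 0.5, size=(7, n_iter))
        p = per_iteration_significance(a, b, mode="exact")
        assert p.shape == (n_iter,)
        assert np.allclose(p, 2.0 / 3432.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            per_iteration_significance(np.ones((3, 5)), np.ones((3, 4)))


class TestGroupSummary:
    def test_mean_median(self):
        s = group_summary([1.0, 2.0, 3.0])
        assert s["mean"] == 2.0 and s["median"] == 2.0

    def test_ci_symmetric_and_matches_t_interval(self):
        x = np.array([4.1, 5.2, 6.0, 5.5, 4.8])
        s = group_summary(x)
        half = sps.t.ppf(0.975, df=4) * x.std(ddof=1) / np.sqrt(5)
        assert s["ci_low"] == pytest.approx(x.mean() - half)
        assert s["ci_high"] == pytest.approx(x.mean() + half)
        assert (s["ci_high"] - s["mean"]) == pytest.approx(s["mean"] - s["ci_low"])

    def test_single_observation_ci_undefined(self):
        s = group_summary([2.0])
        assert not s["ci_defined"]
        assert np.isnan(s["ci_low"])
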