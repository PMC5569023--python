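"""Group-separation statistics for small simulated cohorts.

Covers the nonparametric comparisons used to test whether simulated
degeneration metrics separate radiographic severity groups: Mann-Whitney
U tests (exact at the n = 7 per group scale), per-iteration significance
trajectories, ROC curves with trapezoidal AUC and an exact AUC p-value
through the identity AUC = U / (n1 n2), Youden-index cutoff selection,
and three-group confusion matrices built from two cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .results import GROUP_LABELS


def mann_whitney_u(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts pairs in which an ``a`` value exceeds
    a ``b`` value (ties count one half).  ``mode``:

    - ``"exact"``: exact permutation null (no tie correction),
    - ``"normal_approx"``: tie-corrected normal approximation,
    - ``"auto"``: exact when tie-free and both samples have at most 12
      observations, normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # every pairwise comparison ties: no evidence of separation
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        mode = "normal_approx" if has_ties or max(a.size, b.size) > 12 else "exact"
    method = {"exact": "exact", "normal_approx": "asymptotic"}[mode]
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RocAnalysis:
    """ROC curve for one pairwise group comparison on one feature."""

    feature_name: str
    group_pair: tuple[str, str]
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_p_value: float
    youden_cutoff: float
    youden_index: float


def roc_curve(
    scores,
    is_positive,
    feature_name: str = "feature",
    group_pair: tuple[str, str] = ("negative", "positive"),
) -> RocAnalysis:
    """ROC analysis with higher scores predicting the positive class.

    A subject is called positive when its score is >= the threshold.
    Thresholds sweep all distinct scores plus sentinels below the minimum
    (everything positive) and above the maximum (nothing positive).  The
    AUC is the trapezoidal area, identical to the fraction of
    (positive, negative) pairs correctly ordered with ties counting one
    half; its p-value comes from the exact Mann-Whitney null through
    AUC = U / (n1 n2).  The Youden cutoff maximizes
    sensitivity + specificity - 1, ties broken toward higher specificity
    (the larger threshold).
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if scores.shape != is_positive.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    distinct = np.unique(scores)
    lo = distinct[0] - 1.0
    hi = distinct[-1] + 1.0
    thresholds = np.concatenate([[lo], distinct, [hi]])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    pos = scores[is_positive]
    neg = scores[~is_positive]
    for i, thr in enumerate(thresholds):
        sens[i] = np.mean(pos >= thr)
        spec[i] = np.mean(neg < thr)

    # trapezoid over the (1 - specificity, sensitivity) polyline, swept from
    # the all-positive corner (1, 1) to the all-negative corner (0, 0)
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    _, p = mann_whitney_u(pos, neg, mode="auto")

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # last index = larger threshold
    return RocAnalysis(
        feature_name=feature_name,
        group_pair=group_pair,
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_p_value=p,
        youden_cutoff=float(thresholds[best]),
        youden_index=float(j[best]),
    )


@dataclass
class ConfusionMatrix:
    """True-by-predicted counts over the ordered severity groups."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def classify_three_groups(
    features,
    true_labels,
    cutoff_low: float,
    cutoff_high: float,
    labels: tuple[str, ...] = GROUP_LABELS,
) -> ConfusionMatrix:
    """Predict the severity group from a scalar feature with two cutoffs:
    below ``cutoff_low`` -> first group, in [cutoff_low, cutoff_high) ->
    middle group, at or above ``cutoff_high`` -> last group.  Cutoffs are
    swap-normalized."""
    if cutoff_low > cutoff_high:
        cutoff_low, cutoff_high = cutoff_high, cutoff_low
    features = np.asarray(features, dtype=float)
    counts = np.zeros((3, 3), dtype=int)
    idx = {lab: i for i, lab in enumerate(labels)}
    for x, lab in zip(features, true_labels):
        pred = 0 if x < cutoff_low else (1 if x < cutoff_high else 2)
        counts[idx[lab], pred] += 1
    return ConfusionMatrix(labels=tuple(labels), counts=counts)


def per_iteration_significance(
    trajectories_a: np.ndarray,
    trajectories_b: np.ndarray,
    mode: str = "auto",
) -> np.ndarray:
    """Mann-Whitney p-value at each iteration between two groups.

    ``trajectories_*`` have shape (n_subjects, n_iterations) holding one
    feature series per subject on a shared iteration grid.
    """
    a = np.atleast_2d(np.asarray(trajectories_a, dtype=float))
    b = np.atleast_2d(np.asarray(trajectories_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the iteration grid")
    return np.array(
        [mann_whitney_u(a[:, t], b[:, t], mode=mode)[1] for t in range(a.shape[1])]
    )


def group_summary(values) -> dict[str, float]:
    """Mean, median and Student-t 95% confidence interval of the mean.

    For a single observation the CI is undefined and returned as NaN with
    ``ci_defined`` False.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("group must be non-empty")
    mean = float(x.mean())
    median = float(np.median(x))
    if x.size < 2:
        return {
            "mean": mean, "median": median,
            "ci_low": float("nan"), "ci_high": float("nan"),
            "ci_defined": False,
        }
    sem = float(x.std(ddof=1) / np.sqrt(x.size))
    tcrit = float(sps.t.ppf(0.975, df=x.size - 1))
    return {
        "mean": mean, "median": median,
        "ci_low": mean - tcrit * sem, "ci_high": mean + tcrit * sem,
        "ci_defined": True,
    }
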