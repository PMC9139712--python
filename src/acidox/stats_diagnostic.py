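"""Genotype-differentiation statistics.

Two-group comparisons are normality-gated: Welch's t-test when both groups
pass Shapiro–Wilk at alpha = 0.05, Mann–Whitney U otherwise (exact
enumeration for small samples, normal approximation with tie correction for
larger ones). Tissue-type comparisons use Kruskal–Wallis with Tukey–Kramer
pairwise contrasts on rank means. ROC analysis reports AUC, the operating
cutoff (Youden's J by default), sensitivity, specificity and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "RocResult",
    "compare_two_groups",
    "compare_tissue_types",
    "roc_analysis",
]


@dataclass
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    group_summaries: list  # (n, mean, sd) per group
    pairwise: list = field(default_factory=list)  # (i, j, statistic, p) for >2 groups

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class RocResult:
    auc: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _summaries(*groups):
    return [(len(g), float(np.mean(g)), float(np.std(g, ddof=1))) for g in groups]


def compare_two_groups(
    values_a, values_b, normality_alpha: float = 0.05, test: str = "auto"
) -> GroupComparison:
    """Normality-gated two-sample comparison (two-sided).

    Welch's unequal-variance t-test when Shapiro–Wilk accepts normality for
    both groups at ``normality_alpha``; Mann–Whitney U otherwise — exact
    when both n <= 20 and there are no ties, else the normal approximation
    with tie correction. ``test`` overrides the gate ("t" or
    "mann_whitney"). Requires n >= 3 per group.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 finite values")
    if test not in ("auto", "t", "mann_whitney"):
        raise ValueError("test must be 'auto', 't' or 'mann_whitney'")

    def _normal(x):
        if np.ptp(x) == 0:
            return False  # Shapiro undefined on constant data
        return stats.shapiro(x).pvalue > normality_alpha

    use_t = test == "t" or (test == "auto" and _normal(a) and _normal(b))
    if use_t:
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), _summaries(a, b))

    has_ties = np.unique(np.concatenate([a, b])).size < len(a) + len(b)
    small = max(len(a), len(b)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        "mann_whitney", float(res.statistic), float(res.pvalue), _summaries(a, b)
    )


def compare_tissue_types(values_by_class: dict) -> GroupComparison:
    """Kruskal–Wallis across classes plus Tukey–Kramer contrasts on rank means.

    Pairwise p-values use the studentized-range distribution on the mean
    ranks of the pooled ranking, the standard nonparametric multiple-
    comparison companion to Kruskal–Wallis. Requires >= 3 classes of
    >= 3 values each.
    """
    names = list(values_by_class)
    groups = [np.asarray(values_by_class[k], float) for k in names]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 3 or any(len(g) < 3 for g in groups):
        raise ValueError("need >= 3 classes with >= 3 values each")

    h, p = stats.kruskal(*groups)
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    k = len(groups)
    # tie correction factor for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    var = n_total * (n_total + 1) / 12.0 * tie_term

    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)

    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / (se / np.sqrt(2.0))
            p_ij = float(stats.studentized_range.sf(q, k, np.inf))
            pairwise.append((names[i], names[j], float(q), p_ij))

    return GroupComparison(
        "kruskal_wallis", float(h), float(p), _summaries(*groups), pairwise
    )


def roc_analysis(
    scores,
    labels,
    positive_label,
    cutoff_criterion: str = "youden",
) -> RocResult:
    """Empirical ROC by threshold sweep; higher scores indicate the positive class.

    AUC is the trapezoidal area under the empirical curve, which equals the
    tie-corrected pairwise concordance probability. The operating cutoff is
    chosen among observed score values: the maximizer of Youden's J
    (sensitivity + specificity − 1) by default, with ties broken toward
    higher specificity; ``cutoff_criterion="accuracy"`` maximizes accuracy
    instead. A case is called positive when its score >= cutoff. Pairs with
    missing scores are dropped.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    y = labels == positive_label
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # threshold sweep over unique observed scores, descending
    uniq = np.unique(scores)[::-1]
    tpr = np.empty(uniq.size + 1)
    fpr = np.empty(uniq.size + 1)
    sens = np.empty(uniq.size)
    spec = np.empty(uniq.size)
    tpr[0] = fpr[0] = 0.0
    for i, c in enumerate(uniq):
        pred = scores >= c
        tp = int((pred & y).sum())
        fp = int((pred & ~y).sum())
        sens[i] = tp / n_pos
        spec[i] = 1.0 - fp / n_neg
        tpr[i + 1] = tp / n_pos
        fpr[i + 1] = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    if cutoff_criterion == "youden":
        objective = sens + spec - 1.0
    elif cutoff_criterion == "accuracy":
        objective = acc
    else:
        raise ValueError("cutoff_criterion must be 'youden' or 'accuracy'")
    best = objective.max()
    candidates = np.flatnonzero(np.isclose(objective, best))
    i_best = candidates[np.argmax(spec[candidates])]

    return RocResult(
        auc=auc,
        cutoff=float(uniq[i_best]),
        sensitivity_pct=100.0 * float(sens[i_best]),
        specificity_pct=100.0 * float(spec[i_best]),
        accuracy_pct=100.0 * float(acc[i_best]),
        fpr=fpr,
        tpr=tpr,
        thresholds=uniq,
    )
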