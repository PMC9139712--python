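"""Group-comparison tests and ROC analysis against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acidox.stats_diagnostic import compare_two_groups, compare_tissue_types, roc_analysis


def _auc_concordance_oracle(scores, y):
    """Pairwise concordance count (+1/2 for ties) / (n_pos * n_neg)."""
    pos = scores[y]
    neg = scores[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestCompareTwoGroups:
    def test_identical_nonnormal_samples_null(self):
        # clearly non-normal data forces the Mann-Whitney branch
        a = np.array([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 20.0, 21.0, 22.0, 23.0])
        res = compare_two_groups(a, a.copy())
        assert res.test_name == "mann_whitney"
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value > 0.95

    def test_normal_groups_use_welch_t(self, rng):
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(0.5, 1.5, 60)
        res = compare_two_groups(a, b)
        assert res.test_name == "t"

    @pytest.mark.parametrize(
        "a, b",
        [
            ([0.3, 1.7, 2.9, 5.2], [0.9, 3.4, 4.1, 6.6]),
            ([0.1, 0.2, 0.3, 9.0], [0.15, 0.25, 8.0, 10.0]),
            ([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0]),
        ],
    )
    def test_exact_mw_matches_full_enumeration(self, a, b):
        # n = (4, 4): all C(8,4) = 70 arrangements enumerated
        a, b = np.asarray(a), np.asarray(b)
        res = compare_two_groups(a, b, test="mann_whitney")
        assert res.test_name == "mann_whitney"
        pooled = np.concatenate([a, b])
        ranks = np.argsort(np.argsort(pooled)) + 1
        u_obs = max(res.statistic, 16 - res.statistic)
        count = 0
        for comb in itertools.combinations(range(8), 4):
            u = sum(ranks[list(comb)]) - 10
            if max(u, 16 - u) >= u_obs:
                count += 1
        p_oracle = count / 70.0
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_power_at_study_group_parameters(self):
        # group means/SDs 1.48 +/- 0.45 vs 1.73 +/- 0.50 at n = 70/89: a
        # modest-size check that significance is reached most of the time
        rng = np.random.default_rng(0)
        hits = 0
        reps = 50
        for _ in range(reps):
            a = rng.normal(1.48, 0.45, 70)
            b = rng.normal(1.73, 0.50, 89)
            if compare_two_groups(a, b).p_value < 0.05:
                hits += 1
        assert hits / reps >= 0.8

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_two_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareTissueTypes:
    def test_hand_computed_kruskal_wallis(self):
        # 3 classes x 3 values, no ties: H from the rank-sum formula
        data = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0], "c": [7.0, 8.0, 9.0]}
        res = compare_tissue_types(data)
        n = 9
        rank_sums = {"a": 1 + 2 + 3, "b": 4 + 5 + 6, "c": 7 + 8 + 9}
        h_oracle = 12.0 / (n * (n + 1)) * sum(r**2 / 3 for r in rank_sums.values()) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h_oracle, abs=1e-9)

    def test_identical_distributions_h_near_zero(self, rng):
        x = rng.normal(0, 1, 30)
        res = compare_tissue_types({"a": x, "b": x.copy(), "c": x.copy()})
        assert res.p_value > 0.9

    def test_single_shifted_class_flagged_pairwise(self, rng):
        base = rng.normal(0.0, 1.0, 200)
        shifted = rng.normal(2.5, 1.0, 200)
        res = compare_tissue_types(
            {"a": base, "b": base + rng.normal(0, 0.01, 200), "c": shifted}
        )
        pair_p = {frozenset((i, j)): p for i, j, _, p in res.pairwise}
        assert pair_p[frozenset(("a", "c"))] < 0.001
        assert pair_p[frozenset(("b", "c"))] < 0.001
        assert pair_p[frozenset(("a", "b"))] > 0.05

    def test_requires_three_classes(self):
        with pytest.raises(ValueError, match="3 classes"):
            compare_tissue_types({"a": [1, 2, 3], "b": [4, 5, 6]})


class TestRocAnalysis:
    def test_perfectly_separable(self):
        res = roc_analysis([0.0, 1.0, 2.0, 3.0], ["n", "n", "p", "p"], "p")
        assert res.auc == 1.0
        assert res.sensitivity_pct == 100.0 and res.specificity_pct == 100.0

    def test_all_scores_tied_gives_half(self):
        res = roc_analysis([1.0] * 10, ["n"] * 5 + ["p"] * 5, "p")
        assert res.auc == pytest.approx(0.5)

    def test_auc_equals_concordance_oracle(self, rng):
        for _ in range(25):
            scores = rng.choice(np.linspace(0, 5, 12), size=30)  # ties likely
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            labels = np.where(y, "p", "n")
            res = roc_analysis(scores, labels, "p")
            assert res.auc == pytest.approx(_auc_concordance_oracle(scores, y), abs=1e-12)

    def test_negation_identity(self, rng):
        scores = rng.normal(size=40)
        labels = np.where(rng.random(40) < 0.5, "p", "n")
        if (labels == "p").sum() in (0, 40):
            labels[0] = "p"
            labels[1] = "n"
        a1 = roc_analysis(scores, labels, "p").auc
        a2 = roc_analysis(-scores, labels, "p").auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=25)
        labels = np.where(rng.random(25) < 0.5, "p", "n")
        if (labels == "p").sum() in (0, 25):
            labels[0] = "p"
            labels[1] = "n"
        a1 = roc_analysis(scores, labels, "p").auc
        a2 = roc_analysis(np.exp(2.0 * scores), labels, "p").auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_permutation_null_centered(self, rng):
        scores = rng.normal(size=60)
        labels = np.array(["p"] * 25 + ["n"] * 35)
        aucs = []
        for _ in range(1000):
            perm = rng.permutation(labels)
            aucs.append(roc_analysis(scores, perm, "p").auc)
        assert 0.48 <= np.mean(aucs) <= 0.52

    def test_youden_cutoff_reported_metrics_consistent(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(1.2, 1, 50)])
        labels = np.array(["n"] * 50 + ["p"] * 50)
        res = roc_analysis(scores, labels, "p")
        pred = scores >= res.cutoff
        y = labels == "p"
        assert res.sensitivity_pct == pytest.approx(100.0 * (pred & y).sum() / y.sum())
        assert res.specificity_pct == pytest.approx(100.0 * (~pred & ~y).sum() / (~y).sum())
        acc = ((pred & y).sum() + (~pred & ~y).sum()) / 100
        assert res.accuracy_pct == pytest.approx(100.0 * acc)

    def test_single_class_refused(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], ["p", "p"], "p")

    def test_missing_scores_dropped(self):
        res = roc_analysis([np.nan, 1.0, 2.0, 3.0], ["p", "n", "p", "p"], "p")
        assert res.auc == 1.0
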