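"""Survival statistics: Cox partial likelihood, KM/log-rank, median split."""

import numpy as np
import pandas as pd
import pytest

from acidox import phantom
from acidox.stats_prognostic import cox_fit, km_curve, median_split, survival_table


class TestCoxFit:
    def test_toy_matches_grid_maximized_partial_likelihood(self):
        # 5 subjects, distinct event times, one binary covariate, no censoring
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.ones(5, int)
        x = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        df = pd.DataFrame({"t": time, "e": event, "x": x})
        res = cox_fit(df, "t", "e", ["x"])

        def neg_log_pl(beta):
            # written-out partial likelihood over the ordered event times
            order = np.argsort(time)
            ll = 0.0
            for i, idx in enumerate(order):
                risk = order[i:]
                ll += beta * x[idx] - np.log(np.sum(np.exp(beta * x[risk])))
            return -ll

        grid = np.linspace(-4.0, 4.0, 160001)
        beta_oracle = grid[np.argmin([neg_log_pl(b) for b in grid])]
        assert res.coef["x"] == pytest.approx(beta_oracle, abs=1e-4)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2, 3, 4], "e": [1, 1, 0, 1], "x": [2.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, "t", "e", ["x"])

    def test_missing_rows_dropped(self):
        df = pd.DataFrame(
            {"t": [1.0, 2, 3, 4, 5, 6], "e": [1, 1, 0, 1, 1, 0],
             "x": [0.1, np.nan, 0.5, 1.2, 0.7, np.nan]}
        )
        res = cox_fit(df, "t", "e", ["x"])
        assert res.n == 4

    def test_estimate_consistency_with_n(self):
        # absolute bias of the log-HR shrinks as the cohort grows
        biases = []
        for n, seed in ((100, 1), (500, 1), (2000, 1)):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(1.0 / (0.01 * np.exp(np.log(2.0) * x)))
            df = pd.DataFrame({"t": t, "e": np.ones(n, int), "x": x})
            res = cox_fit(df, "t", "e", ["x"])
            biases.append(abs(res.coef["x"] - np.log(2.0)))
        assert biases[2] < biases[0]

    def test_time_scale_invariance(self):
        rng = np.random.default_rng(7)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.02 * np.exp(0.5 * x)))
        e = (rng.random(n) < 0.8).astype(int)
        df1 = pd.DataFrame({"t": t, "e": e, "x": x})
        df2 = pd.DataFrame({"t": 365.0 * t, "e": e, "x": x})
        r1 = cox_fit(df1, "t", "e", ["x"])
        r2 = cox_fit(df2, "t", "e", ["x"])
        assert r1.hazard_ratio["x"] == pytest.approx(r2.hazard_ratio["x"], rel=1e-6)
        assert r1.p_value["x"] == pytest.approx(r2.p_value["x"], rel=1e-6)


class TestKmLogrank:
    def test_identical_groups_null(self):
        t = np.array([3.0, 5.0, 7.0, 9.0, 11.0, 13.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        time = np.concatenate([t, t])
        event = np.concatenate([e, e])
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = km_curve(time, event, groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_no_censoring_single_group_steps(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        res = km_curve(t, np.ones(4, int), np.array(["a"] * 4))
        sf = res.survival["a"]
        surv_at_events = sf.set_index("time")["survival"]
        np.testing.assert_allclose(
            [surv_at_events[v] for v in t], [0.75, 0.5, 0.25, 0.0], atol=1e-12
        )

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(10.0, 50)
        res = km_curve(t, np.ones(50, int), np.array(["a"] * 50))
        sf = res.survival["a"]
        for _, row in sf.iloc[1:].iterrows():
            emp = np.mean(t > row["time"])
            assert row["survival"] == pytest.approx(emp, abs=1e-12)

    def test_six_subject_toy_matches_hand_expanded_logrank(self):
        # two groups of 3, all events, distinct times: O, E, V expanded by hand
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, int)
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        res = km_curve(time, event, groups)

        # hand computation: at each event time, expected a-events = n_a/n
        o_a, e_a, v = 0.0, 0.0, 0.0
        n_a, n = 3.0, 6.0
        for i, g in enumerate(groups):
            if g == "a":
                o_a += 1
            e_a += n_a / n
            v += (n_a / n) * (1 - n_a / n)  # single event, no tie term
            if g == "a":
                n_a -= 1
            n -= 1
        chi2_oracle = (o_a - e_a) ** 2 / v
        assert res.chi_square == pytest.approx(chi2_oracle, abs=1e-9)

    def test_time_scale_invariance(self, rng):
        t = rng.exponential(10.0, 40)
        e = (rng.random(40) < 0.7).astype(int)
        g = np.where(rng.random(40) < 0.5, "a", "b")
        r1 = km_curve(t, e, g)
        r2 = km_curve(1000.0 * t, e, g)
        assert r1.chi_square == pytest.approx(r2.chi_square, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_array_equal(labels, ["low", "low", "high", "high"])

    def test_all_equal_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([5.0] * 6)

    def test_split_sizes_bounded_by_ties(self, rng):
        for _ in range(20):
            v = rng.choice(np.arange(10.0), size=31)
            try:
                labels = median_split(v)
            except ValueError:
                continue
            med = np.median(v)
            n_ties = int((v == med).sum())
            n_low = int((labels == "low").sum())
            n_high = int((labels == "high").sum())
            # enumeration check: low = #{<= med}, high = #{> med}; ties at
            # the median all land low, so the imbalance is at most 2*ties
            assert n_low == int((v <= med).sum())
            assert n_high == int((v > med).sum())
            assert -1 <= n_low - n_high <= 2 * n_ties + 1

    def test_missing_values_labeled(self):
        labels = median_split([1.0, np.nan, 2.0, 3.0, 4.0])
        assert labels[1] == "missing"


@pytest.fixture(scope="module")
def cohort():
    return phantom.simulate_cohort(phantom.default_cohort_spec(seed=1))


class TestSurvivalTable:
    def test_zero_effect_cohort_hrs_near_one(self):
        import dataclasses

        gd = phantom.GroupDef("mutant", 1.5, 0.4, 5.5, 1.5, 1.3, 0.5)
        spec = phantom.CohortSpec(
            n_per_group={"a": 150, "b": 150},
            group_defs={"a": gd, "b": dataclasses.replace(gd, idh="wildtype")},
            survival_os=phantom.SurvivalModel(log_hr={}, censoring_rate=0.3),
            survival_pfs=phantom.SurvivalModel(log_hr={}, censoring_rate=0.3),
            seed=2,
        )
        df = phantom.simulate_cohort(spec)
        tab = survival_table(df, endpoints=("os",), variables=["median_mtr_asym_pct"])
        row = tab[tab.variable == "median_mtr_asym_pct"].iloc[0]
        assert row.uni_ci_lo < 1.0 < row.uni_ci_hi
        assert row.uni_stars == ""

    def test_positive_hazard_feature_detected(self, cohort):
        tab = survival_table(cohort, endpoints=("os",))
        row = tab[tab.variable == "median_mtrxr2p"].iloc[0]
        assert row.uni_hr > 1.0
        assert row.multi_hr > 1.0  # effect survives clinical adjustment

    def test_missing_feature_reduces_row_n(self):
        spec = phantom.default_cohort_spec(seed=4, frac_single_echo=0.4)
        df = phantom.simulate_cohort(spec)
        tab = survival_table(df, endpoints=("os",))
        n_r2p = tab[tab.variable == "median_r2prime_s"].iloc[0].n
        n_mtr = tab[tab.variable == "median_mtr_asym_pct"].iloc[0].n
        assert n_r2p < n_mtr == len(df)

    def test_table_shape(self, cohort):
        tab = survival_table(cohort)
        assert set(tab.endpoint) == {"os", "pfs"}
        assert {"uni_hr", "uni_p", "multi_hr", "multi_p"} <= set(tab.columns)
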