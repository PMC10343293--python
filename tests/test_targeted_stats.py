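import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pkunmr.errors import InvalidParameterError, RankDeficiencyError, UndefinedRatioError
from pkunmr.targeted_stats import (
    StatsConfig,
    compare_groups,
    comparison_to_frame,
    fold_change,
    lod_filter,
    mann_whitney_u,
    standardized_regression,
)


def exact_oracle(x, y):
    """Independent brute force: full enumeration of the U distribution."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    m = n1 * len(y)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    dev = abs(u_obs - m / 2)
    us = []
    for combo in combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = float(np.mean(np.abs(us - m / 2) >= dev - 1e-9))
    return u_obs, p


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_small_exact_example(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 7), (7, 8), (8, 8)])
    def test_matches_enumeration_oracle(self, n1, n2, rng):
        for _ in range(3):
            x = rng.integers(0, 6, size=n1).astype(float)  # integers force ties
            y = rng.integers(0, 6, size=n2).astype(float)
            u, p = mann_whitney_u(x, y)
            u_ref, p_ref = exact_oracle(x, y)
            assert u == pytest.approx(u_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_sample_matches_scipy_asymptotic(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(loc=0.5, size=45)
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_values_tied_large_n(self):
        u, p = mann_whitney_u([2.0] * 20, [2.0] * 20)
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            mann_whitney_u([], [1.0])

    def test_null_rejection_rate(self):
        """Type-I error at alpha=0.05 within the binomial 99% interval."""
        rng = np.random.default_rng(12)
        reps, hits = 2000, 0
        for _ in range(reps):
            x = rng.normal(size=51)
            y = rng.normal(size=51)
            _, p = mann_whitney_u(x, y)
            hits += p < 0.05
        rate = hits / reps
        hw = 2.576 * math.sqrt(0.05 * 0.95 / reps)
        assert 0.05 - hw <= rate <= 0.05 + hw


class TestFoldChange:
    @pytest.mark.parametrize(
        "case,control,expected",
        [
            (38.8, 27.8, 1.396),
            (74.1, 93.1, 0.796),
            (282.6, 117.8, 2.399),
            (7.1, 16.2, 0.438),
        ],
    )
    def test_reference_ratios(self, case, control, expected):
        assert fold_change(case, control) == pytest.approx(expected, abs=5e-4)

    def test_equal_means(self):
        assert fold_change(4.2, 4.2) == 1.0

    def test_zero_control_rejected(self):
        with pytest.raises(UndefinedRatioError):
            fold_change(1.0, 0.0)

    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.0, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_case_mean(self, case, control, bump):
        assert fold_change(case + bump, control) >= fold_change(case, control)


class TestLodFilter:
    def test_strict_boundary(self):
        table = pd.DataFrame({
            "ten": [1.0] * 10 + [np.nan] * 10,
            "eleven": [1.0] * 11 + [np.nan] * 9,
            "none": [np.nan] * 20,
        })
        assert lod_filter(table) == ["eleven"]

    def test_exactly_98_of_149_pass(self, rng):
        """Constructed table mirroring the reference panel-reduction counts."""
        n = 102
        data = {}
        for i in range(149):
            n_present = 60 if i < 98 else 10
            col = np.full(n, np.nan)
            col[rng.choice(n, size=n_present, replace=False)] = rng.random(n_present)
            data[f"m{i}"] = col
        retained = lod_filter(pd.DataFrame(data))
        assert len(retained) == 98

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidParameterError):
            lod_filter(pd.DataFrame(index=range(5)))


def _toy_table(rng, n=30):
    idx = pd.Index([f"s{i}" for i in range(2 * n)], name="sample_id")
    labels = pd.Series(["PKU"] * n + ["control"] * n, index=idx)
    table = pd.DataFrame(
        {
            "shifted": np.concatenate([rng.normal(10, 1, n), rng.normal(2, 1, n)]),
            "null_a": rng.normal(5, 1, 2 * n),
            "null_b": rng.normal(7, 2, 2 * n),
        },
        index=idx,
    )
    return table, labels


class TestCompareGroups:
    def test_identical_groups_empty(self, rng):
        idx = pd.Index([f"s{i}" for i in range(40)])
        vals = rng.lognormal(1.0, 0.5, size=40)
        table = pd.DataFrame({"m": np.concatenate([vals[:20], vals[:20]])}, index=idx)
        labels = ["PKU"] * 20 + ["control"] * 20
        assert compare_groups(table, labels) == []

    def test_shifted_metabolite_ranked_first(self, rng):
        table, labels = _toy_table(rng)
        rows = compare_groups(table, labels)
        assert rows[0].metabolite == "shifted"
        assert rows[0].p_value < 1e-6
        assert rows[0].fold_change == pytest.approx(5.0, rel=0.3)

    def test_order_invariance(self, rng):
        table, labels = _toy_table(rng)
        perm = rng.permutation(len(table))
        rows_a = compare_groups(table, labels)
        rows_b = compare_groups(table.iloc[perm], labels.iloc[perm])
        assert [r.metabolite for r in rows_a] == [r.metabolite for r in rows_b]
        for a, b in zip(rows_a, rows_b):
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_label_swap_inverts_fold_change(self, rng):
        table, labels = _toy_table(rng)
        swapped = labels.map({"PKU": "control", "control": "PKU"})
        rows = {r.metabolite: r for r in compare_groups(table, labels, StatsConfig(alpha=0.999))}
        inv = {r.metabolite: r for r in compare_groups(table, swapped, StatsConfig(alpha=0.999))}
        for name in rows:
            assert rows[name].p_value == pytest.approx(inv[name].p_value, abs=1e-12)
            assert rows[name].fold_change == pytest.approx(1 / inv[name].fold_change)

    def test_missing_group_rejected(self, rng):
        table, _ = _toy_table(rng)
        with pytest.raises(InvalidParameterError):
            compare_groups(table, ["PKU"] * len(table))

    def test_phenylpyruvate_like_tops_ranking(self, default_panel):
        """The highest-fold-change analyte wins the ranking in >=90% of runs."""
        from pkunmr.synthetic_cohort import CohortConfig, generate_concentrations

        wins = 0
        reps = 100
        for seed in range(reps):
            table, labels = generate_concentrations(
                CohortConfig(n_case=51, n_control=51, panel=default_panel, seed=seed)
            )
            rows = compare_groups(table, labels)
            if rows and rows[0].metabolite == "Phenylpyruvic acid":
                wins += 1
        assert wins >= 90

    def test_frame_columns(self, rng):
        table, labels = _toy_table(rng)
        frame = comparison_to_frame(compare_groups(table, labels))
        assert list(frame.columns) == [
            "metabolite", "n_control", "mean_control", "sd_control",
            "n_case", "mean_case", "sd_case", "u_statistic", "p_value", "fold_change",
        ]


class TestStandardizedRegression:
    def test_identity_beta(self, rng):
        x = rng.normal(size=200)
        other = rng.normal(size=200)
        predictors = pd.DataFrame({"x": x, "other": other})
        result = standardized_regression(x, predictors)
        assert result.loc["x", "beta"] == pytest.approx(1.0, abs=1e-8)
        assert abs(result.loc["other", "beta"]) < 1e-8

    def test_parameter_recovery(self):
        """Planted standardized betas (-0.5, +0.4, 0) recovered at n=500."""
        rng = np.random.default_rng(100)
        estimates = []
        for _ in range(200):
            age = rng.uniform(0.25, 33, 500)
            prot = rng.lognormal(0, 0.5, 500)
            phe = rng.normal(600, 300, 500)
            z = lambda v: (v - v.mean()) / v.std(ddof=1)
            y = -0.5 * z(age) + 0.4 * z(prot) + rng.normal(0, math.sqrt(0.59), 500)
            res = standardized_regression(y, pd.DataFrame({"age": age, "prot": prot, "phe": phe}))
            estimates.append(res["beta"].to_numpy())
        means = np.mean(estimates, axis=0)
        np.testing.assert_allclose(means, [-0.5, 0.4, 0.0], atol=0.05)

    def test_independent_predictor_small_beta(self, rng):
        y = rng.normal(size=10000)
        x = rng.normal(size=10000)
        res = standardized_regression(y, pd.DataFrame({"x": x}))
        assert abs(res.loc["x", "beta"]) < 0.05

    def test_collinearity_named(self, rng):
        x = rng.normal(size=50)
        predictors = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        with pytest.raises(RankDeficiencyError) as err:
            standardized_regression(rng.normal(size=50), predictors)
        assert "b" in str(err.value) or "a" in str(err.value)

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            standardized_regression([1.0, 2.0], pd.DataFrame({"a": [1.0, 2.0]}))

    def test_synthetic_metadata_regression(self, default_panel):
        """Cohort generator's planted response is recovered from its records."""
        from pkunmr.synthetic_cohort import CohortConfig, generate_metadata

        config = CohortConfig(n_case=2000, n_control=2, panel=default_panel[:1], seed=13)
        records = generate_metadata(config)
        frame = pd.DataFrame(
            {
                "age": [r.age for r in records],
                "protein": [r.protein_intake for r in records],
                "phe": [r.phe_serum for r in records],
            }
        )
        y = [r.response for r in records]
        res = standardized_regression(y, frame)
        assert res.loc["age", "beta"] == pytest.approx(-0.5, abs=0.06)
        assert res.loc["protein", "beta"] == pytest.approx(0.4, abs=0.06)
        assert abs(res.loc["phe", "beta"]) < 0.08
        assert res.loc["age", "p_value"] < 1e-6


class TestStatsConfig:
    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            StatsConfig(alpha=0.0)
        with pytest.raises(InvalidParameterError):
            StatsConfig(min_values=-1)
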