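"""Differential statistics: filtering, imputation, s0 test, permutation FDR,
rank tests, correlations, separation summary."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import build_log2_matrix
from pepmarker.diffstats import (
    DiffParams,
    impute_gaussian,
    kruskal_dunn,
    permutation_fdr,
    prepare_matrix,
    s0_t_test,
    separation_summary,
    spearman_matrix,
    wilcoxon_rank_sum,
)
from pepmarker.io import DataError, QuantMatrix


def _quant(data):
    return QuantMatrix(pd.DataFrame(data), "stdpep", ())


class TestPrepareMatrix:
    def _matrix(self, present_con, present_als, n=24):
        cols = [f"Con_{i}" for i in range(n)] + [f"ALS_{i}" for i in range(n)]
        row = [10.0 if i < present_con else np.nan for i in range(n)] + [
            10.0 if i < present_als else np.nan for i in range(n)
        ]
        data = pd.DataFrame([row], index=["pep"], columns=cols)
        labels = {c: ("Con" if c.startswith("Con") else "ALS") for c in cols}
        return QuantMatrix(data, "stdpep", ()), labels

    def test_70_percent_bound_is_inclusive(self):
        # 17/24 = 70.8% of controls, absent in ALS -> retained by any-group
        m, labels = self._matrix(17, 0)
        params = DiffParams(presence_policy="in_70pct_any_group")
        logged, _, _ = prepare_matrix(m, labels, params)
        assert list(logged.index) == ["pep"]

    @pytest.mark.parametrize(
        "policy", ["in_70pct_each_group", "in_70pct_any_group", "in_70pct_all"]
    )
    def test_below_70_percent_in_both_groups_dropped(self, policy):
        m, labels = self._matrix(16, 16)  # 66.7% in each group
        params = DiffParams(presence_policy=policy)
        logged, _, report = prepare_matrix(m, labels, params)
        assert len(logged) == 0
        assert report["dropped_presence"] == 1

    def test_quality_threshold_is_inclusive_at_five(self):
        m, labels = self._matrix(24, 24)
        params = DiffParams()
        kept, _, _ = prepare_matrix(m, labels, params, quality={"pep": 5.0})
        dropped, _, _ = prepare_matrix(m, labels, params, quality={"pep": 4.9})
        assert list(kept.index) == ["pep"] and len(dropped) == 0

    def test_min3_policies_do_not_require_70_percent(self):
        m, labels = self._matrix(3, 3)
        params = DiffParams(presence_policy="min3_each_group")
        logged, _, _ = prepare_matrix(m, labels, params)
        assert list(logged.index) == ["pep"]

    def test_output_is_log2(self):
        m, labels = self._matrix(24, 24)
        logged, _, _ = prepare_matrix(m, labels, DiffParams())
        assert logged.loc["pep"].dropna().iloc[0] == pytest.approx(np.log2(10))


class TestImputation:
    def test_complete_matrix_unchanged(self):
        df, _ = build_log2_matrix(20, 5, 5, seed=3)
        out = impute_gaussian(df, DiffParams(seed=1))
        pd.testing.assert_frame_equal(out, df)

    def test_deterministic_given_seed(self):
        df, _ = build_log2_matrix(50, 6, 6, seed=4)
        df = df.mask(np.random.default_rng(0).random(df.shape) < 0.2)
        a = impute_gaussian(df, DiffParams(seed=9))
        b = impute_gaussian(df, DiffParams(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_observed_entries_bit_identical(self):
        df, _ = build_log2_matrix(50, 6, 6, seed=5)
        masked = df.mask(np.random.default_rng(1).random(df.shape) < 0.3)
        out = impute_gaussian(masked, DiffParams(seed=2))
        obs = ~masked.isna()
        assert (out.to_numpy()[obs.to_numpy()]
                == masked.to_numpy()[obs.to_numpy()]).all()

    def test_imputed_values_center_on_downshifted_mean(self):
        """Monte Carlo: empirical mean of imputed draws ~ mean - 1.8 sd."""
        rng = np.random.default_rng(6)
        n = 20_000
        col = pd.Series(rng.normal(20.0, 1.0, size=n))
        col.iloc[: n // 2] = np.nan
        df = pd.DataFrame({"s1": col})
        params = DiffParams(impute_width=0.3, impute_downshift=1.8, seed=3)
        out = impute_gaussian(df, params)
        observed = col.dropna()
        target = observed.mean() - 1.8 * observed.std(ddof=1)
        imputed = out["s1"][col.isna()]
        assert abs(imputed.mean() - target) < 0.05
        assert imputed.std(ddof=1) == pytest.approx(
            0.3 * observed.std(ddof=1), rel=0.1
        )


class TestS0Statistic:
    def test_equal_means_give_zero(self):
        _, stat = s0_t_test([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=0.1)
        assert stat == 0.0

    def test_s0_zero_reduces_to_student_t(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.normal(0, 1, size=rng.integers(3, 12))
            b = rng.normal(0.5, 2, size=rng.integers(3, 12))
            _, stat = s0_t_test(a, b, s0=0.0)
            ref = stats.ttest_ind(a, b, equal_var=True).statistic
            assert stat == pytest.approx(ref, abs=1e-10)

    def test_hand_computed_example(self):
        # a=(1,2,3), b=(3,4,5): diff=-2, pooled var=1, se=sqrt(2/3)=0.8165
        diff, stat = s0_t_test([1, 2, 3], [3, 4, 5], s0=0.1)
        assert diff == pytest.approx(-2.0)
        assert stat == pytest.approx(-2.1822, abs=1e-4)

    def test_statistic_magnitude_nonincreasing_in_s0(self):
        rng = np.random.default_rng(8)
        a = rng.normal(1, 1, 10)
        b = rng.normal(0, 1, 10)
        mags = [abs(s0_t_test(a, b, s0=s)[1]) for s in (0.0, 0.1, 0.5, 1.0, 5.0)]
        assert all(x >= y for x, y in zip(mags, mags[1:]))

    def test_degenerate_variance_with_zero_s0_rejected(self):
        with pytest.raises(DataError):
            s0_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], s0=0.0)


class TestPermutationFDR:
    def test_deterministic_given_seed(self):
        df, labels = build_log2_matrix(80, 8, 8, seed=10,
                                       effects={0: 2.0})
        params = DiffParams(seed=42, n_permutations=100)
        r1 = permutation_fdr(df, labels, params)
        r2 = permutation_fdr(df, labels, params)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_q_values_monotone_in_statistic_magnitude(self):
        df, labels = build_log2_matrix(120, 10, 10, seed=11,
                                       effects={0: 1.5, 1: 0.8})
        res = permutation_fdr(df, labels, DiffParams(seed=1))
        t = res.table.reindex(
            res.table["statistic"].abs().sort_values(ascending=False).index
        )
        q = t["q_value"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_small_design_falls_back_to_full_enumeration(self):
        df, labels = build_log2_matrix(30, 3, 3, seed=12)
        res = permutation_fdr(df, labels, DiffParams(n_permutations=250))
        assert res.n_permutations_used == 20  # C(6,3)

    def test_strong_effect_detected_among_nulls(self):
        detected = 0
        for rep in range(5):
            df, labels = build_log2_matrix(
                500, 24, 24, cv=0.2, seed=100 + rep, effects={7: 2.0}
            )
            res = permutation_fdr(df, labels,
                                  DiffParams(seed=rep, n_permutations=250))
            detected += bool(res.table.iloc[7]["significant"])
        assert detected == 5

    def test_direction_matches_difference_sign(self):
        df, labels = build_log2_matrix(
            100, 12, 12, seed=13, effects={0: 2.0, 1: -2.0}
        )
        res = permutation_fdr(df, labels, DiffParams(seed=5))
        assert res.table.iloc[0]["direction"] == "up"
        assert res.table.iloc[1]["direction"] == "down"
        ns = res.table[~res.table["significant"]]
        assert (ns["direction"] == "ns").all()

    def test_incomplete_matrix_rejected(self):
        df, labels = build_log2_matrix(10, 4, 4, seed=14)
        df.iloc[0, 0] = np.nan
        with pytest.raises(DataError):
            permutation_fdr(df, labels, DiffParams())


class TestRankTests:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) > 0.6
        assert wilcoxon_rank_sum([5, 5, 5], [5, 5, 5]) == 1.0

    def test_kruskal_on_two_groups_agrees_with_wilcoxon(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 20)
        p_kw, _ = kruskal_dunn({"a": a, "b": b})
        p_w = wilcoxon_rank_sum(a, b)
        assert p_kw == pytest.approx(p_w, abs=0.01)

    def test_dunn_pairwise_matches_brute_force_rank_arithmetic(self):
        groups = {
            "g1": [1.0, 3.0, 5.0, 7.0, 9.0],
            "g2": [2.0, 4.0, 6.0, 8.0, 10.0],
            "g3": [11.0, 12.0, 13.0, 14.0, 2.0],
        }
        _, pairs = kruskal_dunn(groups)
        # independent oracle: explicit rank arithmetic
        pooled = np.concatenate([groups[g] for g in ("g1", "g2", "g3")])
        order = np.argsort(pooled, kind="stable")
        ranks = np.empty_like(pooled)
        # mid-ranks for ties, computed by hand-rolled pass
        sorted_vals = pooled[order]
        i = 0
        while i < len(sorted_vals):
            j = i
            while j < len(sorted_vals) and sorted_vals[j] == sorted_vals[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        N = len(pooled)
        mean_ranks = {
            "g1": ranks[0:5].mean(), "g2": ranks[5:10].mean(),
            "g3": ranks[10:15].mean(),
        }
        _, counts = np.unique(pooled, return_counts=True)
        tie = np.sum(counts**3 - counts) / (12 * (N - 1))
        var = N * (N + 1) / 12 - tie
        for row in pairs.itertuples():
            z_oracle = (mean_ranks[row.group_1] - mean_ranks[row.group_2]) / (
                np.sqrt(var * (1 / 5 + 1 / 5))
            )
            assert row.z == pytest.approx(z_oracle, abs=1e-12)
            assert row.p == pytest.approx(
                2 * stats.norm.sf(abs(z_oracle)), abs=1e-12
            )

    def test_holm_adjustment_is_monotone_and_bounded(self):
        rng = np.random.default_rng(16)
        groups = {g: rng.normal(i, 1, 8) for i, g in enumerate("abc")}
        _, pairs = kruskal_dunn(groups)
        assert (pairs["p_adjusted"] >= pairs["p"] - 1e-15).all()
        assert (pairs["p_adjusted"] <= 1.0).all()

    def test_tiny_group_rejected(self):
        with pytest.raises(DataError):
            kruskal_dunn({"a": [1.0], "b": [1.0, 2.0]})


class TestSpearman:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.linspace(0, 5, 12)
        df = pd.DataFrame({"x": x, "y": np.exp(x), "z": -x})
        r, _ = spearman_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)
        assert (np.diag(r) == 1.0).all()

    def test_matches_brute_force_rank_formula_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 6.0, 8.0, 9.0, 9.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 5.0, 7.0, 7.0, 6.0, 9.0, 10.0])
        df = pd.DataFrame({"x": x, "y": y})
        r, _ = spearman_matrix(df)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]  # Pearson on mid-ranks
        assert r.loc["x", "y"] == pytest.approx(oracle, abs=1e-12)

    def test_pairwise_complete_and_minimum_pairs(self):
        df = pd.DataFrame(
            {"x": [1.0, 2.0, np.nan, np.nan], "y": [1.0, 2.0, 3.0, 4.0]}
        )
        r, p = spearman_matrix(df)
        assert np.isnan(r.loc["x", "y"]) and np.isnan(p.loc["x", "y"])


class TestSeparation:
    def test_well_separated_groups_are_fully_specific(self):
        rng = np.random.default_rng(17)
        n_pep, n = 10, 12
        a = rng.normal(0, 1, size=(n_pep, n))
        b = rng.normal(8, 1, size=(n_pep, n))  # 8-sd separation
        df = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"p{i}" for i in range(n_pep)],
            columns=[f"Con_{i}" for i in range(n)] + [f"ALS_{i}" for i in range(n)],
        )
        labels = {c: c.split("_")[0] for c in df.columns}
        out = separation_summary(df, labels)
        assert out["specificity_percent"] == 100.0
        assert out["explained_variance_fraction"][0] > 0.5

    def test_permuted_labels_give_chance_specificity_on_average(self):
        rng = np.random.default_rng(18)
        specs = []
        for rep in range(20):
            df = pd.DataFrame(
                rng.normal(0, 1, size=(8, 20)),
                index=[f"p{i}" for i in range(8)],
                columns=[f"s{i}" for i in range(20)],
            )
            groups = np.array(["Con"] * 10 + ["ALS"] * 10)
            rng.shuffle(groups)
            labels = dict(zip(df.columns, groups))
            specs.append(separation_summary(df, labels)["specificity_percent"])
        assert 30.0 <= float(np.mean(specs)) <= 70.0

    def test_duplicated_sample_coclusters_with_its_twin(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame(
            rng.normal(0, 1, size=(6, 8)),
            index=[f"p{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(8)],
        )
        df["dup"] = df["s0"]
        labels = {c: ("Con" if i < 4 else "ALS")
                  for i, c in enumerate(df.columns)}
        out = separation_summary(df, labels)
        assert (out["cluster_assignments"]["dup"]
                == out["cluster_assignments"]["s0"])

    def test_single_peptide_rejected(self):
        df = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["p"],
                          columns=["a", "b", "c", "d"])
        labels = {"a": "Con", "b": "Con", "c": "ALS", "d": "ALS"}
        with pytest.raises(DataError):
            separation_summary(df, labels)
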