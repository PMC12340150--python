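"""PRM quantification, group statistics, ROC, external correlation."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepmarker.io import DataError, SampleAnnotation
from pepmarker.prm import (
    PRMResult,
    _auc_mann_whitney,
    correlate_external,
    flag_interference,
    group_stats,
    quantify_prm,
    roc_combined,
    roc_single,
)
from pepmarker.sim import PanelEntry, PRMSimConfig, simulate_prm


def _report(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "peptide_id", "transition", "channel",
                       "rt_min", "area"]
    )


class TestQuantify:
    def _toy(self, light=(100.0, 80.0, 60.0), heavy=(100.0, 80.0, 60.0)):
        rows = []
        for i, (l, h) in enumerate(zip(light, heavy)):
            rows.append(("S1", "NFL", f"y{i}", "light", 20.0, l))
            rows.append(("S1", "NFL", f"y{i}", "heavy", 20.0, h))
        return _report(rows)

    def test_equal_channels_give_unit_ratio(self):
        res = quantify_prm(self._toy(), ["NFL"])
        assert res.ratios.loc["S1", "NFL"] == pytest.approx(1.0)

    def test_interference_exclusion_is_symmetric(self):
        rep = self._toy(light=(100.0, 80.0, 600.0), heavy=(100.0, 80.0, 60.0))
        res = quantify_prm(rep, ["NFL"], exclude_transitions={"NFL": ["y2"]})
        # remaining transitions: light (100+80) / heavy (100+80)
        assert res.ratios.loc["S1", "NFL"] == pytest.approx(1.0)
        assert res.excluded_transitions["NFL"] == ("y2",)

    def test_no_light_signal_is_missing_with_reason(self):
        rows = [("S1", "NFL", f"y{i}", "heavy", 20.0, 100.0) for i in range(3)]
        res = quantify_prm(_report(rows), ["NFL"])
        assert np.isnan(res.ratios.loc["S1", "NFL"])
        assert res.missing_reason.loc["S1", "NFL"] == "no peak"

    def test_missing_heavy_standard_is_an_assay_failure(self):
        rows = [("S1", "NFL", f"y{i}", "light", 20.0, 100.0) for i in range(3)]
        with pytest.raises(DataError, match="heavy"):
            quantify_prm(_report(rows), ["NFL"])

    def test_invariant_to_transition_order_and_common_scale(self):
        rep = self._toy(light=(90.0, 50.0, 20.0))
        base = quantify_prm(rep, ["NFL"]).ratios.loc["S1", "NFL"]
        shuffled = rep.iloc[::-1].reset_index(drop=True)
        assert quantify_prm(shuffled, ["NFL"]).ratios.loc["S1", "NFL"] == base
        scaled = rep.copy()
        scaled["area"] *= 7.5  # both channels scaled together
        assert quantify_prm(scaled, ["NFL"]).ratios.loc["S1", "NFL"] == (
            pytest.approx(base)
        )

    def test_simulated_interference_flagged_and_recovered(self):
        panel = [PanelEntry("NFL", "NFL", tuple(f"y{i}" for i in range(8)), 20.0)]
        ann = [SampleAnnotation(f"S{i}", "Con") for i in range(12)]
        cfg = PRMSimConfig(interference=(("NFL", "y2", 4.0),))
        rep = simulate_prm(panel, ann, cfg, 7)
        flagged = flag_interference(rep)
        assert flagged.get("NFL") == ("y2",)


class TestGroupStats:
    def _result(self, seed=0, folds=None):
        folds = folds or {}
        panel = [
            PanelEntry(p, p, tuple(f"y{i}" for i in range(5)), 10.0 + k)
            for k, p in enumerate(folds)
        ]
        ann = [SampleAnnotation(f"ALS_{i}", "ALS") for i in range(44)] + [
            SampleAnnotation(f"Con_{i}", "Con") for i in range(42)
        ]
        cfg = PRMSimConfig(fold_by_group={p: {"ALS": f} for p, f in folds.items()})
        rep = simulate_prm(panel, ann, cfg, seed)
        return quantify_prm(rep, list(folds)), ann

    def test_planted_direction_signs_recovered(self):
        folds = {"u1": 2.0, "u2": 2.0, "u3": 2.0, "u4": 2.0,
                 "d1": 0.5, "d2": 0.5, "d3": 0.5}
        res, ann = self._result(seed=3, folds=folds)
        table = group_stats(res, ann)
        for pep, fold in folds.items():
            want = "up" if fold > 1 else "down"
            assert table.loc[pep, "direction"] == want
            assert table.loc[pep, "p"] < 0.05

    def test_identical_groups_give_large_p(self):
        ratios = pd.DataFrame(
            {"pep": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
            index=[f"s{i}" for i in range(6)],
        )
        res = PRMResult(ratios, pd.DataFrame("", index=ratios.index, columns=ratios.columns))
        ann = [SampleAnnotation(f"s{i}", "ALS" if i < 3 else "Con")
               for i in range(6)]
        table = group_stats(res, ann)
        assert table.loc["pep", "p"] > 0.5

    def test_single_member_group_is_flagged_not_tested(self):
        ratios = pd.DataFrame(
            {"pep": [1.0, 2.0, 3.0, np.nan, np.nan, 4.0]},
            index=[f"s{i}" for i in range(6)],
        )
        res = PRMResult(ratios, pd.DataFrame("", index=ratios.index, columns=ratios.columns))
        ann = [SampleAnnotation(f"s{i}", "ALS" if i < 3 else "Con")
               for i in range(6)]
        table = group_stats(res, ann)
        assert table.loc["pep", "direction"] == "untested"
        assert np.isnan(table.loc["pep", "p"])

    def test_three_groups_use_kruskal_dunn(self):
        rng = np.random.default_rng(9)
        idx = [f"s{i}" for i in range(30)]
        ratios = pd.DataFrame({"pep": rng.lognormal(0, 0.3, 30)}, index=idx)
        ann = [SampleAnnotation(s, g) for s, g in zip(
            idx, ["Con"] * 10 + ["sALS"] * 10 + ["gALS"] * 10)]
        res = PRMResult(ratios, pd.DataFrame("", index=ratios.index, columns=ratios.columns))
        table = group_stats(res, ann)
        assert "pairwise_p_adjusted" in table.columns
        assert len(table.loc["pep", "pairwise_p_adjusted"]) == 3


class TestROCSingle:
    def test_perfect_separation_gives_unit_auc(self):
        v = [1, 2, 3, 10, 11, 12]
        y = [0, 0, 0, 1, 1, 1]
        res = roc_single(v, y)
        assert res.auc == 1.0

    def test_negated_scores_same_auc_flipped_orientation(self):
        rng = np.random.default_rng(22)
        v = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        y = np.array([0] * 30 + [1] * 30)
        a = roc_single(v, y)
        b = roc_single(-v, y)
        assert a.auc == pytest.approx(b.auc)
        assert a.orientation == -b.orientation

    def test_null_scores_give_chance_auc(self):
        rng = np.random.default_rng(23)
        v = rng.normal(0, 1, 500)
        y = np.array([0, 1] * 250)
        res = roc_single(v, y)
        assert 0.45 <= res.auc <= 0.55
        assert res.ci_low < 0.5 < res.ci_high

    def test_auc_equals_pair_counting_on_all_small_arrangements(self):
        """Mann-Whitney identity vs brute-force pair counting, n = 2..6."""
        rng = np.random.default_rng(24)
        for n in range(2, 7):
            values = np.round(rng.normal(0, 1, n), 1)  # rounding makes ties
            for pattern in product([0, 1], repeat=n):
                y = np.array(pattern)
                if y.sum() == 0 or y.sum() == n:
                    continue
                pos = values[y == 1]
                neg = values[y == 0]
                wins = sum(
                    1.0 if p > q else (0.5 if p == q else 0.0)
                    for p in pos for q in neg
                )
                brute = wins / (len(pos) * len(neg))
                assert _auc_mann_whitney(values, y) == pytest.approx(
                    brute, abs=1e-12
                )

    def test_one_class_input_rejected(self):
        with pytest.raises(DataError):
            roc_single([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])


class TestROCCombined:
    def _panel_data(self, seed, n=60, d1=1.19, d2=1.19):
        rng = np.random.default_rng(seed)
        y = np.array([0] * n + [1] * n)
        x1 = rng.normal(0, 1, 2 * n) + d1 * y
        x2 = rng.normal(0, 1, 2 * n) + d2 * y
        df = pd.DataFrame({"p1": x1, "p2": x2},
                          index=[f"s{i}" for i in range(2 * n)])
        return df, dict(zip(df.index, y))

    def test_single_peptide_panel_reduces_to_that_auc(self):
        df, labels = self._panel_data(25)
        model = roc_combined(df[["p1"]], labels)
        single = roc_single(df["p1"], [labels[s] for s in df.index])
        assert model.combined_auc.auc == pytest.approx(single.auc, abs=1e-12)

    def test_two_informative_peptides_combine_better_than_each(self):
        wins = 0
        for rep in range(10):
            df, labels = self._panel_data(300 + rep)
            model = roc_combined(df, labels)
            best_single = max(r.auc for r in model.per_peptide_auc.values())
            wins += model.combined_auc.auc > best_single
        assert wins >= 9

    def test_separable_data_converges_via_ridge_with_unit_auc(self):
        df = pd.DataFrame(
            {"p1": np.r_[np.zeros(10), np.ones(10) * 5]},
            index=[f"s{i}" for i in range(20)],
        )
        labels = {f"s{i}": int(i >= 10) for i in range(20)}
        model = roc_combined(df, labels)
        assert model.combined_auc.auc == 1.0
        assert model.ridge_used

    def test_excess_missingness_rejected(self):
        df, labels = self._panel_data(26)
        df.loc[df.index[:50], "p2"] = np.nan
        with pytest.raises(DataError, match="missing"):
            roc_combined(df, labels)

    def test_listwise_deletion_reported(self):
        df, labels = self._panel_data(27)
        df.loc[df.index[0], "p1"] = np.nan
        model = roc_combined(df, labels)
        assert model.dropped_samples == (df.index[0],)
        assert model.n_samples_used == len(df) - 1

    def test_generating_coefficient_signs_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            n = 109  # validation-cohort scale
            y = (rng.random(n) < 0.6).astype(int)
            x_up = rng.normal(0, 1, n) + 1.0 * y
            x_dn = rng.normal(0, 1, n) - 1.0 * y
            df = pd.DataFrame({"up": x_up, "dn": x_dn},
                              index=[f"s{i}" for i in range(n)])
            model = roc_combined(df, dict(zip(df.index, y)))
            hits += (model.coefficients["up"] > 0
                     and model.coefficients["dn"] < 0)
        assert hits >= 9


class TestExternalCorrelation:
    def test_monotone_transform_gives_unit_r(self):
        x = pd.Series(np.linspace(1, 10, 20))
        r, p, pairs = correlate_external(x, np.exp(x))
        assert r == pytest.approx(1.0)
        assert len(pairs) == 20

    def test_shared_signal_with_noise_correlates_strongly(self):
        rng = np.random.default_rng(28)
        signal = rng.lognormal(0, 1, 100)
        a = pd.Series(signal * rng.lognormal(0, 0.1, 100))
        b = pd.Series(signal * rng.lognormal(0, 0.1, 100))
        r, _, _ = correlate_external(a, b)
        assert r > 0.9

    def test_unrelated_values_weakly_correlated(self):
        rng = np.random.default_rng(29)
        a = pd.Series(rng.normal(0, 1, 100))
        b = pd.Series(rng.normal(0, 1, 100))
        r, _, _ = correlate_external(a, b)
        assert abs(r) < 0.25

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DataError):
            correlate_external(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))
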