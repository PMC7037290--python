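"""Differential-expression calling: the t-test, BH adjustment and the signed
call rules, checked against independent closed-form oracles."""

import numpy as np
import pytest

from diseasome_kit import (
    PanelScenario,
    bh_adjust,
    call_degs,
    generate_expression_study,
    two_group_ttest,
)
from diseasome_kit.deg import top_by_magnitude
from oracles import bh_stepup, welch_ttest

from diseasome_kit import ExpressionStudy


class TestTwoGroupTtest:
    def test_identical_groups_are_vacuous(self):
        t, p = two_group_ttest([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0) or (abs(t) < 1e-12 and abs(p - 1) < 1e-12)

    def test_matches_textbook_welch_computation(self):
        # frozen from the hand Welch formula with Satterthwaite df
        t, p = two_group_ttest([3.1, 2.9, 3.0, 3.2], [1.0, 1.1, 0.9, 1.0])
        assert abs(t - 26.84080049902704) < 1e-10
        assert abs(p - 1.1632113951563287e-06) < 1e-16

    def test_two_sided_symmetry(self):
        case, control = [1.0, 2.0, 4.0], [5.0, 6.0, 9.0]
        t1, p1 = two_group_ttest(case, control)
        t2, p2 = two_group_ttest(control, case)
        assert t1 == -t2 and abs(p1 - p2) < 1e-15

    def test_both_groups_constant_equal_means_vacuous(self):
        assert two_group_ttest([2, 2, 2], [2, 2, 2]) == (0.0, 1.0)

    def test_both_groups_constant_unequal_means_degenerate(self):
        t, p = two_group_ttest([2, 2, 2], [3, 3, 3])
        assert np.isnan(t) and np.isnan(p)

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            two_group_ttest([1.0], [1.0, 2.0])

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(2, 9, size=2)
            case = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), n1)
            control = rng.normal(0, 1, n2)
            t, p = two_group_ttest(case, control)
            t_ref, p_ref = welch_ttest(case.tolist(), control.tolist())
            assert abs(t - t_ref) < 1e-10
            assert abs(p - p_ref) < 1e-10


class TestBhAdjust:
    def test_stepup_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_stepup_enumeration_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_stepup(p.tolist()), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 50)
        assert np.all(bh_adjust(p) >= p - 1e-15)


def tiny_study(rows, genes):
    values = np.asarray(rows, dtype=float)
    n = values.shape[1] // 2
    return ExpressionStudy(
        "D", genes, [f"s{i}" for i in range(values.shape[1])], values,
        ["case"] * n + ["control"] * n,
    )


class TestCallDegs:
    def test_call_rules_and_strict_boundaries(self):
        # rows engineered for tiny p: near-zero within-group noise
        eps = 1e-3
        rows = [
            [1.5 + eps, 1.5 - eps, 1.5, 0.0 + eps, 0.0 - eps, 0.0],   # up
            [-1.2 + eps, -1.2 - eps, -1.2, 0.0 + eps, 0.0 - eps, 0.0],  # down
            [1.0 + eps, 1.0 - eps, 1.0, 0.0 + eps, 0.0 - eps, 0.0],   # boundary
            [0.0 + eps, 0.0 - eps, 0.0, 0.0 + 2 * eps, 0.0, 0.0 - eps],  # null
        ]
        table, gset = call_degs(tiny_study(rows, ["UP1", "DN1", "EDGE", "NULL"]))
        calls = dict(zip(table["symbol"], table["call"]))
        assert calls["UP1"] == "up"
        assert calls["DN1"] == "down"
        assert calls["EDGE"] == "neutral"  # logFC exactly 1.0: strict cut
        assert calls["NULL"] == "neutral"
        assert gset.up == {"UP1"} and gset.down == {"DN1"}

    def test_large_fold_change_without_significance_is_neutral(self):
        rows = [[4.0, 0.1, 2.0, 0.2, 0.1, 0.3]]  # huge logFC, noisy p
        table, _ = call_degs(tiny_study(rows, ["A"]))
        assert table["call"].iloc[0] == "neutral"

    def test_degenerate_rows_never_called(self):
        rows = [[2.0, 2.0, 2.0, 3.0, 3.0, 3.0]]
        table, gset = call_degs(tiny_study(rows, ["A"]))
        assert table["call"].iloc[0] == "degenerate"
        assert not gset.up and not gset.down

    def test_adjusted_mode_is_more_conservative(self):
        scenario = PanelScenario(n_genes=800, diseases=("T2D",), n_case=5,
                                 n_control=5, de_fraction=0.05,
                                 effect_size=1.6, noise_sd=0.7, seed=5)
        study, _ = generate_expression_study(scenario, "T2D")
        _t_raw, raw = call_degs(study, p_mode="raw", alpha=0.01)
        _t_adj, adj = call_degs(study, p_mode="adjusted", alpha=0.01)
        assert adj.up <= raw.up and adj.down <= raw.down

    def test_planted_truth_recovered_in_high_power_regime(self):
        scenario = PanelScenario(n_genes=600, diseases=("T2D",), n_case=12,
                                 n_control=12, de_fraction=0.05,
                                 effect_size=4.0, noise_sd=0.25, seed=3)
        study, truth = generate_expression_study(scenario, "T2D")
        _table, called = call_degs(study)
        assert called.up == truth.up and called.down == truth.down

    def test_top_by_magnitude_ranks_called_genes(self):
        eps = 1e-3
        rows = [
            [3.0 + eps, 3.0 - eps, 3.0, 0.0 + eps, 0.0 - eps, 0.0],
            [1.5 + eps, 1.5 - eps, 1.5, 0.0 + eps, 0.0 - eps, 0.0],
        ]
        table, _ = call_degs(tiny_study(rows, ["BIG", "SMALL"]))
        top = top_by_magnitude(table, 1)
        assert top["symbol"].tolist() == ["BIG"]


class TestCalibration:
    def test_null_panel_raw_p_fraction_near_alpha(self):
        # de_fraction 0: raw p < 0.01 should occur at ~1% of genes
        fractions = []
        for seed in range(5):
            scenario = PanelScenario(n_genes=2000, diseases=("T2D",),
                                     n_case=10, n_control=10,
                                     de_fraction=0.0, seed=seed)
            study, _ = generate_expression_study(scenario, "T2D")
            table, _ = call_degs(study)
            fractions.append((table["p"] < 0.01).mean())
        mean_frac = np.mean(fractions)
        se = np.sqrt(0.01 * 0.99 / (2000 * 5))
        assert abs(mean_frac - 0.01) < 3 * se

    def test_recall_monotone_in_effect_size(self):
        recalls = []
        for effect in (0.5, 1.5, 3.0):
            scenario = PanelScenario(n_genes=500, diseases=("T2D",),
                                     n_case=6, n_control=6, de_fraction=0.1,
                                     effect_size=effect, noise_sd=0.7, seed=13)
            study, truth = generate_expression_study(scenario, "T2D")
            _t, called = call_degs(study)
            planted = truth.up | truth.down
            found = (called.up | called.down) & planted
            recalls.append(len(found) / len(planted))
        assert recalls == sorted(recalls)
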