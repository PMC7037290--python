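"""The generators honour their planted-truth contracts exactly."""

import numpy as np
import pytest

from diseasome_kit import (
    PanelScenario,
    generate_expression_study,
    generate_gmt_library,
    generate_interaction_table,
    generate_panel,
)
from diseasome_kit.synthetic import plan_truth


def scenario(**kw) -> PanelScenario:
    base = dict(n_genes=1000, diseases=("T2D", "MS"), n_case=4, n_control=4,
                de_fraction=0.05, seed=3)
    base.update(kw)
    return PanelScenario(**base)


class TestExpressionStudies:
    def test_planted_de_count_forced_by_parameters(self):
        _study, gset = generate_expression_study(scenario(), "T2D")
        assert len(gset.up) + len(gset.down) == 50

    def test_zero_effect_keeps_truth_but_identical_distributions(self):
        s = scenario(effect_size=0.0, seed=9)
        study, gset = generate_expression_study(s, "T2D")
        assert len(gset.up) + len(gset.down) == 50
        # with no shift, case and control columns come from one distribution
        case = study.values[:, study.group_columns("case")]
        ctrl = study.values[:, study.group_columns("control")]
        assert abs(case.mean() - ctrl.mean()) < 0.05

    def test_same_seed_gives_byte_identical_matrices(self):
        a, _ = generate_expression_study(scenario(seed=7), "MS")
        b, _ = generate_expression_study(scenario(seed=7), "MS")
        assert a.values.tobytes() == b.values.tobytes()
        assert a.gene_ids == b.gene_ids

    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            scenario(n_case=1)

    def test_planted_shift_appears_in_group_means(self):
        s = scenario(effect_size=2.0, noise_sd=0.3, n_case=10, n_control=10)
        study, gset = generate_expression_study(s, "T2D")
        idx = {g: i for i, g in enumerate(study.gene_ids)}
        case = study.values[:, study.group_columns("case")]
        ctrl = study.values[:, study.group_columns("control")]
        diff = case.mean(axis=1) - ctrl.mean(axis=1)
        up_rows = [idx[g] for g in gset.up]
        down_rows = [idx[g] for g in gset.down]
        assert np.allclose(diff[up_rows], 2.0, atol=0.6)
        assert np.allclose(diff[down_rows], -2.0, atol=0.6)


class TestPanels:
    def test_overlap_plan_realized_exactly(self):
        s = scenario(overlap_plan={("T2D", "MS"): (5, 3)})
        truth = plan_truth(s)
        assert len(truth.up["T2D"] & truth.up["MS"]) == 5
        assert len(truth.down["T2D"] & truth.down["MS"]) == 3

    def test_empty_plan_gives_disjoint_truths(self):
        truth = plan_truth(scenario())
        assert not truth.up["T2D"] & truth.up["MS"]
        assert not truth.down["T2D"] & truth.down["MS"]

    def test_unsatisfiable_plan_names_the_constraint(self):
        s = scenario(overlap_plan={("T2D", "MS"): (26, 0)})  # up budget is 25
        with pytest.raises(ValueError, match="up budget"):
            plan_truth(s)

    def test_truth_sets_disjoint_within_disease(self, overlap_panel):
        _studies, truth = overlap_panel
        for d in truth.up:
            assert not truth.up[d] & truth.down[d]

    def test_panel_regeneration_is_bit_identical(self):
        s = scenario(overlap_plan={("T2D", "MS"): (2, 2)})
        (a, _), (b, _) = generate_panel(s), generate_panel(s)
        for x, y in zip(a, b):
            assert x.values.tobytes() == y.values.tobytes()


class TestGmtLibraries:
    universe = [f"G{i:06d}" for i in range(200)]

    def test_planted_term_present_verbatim(self):
        planted = set(self.universe[:20])
        lib = generate_gmt_library(10, (5, 15), planted, self.universe, seed=2)
        assert lib.term("PLANTED_TERM") == frozenset(planted)
        assert len(lib) == 10

    def test_single_term_library_is_just_the_planted_term(self):
        lib = generate_gmt_library(1, (5, 15), set(self.universe[:5]),
                                   self.universe)
        assert len(lib) == 1

    def test_fixed_seed_reproduces_library(self):
        planted = set(self.universe[:8])
        a = generate_gmt_library(20, (5, 30), planted, self.universe, seed=5)
        b = generate_gmt_library(20, (5, 30), planted, self.universe, seed=5)
        assert a.terms == b.terms

    def test_term_size_beyond_universe_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            generate_gmt_library(5, (10, 500), set(self.universe[:5]),
                                 self.universe)


class TestInteractionTables:
    def test_planted_ppi_hub_has_exact_thresholded_degree(self):
        table = generate_interaction_table("ppi", 100, ("HUB1", 20), seed=4)
        degree = sum(
            1 for a, b, s in table.edges
            if s >= 900 and "HUB1" in (a, b)
        )
        assert degree == 20

    def test_tf_table_is_bipartite(self):
        table = generate_interaction_table("tf", 50, ("TF_HUB", 10), seed=1)
        regulators = table.regulators()
        targets = table.targets()
        assert not regulators & targets

    def test_high_score_range_survives_thresholding(self):
        table = generate_interaction_table(
            "ppi", 60, ("HUB1", 5), score_range=(950, 1000), seed=8
        )
        assert all(s >= 900 for _a, _b, s in table.edges)

    def test_degree_at_least_n_nodes_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            generate_interaction_table("ppi", 10, ("HUB1", 10))
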