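"""Expression classification and condition-specific model extraction."""

import numpy as np
import pytest

import phasegem as pg
from phasegem.core import Medium, Metabolite, Model, ModelError, Reaction
from phasegem.gpr import GPR
from phasegem.lp import apply_medium, fba
from phasegem.reduction import (
    ExpressionProfile,
    classify_expressed,
    diff_models,
    reduce_model,
    unsupported_reactions,
)


class TestClassifyExpressed:
    def test_threshold_boundary_inclusive(self):
        profile = ExpressionProfile({"g1": 10.0, "g2": 9.99})
        expressed = classify_expressed(profile, threshold=10.0)
        assert expressed == {"g1"}

    def test_percentile_mode_top_quartile_with_ties(self):
        """Sort-based oracle: exactly the top 25 of 100 genes, ties by id."""
        rng = np.random.default_rng(1)
        values = {f"g{i:03d}": float(rng.integers(0, 40)) for i in range(100)}
        expressed = classify_expressed(ExpressionProfile(values), mode="percentile")
        ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
        assert expressed == {g for g, _ in ranked[:25]}
        assert len(expressed) == 25

    def test_empty_profile_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert classify_expressed(ExpressionProfile({})) == set()

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ModelError):
            ExpressionProfile({"g1": -1.0})

    def test_tsv_roundtrip(self, tmp_path):
        profile = ExpressionProfile({"gA": 12.5, "gB": 0.2}, condition="AP")
        path = str(tmp_path / "expr.tsv")
        profile.to_tsv(path)
        again = ExpressionProfile.from_tsv(path, condition="AP")
        assert again.values == pytest.approx(profile.values)


class TestUnsupported:
    def test_orphans_and_exchanges_never_unsupported(self, toy_model):
        u = unsupported_reactions(toy_model, expressed=set())
        assert all(not toy_model.is_exchange(r) for r in u)
        assert all(not toy_model.reaction(r).gpr.is_empty for r in u)
        assert "ATPM" not in u and "BIOMASS" not in u

    def test_ground_truth_unsupported_sets(self, toy, toy_truth):
        model, truth = toy
        for cond in ("AP", "GP"):
            u = unsupported_reactions(model, set(truth.condition_genes[cond]))
            assert sorted(u) == truth.unsupported[cond]

    def test_threshold_monotonicity(self, toy, toy_truth):
        """Raising the expression threshold never shrinks U."""
        model, truth = toy
        profile = pg.generate_expression(model, "GP", seed=3, truth=truth)
        sizes = []
        for thr in (1.0, 10.0, 50.0, 200.0, 1e6):
            u = unsupported_reactions(model, classify_expressed(profile, thr))
            sizes.append(len(u))
        assert sizes == sorted(sizes)


def _two_path_energy_toy():
    """Two alternative ATP-generating paths; ground truth for removal.

    A (uptake 10) feeds OBJ either through supported path S or unsupported
    path X; an unsupported waste path W can never help.  At fraction 1.0 the
    supported path alone sustains the optimum, so X and W are removable.
    """
    m = Model(id="twopath", compartments={"c", "e"})
    for mid, comp in (("a_e", "e"), ("a_c", "c"), ("p_c", "c"), ("w_c", "c"),
                      ("w_e", "e")):
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1},
                            lower_bound=-10, upper_bound=0))
    m.add_reaction(Reaction("At", stoichiometry={"a_e": -1, "a_c": 1}))
    m.add_reaction(Reaction("S", stoichiometry={"a_c": -1, "p_c": 1},
                            gpr=GPR.parse("g_on")))
    m.add_reaction(Reaction("X", stoichiometry={"a_c": -1, "p_c": 1},
                            gpr=GPR.parse("g_off")))
    m.add_reaction(Reaction("W", stoichiometry={"a_c": -1, "w_c": 1},
                            gpr=GPR.parse("g_off2")))
    m.add_reaction(Reaction("Wt", stoichiometry={"w_c": -1, "w_e": 1}))
    m.add_reaction(Reaction("EX_w_e", stoichiometry={"w_e": -1}))
    m.add_reaction(Reaction("OBJ", stoichiometry={"p_c": -1}))
    m.objective_id = "OBJ"
    return m


class TestReduceModel:
    MEDIUM = Medium({"EX_a_e": 10.0})

    def test_all_genes_expressed_removes_only_blocked(self, toy, minimal_medium):
        model, truth = toy
        cm = reduce_model(model, set(model.genes), minimal_medium,
                          objective_id="ATPM")
        assert cm.removed_unsupported == set()
        assert all(reason == "blocked-after-pruning" for reason in cm.removed.values())

    def test_unsupported_alternative_path_removed(self):
        m = _two_path_energy_toy()
        cm = reduce_model(m, {"g_on"}, self.MEDIUM, fraction=1.0)
        assert cm.removed_unsupported == {"X", "W"}
        # objective preserved exactly
        assert cm.reduced_optimum == pytest.approx(cm.source_optimum)

    def test_required_unsupported_reaction_kept(self):
        m = _two_path_energy_toy()
        cm = reduce_model(m, {"g_nothing"}, self.MEDIUM, fraction=0.9)
        # both S and X are unsupported; together they must carry the optimum,
        # and either alone suffices, so the conservative rule keeps both
        assert {"S", "X"} <= {r.id for r in cm.model.reactions}
        assert "W" in cm.removed_unsupported

    def test_functionality_preserved_invariant(self, phase_reductions):
        for cm in phase_reductions:
            assert cm.reduced_optimum + 1e-6 >= cm.objective_fraction * cm.source_optimum

    def test_subnetwork_and_no_loosened_bounds(self, toy_model, phase_reductions):
        for cm in phase_reductions:
            source = apply_medium(toy_model,
                                  pg.generate_media(toy_model,
                                                    "minimal" if cm.condition == "AP" else "rich"))
            src = source.reaction_map
            for rxn in cm.model.reactions:
                assert rxn.id in src
                assert rxn.lower_bound >= src[rxn.id].lower_bound
                assert rxn.upper_bound <= src[rxn.id].upper_bound

    def test_removal_reasons_recorded(self, phase_reductions):
        ap, gp = phase_reductions
        assert gp.removed_unsupported == {"HEX1", "EMP", "PDH", "CS", "ACONT", "ICDH"}
        assert {"GLCtex", "GLCtpp", "EX_glc__D_e"} <= gp.removed_blocked
        assert set(ap.unexpressed_unsupported) == ap.removed_unsupported

    def test_infeasible_condition_raises_before_reduction(self, toy_model):
        with pytest.raises(ModelError, match="not functional"):
            reduce_model(toy_model, set(toy_model.genes), Medium({}),
                         objective_id="BIOMASS")

    def test_fraction_out_of_range(self, toy_model, rich_medium):
        with pytest.raises(ModelError):
            reduce_model(toy_model, set(), rich_medium, fraction=1.5)


class TestDiffModels:
    def test_identity_diff_empty_exclusives(self, phase_reductions):
        ap, _ = phase_reductions
        d = diff_models(ap, ap)
        assert d["a_only"] == set() and d["b_only"] == set()

    def test_hand_built_pair_matches_set_difference(self, phase_reductions):
        ap, gp = phase_reductions
        d = diff_models(ap, gp)
        ra = {r.id for r in ap.model.reactions}
        rb = {r.id for r in gp.model.reactions}
        assert d["a_only"] == ra - rb
        assert d["b_only"] == rb - ra
        assert d["shared"] == ra & rb

    def test_different_sources_rejected(self, phase_reductions):
        ap, gp = phase_reductions
        import copy

        other = copy.copy(gp)
        other.source_model_id = "someone_else"
        with pytest.raises(ModelError):
            diff_models(ap, other)

    def test_phase_exclusive_content(self, phase_reductions, toy_truth):
        """AP keeps the whole TCA-like cycle; GP drops the decarboxylative
        branch but keeps gluconeogenesis — the designed phase shift."""
        ap, gp = phase_reductions
        ap_ids = {r.id for r in ap.model.reactions}
        gp_ids = {r.id for r in gp.model.reactions}
        assert set(toy_truth.decarboxylative_branch) <= ap_ids
        assert set(toy_truth.decarboxylative_branch) & gp_ids == set()
        assert set(toy_truth.gluconeogenic) <= gp_ids
        assert {"AKGDH", "SDH2"} <= ap_ids & gp_ids  # shared lower branch
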