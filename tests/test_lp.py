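"""FBA, FVA, medium application and single-reaction deletion screens."""

import itertools

import numpy as np
import pytest

import phasegem as pg
from phasegem.core import Medium, Metabolite, Model, ModelError, Reaction
from phasegem.lp import (
    StoichiometricSystem,
    apply_medium,
    fba,
    flux_variability,
    single_reaction_deletion,
)


def _linear_chain(uptake=10.0):
    """EX_a (uptake) → transport → OBJ consuming a 1:1."""
    m = Model(id="chain", compartments={"c", "e"})
    m.add_metabolite(Metabolite("a_e", compartment="e"))
    m.add_metabolite(Metabolite("a_c", compartment="c"))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1},
                            lower_bound=-uptake, upper_bound=0))
    m.add_reaction(Reaction("At", stoichiometry={"a_e": -1, "a_c": 1}))
    m.add_reaction(Reaction("OBJ", stoichiometry={"a_c": -1}))
    m.objective_id = "OBJ"
    return m


def _parallel_paths():
    """10 units of A; path P1 yields 1 B per A, path P2 yields 2 B per A."""
    m = Model(id="parallel", compartments={"c", "e"})
    for mid, comp in (("a_e", "e"), ("a_c", "c"), ("b_c", "c")):
        m.add_metabolite(Metabolite(mid, compartment=comp))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1},
                            lower_bound=-10, upper_bound=0))
    m.add_reaction(Reaction("At", stoichiometry={"a_e": -1, "a_c": 1}))
    m.add_reaction(Reaction("P1", stoichiometry={"a_c": -1, "b_c": 1}))
    m.add_reaction(Reaction("P2", stoichiometry={"a_c": -1, "b_c": 2}))
    m.add_reaction(Reaction("OBJ", stoichiometry={"b_c": -1}))
    m.objective_id = "OBJ"
    return m


class TestFBA:
    def test_single_path_throughput(self):
        sol = fba(_linear_chain())
        assert sol.ok
        assert sol.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_parallel_paths_vertex_oracle(self):
        """Optimum matches enumeration of the 2-variable polytope vertices."""
        sol = fba(_parallel_paths())
        # vertices of {p1 + p2 <= 10, p1, p2 >= 0} scored by p1 + 2 p2
        vertices = [(0, 0), (10, 0), (0, 10)]
        best = max(p1 + 2 * p2 for p1, p2 in vertices)
        assert sol.objective_value == pytest.approx(best, abs=1e-8)
        assert best == 20

    def test_infeasible_reported_not_raised(self):
        m = _linear_chain()
        m.reaction("OBJ").lower_bound = 50.0  # demand exceeds supply
        m.reaction("OBJ").upper_bound = 60.0
        sol = fba(m)
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_unbounded_reported(self):
        m = Model(id="unbounded", compartments={"c"})
        m.add_metabolite(Metabolite("a_c", compartment="c"))
        m.add_reaction(Reaction("make", stoichiometry={"a_c": 1},
                                lower_bound=-float("inf"), upper_bound=float("inf")))
        m.add_reaction(Reaction("use", stoichiometry={"a_c": -1},
                                lower_bound=-float("inf"), upper_bound=float("inf")))
        m.objective_id = "use"
        assert fba(m).status == "unbounded"

    def test_feasibility_certificate(self, toy_model, rich_medium):
        constrained = apply_medium(toy_model, rich_medium)
        system = StoichiometricSystem(constrained)
        sol = fba(system)
        v = np.array([sol.fluxes[r] for r in system.rxn_ids])
        assert system.residual(v) <= 1e-6
        assert np.all(v >= system.lb - 1e-9)
        assert np.all(v <= system.ub + 1e-9)

    def test_missing_objective_raises(self):
        m = _linear_chain()
        m.objective_id = None
        with pytest.raises(ModelError):
            fba(m)


class TestFVA:
    def test_fully_determined_chain(self):
        m = _linear_chain()
        m.reaction("EX_a_e").upper_bound = -10.0  # force full uptake
        ranges = flux_variability(m, objective_fraction=1.0)
        sol = fba(m)
        for rid, (lo, hi) in ranges.items():
            assert lo == pytest.approx(hi, abs=1e-7)
            assert lo == pytest.approx(sol.fluxes[rid], abs=1e-7)

    def test_fraction_zero_ignores_objective(self):
        m = _parallel_paths()
        ranges = flux_variability(m, objective_fraction=0.0)
        assert ranges["P2"] == (pytest.approx(0.0), pytest.approx(10.0))
        # at optimum P2 is forced to 10; without the constraint it is free
        at_opt = flux_variability(m, objective_fraction=1.0)
        assert at_opt["P2"][0] == pytest.approx(10.0, abs=1e-7)

    def test_free_cycle_range_equals_capacity(self):
        """A reversible 2-cycle off the objective path spans its bound interval."""
        m = _linear_chain()
        m.add_metabolite(Metabolite("x_c", compartment="c"))
        m.add_metabolite(Metabolite("y_c", compartment="c"))
        m.add_reaction(Reaction("C1", stoichiometry={"x_c": -1, "y_c": 1},
                                lower_bound=-30, upper_bound=1000))
        m.add_reaction(Reaction("C2", stoichiometry={"y_c": -1, "x_c": 1},
                                lower_bound=-1000, upper_bound=30))
        ranges = flux_variability(m, objective_fraction=1.0)
        # 1-D interval oracle: cycle flux t satisfies -30 <= t <= 30
        assert ranges["C1"] == (pytest.approx(-30.0), pytest.approx(30.0))
        assert ranges["C2"] == (pytest.approx(-30.0), pytest.approx(30.0))

    def test_min_never_exceeds_max(self, toy_model, rich_medium):
        ranges = flux_variability(apply_medium(toy_model, rich_medium),
                                  objective_fraction=0.9)
        assert all(lo <= hi + 1e-12 for lo, hi in ranges.values())


class TestApplyMedium:
    def test_sign_convention_and_closure(self, toy_model):
        medium = Medium({"EX_glc__D_e": 10.0})
        constrained = apply_medium(toy_model, medium)
        assert constrained.reaction("EX_glc__D_e").lower_bound == -10.0
        for rxn in constrained.exchanges:
            if rxn.id != "EX_glc__D_e":
                assert rxn.lower_bound == 0.0
            assert rxn.upper_bound == toy_model.reaction(rxn.id).upper_bound

    def test_original_untouched(self, toy_model):
        before = {r.id: (r.lower_bound, r.upper_bound) for r in toy_model.reactions}
        apply_medium(toy_model, Medium({"EX_glc__D_e": 5.0}))
        after = {r.id: (r.lower_bound, r.upper_bound) for r in toy_model.reactions}
        assert before == after

    def test_empty_medium_starves(self, prototroph):
        model, _ = prototroph
        relaxed = pg.install_ngam(model, 0.0)  # no forced maintenance drain
        sol = fba(apply_medium(relaxed, Medium({})))
        assert sol.ok and sol.objective_value <= 1e-9

    def test_forced_maintenance_makes_starvation_infeasible(self, prototroph):
        """With NGAM > 0 a model with no nutrient source has no feasible state."""
        model, _ = prototroph
        assert fba(apply_medium(model, Medium({}))).status == "infeasible"

    def test_unknown_exchange_listed(self, toy_model):
        with pytest.raises(ModelError) as exc:
            apply_medium(toy_model, Medium({"EX_unobtainium_e": 1.0}))
        assert "EX_unobtainium_e" in str(exc.value)

    def test_rich_dominates_all_submedia(self, prototroph):
        """Enlarging uptake bounds never decreases the FBA optimum."""
        model, _ = prototroph
        model = pg.install_ngam(model, 0.0)  # keep every submedium feasible
        full = pg.generate_media(model, "minimal")
        # enumerate submedia of the 3 organic/key components
        keys = ["EX_glc__D_e", "EX_nh4_e", "EX_o2_e"]
        base = {k: v for k, v in full.uptakes.items() if k not in keys}
        full_growth = fba(apply_medium(model, full)).objective_value
        for r in range(len(keys) + 1):
            for combo in itertools.combinations(keys, r):
                sub = Medium({**base, **{k: full.uptakes[k] for k in combo}})
                growth = fba(apply_medium(model, sub)).objective_value
                assert growth <= full_growth + 1e-7


def _redundant_model():
    """One isoenzyme-duplicated step (two parallel copies) and one unique step."""
    m = Model(id="redundant", compartments={"c", "e"})
    for mid, comp in (("a_e", "e"), ("a_c", "c"), ("b_c", "c"), ("p_c", "c")):
        m.add_metabolite(Metabolite(mid, comp[0], compartment=comp))
    m.add_reaction(Reaction("EX_a_e", stoichiometry={"a_e": -1},
                            lower_bound=-10, upper_bound=0))
    m.add_reaction(Reaction("UNIQUE", stoichiometry={"a_e": -1, "a_c": 1}))
    m.add_reaction(Reaction("DUP_A", stoichiometry={"a_c": -1, "b_c": 1}))
    m.add_reaction(Reaction("DUP_B", stoichiometry={"a_c": -1, "b_c": 1}))
    m.add_reaction(Reaction("OBJ", stoichiometry={"b_c": -1, "p_c": 1}))
    m.add_reaction(Reaction("DM_p", stoichiometry={"p_c": -1}))
    m.objective_id = "OBJ"
    return m


class TestSingleReactionDeletion:
    def test_zero_flux_reaction_nonessential(self):
        m = _parallel_paths()
        m.add_metabolite(Metabolite("z_c", compartment="c"))
        m.add_reaction(Reaction("IDLE", stoichiometry={"b_c": -1, "z_c": 1},
                                upper_bound=0.0))
        res = single_reaction_deletion(m)
        assert res.rows["IDLE"]["ratio"] == pytest.approx(1.0)
        assert not res.rows["IDLE"]["essential"]

    def test_severed_lifeline_is_essential(self):
        res = single_reaction_deletion(_redundant_model())
        assert res.rows["UNIQUE"]["ratio"] == pytest.approx(0.0, abs=1e-9)
        assert res.rows["UNIQUE"]["essential"]

    def test_isoenzyme_duplication_vs_exhaustive_enumeration(self):
        m = _redundant_model()
        res = single_reaction_deletion(m, threshold=0.10)
        # brute-force oracle: re-solve FBA for every singleton deletion
        expected = set()
        wt = fba(m).objective_value
        for rxn in m.reactions:
            if rxn.id == "OBJ" or m.is_exchange(rxn):
                continue
            mm = m.copy()
            mm.reaction(rxn.id).lower_bound = 0.0
            mm.reaction(rxn.id).upper_bound = 0.0
            sol = fba(mm)
            mutant = sol.objective_value if sol.ok else 0.0
            if max(0.0, mutant) / wt < 0.10:
                expected.add(rxn.id)
        assert res.essential == expected
        assert expected == {"UNIQUE", "DM_p"}

    def test_objective_and_exchanges_skipped(self):
        res = single_reaction_deletion(_redundant_model())
        assert "OBJ" not in res.rows
        assert "EX_a_e" not in res.rows
        assert "EX_a_e" in res.skipped
        kept = single_reaction_deletion(_redundant_model(), exclude_exchanges=False)
        assert "EX_a_e" in kept.rows and kept.rows["EX_a_e"]["essential"]

    def test_threshold_monotonicity(self, toy_model, rich_medium):
        constrained = apply_medium(toy_model, rich_medium)
        strict = single_reaction_deletion(constrained, threshold=0.10)
        loose = single_reaction_deletion(constrained, threshold=0.50)
        assert strict.essential <= loose.essential

    def test_non_growing_wild_type_raises(self, toy_model):
        starved = apply_medium(toy_model, Medium({}))
        with pytest.raises(ModelError, match="non-growing"):
            single_reaction_deletion(starved)
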