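"""Formula parsing, reaction balance checking, and dead-end detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import phasegem as pg
from phasegem.core import (
    BalanceResult,
    FormulaError,
    Metabolite,
    Model,
    Reaction,
    check_reaction_balance,
    dead_end_report,
    find_dead_end_metabolites,
    format_formula,
    molecular_weight,
    parse_formula,
)


def _char_oracle(formula):
    """Character-by-character reference parser for element-count grammar."""
    counts = {}
    i = 0
    while i < len(formula):
        assert formula[i].isupper()
        sym = formula[i]
        i += 1
        if i < len(formula) and formula[i].islower():
            sym += formula[i]
            i += 1
        digits = ""
        while i < len(formula) and formula[i].isdigit():
            digits += formula[i]
            i += 1
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
    return counts


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("H2O", {"H": 2, "O": 1}),
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("CHO2", {"C": 1, "H": 1, "O": 2}),  # implicit count of one
            ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_examples(self, formula, expected):
        assert parse_formula(formula) == expected
        assert parse_formula(formula) == _char_oracle(formula)

    @pytest.mark.parametrize("bad", ["", "h2o", "C6H12O6!", "2CO", "C-3"])
    def test_malformed_raises_with_position(self, bad):
        with pytest.raises(FormulaError) as exc:
            parse_formula(bad)
        assert exc.value.position >= 0

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S", "Na", "Fe"]),
            st.integers(min_value=1, max_value=99),
            min_size=1,
            max_size=6,
        )
    )
    def test_format_parse_roundtrip(self, counts):
        assert parse_formula(format_formula(counts)) == counts

    def test_molecular_weight_water(self):
        assert molecular_weight("H2O") == pytest.approx(18.015, abs=1e-3)


class TestBalance:
    def _lookup(self, *mets):
        return {m.id: m for m in mets}

    def test_identity_transfer_balanced(self):
        mets = self._lookup(
            Metabolite("a_c", formula="C", compartment="c"),
            Metabolite("b_c", formula="C", compartment="c"),
        )
        rxn = Reaction("r", stoichiometry={"a_c": -1, "b_c": 1})
        assert check_reaction_balance(rxn, mets).is_balanced

    def test_stoichiometric_doubling_balanced(self):
        mets = self._lookup(
            Metabolite("glc_c", formula="C6H12O6", compartment="c"),
            Metabolite("half_c", formula="C3H6O3", compartment="c"),
        )
        rxn = Reaction("split", stoichiometry={"glc_c": -1, "half_c": 2})
        assert check_reaction_balance(rxn, mets).is_balanced

    def test_charge_imbalance_reported(self):
        mets = self._lookup(
            Metabolite("a_c", formula="H", charge=1, compartment="c"),
            Metabolite("b_c", formula="H", charge=0, compartment="c"),
        )
        rxn = Reaction("r", stoichiometry={"a_c": -1, "b_c": 1})
        res = check_reaction_balance(rxn, mets)
        assert res.status == "unbalanced"
        assert res.charge_imbalance == -1

    def test_boundary_reactions_skipped(self):
        mets = self._lookup(Metabolite("a_e", formula="C", compartment="e"))
        rxn = Reaction("EX_a", stoichiometry={"a_e": -1})
        assert check_reaction_balance(rxn, mets).status == "skipped"

    def test_missing_formula_unverifiable_not_balanced(self):
        mets = self._lookup(
            Metabolite("a_c", formula=None, compartment="c"),
            Metabolite("b_c", formula="C", compartment="c"),
        )
        rxn = Reaction("r", stoichiometry={"a_c": -1, "b_c": 1})
        assert check_reaction_balance(rxn, mets).status == "unverifiable"

    def test_random_reactions_match_elemental_ledger(self):
        """Imbalance equals an independently summed elemental ledger."""
        rng = np.random.default_rng(11)
        formulas = ["C3H4O3", "C6H12O6", "CO2", "H2O", "C2H3O2", "NH3"]
        for _ in range(50):
            k = int(rng.integers(2, 5))
            ids = [f"x{i}_c" for i in range(k)]
            chosen = rng.choice(formulas, size=k)
            coeffs = rng.integers(-3, 4, size=k).astype(float)
            coeffs[coeffs == 0] = 1.0
            mets = {
                mid: Metabolite(mid, formula=str(f), compartment="c")
                for mid, f in zip(ids, chosen)
            }
            rxn = Reaction("r", stoichiometry=dict(zip(ids, coeffs)))
            res = check_reaction_balance(rxn, mets)
            ledger = {}
            charge = 0.0
            for mid, coeff in rxn.stoichiometry.items():
                for e, n in _char_oracle(mets[mid].formula).items():
                    ledger[e] = ledger.get(e, 0.0) + coeff * n
                charge += coeff * mets[mid].charge
            ledger = {e: v for e, v in ledger.items() if abs(v) > 1e-9}
            if not ledger and abs(charge) <= 1e-9:
                assert res.is_balanced
            else:
                assert res.status == "unbalanced"
                assert res.element_imbalance == pytest.approx(ledger)


def _chain_model():
    m = Model(id="chain", compartments={"c"})
    for mid in ("a_c", "b_c", "cc_c"):
        m.add_metabolite(Metabolite(mid, formula="C", compartment="c"))
    m.add_reaction(Reaction("r1", stoichiometry={"a_c": -1, "b_c": 1}))
    m.add_reaction(Reaction("r2", stoichiometry={"b_c": -1, "cc_c": 1}))
    return m


class TestDeadEnds:
    def test_terminal_sink_is_dead_end(self):
        m = _chain_model()
        # a_c has no producer, cc_c no consumer: both dead ends
        dead = find_dead_end_metabolites(m)
        assert dead == {"a_c", "cc_c"}

    def test_balanced_cycle_has_none(self):
        m = Model(id="cycle", compartments={"c"})
        m.add_metabolite(Metabolite("a_c", compartment="c"))
        m.add_metabolite(Metabolite("b_c", compartment="c"))
        m.add_reaction(Reaction("fwd", stoichiometry={"a_c": -1, "b_c": 1}))
        m.add_reaction(Reaction("back", stoichiometry={"b_c": -1, "a_c": 1}))
        assert find_dead_end_metabolites(m) == set()

    def test_reversible_reaction_counts_both_ways(self):
        m = Model(id="rev", compartments={"c"})
        m.add_metabolite(Metabolite("a_c", compartment="c"))
        m.add_metabolite(Metabolite("b_c", compartment="c"))
        m.add_reaction(Reaction("r", stoichiometry={"a_c": -1, "b_c": 1},
                                lower_bound=-1000))
        assert find_dead_end_metabolites(m) == set()

    def test_random_networks_match_connectivity_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n_mets = int(rng.integers(3, 8))
            n_rxns = int(rng.integers(2, 10))
            m = Model(id="rand", compartments={"c"})
            for i in range(n_mets):
                m.add_metabolite(Metabolite(f"m{i}_c", compartment="c"))
            for j in range(n_rxns):
                k = int(rng.integers(1, 4))
                mets = rng.choice(n_mets, size=min(k, n_mets), replace=False)
                coeffs = rng.choice([-2, -1, 1, 2], size=len(mets))
                rev = bool(rng.random() < 0.4)
                m.add_reaction(Reaction(
                    f"r{j}",
                    stoichiometry={f"m{int(i)}_c": float(c) for i, c in zip(mets, coeffs)},
                    lower_bound=-1000.0 if rev else 0.0,
                ))
            # brute-force producer/consumer tally
            produced, consumed = set(), set()
            for r in m.reactions:
                for mid, coeff in r.stoichiometry.items():
                    if coeff > 0 or r.lower_bound < 0:
                        produced.add(mid)
                    if coeff < 0 or r.lower_bound < 0:
                        consumed.add(mid)
            expected = {
                mm.id for mm in m.metabolites
                if (mm.id in produced) != (mm.id in consumed)
                or (mm.id not in produced and mm.id not in consumed)
            }
            assert find_dead_end_metabolites(m) == expected

    def test_dead_end_report_lists_touching_reactions(self):
        m = _chain_model()
        dead, rxns = dead_end_report(m)
        assert rxns == {"r1", "r2"}


class TestModelValidation:
    def test_duplicate_and_dangling_references_all_listed(self):
        m = Model(id="bad", compartments={"c"})
        m.metabolites.append(Metabolite("a_c", compartment="c"))
        m.metabolites.append(Metabolite("a_c", compartment="c"))
        m.reactions.append(Reaction("r1", stoichiometry={"ghost_c": -1}))
        m.objective_id = "nope"
        with pytest.raises(pg.ModelError) as exc:
            m.validate()
        msg = str(exc.value)
        assert "duplicate metabolite" in msg
        assert "ghost_c" in msg
        assert "nope" in msg

    def test_exchange_classification(self, toy_model):
        assert toy_model.is_exchange("EX_glc__D_e")
        assert not toy_model.is_exchange("GLCtex")  # two metabolites
        assert not toy_model.is_exchange("DM_biomass_c")  # boundary but cytoplasmic

    def test_bounds_invariant(self):
        with pytest.raises(pg.ModelError):
            Reaction("r", stoichiometry={"a": -1}, lower_bound=5, upper_bound=1)
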