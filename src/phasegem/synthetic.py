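"""Deterministic generator of toy compartmented GEMs with known ground truth.

The generated model emulates, at desk scale, the metabolic situation of a
biphasic predatory bacterium: a three-compartment (c/p/e) core network with

* glucose uptake through the periplasm and a lumped glycolytic chain,
* a TCA-like cycle whose decarboxylative branch (citrate synthase CS,
  aconitase ACONT, isocitrate dehydrogenase ICDH) is separable from the
  lower branch (AKGDH, SDH2) — the structure behind the attack/growth-phase
  flux shift,
* lumped respiration (NADH + O₂ + ADP + Pi → ATP at P/O = 2) and an ATP
  maintenance drain (ATPM, the attack-phase objective),
* per-branch amino acid-like monomer biosynthesis (precursor + NH₄⁺ + ATP →
  intermediate → monomer), written reversibly so monomers taken up from a
  rich, prey-cytoplasm-like medium can also be catabolised for carbon and
  energy (the "glutamate as fuel" mode of the growth phase),
* monomer transporters and exchanges, overflow secretion of pyruvate and
  acetate, a biomass objective assembled by the biomass builder, and
  optional designed dead-end metabolites.

Designed *deletions* of whole biosynthetic branches create auxotrophies with
exact ground truth; designed isoenzyme duplications (two parallel reaction
copies, one gene each) create reaction-level redundancy; AND-type GPRs mark
complex-encoded steps.  Every reaction except the biomass pseudo-reaction is
elementally and charge balanced (BIGG-style charged species).

All randomness sits behind a single integer seed; identical specs give
bit-identical models, expression profiles and media.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np

from .biomass import BiomassComposition, install_biomass, install_ngam
from .core import Medium, Metabolite, Model, ModelError, Reaction, molecular_weight
from .gpr import GPR

__all__ = [
    "ToySpec",
    "GroundTruth",
    "generate_core_model",
    "generate_expression",
    "generate_media",
    "ExpressionProfile",
]

# imported lazily at bottom to avoid a cycle at module import time
from .reduction import ExpressionProfile  # noqa: E402

Step = Tuple[int, int]  # (branch index, step 1 or 2)

#: formula/charge of the toy species (BIGG-style charged forms)
_SPECIES = {
    "glc__D": ("C6H12O6", 0),
    "g6p": ("C6H11O9P", -2),
    "pyr": ("C3H3O3", -1),
    "ac": ("C2H3O2", -1),
    "oaa": ("C4H2O5", -2),
    "cit": ("C6H5O7", -3),
    "icit": ("C6H5O7", -3),
    "akg": ("C5H4O5", -2),
    "succ": ("C4H4O4", -2),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "pi": ("HO4P", -2),
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "o2": ("O2", 0),
    "co2": ("CO2", 0),
    "nh4": ("H4N", 1),
}

#: precursor cycle for the biosynthetic branches
_PRECURSORS = ("pyr", "akg", "oaa", "ac")

_INORGANIC = ("o2", "co2", "nh4", "pi", "h2o", "h")


@dataclass(frozen=True)
class ToySpec:
    """Specification of one toy model; the generator is a pure function of it.

    ``deleted_branches`` are designed auxotrophies: those branches'
    biosynthesis reactions are omitted, so their monomer must be taken up.
    ``isoenzyme_steps`` get two parallel reaction copies with one gene each;
    ``complex_steps`` get a two-gene AND rule.  Steps are (branch, 1|2).
    """

    n_biosynthesis_branches: int = 6
    deleted_branches: FrozenSet[int] = frozenset({2, 4})
    isoenzyme_steps: FrozenSet[Step] = frozenset({(0, 1)})
    complex_steps: FrozenSet[Step] = frozenset({(1, 1)})
    add_dead_ends: int = 2
    seed: int = 0
    gam: float = 10.0
    ngam: float = 1.0
    glucose_uptake: float = 10.0
    monomer_uptake: float = 10.0

    def __post_init__(self):
        n = self.n_biosynthesis_branches
        if n < 1 or n > 8:
            raise ModelError("n_biosynthesis_branches must be between 1 and 8")
        object.__setattr__(self, "deleted_branches", frozenset(self.deleted_branches))
        object.__setattr__(self, "isoenzyme_steps",
                           frozenset(tuple(s) for s in self.isoenzyme_steps))
        object.__setattr__(self, "complex_steps",
                           frozenset(tuple(s) for s in self.complex_steps))
        if not self.deleted_branches <= set(range(n)):
            raise ModelError("deleted_branches must be a subset of the branch indices")
        for label, steps in (("isoenzyme", self.isoenzyme_steps),
                             ("complex", self.complex_steps)):
            for b, s in steps:
                if b not in range(n) or s not in (1, 2):
                    raise ModelError(f"{label} step {(b, s)} out of range")
                if b in self.deleted_branches:
                    raise ModelError(
                        f"branch {b} is deleted yet its step {(b, s)} is marked "
                        f"{label}-modified: contradictory specification"
                    )
        if self.isoenzyme_steps & self.complex_steps:
            raise ModelError("a step cannot be both isoenzyme-duplicated and complex-encoded")
        if self.add_dead_ends < 0:
            raise ModelError("add_dead_ends must be non-negative")


@dataclass
class GroundTruth:
    """The designed facts about a generated model, for oracle-style testing."""

    auxotrophic_monomers: List[str]
    auxotrophic_exchanges: List[str]
    dead_end_metabolites: List[str]
    dead_end_reactions: List[str]
    unsupported: Dict[str, List[str]]  # condition -> reaction ids with false GPR
    condition_genes: Dict[str, List[str]]
    decarboxylative_branch: List[str]
    gluconeogenic: List[str]
    isoenzyme_pairs: List[Tuple[str, str]]
    branch_reactions: Dict[int, List[str]]
    monomer_exchange: Dict[str, str]
    monomer_ids: List[str]


def _add_species(model: Model, base: str, compartment: str) -> str:
    formula, charge = _SPECIES[base]
    mid = f"{base}_{compartment}"
    if mid not in model.metabolite_map:
        model.add_metabolite(Metabolite(mid, name=base, formula=formula,
                                        charge=charge, compartment=compartment))
    return mid


def _monomer_formula(prec: str) -> Tuple[str, int]:
    """Monomer = precursor + NH3 + H2 (amination then reduction), same charge."""
    from .core import format_formula, parse_formula

    counts = parse_formula(_SPECIES[prec][0])
    counts["N"] = counts.get("N", 0) + 1
    counts["H"] = counts.get("H", 0) + 5
    return format_formula(counts), _SPECIES[prec][1]


def generate_core_model(spec: ToySpec) -> Tuple[Model, GroundTruth]:
    """Build the toy model and its designed ground truth.

    Raises :class:`ModelError` for contradictory specs (see
    :class:`ToySpec`) or if the generated model fails to grow on its rich
    medium, which would make the designed auxotrophies meaningless.
    """
    n = spec.n_biosynthesis_branches
    model = Model(id=f"toy_gem_seed{spec.seed}", compartments={"c", "p", "e"})

    # core cytoplasmic species
    for base in _SPECIES:
        _add_species(model, base, "c")
    for base in ("glc__D",):
        _add_species(model, base, "p")
        _add_species(model, base, "e")
    for base in _INORGANIC + ("pyr", "ac"):
        _add_species(model, base, "e")

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, gpr="", subsystem=""):
        model.add_reaction(Reaction(rid, name=name, stoichiometry=stoich,
                                    lower_bound=lb, upper_bound=ub,
                                    gpr=GPR.parse(gpr), subsystem=subsystem))

    # -- uptake and catabolic chain -------------------------------------
    rxn("EX_glc__D_e", "D-glucose exchange", {"glc__D_e": -1}, 0, 1000,
        subsystem="Exchange")
    rxn("GLCtex", "glucose transport e<->p", {"glc__D_e": -1, "glc__D_p": 1},
        -1000, 1000, subsystem="Transport")
    rxn("GLCtpp", "glucose transport p<->c", {"glc__D_p": -1, "glc__D_c": 1},
        -1000, 1000, subsystem="Transport")
    rxn("HEX1", "hexokinase", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1,
                               "adp_c": 1, "h_c": 1},
        0, 1000, gpr="g_HEX1", subsystem="Glycolysis")
    rxn("EMP", "glycolysis (lumped, g6p to pyruvate)",
        {"g6p_c": -1, "adp_c": -3, "nad_c": -2, "pi_c": -2,
         "pyr_c": 2, "atp_c": 3, "nadh_c": 2, "h_c": 1, "h2o_c": 2},
        0, 1000, gpr="g_EMP", subsystem="Glycolysis")
    rxn("PDH", "pyruvate dehydrogenase (acetate-level lump)",
        {"pyr_c": -1, "nad_c": -1, "h2o_c": -1,
         "ac_c": 1, "co2_c": 1, "nadh_c": 1, "h_c": 1},
        0, 1000, gpr="g_PDH", subsystem="Pyruvate metabolism")

    # -- TCA-like cycle ---------------------------------------------------
    rxn("CS", "citrate synthase", {"ac_c": -1, "oaa_c": -1, "cit_c": 1},
        0, 1000, gpr="g_CS", subsystem="TCA cycle")
    rxn("ACONT", "aconitase", {"cit_c": -1, "icit_c": 1},
        -1000, 1000, gpr="g_ACONT", subsystem="TCA cycle")
    rxn("ICDH", "isocitrate dehydrogenase",
        {"icit_c": -1, "nad_c": -1, "akg_c": 1, "co2_c": 1, "nadh_c": 1},
        0, 1000, gpr="g_ICDH", subsystem="TCA cycle")
    rxn("AKGDH", "alpha-ketoglutarate dehydrogenase (lumped)",
        {"akg_c": -1, "nad_c": -1, "h2o_c": -1,
         "succ_c": 1, "co2_c": 1, "nadh_c": 1, "h_c": 1},
        0, 1000, gpr="g_AKGDH", subsystem="TCA cycle")
    rxn("SDH2", "succinate to oxaloacetate (lumped lower branch)",
        {"succ_c": -1, "nad_c": -2, "h2o_c": -1,
         "oaa_c": 1, "nadh_c": 2, "h_c": 2},
        0, 1000, gpr="g_SDH2", subsystem="TCA cycle")
    rxn("PC", "pyruvate carboxylase (anaplerosis)",
        {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1,
         "oaa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2},
        0, 1000, gpr="g_PC", subsystem="Anaplerosis")
    rxn("OADC", "oxaloacetate decarboxylase",
        {"oaa_c": -1, "h_c": -1, "pyr_c": 1, "co2_c": 1},
        0, 1000, gpr="g_OADC", subsystem="Anaplerosis")
    rxn("GNG", "gluconeogenesis (lumped, pyruvate to g6p)",
        {"pyr_c": -2, "atp_c": -4, "nadh_c": -2, "h2o_c": -3,
         "g6p_c": 1, "adp_c": 4, "nad_c": 2, "pi_c": 3},
        0, 1000, gpr="g_GNG", subsystem="Gluconeogenesis")
    rxn("RESP", "respiration (NADH oxidase + oxidative phosphorylation, P/O=2)",
        {"nadh_c": -2, "h_c": -6, "o2_c": -1, "adp_c": -4, "pi_c": -4,
         "nad_c": 2, "h2o_c": 6, "atp_c": 4},
        0, 1000, gpr="g_RESP", subsystem="Oxidative phosphorylation")

    # -- overflow secretion and inorganic exchange ------------------------
    rxn("PYRt", "pyruvate transport c<->e", {"pyr_c": -1, "pyr_e": 1},
        -1000, 1000, subsystem="Transport")
    rxn("EX_pyr_e", "pyruvate exchange", {"pyr_e": -1}, 0, 1000, subsystem="Exchange")
    rxn("ACt", "acetate transport c<->e", {"ac_c": -1, "ac_e": 1},
        -1000, 1000, subsystem="Transport")
    rxn("EX_ac_e", "acetate exchange", {"ac_e": -1}, 0, 1000, subsystem="Exchange")
    for base in _INORGANIC:
        rxn(f"{base.upper()}t", f"{base} transport e<->c",
            {f"{base}_e": -1, f"{base}_c": 1}, -1000, 1000, subsystem="Transport")
        rxn(f"EX_{base}_e", f"{base} exchange", {f"{base}_e": -1}, 0, 1000,
            subsystem="Exchange")

    # -- biosynthetic branches -------------------------------------------
    monomer_ids: List[str] = []
    monomer_exchange: Dict[str, str] = {}
    branch_reactions: Dict[int, List[str]] = {}
    isoenzyme_pairs: List[Tuple[str, str]] = []
    biosynthesis_genes: List[str] = []

    for k in range(n):
        prec = _PRECURSORS[k % len(_PRECURSORS)]
        mon = f"mon{k}"
        mon_formula, mon_charge = _monomer_formula(prec)
        from .core import format_formula, parse_formula

        int_counts = parse_formula(_SPECIES[prec][0])
        int_counts["N"] = int_counts.get("N", 0) + 1
        int_counts["H"] = int_counts.get("H", 0) + 3
        int_formula = format_formula(int_counts)

        for comp in ("c", "p", "e"):
            model.add_metabolite(Metabolite(f"{mon}_{comp}", name=f"monomer {k} ({prec}-family)",
                                            formula=mon_formula, charge=mon_charge,
                                            compartment=comp))
        rxn(f"MON{k}tex", f"monomer {k} transport e<->p",
            {f"{mon}_e": -1, f"{mon}_p": 1}, -1000, 1000, subsystem="Transport")
        rxn(f"MON{k}tpp", f"monomer {k} transport p<->c",
            {f"{mon}_p": -1, f"{mon}_c": 1}, -1000, 1000, subsystem="Transport")
        rxn(f"EX_{mon}_e", f"monomer {k} exchange", {f"{mon}_e": -1}, 0, 1000,
            subsystem="Exchange")
        monomer_ids.append(f"{mon}_c")
        monomer_exchange[f"{mon}_c"] = f"EX_{mon}_e"

        if k in spec.deleted_branches:
            branch_reactions[k] = []
            continue  # designed auxotrophy: no biosynthesis for this branch

        model.add_metabolite(Metabolite(f"int{k}_c", name=f"branch {k} intermediate",
                                        formula=int_formula, charge=mon_charge,
                                        compartment="c"))
        branch_reactions[k] = []

        def biosynthesis_step(step_no: int, rid: str, stoich, gene_base: str):
            """One branch step, honouring isoenzyme/complex design."""
            key = (k, step_no)
            if key in spec.complex_steps:
                gpr = f"{gene_base}_a and {gene_base}_b"
                rxn(rid, f"branch {k} step {step_no}", stoich, -1000, 1000,
                    gpr=gpr, subsystem="Biosynthesis")
                biosynthesis_genes.extend([f"{gene_base}_a", f"{gene_base}_b"])
                branch_reactions[k].append(rid)
            elif key in spec.isoenzyme_steps:
                rxn(rid, f"branch {k} step {step_no} (isoenzyme A)", stoich,
                    -1000, 1000, gpr=f"{gene_base}_a", subsystem="Biosynthesis")
                rxn(f"{rid}_iso", f"branch {k} step {step_no} (isoenzyme B)",
                    dict(stoich), -1000, 1000, gpr=f"{gene_base}_b",
                    subsystem="Biosynthesis")
                biosynthesis_genes.extend([f"{gene_base}_a", f"{gene_base}_b"])
                isoenzyme_pairs.append((rid, f"{rid}_iso"))
                branch_reactions[k].extend([rid, f"{rid}_iso"])
            else:
                rxn(rid, f"branch {k} step {step_no}", stoich, -1000, 1000,
                    gpr=gene_base, subsystem="Biosynthesis")
                biosynthesis_genes.append(gene_base)
                branch_reactions[k].append(rid)

        biosynthesis_step(
            1, f"BS1_{k}",
            {f"{prec}_c": -1, "nh4_c": -1, "atp_c": -1, "h2o_c": -1,
             f"int{k}_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2},
            f"g_BS1_{k}",
        )
        biosynthesis_step(
            2, f"BS2_{k}",
            {f"int{k}_c": -1, "nadh_c": -1, "h_c": -1,
             f"mon{k}_c": 1, "nad_c": 1},
            f"g_BS2_{k}",
        )

    # -- designed dead ends ----------------------------------------------
    dead_mets, dead_rxns = [], []
    for i in range(spec.add_dead_ends):
        did = f"de{i}_c"
        model.add_metabolite(Metabolite(did, name=f"dead-end metabolite {i}",
                                        formula=_SPECIES["pyr"][0],
                                        charge=_SPECIES["pyr"][1], compartment="c"))
        rxn(f"DEADSYN{i}", f"dead-end synthesis {i}", {"pyr_c": -1, did: 1},
            0, 1000, subsystem="Dead ends")
        dead_mets.append(did)
        dead_rxns.append(f"DEADSYN{i}")

    # -- biomass and maintenance -----------------------------------------
    composition = _default_composition(spec, monomer_ids, model)
    model = install_biomass(model, composition)
    model = install_ngam(model, spec.ngam)

    # -- condition gene regimes ------------------------------------------
    ap_only = ["g_HEX1", "g_EMP", "g_PDH", "g_CS", "g_ACONT", "g_ICDH"]
    gp_only = sorted(set(biosynthesis_genes)) + ["g_GNG", "g_OADC"]
    both = ["g_AKGDH", "g_SDH2", "g_PC", "g_RESP"]
    condition_genes = {"AP": sorted(ap_only + both), "GP": sorted(gp_only + both)}
    unsupported = {
        cond: sorted(
            r.id for r in model.reactions
            if not r.gpr.is_empty and not model.is_exchange(r)
            and not r.gpr.evaluate(set(genes))
        )
        for cond, genes in condition_genes.items()
    }

    truth = GroundTruth(
        auxotrophic_monomers=[f"mon{k}_c" for k in sorted(spec.deleted_branches)],
        auxotrophic_exchanges=[f"EX_mon{k}_e" for k in sorted(spec.deleted_branches)],
        dead_end_metabolites=dead_mets,
        dead_end_reactions=dead_rxns,
        unsupported=unsupported,
        condition_genes=condition_genes,
        decarboxylative_branch=["CS", "ACONT", "ICDH"],
        gluconeogenic=["GNG"],
        isoenzyme_pairs=isoenzyme_pairs,
        branch_reactions=branch_reactions,
        monomer_exchange=monomer_exchange,
        monomer_ids=monomer_ids,
    )

    model.validate()
    # generation-time sanity: the model must grow on its own rich medium
    from .lp import apply_medium, fba

    rich = generate_media(model, "rich", spec=spec)
    sol = fba(apply_medium(model, rich))
    if not sol.ok or sol.objective_value <= 1e-6:
        raise ModelError(
            "contradictory spec: generated model does not grow on the rich medium "
            f"(status {sol.status}, objective {sol.objective_value})"
        )
    return model, truth


def _default_composition(spec: ToySpec, monomer_ids: List[str], model: Model) -> BiomassComposition:
    """Protein + carbohydrate composition; glutamate-family monomers are kept
    at a low mole fraction so the rich medium leaves them in excess as the
    growth-phase energy source."""
    akg_branches = {k for k in range(spec.n_biosynthesis_branches)
                    if _PRECURSORS[k % len(_PRECURSORS)] == "akg"}
    n = spec.n_biosynthesis_branches
    x_akg = 0.08 if len(akg_branches) not in (0, n) else 1.0 / n
    n_other = n - len(akg_branches)
    x_other = (1.0 - x_akg * len(akg_branches)) / n_other if n_other else 0.0
    fractions = {
        mid: (x_akg if k in akg_branches else x_other)
        for k, mid in enumerate(monomer_ids)
    }
    weights = {mid: molecular_weight(model.metabolite(mid).formula) for mid in monomer_ids}
    weights["g6p_c"] = molecular_weight(model.metabolite("g6p_c").formula)
    return BiomassComposition(
        class_fractions={"protein": 0.85, "carbohydrate": 0.15},
        monomer_fractions={"protein": fractions, "carbohydrate": {"g6p_c": 1.0}},
        monomer_weights=weights,
        gam=spec.gam,
        ngam=spec.ngam,
    ).validate()


def generate_media(model: Model, kind: str, spec: Optional[ToySpec] = None) -> Medium:
    """Minimal (glucose + inorganics) or rich (monomers + inorganics) medium.

    The rich medium emulates the prey cytoplasm: amino acid-like monomers are
    the carbon and energy source and free sugar is absent, mirroring the
    predator's intraperiplasmic feeding mode.
    """
    glc = spec.glucose_uptake if spec is not None else 10.0
    mon = spec.monomer_uptake if spec is not None else 10.0
    inorganics = {
        "EX_o2_e": 100.0, "EX_nh4_e": 100.0, "EX_pi_e": 100.0,
        "EX_h2o_e": 1000.0, "EX_h_e": 1000.0,
    }
    exch = model.exchange_ids
    if kind == "minimal":
        uptakes = dict(inorganics)
        uptakes["EX_glc__D_e"] = glc
    elif kind == "rich":
        uptakes = dict(inorganics)
        for rid in sorted(exch):
            if rid.startswith("EX_mon"):
                uptakes[rid] = mon
    else:
        raise ModelError(f"unknown medium kind {kind!r} (expected 'minimal' or 'rich')")
    return Medium({k: v for k, v in uptakes.items() if k in exch}, name=kind)


def generate_expression(
    model: Model,
    condition: str,
    seed: int = 0,
    truth: Optional[GroundTruth] = None,
    threshold: float = 10.0,
) -> ExpressionProfile:
    """Seed-deterministic RPKM profile for an AP-like or GP-like condition.

    Genes of the condition's active set draw log-normal values well above the
    expressed threshold; all other genes draw below it.  The active sets are
    the generator's designed regimes: catabolic/respiratory genes in the
    attack phase, biosynthetic/gluconeogenic genes in the growth phase, the
    lower TCA branch and respiration in both.
    """
    cond = condition.upper().replace("-LIKE", "")
    if cond not in ("AP", "GP"):
        raise ModelError(f"unknown condition {condition!r} (expected 'AP' or 'GP')")
    if truth is None:
        active = _condition_genes_from_model(model, cond)
    else:
        active = set(truth.condition_genes[cond])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0 if cond == "AP" else 1]))
    values: Dict[str, float] = {}
    for gene in sorted(model.genes):
        if gene in active:
            v = float(np.exp(rng.normal(math.log(120.0), 0.6)))
            values[gene] = max(threshold, v)
        else:
            v = float(np.exp(rng.normal(math.log(1.5), 0.8)))
            values[gene] = min(threshold - 0.1, v)
    return ExpressionProfile(values=values, condition=cond)


def _condition_genes_from_model(model: Model, cond: str) -> Set[str]:
    ap_only = {"g_HEX1", "g_EMP", "g_PDH", "g_CS", "g_ACONT", "g_ICDH"}
    both = {"g_AKGDH", "g_SDH2", "g_PC", "g_RESP"}
    gp_only = {g for g in model.genes if g.startswith("g_BS")} | {"g_GNG", "g_OADC"}
    return (ap_only | both) if cond == "AP" else (gp_only | both)
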