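"""Core data model for compartmented genome-scale metabolic networks.

A :class:`Model` is the in-memory twin of an SBML-FBC file or of a paired
reaction/metabolite table: compartments, metabolites with elemental formula
and charge, reactions with stoichiometry, flux bounds (mmol·gDW⁻¹·h⁻¹) and
Boolean gene-protein-reaction (GPR) rules, plus a designated objective
reaction whose flux is the growth (or ATP-production) rate.

The module also provides the structural quality checks that a reconstruction
is expected to pass: elemental/charge balancing of every non-boundary
reaction and detection of dead-end metabolites (species that are only ever
produced or only ever consumed, which block flux through their reactions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .gpr import GPR

__all__ = [
    "FormulaError",
    "ModelError",
    "Metabolite",
    "Reaction",
    "Model",
    "Medium",
    "BalanceResult",
    "parse_formula",
    "format_formula",
    "molecular_weight",
    "check_reaction_balance",
    "check_model_balance",
    "find_dead_end_metabolites",
    "dead_end_report",
]


class FormulaError(ValueError):
    """Raised when an elemental formula string cannot be parsed."""

    def __init__(self, formula: str, position: int, message: str):
        self.formula = formula
        self.position = position
        super().__init__(f"cannot parse formula {formula!r} at position {position}: {message}")


class ModelError(ValueError):
    """Raised when a model violates a structural invariant."""


# Standard atomic weights (g/mol), sufficient for metabolic reconstructions.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Cl": 35.45, "Mg": 24.305,
    "Ca": 40.078, "Fe": 55.845, "Zn": 65.38, "Mn": 54.938, "Cu": 63.546,
    "Co": 58.933, "Mo": 95.95, "Se": 78.971, "Ni": 58.693, "F": 18.998,
    "I": 126.904, "B": 10.81, "Si": 28.085, "R": 0.0, "X": 0.0,
}

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse an elemental formula such as ``"C6H12O6"`` into element counts.

    The grammar is a sequence of (element symbol, optional positive integer)
    tokens; a missing integer means a count of one.  Raises
    :class:`FormulaError` naming the offending position on malformed input.
    """
    if not isinstance(formula, str):
        raise FormulaError(str(formula), 0, "not a string")
    if formula == "":
        raise FormulaError(formula, 0, "empty formula")
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN_RE.match(formula, pos)
        if m is None or m.start() != pos or m.group(0) == "":
            raise FormulaError(formula, pos, f"expected element symbol, found {formula[pos]!r}")
        element, digits = m.group(1), m.group(2)
        count = int(digits) if digits else 1
        if digits and count == 0:
            raise FormulaError(formula, pos + len(element), "zero count")
        counts[element] = counts.get(element, 0) + count
        pos = m.end()
    return counts


def format_formula(counts: Dict[str, int]) -> str:
    """Format element counts canonically (Hill order: C, H, then alphabetical)."""
    elements = sorted(counts)
    if "C" in counts:
        elements = ["C"] + (["H"] if "H" in counts else []) + [
            e for e in elements if e not in ("C", "H")
        ]
    parts = []
    for e in elements:
        n = counts[e]
        if n <= 0:
            continue
        parts.append(e if n == 1 else f"{e}{n}")
    return "".join(parts)


def molecular_weight(formula: str | Dict[str, int]) -> float:
    """Molar mass in g/mol of a formula string or element-count map."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    try:
        return sum(ATOMIC_WEIGHTS[e] * n for e, n in counts.items())
    except KeyError as exc:
        raise FormulaError(format_formula(counts), 0, f"unknown element {exc.args[0]!r}") from exc


@dataclass
class Metabolite:
    """A chemical species in a specific compartment.

    ``formula`` may be ``None`` for pseudo-species (e.g. biomass); such
    metabolites make the reactions touching them unverifiable, not balanced.
    Compartment ids follow the c/p/e (cytoplasm, periplasm, extracellular)
    convention and metabolite ids carry a matching ``_c``/``_p``/``_e`` suffix.
    """

    id: str
    name: str = ""
    formula: Optional[str] = None
    charge: int = 0
    compartment: str = "c"

    @property
    def elements(self) -> Optional[Dict[str, int]]:
        return None if self.formula is None else parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and a GPR rule.

    Stoichiometry maps metabolite id to a signed coefficient (negative =
    substrate).  Bounds are in mmol·gDW⁻¹·h⁻¹; a reaction is reversible iff
    its lower bound is negative.  An empty GPR marks an orphan reaction,
    treated as supported under every expression state.
    """

    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: GPR = field(default_factory=GPR)
    subsystem: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_boundary(self) -> bool:
        """True for single-metabolite (exchange/demand/sink) reactions."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class Model:
    """A genome-scale metabolic model.

    All id namespaces (metabolites, reactions, genes) are unique; every
    stoichiometry key resolves to a declared metabolite, every GPR leaf to a
    declared gene, and ``objective_id`` to a declared reaction.
    :meth:`validate` checks these invariants and lists *all* offenders.
    """

    id: str = "model"
    compartments: Set[str] = field(default_factory=lambda: {"c", "p", "e"})
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    genes: Set[str] = field(default_factory=set)
    objective_id: Optional[str] = None

    # -- lookups ---------------------------------------------------------

    @property
    def metabolite_map(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reaction_map(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    # -- boundary classification -----------------------------------------

    def is_exchange(self, reaction: Reaction | str) -> bool:
        """True iff the reaction touches exactly one metabolite and it is extracellular."""
        rxn = self.reaction(reaction) if isinstance(reaction, str) else reaction
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        met = self.metabolite_map.get(met_id)
        return met is not None and met.compartment == "e"

    @property
    def exchanges(self) -> List[Reaction]:
        mets = self.metabolite_map
        out = []
        for r in self.reactions:
            if len(r.stoichiometry) == 1:
                (met_id,) = r.stoichiometry
                m = mets.get(met_id)
                if m is not None and m.compartment == "e":
                    out.append(r)
        return out

    @property
    def exchange_ids(self) -> Set[str]:
        return {r.id for r in self.exchanges}

    # -- mutation --------------------------------------------------------

    def copy(self) -> "Model":
        return Model(
            id=self.id,
            compartments=set(self.compartments),
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=set(self.genes),
            objective_id=self.objective_id,
        )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolite_map:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites.append(met)

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reaction_map:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        self.reactions.append(rxn)
        self.genes.update(rxn.gpr.genes)

    def remove_reactions(self, rxn_ids: Iterable[str]) -> None:
        drop = set(rxn_ids)
        missing = drop - {r.id for r in self.reactions}
        if missing:
            raise ModelError(f"cannot remove unknown reactions: {sorted(missing)}")
        self.reactions = [r for r in self.reactions if r.id not in drop]

    # -- validation ------------------------------------------------------

    def validate(self) -> "Model":
        problems: List[str] = []
        seen_m: Set[str] = set()
        for m in self.metabolites:
            if m.id in seen_m:
                problems.append(f"duplicate metabolite id {m.id!r}")
            seen_m.add(m.id)
            if m.compartment not in self.compartments:
                problems.append(
                    f"metabolite {m.id!r} in undeclared compartment {m.compartment!r}"
                )
            if m.formula is not None:
                try:
                    parse_formula(m.formula)
                except FormulaError as exc:
                    problems.append(f"metabolite {m.id!r}: {exc}")
        seen_r: Set[str] = set()
        for r in self.reactions:
            if r.id in seen_r:
                problems.append(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            if not r.stoichiometry:
                problems.append(f"reaction {r.id!r} has empty stoichiometry")
            for met_id in r.stoichiometry:
                if met_id not in seen_m and met_id not in self.metabolite_map:
                    problems.append(
                        f"reaction {r.id!r} references unknown metabolite {met_id!r}"
                    )
            for g in r.gpr.genes:
                if g not in self.genes:
                    problems.append(f"reaction {r.id!r} GPR references unknown gene {g!r}")
            if r.lower_bound > r.upper_bound:
                problems.append(f"reaction {r.id!r} has lower bound > upper bound")
        if self.objective_id is not None and self.objective_id not in seen_r:
            problems.append(f"objective {self.objective_id!r} is not a declared reaction")
        if problems:
            raise ModelError(
                f"model {self.id!r} failed validation with {len(problems)} problem(s):\n  "
                + "\n  ".join(problems)
            )
        return self


@dataclass
class Medium:
    """An in-silico medium: maximum uptake rate per exchange reaction.

    Rates are non-negative (mmol·gDW⁻¹·h⁻¹); applying a medium sets the lower
    bound of each listed exchange to minus its rate and closes the uptake of
    every other exchange, leaving secretion (upper) bounds untouched.
    """

    uptakes: Dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        bad = {k: v for k, v in self.uptakes.items() if v < 0}
        if bad:
            raise ModelError(f"negative uptake rates in medium: {bad}")

    def validate_for(self, model: Model) -> "Medium":
        exch = model.exchange_ids
        unknown = sorted(set(self.uptakes) - exch)
        if unknown:
            raise ModelError(
                f"medium lists non-exchange or unknown reactions: {unknown}"
            )
        return self

    def without(self, *components: str) -> "Medium":
        """A copy of the medium with the given exchange ids removed."""
        return Medium(
            {k: v for k, v in self.uptakes.items() if k not in set(components)},
            name=self.name,
        )

    def copy(self) -> "Medium":
        return Medium(dict(self.uptakes), name=self.name)


# ---------------------------------------------------------------------------
# Balance checking
# ---------------------------------------------------------------------------

@dataclass
class BalanceResult:
    """Outcome of an elemental/charge balance check on one reaction.

    ``status`` is one of ``balanced``, ``unbalanced``, ``skipped`` (boundary
    reactions, which are net importers/exporters by design) or
    ``unverifiable`` (some participant lacks a formula).
    """

    reaction_id: str
    status: str
    element_imbalance: Dict[str, float] = field(default_factory=dict)
    charge_imbalance: float = 0.0

    @property
    def is_balanced(self) -> bool:
        return self.status == "balanced"


def check_reaction_balance(
    reaction: Reaction,
    metabolites: Dict[str, Metabolite],
    tol: float = 1e-9,
) -> BalanceResult:
    """Per-element and charge imbalance of one reaction.

    For each element e, imbalance(e) = Σ_i coeff_i × count_i(e) over the
    reaction's stoichiometry, and likewise for charge; a perfectly balanced
    reaction has an all-zero ledger.  Boundary (single-metabolite) reactions
    are exempt and reported as skipped.
    """
    if reaction.is_boundary:
        return BalanceResult(reaction.id, "skipped")
    elements: Dict[str, float] = {}
    charge = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        met = metabolites.get(met_id)
        if met is None or met.formula is None:
            return BalanceResult(reaction.id, "unverifiable")
        for e, n in parse_formula(met.formula).items():
            elements[e] = elements.get(e, 0.0) + coeff * n
        charge += coeff * met.charge
    imbalance = {e: v for e, v in elements.items() if abs(v) > tol}
    if abs(charge) <= tol:
        charge = 0.0
    status = "balanced" if not imbalance and charge == 0.0 else "unbalanced"
    return BalanceResult(reaction.id, status, imbalance, charge)


def check_model_balance(model: Model, tol: float = 1e-9) -> Dict[str, BalanceResult]:
    """Balance check for every reaction of the model, keyed by reaction id."""
    mets = model.metabolite_map
    return {r.id: check_reaction_balance(r, mets, tol=tol) for r in model.reactions}


# ---------------------------------------------------------------------------
# Dead-end detection
# ---------------------------------------------------------------------------

def _producers_consumers(model: Model) -> Tuple[Dict[str, Set[str]], Dict[str, Set[str]]]:
    producers: Dict[str, Set[str]] = {m.id: set() for m in model.metabolites}
    consumers: Dict[str, Set[str]] = {m.id: set() for m in model.metabolites}
    for r in model.reactions:
        for met_id, coeff in r.stoichiometry.items():
            forward_produces = coeff > 0
            # forward direction allowed whenever ub > 0, backward whenever lb < 0
            if r.upper_bound > 0:
                (producers if forward_produces else consumers)[met_id].add(r.id)
            if r.lower_bound < 0:
                (consumers if forward_produces else producers)[met_id].add(r.id)
    return producers, consumers


def find_dead_end_metabolites(model: Model) -> Set[str]:
    """Metabolites that are only produced or only consumed across all reactions.

    Reversible reactions count as both producer and consumer of each
    participant.  A metabolite touched by no reaction at all is also reported
    (it is trivially dead).
    """
    producers, consumers = _producers_consumers(model)
    dead = set()
    for met_id in producers:
        has_p, has_c = bool(producers[met_id]), bool(consumers[met_id])
        if has_p != has_c or (not has_p and not has_c):
            dead.add(met_id)
    return dead


def dead_end_report(model: Model) -> Tuple[Set[str], Set[str]]:
    """Dead-end metabolites plus the reactions touching them (dead-end reactions)."""
    dead = find_dead_end_metabolites(model)
    reactions = {
        r.id for r in model.reactions if any(m in dead for m in r.stoichiometry)
    }
    return dead, reactions
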