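"""Assembly of biomass objective reactions and ATP maintenance costs.

A biomass reaction drains the monomeric precursors of one gram of cell dry
weight (gDW) in experimentally derived proportions; its flux is the specific
growth rate (h⁻¹).  The composition is specified hierarchically: grams of
each macromolecule class (protein, RNA, carbohydrate, ...) per gDW, then
mole fractions of monomers within each class.  The stoichiometric
coefficient of monomer *i* of class *c* is

    coeff_i = 1000 · f_c · x_i / Σ_j x_j · MW_j      [mmol · gDW⁻¹]

with ``f_c`` the class mass fraction, ``x_i`` the mole fraction and ``MW_j``
molar masses in g/mol, so that Σ |coeff_i| · MW_i = 1000 mg per gDW exactly —
one gram of dry weight per unit of biomass flux.

Energy costs enter in two ways: growth-associated maintenance (GAM, mmol ATP
hydrolysed per gDW formed) is folded into the biomass reaction itself, while
non-growth-associated maintenance (NGAM, mmol ATP·gDW⁻¹·h⁻¹) is a standalone
ATP drain with a forced lower bound, which doubles as the maximisable
objective when simulating the energy-driven attack phase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import yaml

from .core import Metabolite, Model, ModelError, Reaction

__all__ = [
    "BiomassComposition",
    "CURRENCY",
    "build_biomass_reaction",
    "install_biomass",
    "install_ngam",
]

#: Default ids of the cytoplasmic ATP-hydrolysis currency metabolites.
CURRENCY = {"atp": "atp_c", "adp": "adp_c", "pi": "pi_c", "h2o": "h2o_c", "h": "h_c"}


@dataclass
class BiomassComposition:
    """Macromolecular composition of one gram of cell dry weight.

    ``class_fractions``: g per gDW per macromolecule class (must sum to 1);
    ``monomer_fractions``: per class, mole fraction per monomer metabolite id
    (each class sums to 1); ``monomer_weights``: molar mass per monomer in
    g/mol; ``gam``/``ngam``: ATP maintenance as described in the module
    docstring.
    """

    class_fractions: Dict[str, float]
    monomer_fractions: Dict[str, Dict[str, float]]
    monomer_weights: Dict[str, float]
    gam: float = 0.0
    ngam: float = 0.0

    TOL = 1e-6

    def validate(self) -> "BiomassComposition":
        problems = []
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > self.TOL:
            problems.append(f"class fractions sum to {total}, expected 1")
        for cls, fracs in self.monomer_fractions.items():
            if cls not in self.class_fractions:
                problems.append(f"monomer table for undeclared class {cls!r}")
            s = sum(fracs.values())
            if abs(s - 1.0) > self.TOL:
                problems.append(f"class {cls!r} mole fractions sum to {s}, expected 1")
            for mon in fracs:
                w = self.monomer_weights.get(mon)
                if w is None:
                    problems.append(f"no molar mass for monomer {mon!r}")
                elif w <= 0:
                    problems.append(f"non-positive molar mass for monomer {mon!r}")
        missing = set(self.class_fractions) - set(self.monomer_fractions)
        if missing:
            problems.append(f"classes without monomer tables: {sorted(missing)}")
        if self.gam < 0 or self.ngam < 0:
            problems.append("gam and ngam must be non-negative")
        if problems:
            raise ModelError(
                "invalid biomass composition:\n  " + "\n  ".join(problems)
            )
        return self

    # -- config file round-trip -----------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "BiomassComposition":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            class_fractions=dict(data["class_fractions"]),
            monomer_fractions={k: dict(v) for k, v in data["monomer_fractions"].items()},
            monomer_weights=dict(data["monomer_weights"]),
            gam=float(data.get("gam", 0.0)),
            ngam=float(data.get("ngam", 0.0)),
        ).validate()

    def to_yaml(self, path) -> None:
        data = {
            "class_fractions": self.class_fractions,
            "monomer_fractions": self.monomer_fractions,
            "monomer_weights": self.monomer_weights,
            "gam": self.gam,
            "ngam": self.ngam,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def monomer_coefficients(composition: BiomassComposition) -> Dict[str, float]:
    """Demand (positive mmol/gDW) per monomer, before sign flip and GAM."""
    composition.validate()
    coeffs: Dict[str, float] = {}
    for cls, f_c in composition.class_fractions.items():
        fracs = composition.monomer_fractions[cls]
        denom = sum(x * composition.monomer_weights[m] for m, x in fracs.items())
        if denom <= 0:
            raise ModelError(f"class {cls!r} has zero total molar mass")
        for mon, x in fracs.items():
            coeffs[mon] = coeffs.get(mon, 0.0) + 1000.0 * f_c * x / denom
    return coeffs


def build_biomass_reaction(
    composition: BiomassComposition,
    model: Optional[Model] = None,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass_c",
    currency: Optional[Dict[str, str]] = None,
) -> Reaction:
    """Assemble the biomass reaction from a composition.

    Monomers are consumed at the coefficients described in the module
    docstring; GAM is appended as ``gam × (atp + h2o → adp + pi + h)``; the
    product side is one unit of a biomass pseudo-metabolite, to be drained by
    a boundary reaction so the objective is an ordinary column of S.

    If ``model`` is given, every monomer id must resolve in it.
    """
    currency = dict(CURRENCY, **(currency or {}))
    coeffs = monomer_coefficients(composition)
    if model is not None:
        known = set(model.metabolite_map)
        unknown = sorted(set(coeffs) - known)
        if unknown:
            raise ModelError(f"biomass monomers not in model: {unknown}")
    stoich: Dict[str, float] = {mon: -c for mon, c in coeffs.items()}
    if composition.gam > 0:
        g = composition.gam
        for met, sign in (("atp", -1), ("h2o", -1), ("adp", 1), ("pi", 1), ("h", 1)):
            mid = currency[met]
            stoich[mid] = stoich.get(mid, 0.0) + sign * g
    stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        name="Biomass objective function",
        stoichiometry={k: v for k, v in stoich.items() if v != 0.0},
        lower_bound=0.0,
        upper_bound=1000.0,
        subsystem="Biomass and maintenance",
    )


def install_biomass(
    model: Model,
    composition: BiomassComposition,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass_c",
    drain_id: str = "DM_biomass_c",
    set_objective: bool = True,
) -> Model:
    """Add biomass pseudo-metabolite, biomass reaction and drain to a copy."""
    out = model.copy()
    if biomass_metabolite not in out.metabolite_map:
        out.add_metabolite(
            Metabolite(biomass_metabolite, name="biomass", formula=None, compartment="c")
        )
    out.add_reaction(build_biomass_reaction(composition, out, reaction_id, biomass_metabolite))
    out.add_reaction(
        Reaction(
            id=drain_id,
            name="Biomass drain",
            stoichiometry={biomass_metabolite: -1.0},
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="Biomass and maintenance",
        )
    )
    if set_objective:
        out.objective_id = reaction_id
    return out.validate()


def install_ngam(
    model: Model,
    ngam: float,
    reaction_id: str = "ATPM",
    currency: Optional[Dict[str, str]] = None,
) -> Model:
    """Install non-growth maintenance as a forced ATP drain on a copy.

    Adds (or updates) ``ATPM: atp + h2o → adp + pi + h`` with lower bound
    ``ngam`` so every feasible state hydrolyses at least that much ATP.  The
    same reaction is the maximisable objective for attack-phase simulations.
    """
    if ngam < 0:
        raise ModelError("ngam must be non-negative")
    currency = dict(CURRENCY, **(currency or {}))
    missing = [mid for mid in currency.values() if mid not in model.metabolite_map]
    if missing:
        raise ModelError(f"currency metabolites missing from model: {sorted(missing)}")
    out = model.copy()
    stoich = {
        currency["atp"]: -1.0,
        currency["h2o"]: -1.0,
        currency["adp"]: 1.0,
        currency["pi"]: 1.0,
        currency["h"]: 1.0,
    }
    existing = out.reaction_map.get(reaction_id)
    if existing is not None:
        existing.stoichiometry = stoich
        existing.lower_bound = float(ngam)
    else:
        out.add_reaction(
            Reaction(
                id=reaction_id,
                name="ATP maintenance requirement",
                stoichiometry=stoich,
                lower_bound=float(ngam),
                upper_bound=1000.0,
                subsystem="Biomass and maintenance",
            )
        )
    return out.validate()
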