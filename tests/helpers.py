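"""Test-side oracles and random model generators.

cobra (with the GLPK backend) acts as the *independent* constraint-based
stack: models travel to it through the package's own SBML writer, so the
oracle cross-validates serialisation as well as the LP answers.  Nothing in
the package itself imports cobra.
"""

from __future__ import annotations

import os
import tempfile
from typing import Dict, Optional, Set, Tuple

import numpy as np

import phasegem as pg
from phasegem.core import Metabolite, Model, Reaction


# ---------------------------------------------------------------------------
# Random LP-scale toy models (bounded by construction)
# ---------------------------------------------------------------------------

def random_lp_model(rng: np.random.Generator, max_reactions: int = 20) -> Model:
    """A random small metabolic network with finite bounds.

    Metabolites live in a single extracellular-free compartment layout:
    a couple of exchange-like boundary columns plus random sparse internal
    conversions.  All bounds are finite, so FBA is never unbounded; the zero
    flux vector may or may not be feasible depending on forced lower bounds.
    """
    n_mets = int(rng.integers(2, 9))
    n_rxns = int(rng.integers(3, max_reactions + 1))
    model = Model(id="random", compartments={"c", "e"})
    for i in range(n_mets):
        model.add_metabolite(Metabolite(f"m{i}_c", compartment="c"))
    for j in range(n_rxns):
        k = int(rng.integers(1, min(4, n_mets) + 1))
        mets = rng.choice(n_mets, size=k, replace=False)
        coeffs = rng.integers(-3, 4, size=k)
        stoich = {f"m{int(i)}_c": float(c) for i, c in zip(mets, coeffs) if c != 0}
        if not stoich:
            stoich = {f"m{int(mets[0])}_c": 1.0}
        reversible = rng.random() < 0.5
        lb = float(-rng.integers(0, 21)) if reversible else 0.0
        ub = float(rng.integers(1, 21))
        model.add_reaction(Reaction(f"r{j}", stoichiometry=stoich,
                                    lower_bound=lb, upper_bound=ub))
    model.objective_id = f"r{int(rng.integers(n_rxns))}"
    return model.validate()


# ---------------------------------------------------------------------------
# Random generator specs for screening oracles
# ---------------------------------------------------------------------------

def random_toy_spec(seed: int) -> pg.ToySpec:
    """A random ToySpec that always yields a viable (rich-medium) model.

    Branches 0 and 1 (one pyruvate-family, one glutamate-family) are never
    deleted: the glutamate branch fuels growth on the glucose-free rich
    medium and the pyruvate branch keeps the anaplerotic entry point, so
    every *intact* branch stays synthesizable and the designed deletions are
    exactly the auxotrophies.  Every spec contains at least one
    isoenzyme-duplicated step (designed redundancy).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    n = int(rng.integers(4, 8))
    candidates = [k for k in range(n) if k not in (0, 1)]
    n_del = int(rng.integers(1, min(3, len(candidates) - 1) + 1))
    deleted = frozenset(int(x) for x in rng.choice(candidates, size=n_del, replace=False))
    intact = [k for k in range(n) if k not in deleted]
    iso_branch = int(rng.choice(intact))
    iso = frozenset({(iso_branch, int(rng.integers(1, 3)))})
    complex_choices = [k for k in intact if k != iso_branch]
    cplx = frozenset()
    if complex_choices and rng.random() < 0.7:
        cplx = frozenset({(int(rng.choice(complex_choices)), int(rng.integers(1, 3)))})
    return pg.ToySpec(
        n_biosynthesis_branches=n,
        deleted_branches=deleted,
        isoenzyme_steps=iso,
        complex_steps=cplx,
        add_dead_ends=int(rng.integers(0, 4)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# cobra/GLPK oracle
# ---------------------------------------------------------------------------

def to_cobra(model: Model):
    """Convert through the package's SBML writer into a cobra model (GLPK)."""
    import cobra

    with tempfile.TemporaryDirectory() as tmp:
        path = os.path.join(tmp, "model.xml")
        pg.write_model(model, path, format="sbml")
        cm = cobra.io.read_sbml_model(path)
    cm.solver = "glpk"
    return cm


def cobra_fba(model: Model, objective_id: Optional[str] = None) -> Tuple[str, Optional[float]]:
    """Independent FBA: returns (status, objective value)."""
    cm = to_cobra(model)
    if objective_id is not None:
        cm.objective = cm.reactions.get_by_id(objective_id)
    sol = cm.optimize()
    if sol.status != "optimal":
        return sol.status, None
    return "optimal", float(sol.objective_value)


def cobra_essential_set(
    model: Model,
    threshold: float,
    objective_id: str,
    candidates,
) -> Set[str]:
    """Exhaustive single-reaction deletion with the independent stack."""
    cm = to_cobra(model)
    cm.objective = cm.reactions.get_by_id(objective_id)
    wt = cm.slim_optimize()
    essential = set()
    for rid in candidates:
        rxn = cm.reactions.get_by_id(rid)
        old = rxn.bounds
        rxn.bounds = (0.0, 0.0)
        mutant = cm.slim_optimize()
        rxn.bounds = old
        if mutant is None or np.isnan(mutant):
            mutant = 0.0
        if max(0.0, mutant) / wt < threshold:
            essential.add(rid)
    return essential
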