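"""Expression-constrained extraction of growth-phase-specific models.

Given a phase medium, a phase objective (ATP maintenance for the attack
phase, biomass for the growth phase) and an RNA-seq profile, a reduced model
is extracted in the style of expression-penalty methods: reactions whose GPR
evaluates false under the set of expressed genes are *unsupported*; the LP
minimises total absolute flux through unsupported reactions while the
objective is held at a fraction of its optimum, and unsupported reactions
that cannot carry flux in any penalty-optimal solution are removed, followed
by pruning of reactions blocked under the phase medium.  The reduction is
conservative: a reaction used by *some* penalty-optimal flux state is kept.

Genes count only as expressed/not expressed (threshold 10 RPKM by default,
or a top-quartile percentile rule); expression magnitudes are never used as
continuous penalties.  Orphan reactions and exchanges carry no expression
evidence and are never penalised or removed for lack of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .core import Medium, Model, ModelError
from .lp import (
    FLUX_CLEAN_TOL,
    StoichiometricSystem,
    apply_medium,
    fba,
    flux_variability,
)

__all__ = [
    "ExpressionProfile",
    "ConditionModel",
    "classify_expressed",
    "reduce_model",
    "diff_models",
]

#: RPKM threshold above which a gene counts as expressed.
DEFAULT_RPKM_THRESHOLD = 10.0
#: Relative slack allowed on the minimum penalty when probing flux ranges.
PENALTY_SLACK = 1e-6


@dataclass
class ExpressionProfile:
    """A gene → RPKM table for one condition (e.g. AP or GP).

    Gene ids need not all exist in the model; extras are ignored (their
    count is reported by the reduction log).  RPKM values are non-negative.
    """

    values: Dict[str, float]
    condition: str = ""

    def __post_init__(self):
        bad = {g: v for g, v in self.values.items() if v < 0}
        if bad:
            raise ModelError(f"negative RPKM values: {bad}")

    @classmethod
    def from_tsv(cls, path, condition: str = "") -> "ExpressionProfile":
        df = pd.read_csv(path, sep="\t")
        gene_col, value_col = df.columns[0], df.columns[1]
        return cls(
            {str(r[gene_col]): float(r[value_col]) for _, r in df.iterrows()},
            condition=condition,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.values.items()), columns=["gene", "rpkm"]
        ).to_csv(path, sep="\t", index=False)


def classify_expressed(
    profile: ExpressionProfile,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
    mode: str = "absolute",
) -> Set[str]:
    """Genes considered expressed.

    ``absolute`` mode (default): RPKM ≥ threshold, boundary inclusive.
    ``percentile`` mode: the top quartile of the profile by value (ties
    broken by gene id), the alternative reading of a first-quartile rule.
    """
    if threshold < 0:
        raise ModelError("expression threshold must be non-negative")
    if not profile.values:
        import warnings

        warnings.warn("empty expression profile: no genes classified as expressed")
        return set()
    if mode == "absolute":
        return {g for g, v in profile.values.items() if v >= threshold}
    if mode == "percentile":
        n = len(profile.values)
        k = max(1, int(n * 0.25))
        ranked = sorted(profile.values.items(), key=lambda item: (-item[1], item[0]))
        return {g for g, _ in ranked[:k]}
    raise ModelError(f"unknown classification mode {mode!r}")


@dataclass
class ConditionModel:
    """A reduced, condition-specific model plus removal provenance.

    ``removed`` maps each removed reaction id to its reason:
    ``unsupported-zero-flux`` (no penalty-optimal flux state uses it) or
    ``blocked-after-pruning`` (cannot carry flux under the phase medium).
    The reduced model is a sub-network of the source and attains at least
    ``objective_fraction`` of the source optimum under the phase medium.
    """

    model: Model
    removed: Dict[str, str]
    source_model_id: str
    condition: str
    objective_id: str
    objective_fraction: float
    expression_threshold: float
    source_optimum: float
    reduced_optimum: float
    unexpressed_unsupported: List[str] = field(default_factory=list)
    ignored_genes: int = 0

    @property
    def removed_unsupported(self) -> Set[str]:
        return {r for r, why in self.removed.items() if why == "unsupported-zero-flux"}

    @property
    def removed_blocked(self) -> Set[str]:
        return {r for r, why in self.removed.items() if why == "blocked-after-pruning"}

    def removal_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.removed.items()), columns=["reaction", "reason"]
        )
        return df


def unsupported_reactions(model: Model, expressed: Set[str]) -> List[str]:
    """Reactions whose GPR evaluates false under the expressed gene set.

    Orphan reactions (empty GPR) and exchanges are excluded: they carry no
    expression evidence either way.
    """
    out = []
    for r in model.reactions:
        if r.gpr.is_empty or model.is_exchange(r):
            continue
        if not r.gpr.evaluate(expressed):
            out.append(r.id)
    return out


def _min_penalty(
    system: StoichiometricSystem,
    unsupported_idx: List[int],
    objective_idx: int,
    required: float,
) -> Tuple[float, np.ndarray]:
    """Minimise Σ|v_j| over unsupported j with the objective held ≥ required.

    Uses auxiliary variables t_j ≥ |v_j|; returns (P*, t-coefficient row)."""
    n = len(system.rxn_ids)
    k = len(unsupported_idx)
    # inequality rows: -t_j + v_j <= 0 ; -t_j - v_j <= 0 ; -v_obj <= -required
    rows = []
    for pos, j in enumerate(unsupported_idx):
        r1 = np.zeros(n + k)
        r1[j] = 1.0
        r1[n + pos] = -1.0
        rows.append(r1)
        r2 = np.zeros(n + k)
        r2[j] = -1.0
        r2[n + pos] = -1.0
        rows.append(r2)
    robj = np.zeros(n + k)
    robj[objective_idx] = -1.0
    rows.append(robj)
    A_ub = np.vstack(rows)
    b_ub = np.concatenate([np.zeros(2 * k), [-required]])
    c = np.zeros(n + k)
    c[n:] = 1.0
    status, x, obj = system.solve(
        c, sense="min", A_ub=A_ub, b_ub=b_ub,
        extra_cols=k, extra_bounds=[(0.0, None)] * k,
    )
    if status != "optimal":
        raise ModelError(f"penalty minimisation LP is {status}")
    return float(obj), (A_ub, b_ub)


def _budgeted_range(
    system: StoichiometricSystem,
    A_ub: np.ndarray,
    b_ub: np.ndarray,
    budget_row: np.ndarray,
    budget: float,
    j: int,
    k: int,
) -> float:
    """max |v_j| subject to steady state, bounds, objective and penalty budget."""
    n = len(system.rxn_ids)
    A = np.vstack([A_ub, budget_row])
    b = np.concatenate([b_ub, [budget]])
    best = 0.0
    c = np.zeros(n + k)
    c[j] = 1.0
    for sense in ("max", "min"):
        status, _, val = system.solve(
            c, sense=sense, A_ub=A, b_ub=b,
            extra_cols=k, extra_bounds=[(0.0, None)] * k,
        )
        if status == "optimal":
            best = max(best, abs(float(val)))
    return best


def reduce_model(
    model: Model,
    expressed: Set[str],
    condition_medium: Medium,
    objective_id: Optional[str] = None,
    fraction: float = 0.9,
    condition: str = "",
    expression_threshold: float = DEFAULT_RPKM_THRESHOLD,
    ignored_genes: int = 0,
) -> ConditionModel:
    """Extract a condition-specific sub-model.

    Steps: (1) collect unsupported reactions U (GPR false under
    ``expressed``; orphans and exchanges exempt); (2) minimise the summed
    absolute flux through U subject to the steady state, the phase medium
    and ``v_objective ≥ fraction × optimum``, giving the minimum penalty P*;
    (3) probe each j ∈ U for its maximum |v_j| under a penalty budget of
    P*(1 + 1e−6) and remove those that can carry none (< 1e−9) — i.e. the
    reactions no penalty-optimal flux state uses; (4) iteratively prune
    reactions blocked under the phase medium until a fixpoint; (5) verify
    the reduced model still attains fraction × optimum.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ModelError("objective fraction must lie in [0, 1]")
    constrained = apply_medium(model, condition_medium)
    objective_id = objective_id or constrained.objective_id
    if objective_id is None:
        raise ModelError("no objective reaction for the condition")
    base = fba(constrained, objective_id=objective_id)
    if not base.ok or base.objective_value <= 0:
        raise ModelError(
            f"model is not functional under the condition medium: "
            f"status {base.status}, optimum {base.objective_value}"
        )
    optimum = base.objective_value
    required = fraction * optimum

    U = unsupported_reactions(constrained, expressed)
    removed: Dict[str, str] = {}

    if U:
        system = StoichiometricSystem(constrained)
        uidx = [system.rxn_index[r] for r in U]
        oidx = system.rxn_index[objective_id]
        p_star, (A_ub, b_ub) = _min_penalty(system, uidx, oidx, required)
        budget = p_star * (1.0 + PENALTY_SLACK)
        # The removal cutoff absorbs the budget slack: a reaction outside
        # every minimum-penalty support can still show flux up to the slack
        # (budget − P*), so the cutoff must sit just above it.
        cutoff = FLUX_CLEAN_TOL + (budget - p_star)
        n, k = len(system.rxn_ids), len(uidx)
        budget_row = np.zeros(n + k)
        budget_row[n:] = 1.0
        for pos, rid in enumerate(U):
            width = _budgeted_range(
                system, A_ub, b_ub, budget_row, budget, uidx[pos], k
            )
            if width < cutoff:
                removed[rid] = "unsupported-zero-flux"

    reduced = constrained.copy()
    reduced.objective_id = objective_id  # the phase objective survives pruning
    reduced.remove_reactions(list(removed))

    # iterative blocked-reaction pruning under the condition medium
    while True:
        fva = flux_variability(reduced, objective_fraction=0.0)
        blocked = [
            rid for rid, (lo, hi) in fva.items()
            if abs(lo) < FLUX_CLEAN_TOL and abs(hi) < FLUX_CLEAN_TOL
            and rid != objective_id
        ]
        if not blocked:
            break
        for rid in blocked:
            removed[rid] = "blocked-after-pruning"
        reduced.remove_reactions(blocked)

    verify = fba(reduced, objective_id=objective_id)
    if not verify.ok or verify.objective_value + 1e-6 < required:
        raise ModelError(
            "internal error: reduced model lost functionality "
            f"({verify.objective_value} < {required})"
        )
    reduced.id = f"{model.id}_{condition or 'reduced'}"
    reduced.objective_id = objective_id
    return ConditionModel(
        model=reduced,
        removed=removed,
        source_model_id=model.id,
        condition=condition,
        objective_id=objective_id,
        objective_fraction=fraction,
        expression_threshold=expression_threshold,
        source_optimum=optimum,
        reduced_optimum=float(verify.objective_value),
        unexpressed_unsupported=sorted(U),
        ignored_genes=ignored_genes,
    )


def reduce_from_profile(
    model: Model,
    profile: ExpressionProfile,
    condition_medium: Medium,
    objective_id: Optional[str] = None,
    fraction: float = 0.9,
    threshold: float = DEFAULT_RPKM_THRESHOLD,
    mode: str = "absolute",
) -> ConditionModel:
    """Convenience wrapper: classify expression, log extras, then reduce."""
    expressed = classify_expressed(profile, threshold=threshold, mode=mode)
    ignored = len(set(profile.values) - model.genes)
    return reduce_model(
        model,
        expressed & model.genes,
        condition_medium,
        objective_id=objective_id,
        fraction=fraction,
        condition=profile.condition,
        expression_threshold=threshold,
        ignored_genes=ignored,
    )


def diff_models(a: ConditionModel, b: ConditionModel) -> Dict[str, Set[str]]:
    """Exact reaction-set differences between two reductions of one source."""
    if a.source_model_id != b.source_model_id:
        raise ModelError(
            f"cannot diff reductions of different sources: "
            f"{a.source_model_id!r} vs {b.source_model_id!r}"
        )
    ra = {r.id for r in a.model.reactions}
    rb = {r.id for r in b.model.reactions}
    return {"a_only": ra - rb, "b_only": rb - ra, "shared": ra & rb}
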