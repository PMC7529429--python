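"""The linear-programming core: FBA, FVA, media and deletion screens.

Flux balance analysis (FBA) optimises the flux ``v_objective`` of one
reaction subject to the steady-state mass balance ``S·v = 0`` — each row of
the stoichiometric matrix S is a metabolite, each column a reaction — and
per-reaction capacity bounds ``α ≤ v ≤ β``.  All solves go through scipy's
HiGHS backend.

Two numerical conventions used throughout the package are fixed here:
reported fluxes below 1e-9 in magnitude are cleaned to exactly zero (which
stabilises downstream zero-flux classification), and growth is compared
against an absolute tolerance of 1e-6 h⁻¹ when deciding "does not grow".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

from .core import Medium, Model, ModelError

__all__ = [
    "FLUX_CLEAN_TOL",
    "GROWTH_TOL",
    "StoichiometricSystem",
    "FluxSolution",
    "EssentialityResult",
    "build_system",
    "fba",
    "flux_variability",
    "apply_medium",
    "single_reaction_deletion",
]

#: Reported fluxes with |v| below this are rounded to exactly zero.
FLUX_CLEAN_TOL = 1e-9
#: Absolute growth-rate tolerance (h⁻¹) for "the model does not grow".
GROWTH_TOL = 1e-6


@dataclass
class FluxSolution:
    """Result of one LP solve: status, objective value, and one flux per reaction."""

    status: str  # optimal | infeasible | unbounded
    objective_value: Optional[float]
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_id: Optional[str] = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class EssentialityResult:
    """Single-reaction deletion screen: per-reaction growth ratios and flags.

    A deletion is lethal (the reaction essential) when the mutant retains
    less than ``threshold`` (default 10%) of the wild-type objective value.
    """

    wild_type: float
    threshold: float
    objective_id: str
    rows: Dict[str, Dict[str, float]] = field(default_factory=dict)
    medium_name: str = ""
    skipped: List[str] = field(default_factory=list)

    @property
    def essential(self) -> set:
        return {rid for rid, row in self.rows.items() if row["essential"]}

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = "reaction"
        return df.sort_index()


class StoichiometricSystem:
    """Matrix form of a model: S (m×n), bounds, and cached LP machinery.

    Column j of S is reaction j's stoichiometry.  The system is built once
    per model and reused across the many solves of FVA, deletion screens and
    reduction, with per-solve bound overrides instead of model copies.
    """

    def __init__(self, model: Model):
        model.validate()
        self.model = model
        self.met_ids: List[str] = [m.id for m in model.metabolites]
        self.rxn_ids: List[str] = [r.id for r in model.reactions]
        self.met_index = {m: i for i, m in enumerate(self.met_ids)}
        self.rxn_index = {r: j for j, r in enumerate(self.rxn_ids)}
        m, n = len(self.met_ids), len(self.rxn_ids)
        S = np.zeros((m, n))
        for j, rxn in enumerate(model.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[self.met_index[met_id], j] = coeff
        self.S = S
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.S.shape

    def residual(self, v: np.ndarray) -> float:
        """‖S·v‖∞ — the steady-state feasibility certificate."""
        return float(np.max(np.abs(self.S @ v))) if len(v) else 0.0

    def solve(
        self,
        c: np.ndarray,
        sense: str = "min",
        lb: Optional[np.ndarray] = None,
        ub: Optional[np.ndarray] = None,
        A_ub: Optional[np.ndarray] = None,
        b_ub: Optional[np.ndarray] = None,
        extra_cols: int = 0,
        extra_bounds: Optional[Sequence[Tuple[float, float]]] = None,
    ) -> Tuple[str, Optional[np.ndarray], Optional[float]]:
        """Solve min/max c·x s.t. S·v = 0, bounds, and optional A_ub·x ≤ b_ub.

        ``extra_cols`` appends auxiliary variables (zero rows in S) — used by
        the reduction module's penalty formulation.  Returns
        ``(status, x, objective)`` with status optimal/infeasible/unbounded.
        """
        lb = self.lb if lb is None else lb
        ub = self.ub if ub is None else ub
        n = len(self.rxn_ids)
        A_eq = self.S
        if extra_cols:
            A_eq = np.hstack([self.S, np.zeros((self.S.shape[0], extra_cols))])
        bounds = [(lb[j], ub[j]) for j in range(n)]
        if extra_cols:
            bounds += list(extra_bounds or [(0.0, None)] * extra_cols)
        sign = 1.0 if sense == "min" else -1.0
        res = linprog(
            sign * c,
            A_eq=A_eq,
            b_eq=np.zeros(A_eq.shape[0]),
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds,
            method="highs",
        )
        if res.status == 0:
            return "optimal", res.x, sign * res.fun
        if res.status == 2:
            return "infeasible", None, None
        if res.status == 3:
            return "unbounded", None, None
        return "failed", None, None  # pragma: no cover - solver breakdown

    def objective_vector(self, rxn_id: str, extra_cols: int = 0) -> np.ndarray:
        c = np.zeros(len(self.rxn_ids) + extra_cols)
        c[self.rxn_index[rxn_id]] = 1.0
        return c


def build_system(model: Model) -> StoichiometricSystem:
    return StoichiometricSystem(model)


def _clean(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float).copy()
    v[np.abs(v) < FLUX_CLEAN_TOL] = 0.0
    return v


def fba(
    model: Model | StoichiometricSystem,
    objective_id: Optional[str] = None,
    direction: str = "max",
) -> FluxSolution:
    """Flux balance analysis: optimise one reaction's flux at steady state.

    Only the objective value is contract-stable; individual fluxes may be one
    of many alternate optima.  Infeasible or unbounded problems are reported
    in the status, not raised.
    """
    system = model if isinstance(model, StoichiometricSystem) else StoichiometricSystem(model)
    objective_id = objective_id or system.model.objective_id
    if objective_id is None:
        raise ModelError("no objective reaction given and the model declares none")
    if objective_id not in system.rxn_index:
        raise ModelError(f"objective reaction {objective_id!r} not in model")
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    status, x, obj = system.solve(system.objective_vector(objective_id), sense=direction)
    if status != "optimal":
        return FluxSolution(status, None, {}, objective_id,
                            message=f"FBA ({direction} {objective_id}) is {status}")
    x = _clean(x)
    return FluxSolution("optimal", float(obj), dict(zip(system.rxn_ids, x)), objective_id)


def flux_variability(
    model: Model | StoichiometricSystem,
    objective_fraction: float = 1.0,
    reactions: Optional[Iterable[str]] = None,
    objective_id: Optional[str] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction [min, max] flux, optionally holding the objective near-optimal.

    With ``objective_fraction > 0``, adds ``v_objective ≥ fraction × optimum``
    before scanning; with fraction ≤ 0 the objective constraint is dropped
    entirely and the scan explores the whole steady-state polytope.
    """
    system = model if isinstance(model, StoichiometricSystem) else StoichiometricSystem(model)
    objective_id = objective_id or system.model.objective_id
    A_ub = b_ub = None
    if objective_fraction > 0:
        if objective_id is None:
            raise ModelError("objective_fraction > 0 requires an objective reaction")
        sol = fba(system, objective_id=objective_id, direction="max")
        if not sol.ok:
            raise ModelError(
                f"cannot run FVA: FBA on {objective_id!r} is {sol.status}"
            )
        row = np.zeros(len(system.rxn_ids))
        row[system.rxn_index[objective_id]] = -1.0
        A_ub = row[None, :]
        b_ub = np.array([-objective_fraction * sol.objective_value])
    targets = list(reactions) if reactions is not None else list(system.rxn_ids)
    out: Dict[str, Tuple[float, float]] = {}
    for rid in targets:
        c = system.objective_vector(rid)
        lo_stat, _, lo = system.solve(c, sense="min", A_ub=A_ub, b_ub=b_ub)
        hi_stat, _, hi = system.solve(c, sense="max", A_ub=A_ub, b_ub=b_ub)
        if lo_stat != "optimal" or hi_stat != "optimal":
            raise ModelError(
                f"FVA subproblem for {rid!r} is {lo_stat}/{hi_stat} "
                "(infeasible after adding the objective constraint?)"
            )
        lo = 0.0 if abs(lo) < FLUX_CLEAN_TOL else float(lo)
        hi = 0.0 if abs(hi) < FLUX_CLEAN_TOL else float(hi)
        out[rid] = (min(lo, hi), max(lo, hi))
    return out


def apply_medium(model: Model, medium: Medium) -> Model:
    """Return a copy of the model constrained to the given medium.

    Listed exchanges get lower bound −uptake; every other exchange has its
    uptake closed (lower bound 0).  Secretion (upper) bounds are untouched
    and the input model is not modified.
    """
    medium.validate_for(model)
    out = model.copy()
    for rxn in out.reactions:
        if not out.is_exchange(rxn):
            continue
        if rxn.id in medium.uptakes:
            rxn.lower_bound = -float(medium.uptakes[rxn.id])
        else:
            rxn.lower_bound = max(0.0, rxn.lower_bound)
        if rxn.upper_bound < rxn.lower_bound:  # keep the bound pair sane
            rxn.upper_bound = rxn.lower_bound
    return out


def single_reaction_deletion(
    model: Model,
    threshold: float = 0.10,
    exclude_exchanges: bool = True,
    objective_id: Optional[str] = None,
    reactions: Optional[Iterable[str]] = None,
) -> EssentialityResult:
    """Screen every reaction by forcing its flux to zero and re-solving FBA.

    ``ratio = mutant/wild-type``; a reaction is essential iff the ratio drops
    below ``threshold``.  The objective reaction itself is always skipped,
    and exchange reactions are skipped by default.  A non-growing wild type
    (optimum ≤ 1e-6) cannot be screened and raises.
    """
    system = StoichiometricSystem(model)
    objective_id = objective_id or model.objective_id
    wt = fba(system, objective_id=objective_id)
    if not wt.ok or wt.objective_value <= GROWTH_TOL:
        raise ModelError(
            "cannot screen a non-growing model: wild-type objective is "
            f"{wt.objective_value if wt.ok else wt.status}"
        )
    exchange_ids = model.exchange_ids
    result = EssentialityResult(
        wild_type=wt.objective_value,
        threshold=threshold,
        objective_id=objective_id,
    )
    targets = list(reactions) if reactions is not None else list(system.rxn_ids)
    c = system.objective_vector(objective_id)
    for rid in targets:
        if rid == objective_id or (exclude_exchanges and rid in exchange_ids):
            result.skipped.append(rid)
            continue
        j = system.rxn_index[rid]
        lb, ub = system.lb.copy(), system.ub.copy()
        lb[j] = ub[j] = 0.0
        status, _, obj = system.solve(c, sense="max", lb=lb, ub=ub)
        mutant = max(0.0, float(obj)) if status == "optimal" else 0.0
        ratio = mutant / wt.objective_value
        result.rows[rid] = {
            "wild_type": wt.objective_value,
            "mutant": mutant,
            "ratio": ratio,
            "essential": ratio < threshold,
        }
    return result
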