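"""Near-uniform sampling of the steady-state flux polytope.

The feasible set {v : S·v = 0, α ≤ v ≤ β} of a (condition-specific) model is
explored with an artificial-centering hit-and-run (ACHR) Markov chain: warm-up
points are the extreme solutions of a flux-variability scan, each step picks
a direction through the running centre of all visited points, intersects the
chord with the flux bounds exactly, and draws the next point uniformly on the
chord.  No objective constraint is imposed — the sampler characterises the
whole solution space, independent of the objective used to build the model.
The per-reaction *median* of the sampled distribution is the reference flux
used when comparing metabolic phases.

Determinism: the chain is a pure function of (model, n_samples, seed,
thinning); identical inputs give bit-identical sample matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .core import Model, ModelError
from .lp import StoichiometricSystem

__all__ = ["SamplingResult", "sample", "reference_fluxes"]

#: tolerance for chord endpoints and degenerate (fixed) directions
CHORD_TOL = 1e-9
#: feasibility tolerance guaranteed for every emitted sample
FEASIBILITY_TOL = 1e-6


@dataclass
class SamplingResult:
    """A matrix of feasible flux vectors plus per-reaction summaries."""

    samples: np.ndarray  # n_samples × n_reactions
    reaction_ids: list
    seed: int
    thinning: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)

    def medians(self) -> Dict[str, float]:
        med = np.median(self.samples, axis=0)
        return dict(zip(self.reaction_ids, med.astype(float)))

    def quantiles(self, q) -> pd.DataFrame:
        return self.to_frame().quantile(q)


def _project_null(basis: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the null space of S (drift control)."""
    return basis @ (basis.T @ v)


def sample(
    model: Model,
    n_samples: int = 2000,
    seed: int = 0,
    thinning: int = 100,
    warmup_per_reaction: bool = True,
) -> SamplingResult:
    """ACHR sampling of the model's steady-state flux polytope.

    Keeps every ``thinning``-th chain point until ``n_samples`` rows are
    collected.  A zero-dimensional polytope (all flux ranges degenerate)
    returns the unique point ``n_samples`` times with a warning; an empty
    polytope raises.
    """
    if n_samples < 1:
        raise ModelError("n_samples must be positive")
    if thinning < 1:
        raise ModelError("thinning must be positive")
    system = StoichiometricSystem(model)
    n = len(system.rxn_ids)

    # Warm-up points: FVA extreme solutions (which certify non-emptiness).
    fva_points = []
    ranges = {}
    targets = system.rxn_ids if warmup_per_reaction else system.rxn_ids[:1]
    for rid in system.rxn_ids:
        c = system.objective_vector(rid)
        for sense in ("min", "max"):
            status, x, val = system.solve(c, sense=sense)
            if status != "optimal":
                raise ModelError(
                    f"flux polytope is empty or unbounded (FVA for {rid!r}: {status})"
                )
            if rid in targets:
                fva_points.append(x)
            ranges.setdefault(rid, []).append(float(val))

    widths = np.array([ranges[rid][1] - ranges[rid][0] for rid in system.rxn_ids])
    if np.all(widths < CHORD_TOL):
        warnings.warn("zero-dimensional flux polytope: returning the unique point")
        point = np.asarray(fva_points[0], dtype=float)
        samples = np.tile(point, (n_samples, 1))
        return SamplingResult(samples, list(system.rxn_ids), seed, thinning)

    W = np.asarray(fva_points, dtype=float)
    basis = null_space(system.S)
    if basis.size == 0:  # S has full column rank: polytope is a single point
        point = W[0]
        samples = np.tile(point, (n_samples, 1))
        return SamplingResult(samples, list(system.rxn_ids), seed, thinning)

    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    lb, ub = system.lb, system.ub
    center = W.mean(axis=0)
    x = W[rng.integers(len(W))].copy()

    samples = np.empty((n_samples, n), dtype=float)
    collected = 0
    step = 0
    while collected < n_samples:
        step += 1
        d = W[rng.integers(len(W))] - center
        norm = np.linalg.norm(d)
        if norm < CHORD_TOL:
            continue
        d = d / norm
        # exact chord limits against the box bounds
        tmax = np.inf
        tmin = -np.inf
        moving = np.abs(d) > CHORD_TOL
        if not np.any(moving):
            continue
        dm = d[moving]
        hi = (ub[moving] - x[moving]) / dm
        lo = (lb[moving] - x[moving]) / dm
        upper = np.where(dm > 0, hi, lo)
        lower = np.where(dm > 0, lo, hi)
        tmax = float(np.min(upper))
        tmin = float(np.max(lower))
        if not (np.isfinite(tmin) and np.isfinite(tmax)) or tmax - tmin < 0:
            # numerical corner: re-project and retry
            x = np.clip(_project_null(basis, x), lb, ub)
            continue
        t = rng.uniform(tmin, tmax) if tmax > tmin else tmin
        x = np.clip(x + t * d, lb, ub)
        center = center + (x - center) / (len(W) + step)
        if step % 1000 == 0:
            x = _project_null(basis, x)
            np.clip(x, lb, ub, out=x)
        if step % thinning == 0:
            samples[collected] = x
            collected += 1

    # final feasibility certification
    resid = np.max(np.abs(system.S @ samples.T))
    if resid > FEASIBILITY_TOL:
        raise ModelError(f"sampler drift exceeded tolerance: ‖S·v‖∞ = {resid}")
    return SamplingResult(samples, list(system.rxn_ids), seed, thinning)


def reference_fluxes(result: SamplingResult) -> Dict[str, float]:
    """Per-reaction empirical median — the reference flux of a phase model."""
    if result.samples.shape[0] < 1:
        raise ModelError("no samples to summarise")
    return result.medians()
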