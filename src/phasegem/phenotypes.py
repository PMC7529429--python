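"""Phenotype screens: auxotrophies, carbon sources, and essentiality comparison.

An auxotrophy is detected exactly as in the wet lab's drop-out experiment:
grow the model on a rich medium, close the uptake of one component at a
time, and call the component essential when growth collapses below the
absolute tolerance (1e−6 h⁻¹).  Carbon-source screening supplements a
minimal medium with one source and reports the resulting growth rate.
Essentiality comparison partitions the essential-reaction sets of several
organisms — restricted to a focal model's reaction namespace — into shared
and group-exclusive cells (e.g. free-living vs intracellular lifestyles)
and exports the model↔reaction bipartite graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx
import pandas as pd

from .core import Medium, Metabolite, Model, ModelError, parse_formula
from .lp import GROWTH_TOL, apply_medium, fba

__all__ = [
    "AuxotrophyReport",
    "EssentialityComparison",
    "auxotrophy_scan",
    "carbon_source_growth",
    "compare_essential_sets",
    "organic_components",
]

#: species treated as inorganic even though their formula contains carbon
_INORGANIC_CARBON = {"co2", "hco3", "co"}


def _is_organic(met: Metabolite) -> bool:
    if met.formula is None:
        return False
    base = met.id.rsplit("_", 1)[0].lower()
    if base in _INORGANIC_CARBON:
        return False
    return parse_formula(met.formula).get("C", 0) > 0


def organic_components(model: Model, medium: Medium) -> List[str]:
    """Medium components whose exchanged metabolite is organic.

    Water, protons and inorganic ions are exempt from auxotrophy scanning by
    default: closing them tests medium bookkeeping, not biosynthesis.
    """
    mets = model.metabolite_map
    out = []
    for rid in sorted(medium.uptakes):
        rxn = model.reaction_map.get(rid)
        if rxn is None or len(rxn.stoichiometry) != 1:
            continue
        (met_id,) = rxn.stoichiometry
        if _is_organic(mets[met_id]):
            out.append(rid)
    return out


@dataclass
class AuxotrophyReport:
    """Outcome of a nutrient drop-out scan on one model."""

    full_growth: float
    growth_tolerance: float
    rows: Dict[str, Dict[str, float]] = field(default_factory=dict)
    categories: Dict[str, str] = field(default_factory=dict)
    medium_name: str = ""

    @property
    def essential_nutrients(self) -> Set[str]:
        return {rid for rid, row in self.rows.items() if row["essential"]}

    def by_category(self) -> Dict[str, Set[str]]:
        out: Dict[str, Set[str]] = {}
        for rid in self.essential_nutrients:
            out.setdefault(self.categories.get(rid, "other"), set()).add(rid)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df["category"] = [self.categories.get(r, "other") for r in df.index]
        df.index.name = "exchange"
        return df.sort_index()


def auxotrophy_scan(
    model: Model,
    rich_medium: Medium,
    scan_set: Optional[Iterable[str]] = None,
    categories: Optional[Dict[str, str]] = None,
    growth_tolerance: float = GROWTH_TOL,
    objective_id: Optional[str] = None,
) -> AuxotrophyReport:
    """Close each scanned component's uptake in turn and re-solve FBA.

    A component is an essential nutrient iff growth without it falls below
    ``growth_tolerance`` while full-medium growth is at least the tolerance.
    ``scan_set`` defaults to the medium's organic components.
    """
    baseline = fba(apply_medium(model, rich_medium), objective_id=objective_id)
    if not baseline.ok or baseline.objective_value < growth_tolerance:
        raise ModelError(
            "auxotrophy scan is meaningless: no growth on the full medium "
            f"(status {baseline.status}, growth {baseline.objective_value})"
        )
    scan = list(scan_set) if scan_set is not None else organic_components(model, rich_medium)
    unknown = sorted(set(scan) - set(rich_medium.uptakes))
    if unknown:
        raise ModelError(f"scan components not present in the medium: {unknown}")
    report = AuxotrophyReport(
        full_growth=baseline.objective_value,
        growth_tolerance=growth_tolerance,
        categories=dict(categories or {}),
        medium_name=rich_medium.name,
    )
    for rid in scan:
        sol = fba(apply_medium(model, rich_medium.without(rid)), objective_id=objective_id)
        growth = sol.objective_value if sol.ok else 0.0
        growth = max(0.0, growth)
        report.rows[rid] = {
            "with_component": baseline.objective_value,
            "without_component": growth,
            "essential": growth < growth_tolerance,
        }
    return report


def carbon_source_growth(
    model: Model,
    minimal_medium: Medium,
    source: str,
    rate: float = 10.0,
    objective_id: Optional[str] = None,
) -> float:
    """Growth on the minimal medium supplemented with one carbon source.

    Returns 0 for an infeasible (non-growing) supplemented model.  A rate of
    zero reproduces the minimal-medium baseline.
    """
    if source not in model.exchange_ids:
        raise ModelError(f"unknown carbon-source exchange {source!r}")
    if rate < 0:
        raise ModelError("uptake rate must be non-negative")
    medium = minimal_medium.copy()
    medium.uptakes[source] = float(rate)
    sol = fba(apply_medium(model, medium), objective_id=objective_id)
    if not sol.ok:
        return 0.0
    return max(0.0, sol.objective_value)


@dataclass
class EssentialityComparison:
    """Cross-organism essential-reaction partition, in a focal namespace."""

    focal: str
    groups: Dict[str, str]
    restricted_sets: Dict[str, Set[str]]
    group_labels: Tuple[str, str]
    shared: Set[str]
    exclusive: Dict[str, Set[str]]

    @property
    def partition_sizes(self) -> Dict[str, int]:
        sizes = {"shared": len(self.shared)}
        for label, s in self.exclusive.items():
            sizes[f"{label}_exclusive"] = len(s)
        return sizes

    def to_graph(self) -> nx.Graph:
        """Bipartite graph: model nodes ↔ essential-reaction nodes."""
        g = nx.Graph()
        for mid, reactions in self.restricted_sets.items():
            g.add_node(mid, kind="model", group=self.groups[mid])
            for rid in reactions:
                if rid not in g:
                    g.add_node(rid, kind="reaction")
                g.add_edge(mid, rid)
        return g

    def write_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_graph(), path)


def compare_essential_sets(
    labeled_sets: Dict[str, Set[str]],
    groups: Dict[str, str],
    focal: str,
    focal_reactions: Optional[Set[str]] = None,
    combine: str = "union",
) -> EssentialityComparison:
    """Partition essential reactions into shared and group-exclusive cells.

    Every organism's set is first restricted to the focal model's reaction
    ids (``focal_reactions`` defaults to the focal organism's own set).  The
    two groups' sets are combined per member (union by default: a reaction
    essential in any member counts for the group; ``intersection``
    available), then partitioned into A∩B, A∖B and B∖A.
    """
    if focal not in labeled_sets:
        raise ModelError(f"focal model {focal!r} not among the labelled sets")
    missing = sorted(set(labeled_sets) - set(groups))
    if missing:
        raise ModelError(f"models without a group label: {missing}")
    labels = sorted(set(groups[m] for m in labeled_sets))
    if len(labels) != 2:
        raise ModelError(f"exactly two group labels required, got {labels}")
    members: Dict[str, List[str]] = {lab: [] for lab in labels}
    for mid in labeled_sets:
        members[groups[mid]].append(mid)
    empty = [lab for lab, ms in members.items() if not ms]
    if empty:
        raise ModelError(f"groups with no members: {empty}")

    namespace = set(focal_reactions) if focal_reactions is not None else set(labeled_sets[focal])
    restricted = {mid: set(s) & namespace for mid, s in labeled_sets.items()}

    def combine_group(lab: str) -> Set[str]:
        sets = [restricted[m] for m in members[lab]]
        if combine == "union":
            out: Set[str] = set()
            for s in sets:
                out |= s
            return out
        if combine == "intersection":
            out = set(sets[0])
            for s in sets[1:]:
                out &= s
            return out
        raise ModelError(f"unknown combine rule {combine!r}")

    a_label, b_label = labels
    a, b = combine_group(a_label), combine_group(b_label)
    return EssentialityComparison(
        focal=focal,
        groups=dict(groups),
        restricted_sets=restricted,
        group_labels=(a_label, b_label),
        shared=a & b,
        exclusive={a_label: a - b, b_label: b - a},
    )
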