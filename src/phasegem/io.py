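"""Readers and writers: SBML Level 3 + FBC, TSV table pairs, and JSON.

Three on-disk representations of a :class:`~phasegem.core.Model` are
supported and round-trip stably (model equality up to ordering):

* ``sbml`` — SBML Level 3 with the FBC v2 package carrying flux bounds,
  gene-product associations and the objective (the community exchange
  format; readable by standard constraint-based toolboxes);
* ``tables`` — a directory holding ``metabolites.tsv`` (id, name, formula,
  charge, compartment), ``reactions.tsv`` (id, name, equation, lower_bound,
  upper_bound, gpr, subsystem) and ``model.json`` metadata.  This is the
  canonical TSV dialect for reconstruction spreadsheets; the importer takes
  a ``column_map`` so spreadsheets with different headers can be ingested
  without editing them;
* ``json`` — a single-file dump of the full model.

Reaction equation strings use the arrow grammar ``"a + 2 b -> c"`` with
``->`` (irreversible, default bounds (0, 1000)), ``<=>`` (reversible,
(−1000, 1000)) and ``<-`` (reverse-only, (−1000, 0)); explicit bound columns
override the arrow defaults.  Media are two-column TSV (exchange id, rate)
or YAML mappings.
"""

from __future__ import annotations

import json
import os
import re
from typing import Dict, Optional, Tuple

import pandas as pd
import yaml

from .core import Medium, Metabolite, Model, ModelError, Reaction
from .gpr import GPR

__all__ = [
    "read_model",
    "write_model",
    "read_medium",
    "write_medium",
    "model_to_dict",
    "model_from_dict",
    "parse_equation",
    "format_equation",
    "DEFAULT_BOUND",
]

DEFAULT_BOUND = 1000.0

_ARROWS = ("<=>", "<->", "->", "<-")


def parse_equation(equation: str) -> Tuple[Dict[str, float], float, float]:
    """Parse ``"atp_c + h2o_c -> adp_c + pi_c + h_c"`` into stoichiometry + bounds."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ModelError(f"no reaction arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?\s+)?(\S+)$", term)
            if m is None:
                raise ModelError(f"cannot parse equation term {term!r} in {equation!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    if arrow in ("<=>", "<->"):
        lb, ub = -DEFAULT_BOUND, DEFAULT_BOUND
    elif arrow == "->":
        lb, ub = 0.0, DEFAULT_BOUND
    else:  # "<-"
        lb, ub = -DEFAULT_BOUND, 0.0
    return stoich, lb, ub


def format_equation(stoich: Dict[str, float], lb: float, ub: float) -> str:
    """Inverse of :func:`parse_equation` (coefficient formatting is canonical)."""
    def fmt(coeff: float) -> str:
        coeff = abs(coeff)
        if coeff == 1.0:
            return ""
        if coeff == int(coeff):
            return f"{int(coeff)} "
        return f"{coeff!r} "  # repr: shortest exact round-trip for floats

    subs = [f"{fmt(c)}{m}" for m, c in sorted(stoich.items()) if c < 0]
    prods = [f"{fmt(c)}{m}" for m, c in sorted(stoich.items()) if c > 0]
    arrow = "<=>" if lb < 0 and ub > 0 else ("<-" if ub <= 0 else "->")
    return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


# ---------------------------------------------------------------------------
# dict / JSON
# ---------------------------------------------------------------------------

def model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "compartments": sorted(model.compartments),
        "objective_id": model.objective_id,
        "genes": sorted(model.genes),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def model_from_dict(data: dict) -> Model:
    model = Model(
        id=data.get("id", "model"),
        compartments=set(data.get("compartments", ["c", "p", "e"])),
        objective_id=data.get("objective_id"),
        genes=set(data.get("genes", [])),
    )
    for m in data.get("metabolites", []):
        model.metabolites.append(
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                formula=m.get("formula"),
                charge=int(m.get("charge", 0)),
                compartment=m.get("compartment", "c"),
            )
        )
    for r in data.get("reactions", []):
        rxn = Reaction(
            id=r["id"],
            name=r.get("name", ""),
            stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
            gpr=GPR.parse(r.get("gpr", "")),
            subsystem=r.get("subsystem", ""),
        )
        model.reactions.append(rxn)
        model.genes.update(rxn.gpr.genes)
    return model.validate()


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_MET_COLUMNS = ("id", "name", "formula", "charge", "compartment")
_RXN_COLUMNS = ("id", "name", "equation", "lower_bound", "upper_bound", "gpr", "subsystem")


def _remap(df: pd.DataFrame, column_map: Optional[Dict[str, str]]) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def _write_tables(model: Model, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    mets = pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "formula": "" if m.formula is None else m.formula,
                "charge": m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites
        ],
        columns=list(_MET_COLUMNS),
    )
    rxns = pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry, r.lower_bound, r.upper_bound),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string(),
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        columns=list(_RXN_COLUMNS),
    )
    mets.to_csv(os.path.join(path, "metabolites.tsv"), sep="\t", index=False)
    rxns.to_csv(os.path.join(path, "reactions.tsv"), sep="\t", index=False)
    meta = {
        "id": model.id,
        "compartments": sorted(model.compartments),
        "objective_id": model.objective_id,
    }
    with open(os.path.join(path, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def _read_tables(
    path: str,
    column_map: Optional[Dict[str, str]] = None,
) -> Model:
    met_path = os.path.join(path, "metabolites.tsv")
    rxn_path = os.path.join(path, "reactions.tsv")
    meta_path = os.path.join(path, "model.json")
    mets = _remap(pd.read_csv(met_path, sep="\t", dtype=str).fillna(""), column_map)
    rxns = _remap(pd.read_csv(rxn_path, sep="\t", dtype=str).fillna(""), column_map)
    meta = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    model = Model(
        id=meta.get("id", os.path.basename(os.path.normpath(path)) or "model"),
        compartments=set(meta.get("compartments", [])) or set(),
        objective_id=meta.get("objective_id"),
    )
    for _, row in mets.iterrows():
        model.metabolites.append(
            Metabolite(
                id=row["id"],
                name=row.get("name", ""),
                formula=row["formula"] or None,
                charge=int(float(row["charge"])) if row.get("charge", "") != "" else 0,
                compartment=row.get("compartment", "c") or "c",
            )
        )
    if not model.compartments:
        model.compartments = {m.compartment for m in model.metabolites} or {"c"}
    for _, row in rxns.iterrows():
        stoich, lb, ub = parse_equation(row["equation"])
        if row.get("lower_bound", "") != "":
            lb = float(row["lower_bound"])
        if row.get("upper_bound", "") != "":
            ub = float(row["upper_bound"])
        rxn = Reaction(
            id=row["id"],
            name=row.get("name", ""),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=GPR.parse(row.get("gpr", "")),
            subsystem=row.get("subsystem", ""),
        )
        model.reactions.append(rxn)
        model.genes.update(rxn.gpr.genes)
    return model.validate()


# ---------------------------------------------------------------------------
# SBML Level 3 + FBC
# ---------------------------------------------------------------------------

def _sbml_escape(prefix: str, raw: str) -> str:
    return prefix + re.sub(r"[^A-Za-z0-9_]", "__", raw)


def _write_sbml(model: Model, path: str) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sbml_escape("", model.id) or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for cid in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)

    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(_sbml_escape("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        splug = sp.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        splug.setCharge(int(met.charge))

    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(_sbml_escape("G_", gene))
        gp.setLabel(gene)

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        sr = sm.createReaction()
        sr.setId(_sbml_escape("R_", rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_sbml_escape("M_", met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(float(rxn.lower_bound)))
        rplug.setUpperFluxBound(bound_param(float(rxn.upper_bound)))
        if not rxn.gpr.is_empty:
            ga = rplug.createGeneProductAssociation()
            infix = rxn.gpr.to_string()
            for gene in sorted(rxn.gpr.genes, key=len, reverse=True):
                infix = re.sub(rf"(?<![A-Za-z0-9_]){re.escape(gene)}(?![A-Za-z0-9_])",
                               _sbml_escape("G_", gene), infix)
            ga.setAssociation(infix, True, False)

    if model.objective_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sbml_escape("R_", model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, path) != 1:
        raise ModelError(f"failed to write SBML to {path!r}")


def _strip(prefix: str, sid: str) -> str:
    return sid[len(prefix):] if sid.startswith(prefix) else sid


def _read_sbml(path: str) -> Model:
    import libsbml

    doc = libsbml.readSBMLFromFile(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [doc.getError(i).getMessage()
                for i in range(doc.getNumErrors())
                if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR]
        raise ModelError(f"SBML parse errors in {path!r}: {msgs}")
    sm = doc.getModel()
    if sm is None:
        raise ModelError(f"no model element in SBML file {path!r}")
    mplug = sm.getPlugin("fbc")

    model = Model(
        id=sm.getId() or "model",
        compartments={sm.getCompartment(i).getId() for i in range(sm.getNumCompartments())},
    )

    gene_labels: Dict[str, str] = {}
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or _strip("G_", gp.getId())

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        splug = sp.getPlugin("fbc")
        formula = None
        charge = 0
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula() or None
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.metabolites.append(
            Metabolite(
                id=_strip("M_", sp.getId()),
                name=sp.getName(),
                formula=formula,
                charge=charge,
                compartment=sp.getCompartment(),
            )
        )

    params = {sm.getParameter(i).getId(): sm.getParameter(i).getValue()
              for i in range(sm.getNumParameters())}

    def assoc_to_gpr(assoc) -> object:
        import libsbml as _ls

        if isinstance(assoc, _ls.GeneProductRef):
            return gene_labels.get(assoc.getGeneProduct(), _strip("G_", assoc.getGeneProduct()))
        children = [assoc_to_gpr(assoc.getAssociation(i))
                    for i in range(assoc.getNumAssociations())]
        op = "and" if isinstance(assoc, _ls.FbcAnd) else "or"
        return children[0] if len(children) == 1 else (op, tuple(children))

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = sr.getPlugin("fbc")
        lb = -DEFAULT_BOUND if sr.getReversible() else 0.0
        ub = DEFAULT_BOUND
        gpr = GPR()
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound(), lb)
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound(), ub)
            ga = rplug.getGeneProductAssociation()
            if ga is not None and ga.getAssociation() is not None:
                gpr = GPR(assoc_to_gpr(ga.getAssociation()))
        rxn = Reaction(
            id=_strip("R_", sr.getId()),
            name=sr.getName(),
            stoichiometry={k: v for k, v in stoich.items() if v != 0.0},
            lower_bound=float(lb),
            upper_bound=float(ub),
            gpr=gpr,
            subsystem="",
        )
        model.reactions.append(rxn)
        model.genes.update(gpr.genes)

    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None and obj.getNumFluxObjectives() > 0:
            model.objective_id = _strip("R_", obj.getFluxObjective(0).getReaction())

    return model.validate()


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "tables"
    ext = os.path.splitext(path)[1].lower()
    if ext in (".xml", ".sbml"):
        return "sbml"
    if ext == ".json":
        return "json"
    if ext == "":
        return "tables"
    raise ModelError(f"cannot infer model format from path {path!r}")


def read_model(path: str, format: Optional[str] = None,
               column_map: Optional[Dict[str, str]] = None) -> Model:
    """Load a model from SBML-FBC, a TSV table directory, or JSON."""
    fmt = format or _infer_format(path)
    if fmt == "sbml":
        return _read_sbml(path)
    if fmt == "tables":
        return _read_tables(path, column_map=column_map)
    if fmt == "json":
        with open(path) as fh:
            return model_from_dict(json.load(fh))
    raise ModelError(f"unknown model format {fmt!r}")


def write_model(model: Model, path: str, format: Optional[str] = None) -> None:
    """Write a model as SBML-FBC, a TSV table directory, or JSON."""
    fmt = format or _infer_format(path)
    model.validate()
    if fmt == "sbml":
        _write_sbml(model, path)
    elif fmt == "tables":
        _write_tables(model, path)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
    else:
        raise ModelError(f"unknown model format {fmt!r}")


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------

def read_medium(path: str) -> Medium:
    """Load a medium from two-column TSV (exchange id, rate) or a YAML mapping."""
    ext = os.path.splitext(path)[1].lower()
    if ext in (".yaml", ".yml"):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        name = data.pop("name", "") if isinstance(data, dict) else ""
        uptakes = data.get("uptakes", data) if isinstance(data, dict) else {}
        return Medium({str(k): float(v) for k, v in uptakes.items()}, name=name)
    df = pd.read_csv(path, sep="\t")
    id_col, rate_col = df.columns[0], df.columns[1]
    return Medium(
        {str(r[id_col]): float(r[rate_col]) for _, r in df.iterrows()},
        name=os.path.splitext(os.path.basename(path))[0],
    )


def write_medium(medium: Medium, path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".yaml", ".yml"):
        with open(path, "w") as fh:
            yaml.safe_dump({"name": medium.name, "uptakes": medium.uptakes}, fh)
        return
    pd.DataFrame(
        sorted(medium.uptakes.items()), columns=["exchange", "uptake"]
    ).to_csv(path, sep="\t", index=False)
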