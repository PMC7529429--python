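"""End-to-end workflow driver: one config in, a directory of artefacts out.

The pipeline chains the package's stages the way a full model-analysis study
runs them: load and validate the model → balance and dead-end report →
auxotrophy scan → reaction-essentiality scan → per-phase expression-
constrained reduction → per-phase flux sampling → cross-phase diff and a
summary report.  Every stage writes its artefacts into the output directory
and a manifest records each file with a content hash; identical configs
(same seeds) reproduce all numeric outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from .core import ModelError, check_model_balance, dead_end_report
from .io import read_medium, read_model, write_model
from .lp import apply_medium, single_reaction_deletion
from .phenotypes import auxotrophy_scan
from .reduction import ExpressionProfile, diff_models, reduce_from_profile
from .sampling import reference_fluxes, sample

__all__ = ["PipelineConfig", "ConditionConfig", "run_pipeline"]

logger = logging.getLogger("phasegem.pipeline")


@dataclass
class ConditionConfig:
    """One growth phase: medium, expression dataset and objective."""

    name: str
    medium: str
    expression: str
    objective_id: str


@dataclass
class PipelineConfig:
    """Declarative description of a full pipeline run.

    Thresholds hold the analysis constants: the RPKM cutoff for "expressed",
    the lethality ratio of the deletion screen, the absolute growth
    tolerance, and the objective fraction preserved during reduction.
    """

    model_path: str
    model_format: Optional[str] = None
    scan_medium: str = ""  # rich medium for auxotrophy + essentiality scans
    conditions: List[ConditionConfig] = field(default_factory=list)
    expression_threshold: float = 10.0
    essentiality_threshold: float = 0.10
    growth_tolerance: float = 1e-6
    objective_fraction: float = 0.9
    sampling_n: int = 1000
    sampling_seed: int = 0
    sampling_thinning: int = 10
    output_dir: str = "phasegem_run"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        conditions = [ConditionConfig(**c) for c in data.pop("conditions", [])]
        return cls(conditions=conditions, **data)

    def validate_paths(self) -> "PipelineConfig":
        paths = [self.model_path, self.scan_medium] + [
            p for c in self.conditions for p in (c.medium, c.expression)
        ]
        missing = [p for p in paths if p and not os.path.exists(p)]
        if missing:
            raise ModelError(f"configured paths do not exist: {missing}")
        for name, value, lo, hi in (
            ("expression_threshold", self.expression_threshold, 0.0, float("inf")),
            ("essentiality_threshold", self.essentiality_threshold, 0.0, 1.0),
            ("objective_fraction", self.objective_fraction, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ModelError(f"{name}={value} outside [{lo}, {hi}]")
        return self


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(data, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the summary report (also written).

    Any stage error aborts with a stage-labelled diagnostic; artefacts
    produced before the failure are retained in the output directory.
    """
    config.validate_paths()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    produced: List[str] = []
    report: dict = {"stages": []}
    stage = "setup"

    def emit(name: str, writer) -> None:
        path = os.path.join(out, name)
        writer(path)
        produced.append(name)

    try:
        # ---- stage: load + validate ---------------------------------
        stage = "load"
        logger.info("loading model from %s", config.model_path)
        model = read_model(config.model_path, format=config.model_format)
        model.validate()
        census = {
            "model_id": model.id,
            "reactions": len(model.reactions),
            "metabolites": len(model.metabolites),
            "genes": len(model.genes),
            "compartments": sorted(model.compartments),
            "exchanges": len(model.exchanges),
            "objective_id": model.objective_id,
        }
        report["model"] = census
        report["stages"].append("load")

        # ---- stage: balance + dead ends ------------------------------
        stage = "quality"
        balance = check_model_balance(model)
        by_status: Dict[str, List[str]] = {}
        for rid, res in balance.items():
            by_status.setdefault(res.status, []).append(rid)
        dead_mets, dead_rxns = dead_end_report(model)
        quality = {
            "balance_counts": {k: len(v) for k, v in sorted(by_status.items())},
            "unbalanced": sorted(by_status.get("unbalanced", [])),
            "unverifiable": sorted(by_status.get("unverifiable", [])),
            "dead_end_metabolites": sorted(dead_mets),
            "dead_end_reactions": sorted(dead_rxns),
        }
        emit("quality.json", lambda p: _dump_json(quality, p))
        report["quality"] = {
            "balance_counts": quality["balance_counts"],
            "dead_end_metabolites": len(dead_mets),
            "dead_end_reactions": len(dead_rxns),
        }
        report["stages"].append("quality")

        scan_medium = read_medium(config.scan_medium) if config.scan_medium else None

        # ---- stage: auxotrophy scan ----------------------------------
        if scan_medium is not None:
            stage = "auxotrophy"
            logger.info("auxotrophy scan on medium %s", scan_medium.name)
            aux = auxotrophy_scan(model, scan_medium,
                                  growth_tolerance=config.growth_tolerance)
            emit("auxotrophy.tsv",
                 lambda p: aux.to_frame().to_csv(p, sep="\t"))
            report["auxotrophy"] = {
                "scanned": len(aux.rows),
                "essential_nutrients": sorted(aux.essential_nutrients),
            }
            report["stages"].append("auxotrophy")

            # ---- stage: essentiality scan ----------------------------
            stage = "essentiality"
            logger.info("single-reaction deletion screen")
            ess = single_reaction_deletion(
                apply_medium(model, scan_medium),
                threshold=config.essentiality_threshold,
            )
            emit("essentiality.tsv",
                 lambda p: ess.to_frame().to_csv(p, sep="\t"))
            report["essentiality"] = {
                "screened": len(ess.rows),
                "essential": len(ess.essential),
                "wild_type_growth": ess.wild_type,
                "threshold": ess.threshold,
            }
            report["stages"].append("essentiality")

        # ---- stage: per-condition reduction + sampling ----------------
        reduced = {}
        report["conditions"] = {}
        for cond in config.conditions:
            stage = f"reduction[{cond.name}]"
            logger.info("reducing model for condition %s", cond.name)
            medium = read_medium(cond.medium)
            profile = ExpressionProfile.from_tsv(cond.expression, condition=cond.name)
            cm = reduce_from_profile(
                model, profile, medium,
                objective_id=cond.objective_id,
                fraction=config.objective_fraction,
                threshold=config.expression_threshold,
            )
            reduced[cond.name] = cm
            emit(f"reduced_{cond.name}.json",
                 lambda p, _cm=cm: write_model(_cm.model, p, format="json"))
            emit(f"removals_{cond.name}.tsv",
                 lambda p, _cm=cm: _cm.removal_frame().to_csv(p, sep="\t", index=False))

            stage = f"sampling[{cond.name}]"
            logger.info("sampling condition %s", cond.name)
            sres = sample(cm.model, n_samples=config.sampling_n,
                          seed=config.sampling_seed, thinning=config.sampling_thinning)
            medians = reference_fluxes(sres)
            emit(f"reference_fluxes_{cond.name}.tsv",
                 lambda p, _m=medians: _write_medians(_m, p))
            report["conditions"][cond.name] = {
                "reactions": len(cm.model.reactions),
                "removed_unsupported": len(cm.removed_unsupported),
                "removed_blocked": len(cm.removed_blocked),
                "source_optimum": cm.source_optimum,
                "reduced_optimum": cm.reduced_optimum,
                "objective_id": cm.objective_id,
                "sampling": {"n": config.sampling_n, "seed": config.sampling_seed,
                             "thinning": config.sampling_thinning},
            }
            report["stages"].append(f"reduce+sample[{cond.name}]")

        # ---- stage: cross-condition diff ------------------------------
        if len(reduced) == 2:
            stage = "diff"
            (na, ca), (nb, cb) = sorted(reduced.items())
            d = diff_models(ca, cb)
            diff = {
                f"{na}_only": sorted(d["a_only"]),
                f"{nb}_only": sorted(d["b_only"]),
                "shared": sorted(d["shared"]),
            }
            emit("condition_diff.json", lambda p: _dump_json(diff, p))
            report["diff"] = {k: len(v) for k, v in diff.items()}
            report["stages"].append("diff")

        # ---- report + manifest ----------------------------------------
        stage = "report"
        report["parameters"] = {
            "expression_threshold": config.expression_threshold,
            "essentiality_threshold": config.essentiality_threshold,
            "growth_tolerance": config.growth_tolerance,
            "objective_fraction": config.objective_fraction,
        }
        emit("report.json", lambda p: _dump_json(report, p))
        manifest = {name: _sha256(os.path.join(out, name)) for name in sorted(produced)}
        _dump_json(manifest, os.path.join(out, "manifest.json"))
        return report
    except Exception as exc:
        raise ModelError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_medians(medians: Dict[str, float], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(medians.items()), columns=["reaction", "median_flux"]
    ).to_csv(path, sep="\t", index=False)
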