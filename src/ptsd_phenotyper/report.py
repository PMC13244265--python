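"""Incidence/subtype reporting and the end-to-end pipeline runner.

Every percentage any report prints sits beside its numerator and
denominator, so the arithmetic is always auditable and re-computable —
rounded percentages alone are ambiguous at small n.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .catalog import CriterionCatalog, default_catalog
from .classify import ClassificationResult, classify_cohort
from .cohort import CohortTable, load_cohort
from .effects import SelectionResult, select_parameters
from .preprocess import resolve_transforms
from .simulate import SimulationConfig, default_simulation_config, simulate_cohort
from .subtype import SubtypeResult, round_pct, subtype_resilient

logger = logging.getLogger("ptsd_phenotyper")


class ReportError(ValueError):
    pass


@dataclass
class IncidenceReport:
    """Susceptible incidence per sex and pooled, with full bookkeeping."""

    rows: pd.DataFrame  # scope, n_exposed, n_susceptible, percentage, controls...
    cutoff: Optional[float] = None
    provenance: dict = field(default_factory=dict)

    def percentage(self, scope: str = "pooled") -> float:
        return float(self.rows.set_index("scope").loc[scope, "percentage"])

    def to_json(self, path=None) -> str:
        doc = {
            "cutoff": self.cutoff,
            "provenance": self.provenance,
            "incidence": self.rows.to_dict(orient="records"),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def incidence_from_counts(counts_by_sex: dict) -> IncidenceReport:
    """Build an incidence report from raw per-sex counts.

    ``counts_by_sex`` maps sex → (n_susceptible, n_exposed).  The pooled
    percentage is computed from pooled counts, never by averaging the
    per-sex percentages.
    """
    rows = []
    tot_s = tot_e = 0
    for sex, (n_s, n_e) in counts_by_sex.items():
        if n_e == 0:
            raise ReportError(f"zero exposed denominator for {sex}")
        if n_s > n_e:
            raise ReportError(f"{sex}: susceptible count exceeds exposed count")
        rows.append(
            {
                "scope": sex,
                "n_exposed": n_e,
                "n_susceptible": n_s,
                "percentage": round_pct(n_s, n_e),
            }
        )
        tot_s += n_s
        tot_e += n_e
    rows.append(
        {
            "scope": "pooled",
            "n_exposed": tot_e,
            "n_susceptible": tot_s,
            "percentage": round_pct(tot_s, tot_e),
        }
    )
    return IncidenceReport(rows=pd.DataFrame(rows))


def incidence_table(result: ClassificationResult) -> IncidenceReport:
    """Incidence report from a classification result (classifiable exposed
    mice only; control self-check counts carried alongside)."""
    sexes = sorted(result.scorecards["sex"].unique().tolist())
    rows = []
    for scope in sexes + ["pooled"]:
        c = result.counts(None if scope == "pooled" else scope)
        if c["n_exposed"] == 0:
            raise ReportError(f"zero classifiable exposed mice ({scope})")
        rows.append(
            {
                "scope": scope,
                "n_exposed": c["n_exposed"],
                "n_susceptible": c["n_susceptible"],
                "percentage": round_pct(c["n_susceptible"], c["n_exposed"]),
                "n_unclassifiable": c["n_unclassifiable"],
                "n_control": c["n_control"],
                "n_control_flagged": c["n_control_flagged"],
            }
        )
    return IncidenceReport(
        rows=pd.DataFrame(rows),
        cutoff=result.cutoff,
        provenance={"coverage": result.coverage},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineArtifacts:
    cohort: CohortTable
    plan: object
    effects: Optional[pd.DataFrame]
    selection: SelectionResult
    classification: ClassificationResult
    incidence: IncidenceReport
    subtypes: Optional[SubtypeResult]
    manifest: dict


def run_pipeline(
    cohort: Optional[CohortTable] = None,
    cohort_path: Optional[str] = None,
    config: Optional[SimulationConfig] = None,
    simulate: bool = False,
    seed: Optional[int] = None,
    catalog: Optional[CriterionCatalog] = None,
    transform_policy: str = "catalog_fixed",
    effect_cutoff: float = 0.5,
    min_per_criterion: int = 2,
    coverage: float = 0.85,
    use_exact_quantile: bool = False,
    selection: Optional[SelectionResult] = None,
    out_dir: Optional[str] = None,
) -> PipelineArtifacts:
    """Execute simulate? → preprocess → selection → classify → subtype →
    report, writing artifacts and a manifest when ``out_dir`` is given."""
    catalog = catalog or default_catalog()
    options = {
        "transform_policy": transform_policy,
        "effect_cutoff": effect_cutoff,
        "min_per_criterion": min_per_criterion,
        "coverage": coverage,
        "use_exact_quantile": use_exact_quantile,
        "seed": seed,
    }
    stage = "input"
    try:
        if simulate or config is not None:
            stage = "simulate"
            cfg = config or default_simulation_config()
            if seed is not None:
                cfg.seed = seed
            logger.info("simulating cohort (seed=%s)", cfg.seed)
            cohort, truth = simulate_cohort(cfg, catalog)
        elif cohort_path is not None:
            stage = "load"
            logger.info("loading cohort from %s", cohort_path)
            cohort = load_cohort(cohort_path, catalog)
            truth = None
        elif cohort is not None:
            truth = None
        else:
            raise ReportError("provide a cohort, a cohort_path, or simulate=True")

        stage = "preprocess"
        logger.info("resolving transforms (policy=%s)", transform_policy)
        plan = resolve_transforms(cohort, policy=transform_policy)

        stage = "selection"
        if selection is None:
            logger.info("selecting parameters (|effect| > %s)", effect_cutoff)
            effects, selection = select_parameters(
                cohort, plan, cutoff=effect_cutoff, min_per_criterion=min_per_criterion
            )
        else:
            effects = None

        stage = "classify"
        logger.info("classifying (coverage=%s)", coverage)
        classification = classify_cohort(
            cohort, selection, plan, coverage, use_exact_quantile
        )
        incidence = incidence_table(classification)

        stage = "subtype"
        try:
            subtypes = subtype_resilient(cohort, classification.labels, coverage)
            for mid, reason in subtypes.excluded:
                logger.warning("subtype: excluded %s (%s)", mid, reason)
        except Exception as err:  # subtyping is optional when inputs lack columns
            logger.warning("subtype stage skipped: %s", err)
            subtypes = None

        stage = "report"
        manifest = {
            "package_version": __version__,
            "options": options,
            "n_mice": cohort.n_mice,
            "sexes": list(cohort.sexes),
            "provenance": cohort.provenance,
            "stages": ["simulate" if simulate else "load", "preprocess",
                       "selection", "classify", "subtype", "report"],
            "artifacts": {},
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            paths = {}
            cohort.write_csv(out / "cohort.csv")
            paths["cohort.csv"] = out / "cohort.csv"
            if truth is not None:
                truth.write_csv(out / "truth.csv")
                paths["truth.csv"] = out / "truth.csv"
            plan.to_json(out / "plan.json")
            paths["plan.json"] = out / "plan.json"
            if effects is not None:
                effects.to_csv(out / "effects.csv", index=False)
                paths["effects.csv"] = out / "effects.csv"
            selection.to_json(out / "selection.json")
            paths["selection.json"] = out / "selection.json"
            classification.scorecards.to_csv(out / "scorecards.csv", index=False)
            paths["scorecards.csv"] = out / "scorecards.csv"
            classification.labels.to_csv(out / "labels.csv", index=False)
            paths["labels.csv"] = out / "labels.csv"
            incidence.to_json(out / "summary.json")
            paths["summary.json"] = out / "summary.json"
            if subtypes is not None:
                subtypes.table.to_csv(out / "subtypes.csv", index=False)
                paths["subtypes.csv"] = out / "subtypes.csv"
                subtypes.crosstab().to_csv(out / "subtype_summary.csv", index=False)
                paths["subtype_summary.csv"] = out / "subtype_summary.csv"
            manifest["artifacts"] = {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in paths.items()
            }
            with open(out / "manifest.json", "w", encoding="utf-8") as fh:
                json.dump(manifest, fh, indent=2)
                fh.write("\n")
        return PipelineArtifacts(
            cohort=cohort,
            plan=plan,
            effects=effects,
            selection=selection,
            classification=classification,
            incidence=incidence,
            subtypes=subtypes,
            manifest=manifest,
        )
    except ReportError:
        raise
    except Exception as err:
        raise ReportError(f"pipeline failed at stage {stage!r}: {err}") from err
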