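"""Criterion catalog: which behavioral parameters measure which DSM-V criteria.

Five of the eight DSM-V criteria for PTSD are behaviorally measurable in a
trauma-exposed mouse (B intrusive thoughts, C avoidance, D negative
alterations in cognition, E altered arousal/reactivity, G social impairment);
A, F and H are satisfied by the experimental design (trauma exposure,
testing ≥30 days post-exposure, no confounding condition).  The catalog maps
each measurable criterion to the per-mouse behavioral parameters that probe
it, and records for each parameter its assay, its type (continuous or
binary) and the variance-stabilizing transform applied before any statistics
are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

MEASURABLE_CRITERIA: tuple[str, ...] = ("B", "C", "D", "E", "G")
DESIGN_CRITERIA: tuple[str, ...] = ("A", "F", "H")

VALID_KINDS = ("continuous", "binary")
VALID_TRANSFORMS = ("identity", "log", "sqrt")
BINARY_OUTCOMES = ("pass", "fail")


@dataclass(frozen=True)
class ParameterSpec:
    """A single per-mouse behavioral parameter.

    ``criteria`` lists the DSM-V criterion codes this parameter contributes
    points to; auxiliary parameters (used only for secondary subtyping, e.g.
    open-field velocity) carry an empty criteria set.  ``transform`` is the
    variance-stabilizing transform applied before z-scores and effect sizes;
    binary parameters are never transformed.
    """

    name: str
    assay: str
    kind: str = "continuous"
    transform: str = "identity"
    criteria: frozenset[str] = frozenset()
    direction_of_pathology: str = "either"
    pathological_outcome: str = "fail"

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"parameter {self.name!r}: unknown kind {self.kind!r}")
        if self.transform not in VALID_TRANSFORMS:
            raise ValueError(
                f"parameter {self.name!r}: unknown transform {self.transform!r}"
            )
        if self.kind == "binary" and self.transform != "identity":
            raise ValueError(
                f"binary parameter {self.name!r} must use the identity transform"
            )
        if self.direction_of_pathology not in ("either", "high", "low"):
            raise ValueError(
                f"parameter {self.name!r}: bad direction {self.direction_of_pathology!r}"
            )
        if self.kind == "binary" and self.pathological_outcome not in BINARY_OUTCOMES:
            raise ValueError(
                f"parameter {self.name!r}: pathological_outcome must be pass/fail"
            )
        bad = set(self.criteria) - set(MEASURABLE_CRITERIA)
        if bad:
            raise ValueError(
                f"parameter {self.name!r}: non-measurable criteria {sorted(bad)}"
            )
        object.__setattr__(self, "criteria", frozenset(self.criteria))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "assay": self.assay,
            "kind": self.kind,
            "transform": self.transform,
            "criteria": sorted(self.criteria),
            "direction_of_pathology": self.direction_of_pathology,
        }
        if self.kind == "binary":
            d["pathological_outcome"] = self.pathological_outcome
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSpec":
        return cls(
            name=d["name"],
            assay=d["assay"],
            kind=d.get("kind", "continuous"),
            transform=d.get("transform", "identity"),
            criteria=frozenset(d.get("criteria", ())),
            direction_of_pathology=d.get("direction_of_pathology", "either"),
            pathological_outcome=d.get("pathological_outcome", "fail"),
        )


@dataclass(frozen=True)
class CriterionCatalog:
    """The full criterion → parameter mapping for one analysis.

    ``parameters`` are the criterion-linked parameters (every one must name at
    least one measurable criterion); ``auxiliary`` holds parameters carried in
    the cohort but outside the point system (subtype inputs).  ``design_notes``
    records how the design-satisfied criteria are met.
    """

    parameters: tuple[ParameterSpec, ...]
    measurable_criteria: tuple[str, ...] = MEASURABLE_CRITERIA
    auxiliary: tuple[ParameterSpec, ...] = ()
    design_notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameters", tuple(self.parameters))
        object.__setattr__(self, "auxiliary", tuple(self.auxiliary))
        names = [p.name for p in self.parameters] + [p.name for p in self.auxiliary]
        if len(names) != len(set(names)):
            raise ValueError("duplicate parameter names in catalog")
        for p in self.parameters:
            if not p.criteria:
                raise ValueError(
                    f"criterion-linked parameter {p.name!r} names no criterion"
                )
        for crit in self.measurable_criteria:
            if not self.parameters_for(crit):
                raise ValueError(f"criterion {crit} covered by no parameter")

    # -- lookups ---------------------------------------------------------
    def parameters_for(self, criterion: str) -> tuple[ParameterSpec, ...]:
        return tuple(p for p in self.parameters if criterion in p.criteria)

    def get(self, name: str) -> ParameterSpec:
        for p in self.all_parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def all_parameters(self) -> tuple[ParameterSpec, ...]:
        return self.parameters + self.auxiliary

    @property
    def continuous_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.all_parameters if p.kind == "continuous")

    @property
    def binary_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.all_parameters if p.kind == "binary")

    def criterion_parameter_sets(self) -> dict[str, tuple[str, ...]]:
        """Ordered mapping criterion → tuple of parameter names."""
        return {
            c: tuple(p.name for p in self.parameters_for(c))
            for c in self.measurable_criteria
        }

    def distinct_parameter_sets(self) -> list[tuple[str, ...]]:
        """Distinct criterion parameter-sets (criteria sharing the identical
        parameter list — C and E in the default catalog — collapse to one set,
        which matters for the null false-positive rate)."""
        seen: list[tuple[str, ...]] = []
        for names in self.criterion_parameter_sets().values():
            if names not in seen:
                seen.append(names)
        return seen

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "measurable_criteria": list(self.measurable_criteria),
            "parameters": [p.to_dict() for p in self.parameters],
            "auxiliary": [p.to_dict() for p in self.auxiliary],
            "design_notes": dict(self.design_notes),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CriterionCatalog":
        if isinstance(source, (dict,)):
            doc = source
        else:
            try:
                doc = json.loads(source)
            except (ValueError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    doc = json.load(fh)
        return cls(
            parameters=tuple(ParameterSpec.from_dict(d) for d in doc["parameters"]),
            measurable_criteria=tuple(
                doc.get("measurable_criteria", MEASURABLE_CRITERIA)
            ),
            auxiliary=tuple(
                ParameterSpec.from_dict(d) for d in doc.get("auxiliary", ())
            ),
            design_notes=doc.get("design_notes", {}),
        )

    def replace_criterion(
        self, criterion: str, parameter_names: Iterable[str], source: "CriterionCatalog"
    ) -> "CriterionCatalog":
        """Return a catalog where ``criterion`` is instead measured by the
        named parameters (taken from ``source``'s parameter pool).  Used to
        build variant catalogs, e.g. disjoint parameter sets for null-rate
        experiments."""
        new_params = []
        for p in self.parameters:
            crits = set(p.criteria) - {criterion}
            if crits:
                new_params.append(replace(p, criteria=frozenset(crits)))
        pool = {p.name: p for p in source.all_parameters}
        existing = {p.name: i for i, p in enumerate(new_params)}
        for name in parameter_names:
            if name in existing:
                i = existing[name]
                new_params[i] = replace(
                    new_params[i],
                    criteria=frozenset(set(new_params[i].criteria) | {criterion}),
                )
            else:
                base = pool[name]
                new_params.append(replace(base, criteria=frozenset({criterion})))
        aux = tuple(p for p in self.auxiliary if p.name not in {q.name for q in new_params})
        return CriterionCatalog(
            parameters=tuple(new_params),
            measurable_criteria=self.measurable_criteria,
            auxiliary=aux,
            design_notes=self.design_notes,
        )


def default_catalog() -> CriterionCatalog:
    """The standard mSPS battery catalog.

    B ← conditioned-stimulus reminder inactivity (pre and post tone, both
    log-transformed); C and E ← the identical pair {EPM open/closed duration
    ratio (sqrt), light/dark dark-side duration}; D ← {Barnes probe pass/fail
    (binary), water consumed in 48 h, sucrose consumed in 24 h}; G ←
    {duration with novel mouse (trial 2), latency to approach novel mouse
    (trial 3, log)}.  Open-field average velocity (sqrt) rides along as an
    auxiliary parameter for the hyperlocomotion subtype stage.
    """
    text = resources.files("ptsd_phenotyper").joinpath("data/default_catalog.json")
    return CriterionCatalog.from_json(text.read_text(encoding="utf-8"))
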