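"""Effect sizes and criterion parameter selection.

Continuous parameters are scored with Glass's delta — the exposed-minus-
control mean difference standardized by the *control* group's SD only, so
the trauma group's (possibly inflated) variance never deflates the effect.
The binary Barnes-probe outcome is scored with the phi coefficient,
sqrt(chi²/N) of the 2×2 group × pass/fail table.  Parameters with
|effect| strictly greater than the cutoff (default 0.5, a moderate-to-large
effect) are selected per criterion; the rule asks for at least two
parameters per criterion and flags a shortfall when fewer clear the cutoff.
Sexes are always analyzed separately and never pooled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import CriterionCatalog
from .cohort import GROUP_COLUMN, CohortTable
from .preprocess import TransformPlan, transformed_frame

DEFAULT_CUTOFF = 0.5
DEFAULT_MIN_PER_CRITERION = 2


class EffectSizeError(ValueError):
    pass


@dataclass(frozen=True)
class GroupStats:
    """Per (sex, parameter) group summary on the analysis scale."""

    sex: str
    parameter: str
    scale: str  # "raw" or "transformed"
    control_mean: float
    control_sd: float
    exposed_mean: float
    n_control: int
    n_exposed: int


def glass_delta(exposed_values, control_values) -> float:
    """Glass's delta: (mean exposed − mean control) / control SD (ddof=1)."""
    exposed = np.asarray(pd.Series(exposed_values).dropna(), dtype=float)
    control = np.asarray(pd.Series(control_values).dropna(), dtype=float)
    if len(control) < 2:
        raise EffectSizeError("need at least 2 control values")
    if len(exposed) < 1:
        raise EffectSizeError("need at least 1 exposed value")
    sd = control.std(ddof=1)
    if sd == 0:
        raise EffectSizeError("degenerate control variance")
    return float((exposed.mean() - control.mean()) / sd)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for (group × outcome): a,b = control (pass, fail); c,d =
    exposed (pass, fail)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise EffectSizeError("counts must be non-negative integers")
        if self.n == 0:
            raise EffectSizeError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def chi_square_2x2(table: ContingencyTable2x2) -> float:
    """Pearson chi-square without continuity correction:
    N·(ad − bc)² / ((a+b)(c+d)(a+c)(b+d))."""
    r1, r2, c1, c2 = table.margins
    if 0 in (r1, r2, c1, c2):
        raise EffectSizeError("degenerate margin in 2x2 table")
    a, b, c, d = table.a, table.b, table.c, table.d
    return table.n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def phi_coefficient(table: ContingencyTable2x2) -> float:
    """phi = sqrt(chi² / N), in [0, 1]."""
    return math.sqrt(chi_square_2x2(table) / table.n)


@dataclass(frozen=True)
class EffectSizeRecord:
    sex: str
    parameter: str
    kind: str  # "glass_delta" or "phi"
    value: float
    criteria: tuple[str, ...]
    selected: bool


@dataclass
class SelectionResult:
    """Per (sex, criterion): the ordered selected parameter names."""

    selected: dict = field(default_factory=dict)  # (sex, criterion) -> tuple[str,...]
    cutoff: float = DEFAULT_CUTOFF
    min_per_criterion: int = DEFAULT_MIN_PER_CRITERION
    shortfalls: list = field(default_factory=list)  # (sex, criterion, n_selected)

    def parameters_for(self, sex: str, criterion: str) -> tuple[str, ...]:
        return self.selected[(sex, criterion)]

    @classmethod
    def from_catalog(cls, catalog: CriterionCatalog, sexes) -> "SelectionResult":
        """A selection that simply takes every catalog parameter of every
        criterion — the 'true catalog' selection used when effect-size
        screening is not wanted (e.g. null simulations)."""
        sel = {}
        for sex in sexes:
            for crit, names in catalog.criterion_parameter_sets().items():
                sel[(sex, crit)] = tuple(sorted(names))
        return cls(selected=sel, cutoff=float("nan"), min_per_criterion=0)

    def to_json(self, path=None) -> str:
        doc = {
            "cutoff": None if math.isnan(self.cutoff) else self.cutoff,
            "min_per_criterion": self.min_per_criterion,
            "shortfalls": [list(s) for s in self.shortfalls],
            "selected": [
                {"sex": sex, "criterion": crit, "parameters": list(names)}
                for (sex, crit), names in sorted(self.selected.items())
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SelectionResult":
        try:
            doc = json.loads(source)
        except (ValueError, TypeError):
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        return cls(
            selected={
                (d["sex"], d["criterion"]): tuple(d["parameters"])
                for d in doc["selected"]
            },
            cutoff=float("nan") if doc["cutoff"] is None else doc["cutoff"],
            min_per_criterion=doc["min_per_criterion"],
            shortfalls=[tuple(s) for s in doc.get("shortfalls", [])],
        )


def _binary_table(df: pd.DataFrame, name: str) -> ContingencyTable2x2:
    ctrl = df[df[GROUP_COLUMN] == "control"][name].dropna()
    expo = df[df[GROUP_COLUMN] == "exposed"][name].dropna()
    return ContingencyTable2x2(
        a=int((ctrl == "pass").sum()),
        b=int((ctrl == "fail").sum()),
        c=int((expo == "pass").sum()),
        d=int((expo == "fail").sum()),
    )


def effect_size_table(
    cohort: CohortTable, plan: TransformPlan, cutoff: float = DEFAULT_CUTOFF
) -> pd.DataFrame:
    """Per (sex, parameter) effect sizes on the transformed scale.

    Columns: sex, parameter, kind, value, abs_value, criteria, selected.
    """
    tx = transformed_frame(cohort, plan)
    rows = []
    for sex in cohort.sexes:
        txs = tx[tx["sex"] == sex]
        raw = cohort.subset(sex=sex)
        for p in cohort.catalog.parameters:
            if p.kind == "continuous":
                ctrl = txs[txs[GROUP_COLUMN] == "control"][p.name]
                expo = txs[txs[GROUP_COLUMN] == "exposed"][p.name]
                try:
                    value = glass_delta(expo, ctrl)
                except EffectSizeError as err:
                    raise EffectSizeError(f"{p.name} ({sex}): {err}") from err
                kind = "glass_delta"
            else:
                try:
                    value = phi_coefficient(_binary_table(raw, p.name))
                except EffectSizeError:
                    value = float("nan")  # degenerate margin: uninformative
                kind = "phi"
            rows.append(
                {
                    "sex": sex,
                    "parameter": p.name,
                    "kind": kind,
                    "value": value,
                    "abs_value": abs(value),
                    "criteria": ",".join(sorted(p.criteria)),
                    "selected": bool(abs(value) > cutoff)
                    if not math.isnan(value)
                    else False,
                }
            )
    return pd.DataFrame(rows)


def select_parameters(
    cohort: CohortTable,
    plan: TransformPlan,
    cutoff: float = DEFAULT_CUTOFF,
    min_per_criterion: int = DEFAULT_MIN_PER_CRITERION,
    strict: bool = False,
) -> tuple[pd.DataFrame, SelectionResult]:
    """Choose the parameters that define each criterion, per sex.

    Selection keeps every parameter whose |effect| is strictly above
    ``cutoff`` (0.5 exactly is NOT selected), ordered by descending
    |effect| with name as the deterministic tie-break.  A criterion with
    fewer than ``min_per_criterion`` survivors is flagged as a shortfall
    (fatal when ``strict``); a criterion with no computable parameter at
    all is always an error.
    """
    effects = effect_size_table(cohort, plan, cutoff)
    result = SelectionResult(cutoff=cutoff, min_per_criterion=min_per_criterion)
    for sex in cohort.sexes:
        es = effects[effects["sex"] == sex]
        for crit in cohort.catalog.measurable_criteria:
            names = [p.name for p in cohort.catalog.parameters_for(crit)]
            sub = es[es["parameter"].isin(names)].copy()
            computable = sub[~sub["value"].isna()]
            if computable.empty:
                raise EffectSizeError(
                    f"criterion {crit} ({sex}): no computable parameters"
                )
            computable = computable.sort_values(
                ["abs_value", "parameter"], ascending=[False, True]
            )
            chosen = computable[computable["abs_value"] > cutoff]["parameter"].tolist()
            if len(chosen) < min_per_criterion:
                result.shortfalls.append((sex, crit, len(chosen)))
                if strict:
                    raise EffectSizeError(
                        f"criterion {crit} ({sex}): only {len(chosen)} parameter(s) "
                        f"exceed |effect| > {cutoff}"
                    )
                if not chosen:
                    # permissive floor: keep the single strongest parameter so
                    # the criterion stays scoreable, flagged above
                    chosen = computable["parameter"].head(1).tolist()
            result.selected[(sex, crit)] = tuple(chosen)
    return effects, result
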