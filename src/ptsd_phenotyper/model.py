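"""Model/Results interface over the phenotyping pipeline.

`SusceptibilityModel` is constructed from a cohort (or CSV) plus the
analysis options; `fit()` runs preprocessing, effect-size-driven parameter
selection and criterion-point classification, and returns a
`SusceptibilityResults` carrying the estimates (per-mouse scorecards and
labels, per-sex incidences), their bookkeeping (counts beside every
percentage), diagnostics (transform evidence, selection shortfalls,
control self-check) and a `summary()` table.  Subtyping of resilient mice
hangs off the results object.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .catalog import CriterionCatalog, default_catalog
from .classify import ClassificationResult, classify_cohort
from .cohort import CohortTable, load_cohort
from .effects import SelectionResult, select_parameters
from .preprocess import TransformPlan, resolve_transforms
from .report import IncidenceReport, incidence_table
from .subtype import SubtypeResult, subtype_resilient


class SusceptibilityModel:
    """Criterion-point susceptibility classifier for one cohort.

    Parameters
    ----------
    cohort : CohortTable
        Per-mouse behavioral table bound to a criterion catalog.
    transform_policy : {"catalog_fixed", "auto"}
        Use each parameter's declared transform, or screen with the
        D'Agostino–Pearson test and climb the log/sqrt ladder.
    effect_cutoff : float
        Parameters with |Glass delta| or phi strictly above this are
        selected per criterion (default 0.5).
    min_per_criterion : int
        Desired selected parameters per criterion (shortfalls flagged).
    coverage : float
        Two-sided normal coverage defining the z cutoff (0.85 → 1.44).
    use_exact_quantile : bool
        Use 1.4395… instead of the conventional rounding 1.44.
    selection : SelectionResult, optional
        Pre-computed selection (bypasses effect-size screening).
    """

    def __init__(
        self,
        cohort: CohortTable,
        transform_policy: str = "catalog_fixed",
        effect_cutoff: float = 0.5,
        min_per_criterion: int = 2,
        coverage: float = 0.85,
        use_exact_quantile: bool = False,
        selection: Optional[SelectionResult] = None,
    ) -> None:
        self.cohort = cohort
        self.transform_policy = transform_policy
        self.effect_cutoff = effect_cutoff
        self.min_per_criterion = min_per_criterion
        self.coverage = coverage
        self.use_exact_quantile = use_exact_quantile
        self._selection = selection

    @classmethod
    def from_csv(
        cls, path, catalog: Optional[CriterionCatalog] = None, **options
    ) -> "SusceptibilityModel":
        catalog = catalog or default_catalog()
        return cls(load_cohort(path, catalog), **options)

    def fit(self) -> "SusceptibilityResults":
        plan = resolve_transforms(self.cohort, policy=self.transform_policy)
        if self._selection is None:
            effects, selection = select_parameters(
                self.cohort,
                plan,
                cutoff=self.effect_cutoff,
                min_per_criterion=self.min_per_criterion,
            )
        else:
            effects, selection = None, self._selection
        classification = classify_cohort(
            self.cohort,
            selection,
            plan,
            coverage=self.coverage,
            use_exact_quantile=self.use_exact_quantile,
        )
        return SusceptibilityResults(self, plan, effects, selection, classification)


class SusceptibilityResults:
    """Fitted classification: scorecards, incidences, diagnostics."""

    def __init__(
        self,
        model: SusceptibilityModel,
        transform_plan: TransformPlan,
        effect_sizes: Optional[pd.DataFrame],
        selection: SelectionResult,
        classification: ClassificationResult,
    ) -> None:
        self.model = model
        self.transform_plan = transform_plan
        self.effect_sizes = effect_sizes
        self.selection = selection
        self.classification = classification

    # -- estimates -------------------------------------------------------
    @property
    def scorecards(self) -> pd.DataFrame:
        return self.classification.scorecards

    @property
    def labels(self) -> pd.DataFrame:
        return self.classification.labels

    @property
    def zscores(self) -> pd.DataFrame:
        return self.classification.zscores

    @property
    def cutoff(self) -> float:
        return self.classification.cutoff

    def incidence(self, sex: Optional[str] = None) -> float:
        return self.classification.incidence(sex)

    def incidence_report(self) -> IncidenceReport:
        return incidence_table(self.classification)

    # -- secondary phenotyping ------------------------------------------
    def subtype_resilient(self) -> SubtypeResult:
        return subtype_resilient(
            self.model.cohort, self.labels, coverage=self.model.coverage
        )

    # -- diagnostics -----------------------------------------------------
    @property
    def selection_shortfalls(self) -> list:
        return self.selection.shortfalls

    @property
    def control_flags(self) -> pd.DataFrame:
        """Controls passing the full point system — the self-check the
        method demands come out (near) empty."""
        sc = self.scorecards
        return sc[(sc["group"] == "control") & (sc["label"] == "control_flagged")]

    def summary(self) -> str:
        rep = self.incidence_report()
        lines = []
        lines.append("Susceptibility classification")
        lines.append("=" * 64)
        lines.append(
            f"cutoff |z| > {self.cutoff:g}   coverage {self.model.coverage:.0%}   "
            f"transform policy {self.model.transform_policy}"
        )
        lines.append("")
        lines.append("Incidence (susceptible / classifiable exposed):")
        for _, row in rep.rows.iterrows():
            lines.append(
                f"  {row['scope']:<8} {row['n_susceptible']:>3}/{row['n_exposed']:<3}"
                f" = {row['percentage']:6.2f}%   controls flagged: "
                f"{row['n_control_flagged']}/{row['n_control']}"
            )
        if self.effect_sizes is not None:
            sel = self.effect_sizes[self.effect_sizes["selected"]]
            lines.append("")
            lines.append(
                f"Selected parameters (|effect| > "
                f"{self.model.effect_cutoff:g}): {len(sel)} of "
                f"{len(self.effect_sizes)} (sex, parameter) pairs"
            )
        if self.selection_shortfalls:
            lines.append("Selection shortfalls (criterion, sex, n selected):")
            for sex, crit, n in self.selection_shortfalls:
                lines.append(f"  {crit} ({sex}): {n}")
        for sex, name, msg in self.classification.warnings:
            lines.append(f"warning [{sex}/{name}]: {msg}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        try:
            inc = f"{self.incidence():.4f}"
        except Exception:
            inc = "n/a"
        return (
            f"<SusceptibilityResults n={self.model.cohort.n_mice} "
            f"incidence={inc} cutoff={self.cutoff:g}>"
        )
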