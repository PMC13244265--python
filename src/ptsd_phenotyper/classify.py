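"""The susceptibility classifier: control-referenced absolute z-scores,
the 85%-CI exceedance rule, and the five-criterion point system.

Each mouse's value on each selected parameter is converted to an absolute
z-score against the *control* mean and SD of its own sex, on the analysis
(transformed) scale.  A parameter counts as extreme when |z| is strictly
above the cutoff — by default 1.44, the two-sided 85% standard-normal
critical value.  A mouse earns one point per measurable criterion if at
least one of that criterion's selected parameters is extreme; an exposed
mouse with all five points (B, C, D, E, G) is labeled susceptible, any
other exposed mouse resilient.  Control mice pass through the identical
scoring as a self-check: a control with five points is labeled
``control_flagged``, never susceptible.  Composite (averaged) z-scores are
deliberately not offered: averaging lets one wildly deviant parameter
dominate the score, which the even per-criterion point system is designed
to avoid.

The binary Barnes-probe outcome has no z-score; it counts as extreme when
the mouse shows the pathological outcome (fail) *and* that outcome is rare
in controls (prevalence at or below 1 − coverage, 0.15 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .cohort import GROUP_COLUMN, SEX_COLUMN, CohortTable
from .effects import GroupStats, SelectionResult
from .preprocess import TransformPlan, transformed_frame

DEFAULT_COVERAGE = 0.85
DEFAULT_CUTOFF = 1.44  # round(critical_z(0.85), 2), the conventional value

LABEL_SUSCEPTIBLE = "susceptible"
LABEL_RESILIENT = "resilient"
LABEL_CONTROL = "control"
LABEL_CONTROL_FLAGGED = "control_flagged"
LABEL_UNCLASSIFIABLE = "unclassifiable"


class ClassifyError(ValueError):
    pass


def critical_z(coverage: float = DEFAULT_COVERAGE) -> float:
    """Two-sided standard-normal critical value at the given coverage
    (quantile at (1+coverage)/2); 1.4395… at 85%, conventionally 1.44."""
    if not 0 < coverage < 1:
        raise ClassifyError("coverage must be in (0, 1)")
    return float(_sps.norm.ppf((1 + coverage) / 2))


@dataclass(frozen=True)
class BinaryControlStats:
    sex: str
    parameter: str
    failure_prevalence: float
    n_control: int


def control_stats(
    cohort: CohortTable, plan: TransformPlan
) -> dict[tuple[str, str], object]:
    """Control mean/SD (sample SD, n−1) per (sex, parameter) on the analysis
    scale; binary parameters yield the control failure prevalence instead."""
    tx = transformed_frame(cohort, plan)
    out: dict[tuple[str, str], object] = {}
    for sex in cohort.sexes:
        txs = tx[(tx[SEX_COLUMN] == sex) & (tx[GROUP_COLUMN] == "control")]
        raw = cohort.subset(sex=sex)
        rawc = raw[raw[GROUP_COLUMN] == "control"]
        expo = tx[(tx[SEX_COLUMN] == sex) & (tx[GROUP_COLUMN] == "exposed")]
        for p in cohort.catalog.all_parameters:
            if p.kind == "continuous":
                vals = txs[p.name].dropna()
                if len(vals) < 2:
                    raise ClassifyError(f"{p.name} ({sex}): fewer than 2 control values")
                sd = float(vals.std(ddof=1))
                if sd == 0:
                    raise ClassifyError(f"{p.name} ({sex}): zero control SD")
                ev = expo[p.name].dropna()
                out[(sex, p.name)] = GroupStats(
                    sex=sex,
                    parameter=p.name,
                    scale="transformed",
                    control_mean=float(vals.mean()),
                    control_sd=sd,
                    exposed_mean=float(ev.mean()) if len(ev) else float("nan"),
                    n_control=len(vals),
                    n_exposed=len(ev),
                )
            else:
                vals = rawc[p.name].dropna()
                if len(vals) < 2:
                    raise ClassifyError(f"{p.name} ({sex}): fewer than 2 control values")
                out[(sex, p.name)] = BinaryControlStats(
                    sex=sex,
                    parameter=p.name,
                    failure_prevalence=float((vals == "fail").mean()),
                    n_control=len(vals),
                )
    return out


@dataclass(frozen=True)
class ZScoreRecord:
    mouse_id: str
    parameter: str
    z_signed: float
    z_abs: float
    exceeds: bool


def zscore(
    value: float,
    stats: GroupStats,
    cutoff: float = DEFAULT_CUTOFF,
    mouse_id: str = "",
) -> Optional[ZScoreRecord]:
    """Signed and absolute z of one value against control stats; ``None``
    (a missing record, never zero) when the value is missing."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    z = (value - stats.control_mean) / stats.control_sd
    return ZScoreRecord(
        mouse_id=mouse_id,
        parameter=stats.parameter,
        z_signed=float(z),
        z_abs=abs(float(z)),
        exceeds=bool(abs(z) > cutoff),
    )


def binary_exceedance(
    outcome: Optional[str],
    control_prevalence_of_outcome: float,
    rarity_bound: float = 1 - DEFAULT_COVERAGE,
    pathological_outcome: str = "fail",
) -> tuple[bool, Optional[str]]:
    """Exceedance rule for a binary parameter.

    True iff the mouse shows the pathological outcome and that outcome is
    rare in controls (prevalence ≤ rarity_bound).  Returns (flag, warning);
    a common-in-controls pathological outcome yields a warning because the
    parameter cannot separate anything at that prevalence.
    """
    if outcome is None or (isinstance(outcome, float) and math.isnan(outcome)):
        return False, None
    if outcome != pathological_outcome:
        return False, None
    if control_prevalence_of_outcome > rarity_bound:
        return False, (
            f"binary parameter uninformative: control prevalence "
            f"{control_prevalence_of_outcome:.2f} > {rarity_bound:.2f}"
        )
    return True, None


@dataclass
class ClassificationResult:
    """Scorecards and incidence for one classified cohort."""

    scorecards: pd.DataFrame  # mouse_id, sex, group, points_*, total_points, label
    zscores: pd.DataFrame  # long: mouse_id, sex, parameter, z_signed, z_abs, exceeds
    cutoff: float
    coverage: float
    selection: SelectionResult
    warnings: list = field(default_factory=list)

    @property
    def labels(self) -> pd.DataFrame:
        return self.scorecards[
            ["mouse_id", "sex", "group", "total_points", "label"]
        ].copy()

    def counts(self, sex: Optional[str] = None) -> dict:
        df = self.scorecards
        if sex is not None:
            df = df[df["sex"] == sex]
        exposed = df[df["group"] == "exposed"]
        classifiable = exposed[exposed["label"] != LABEL_UNCLASSIFIABLE]
        controls = df[df["group"] == "control"]
        return {
            "n_exposed": int(len(classifiable)),
            "n_susceptible": int((classifiable["label"] == LABEL_SUSCEPTIBLE).sum()),
            "n_resilient": int((classifiable["label"] == LABEL_RESILIENT).sum()),
            "n_unclassifiable": int((exposed["label"] == LABEL_UNCLASSIFIABLE).sum()),
            "n_control": int(len(controls)),
            "n_control_flagged": int(
                (controls["label"] == LABEL_CONTROL_FLAGGED).sum()
            ),
        }

    def incidence(self, sex: Optional[str] = None) -> float:
        c = self.counts(sex)
        if c["n_exposed"] == 0:
            raise ClassifyError("zero classifiable exposed mice")
        return c["n_susceptible"] / c["n_exposed"]


def classify_cohort(
    cohort: CohortTable,
    selection: SelectionResult,
    plan: TransformPlan,
    coverage: float = DEFAULT_COVERAGE,
    use_exact_quantile: bool = False,
    cutoff: Optional[float] = None,
    stats: Optional[dict] = None,
) -> ClassificationResult:
    """Score every mouse and label exposed mice susceptible/resilient.

    The cutoff defaults to the conventional two-decimal rounding of the
    two-sided critical value (1.44 at 85% coverage); ``use_exact_quantile``
    switches to the exact quantile (1.4395…), which only changes outcomes
    for |z| falling inside (1.4395, 1.44].  Exact ties with the cutoff do
    not count as exceedances ("above" is strict).  Control statistics use
    all control mice, including when scoring controls themselves.
    """
    if cutoff is None:
        q = critical_z(coverage)
        cutoff = q if use_exact_quantile else round(q, 2)
    rarity_bound = 1 - coverage
    if stats is None:
        stats = control_stats(cohort, plan)
    tx = transformed_frame(cohort, plan)
    catalog = cohort.catalog
    warnings: list = []
    z_frames = []
    sex_cards = []
    for sex in cohort.sexes:
        mask = cohort.frame[SEX_COLUMN] == sex
        sub = cohort.frame[mask].reset_index(drop=True)
        txs = tx[mask.to_numpy()].reset_index(drop=True)
        selected_union = sorted(
            {
                name
                for crit in catalog.measurable_criteria
                for name in selection.parameters_for(sex, crit)
            }
        )
        # per-parameter exceedance matrix (columns: parameter)
        exceed = pd.DataFrame(index=sub.index)
        observed = pd.DataFrame(index=sub.index)
        for name in selected_union:
            spec = catalog.get(name)
            st = stats[(sex, name)]
            if spec.kind == "continuous":
                z = (txs[name] - st.control_mean) / st.control_sd
                exceed[name] = z.abs() > cutoff
                observed[name] = txs[name].notna()
                z_frames.append(
                    pd.DataFrame(
                        {
                            "mouse_id": sub["mouse_id"],
                            "sex": sex,
                            "parameter": name,
                            "z_signed": z,
                            "z_abs": z.abs(),
                            "exceeds": z.abs() > cutoff,
                        }
                    )[z.notna()]
                )
            else:
                outcomes = sub[name]
                prev = (
                    st.failure_prevalence
                    if spec.pathological_outcome == "fail"
                    else 1 - st.failure_prevalence
                )
                is_path = outcomes == spec.pathological_outcome
                if prev > rarity_bound:
                    if is_path.any():
                        warnings.append(
                            (
                                sex,
                                name,
                                f"binary parameter uninformative: control "
                                f"prevalence {prev:.2f} > {rarity_bound:.2f}",
                            )
                        )
                    exceed[name] = False
                else:
                    exceed[name] = is_path.fillna(False).astype(bool)
                observed[name] = outcomes.notna()
        cards = sub[["mouse_id", SEX_COLUMN, GROUP_COLUMN]].copy()
        cards.columns = ["mouse_id", "sex", "group"]
        classifiable = pd.Series(True, index=sub.index)
        total = pd.Series(0, index=sub.index)
        for crit in catalog.measurable_criteria:
            names = list(selection.parameters_for(sex, crit))
            pt = exceed[names].any(axis=1).astype(int)
            crit_observed = observed[names].any(axis=1)
            classifiable &= crit_observed
            cards[f"points_{crit}"] = pt
            total = total + pt
        cards["total_points"] = total
        n_crit = len(catalog.measurable_criteria)
        is_ctrl = cards["group"] == "control"
        label = np.where(
            ~classifiable,
            LABEL_UNCLASSIFIABLE,
            np.where(
                is_ctrl,
                np.where(total == n_crit, LABEL_CONTROL_FLAGGED, LABEL_CONTROL),
                np.where(total == n_crit, LABEL_SUSCEPTIBLE, LABEL_RESILIENT),
            ),
        )
        cards["label"] = label
        sex_cards.append(cards)
    scorecards = pd.concat(sex_cards, ignore_index=True)
    # restore original cohort row order
    order = {m: i for i, m in enumerate(cohort.frame["mouse_id"])}
    scorecards = (
        scorecards.assign(_o=scorecards["mouse_id"].map(order))
        .sort_values("_o")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    zscores = (
        pd.concat(z_frames, ignore_index=True)
        if z_frames
        else pd.DataFrame(
            columns=["mouse_id", "sex", "parameter", "z_signed", "z_abs", "exceeds"]
        )
    )
    # deduplicate warnings
    warnings = list(dict.fromkeys(warnings))
    return ClassificationResult(
        scorecards=scorecards,
        zscores=zscores,
        cutoff=float(cutoff),
        coverage=coverage,
        selection=selection,
        warnings=warnings,
    )


def score_criteria(
    cohort: CohortTable,
    mouse_id: str,
    selection: SelectionResult,
    plan: TransformPlan,
    coverage: float = DEFAULT_COVERAGE,
    cutoff: Optional[float] = None,
) -> pd.Series:
    """Scorecard row for a single mouse (convenience wrapper)."""
    result = classify_cohort(cohort, selection, plan, coverage, cutoff=cutoff)
    row = result.scorecards[result.scorecards["mouse_id"] == mouse_id]
    if row.empty:
        raise KeyError(mouse_id)
    return row.iloc[0]
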