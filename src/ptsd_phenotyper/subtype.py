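"""Secondary phenotyping of resilient mice: aberrant sucrose consumption
(anhedonia axis) and hyperlocomotion.

Resilient mice — exposed mice that did not reach five criterion points —
are re-scored on two axes: sucrose consumed per gram body weight (the
anhedonia readout; canonically decreased, but trauma cohorts can show the
opposite) and average open-field velocity on the square-root scale.  Both
use signed z-scores against the same-sex control mean and SD at the same
1.44 cutoff.  Consumption is judged two-sided with a direction annotation
(increased if z > +cutoff, decreased if z < −cutoff); hyperlocomotion is
one-sided by meaning (z > +cutoff only).  The four-way subtype is
{neither, increased_consumption, hyperlocomotive, both}; decreased-
consumption variants are reported distinctly when they occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .classify import DEFAULT_COVERAGE, ClassificationResult, critical_z
from .cohort import GROUP_COLUMN, SEX_COLUMN, WEIGHT_COLUMN, CohortTable
from .preprocess import apply_transform

CONSUMPTION_NUMERATOR = "sucrose_consumed_24h"
VELOCITY_PARAM = "of_avg_velocity"
VELOCITY_TRANSFORM = "sqrt"

SUBTYPE_NEITHER = "neither"
SUBTYPE_INCREASED = "increased_consumption"
SUBTYPE_DECREASED = "decreased_consumption"
SUBTYPE_HYPER = "hyperlocomotive"
SUBTYPE_BOTH = "both"
SUBTYPE_DECREASED_HYPER = "decreased_consumption_hyperlocomotive"

FOUR_WAY = (SUBTYPE_INCREASED, SUBTYPE_BOTH, SUBTYPE_HYPER, SUBTYPE_NEITHER)


class SubtypeError(ValueError):
    pass


def round_pct(numerator: float, denominator: float, places: int = 2) -> float:
    """Percentage rounded half-away-from-zero to ``places`` decimals."""
    if denominator == 0:
        raise SubtypeError("zero denominator")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    q = Decimal(10) ** -places
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SubtypeResult:
    """Per-resilient-mouse subtype table plus cross-tabs."""

    table: pd.DataFrame  # mouse_id, sex, z_consumption, z_velocity, flags, subtype
    excluded: list = field(default_factory=list)  # (mouse_id, reason)
    cutoff: float = 1.44

    def crosstab(self) -> pd.DataFrame:
        """Counts and percentages per sex and pooled; every percentage is
        printed beside its numerator/denominator."""
        return subtype_crosstab(self.table)


def subtype_crosstab(labels: pd.DataFrame) -> pd.DataFrame:
    """Cross-tab of subtype labels: rows = (scope, subtype) with count,
    denominator and percentage; scope is each sex then 'pooled'.

    ``labels`` needs columns ``sex`` and ``subtype``.
    """
    categories = [c for c in FOUR_WAY] + [
        c
        for c in (SUBTYPE_DECREASED, SUBTYPE_DECREASED_HYPER)
        if (labels["subtype"] == c).any()
    ]
    rows = []
    scopes = [(s, labels[labels["sex"] == s]) for s in ("female", "male")
              if (labels["sex"] == s).any()]
    scopes.append(("pooled", labels))
    for scope, df in scopes:
        denom = len(df)
        for cat in categories:
            n = int((df["subtype"] == cat).sum())
            rows.append(
                {
                    "scope": scope,
                    "subtype": cat,
                    "count": n,
                    "denominator": denom,
                    "percentage": round_pct(n, denom) if denom else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def subtype_resilient(
    cohort: CohortTable,
    labels: pd.DataFrame,
    coverage: float = DEFAULT_COVERAGE,
    cutoff: Optional[float] = None,
) -> SubtypeResult:
    """Assign consumption/locomotion subtypes to resilient mice.

    ``labels`` is the classifier's label frame (mouse_id, label).  Control
    statistics for both axes are computed from the cohort's control mice of
    the same sex; mice missing body weight, consumption or velocity are
    excluded with a logged reason rather than silently dropped.
    """
    if cutoff is None:
        cutoff = round(critical_z(coverage), 2)
    if isinstance(labels, ClassificationResult):
        labels = labels.labels
    df = cohort.frame.set_index("mouse_id", drop=False)
    if WEIGHT_COLUMN not in df.columns:
        raise SubtypeError("cohort has no body_weight column")
    resilient_ids = labels[labels["label"] == "resilient"]["mouse_id"].tolist()

    # per-sex control stats for both axes
    stats = {}
    for sex in cohort.sexes:
        ctrl = df[(df[SEX_COLUMN] == sex) & (df[GROUP_COLUMN] == "control")]
        cons = (ctrl[CONSUMPTION_NUMERATOR] / ctrl[WEIGHT_COLUMN]).dropna()
        vel = apply_transform(
            ctrl[VELOCITY_PARAM], VELOCITY_TRANSFORM, parameter=VELOCITY_PARAM
        ).dropna()
        for name, vals in (("consumption", cons), ("velocity", vel)):
            if len(vals) < 2 or vals.std(ddof=1) == 0:
                raise SubtypeError(f"degenerate control {name} stats for {sex}")
            stats[(sex, name)] = (float(vals.mean()), float(vals.std(ddof=1)))

    rows = []
    excluded = []
    for mid in resilient_ids:
        mouse = df.loc[mid]
        sex = mouse[SEX_COLUMN]
        bw = mouse.get(WEIGHT_COLUMN)
        if pd.isna(bw):
            excluded.append((mid, "missing body weight"))
            continue
        if pd.isna(mouse[CONSUMPTION_NUMERATOR]):
            excluded.append((mid, f"missing {CONSUMPTION_NUMERATOR}"))
            continue
        if pd.isna(mouse[VELOCITY_PARAM]):
            excluded.append((mid, f"missing {VELOCITY_PARAM}"))
            continue
        mu_c, sd_c = stats[(sex, "consumption")]
        mu_v, sd_v = stats[(sex, "velocity")]
        z_cons = (mouse[CONSUMPTION_NUMERATOR] / bw - mu_c) / sd_c
        z_vel = (np.sqrt(mouse[VELOCITY_PARAM]) - mu_v) / sd_v
        aberrant = abs(z_cons) > cutoff
        increased = aberrant and z_cons > 0
        hyper = z_vel > cutoff  # one-sided: "hyper" means elevated
        if aberrant and hyper:
            subtype = SUBTYPE_BOTH if increased else SUBTYPE_DECREASED_HYPER
        elif aberrant:
            subtype = SUBTYPE_INCREASED if increased else SUBTYPE_DECREASED
        elif hyper:
            subtype = SUBTYPE_HYPER
        else:
            subtype = SUBTYPE_NEITHER
        rows.append(
            {
                "mouse_id": mid,
                "sex": sex,
                "z_consumption": float(z_cons),
                "z_velocity": float(z_vel),
                "aberrant_consumption": bool(aberrant),
                "consumption_direction": (
                    "increased" if increased else "decreased" if aberrant else ""
                ),
                "hyperlocomotive": bool(hyper),
                "subtype": subtype,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "mouse_id",
            "sex",
            "z_consumption",
            "z_velocity",
            "aberrant_consumption",
            "consumption_direction",
            "hyperlocomotive",
            "subtype",
        ],
    )
    return SubtypeResult(table=table, excluded=excluded, cutoff=float(cutoff))
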