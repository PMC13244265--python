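"""Normality screening and variance-stabilizing transforms.

Every downstream statistic (effect sizes, control means/SDs, z-scores) is
computed on the transformed scale, so the transform choice is part of the
analysis contract.  Two policies are supported:

* ``catalog_fixed`` — use the transform each parameter declares in the
  catalog (the standard battery declares log for the reminder-test
  inactivity percentages and novel-mouse latency, sqrt for the EPM
  open/closed ratio and open-field velocity).
* ``auto`` — screen each parameter with the D'Agostino–Pearson omnibus K²
  test at alpha = 0.05 on the pooled per-sex sample; if non-normal, try log
  then sqrt and adopt the first transform that passes for every sex, else
  keep identity and flag the parameter as non-normal.

Log transforms of columns containing zeros are offset by half the smallest
positive observed value of that column; the offset is recorded in the plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GROUP_COLUMN, SEX_COLUMN, CohortTable

MIN_NORMALITY_N = 8  # mathematical minimum for the kurtosis component
SMALL_SAMPLE_N = 20
DEFAULT_ALPHA = 0.05


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class NormalityResult:
    """One D'Agostino–Pearson omnibus test: K² against chi-square(2)."""

    parameter: str
    sex: str
    group_scope: str  # "control" or "pooled"
    statistic: float
    p_value: float
    n: int
    warning: Optional[str] = None


def dagostino_pearson(
    values, parameter: str = "", sex: str = "", group_scope: str = "pooled"
) -> NormalityResult:
    """D'Agostino–Pearson omnibus normality test (K² = z_skew² + z_kurt²)."""
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < MIN_NORMALITY_N:
        raise PreprocessError(
            f"insufficient sample for normality test (n={len(x)} < {MIN_NORMALITY_N})"
        )
    if np.ptp(x) == 0:
        raise PreprocessError("degenerate sample: zero variance")
    stat, p = stats.normaltest(x)
    warning = f"small sample (n={len(x)} < {SMALL_SAMPLE_N})" if len(x) < SMALL_SAMPLE_N else None
    return NormalityResult(
        parameter=parameter,
        sex=sex,
        group_scope=group_scope,
        statistic=float(stat),
        p_value=float(p),
        n=len(x),
        warning=warning,
    )


def apply_transform(values, transform: str, offset: float = 0.0, parameter: str = ""):
    """Apply identity/log/sqrt elementwise; order-preserving on its domain.

    ``values`` may be a Series (index = mouse ids, used in error messages)
    or any array-like; missing values pass through as NaN.
    """
    s = pd.Series(values, dtype=float)
    if transform == "identity":
        out = s
    elif transform == "log":
        shifted = s + offset
        bad = shifted[shifted.notna() & (shifted <= 0)]
        if len(bad):
            raise PreprocessError(
                f"log transform of non-positive value for parameter "
                f"{parameter!r}, mouse {bad.index[0]!r}"
            )
        out = np.log(shifted)
    elif transform == "sqrt":
        bad = s[s.notna() & (s < 0)]
        if len(bad):
            raise PreprocessError(
                f"sqrt transform of negative value for parameter "
                f"{parameter!r}, mouse {bad.index[0]!r}"
            )
        out = np.sqrt(s)
    else:
        raise PreprocessError(f"unknown transform {transform!r}")
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return np.asarray(out)


@dataclass(frozen=True)
class TransformEntry:
    parameter: str
    transform: str
    offset: float = 0.0
    non_normal: bool = False  # auto policy exhausted the ladder
    evidence: tuple = ()  # NormalityResults, raw then transformed


@dataclass
class TransformPlan:
    """Chosen transform (and any log offset) per parameter."""

    entries: dict = field(default_factory=dict)  # name -> TransformEntry
    policy: str = "catalog_fixed"
    alpha: float = DEFAULT_ALPHA
    scope: str = "pooled"

    def transform_for(self, parameter: str) -> TransformEntry:
        return self.entries[parameter]

    def apply(self, parameter: str, values):
        e = self.entries[parameter]
        return apply_transform(values, e.transform, e.offset, parameter)

    def to_json(self, path=None) -> str:
        doc = {
            "policy": self.policy,
            "alpha": self.alpha,
            "scope": self.scope,
            "entries": {
                name: {
                    "transform": e.transform,
                    "offset": e.offset,
                    "non_normal": e.non_normal,
                    "evidence": [
                        {
                            "sex": r.sex,
                            "group_scope": r.group_scope,
                            "stage": stage,
                            "statistic": r.statistic,
                            "p_value": r.p_value,
                            "n": r.n,
                        }
                        for stage, r in e.evidence
                    ],
                }
                for name, e in self.entries.items()
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "TransformPlan":
        try:
            doc = json.loads(source)
        except (ValueError, TypeError):
            with open(source, encoding="utf-8") as fh:
                doc = json.load(fh)
        entries = {
            name: TransformEntry(
                parameter=name,
                transform=d["transform"],
                offset=d.get("offset", 0.0),
                non_normal=d.get("non_normal", False),
            )
            for name, d in doc["entries"].items()
        }
        return cls(
            entries=entries,
            policy=doc.get("policy", "catalog_fixed"),
            alpha=doc.get("alpha", DEFAULT_ALPHA),
            scope=doc.get("scope", "pooled"),
        )


def _log_offset(col: pd.Series) -> float:
    vals = col.dropna()
    if (vals > 0).all():
        return 0.0
    positive = vals[vals > 0]
    if positive.empty:
        raise PreprocessError("log transform impossible: no positive values")
    return float(positive.min()) / 2.0


def _sex_samples(cohort: CohortTable, name: str, scope: str):
    for sex in cohort.sexes:
        df = cohort.subset(sex=sex)
        if scope == "control":
            df = df[df[GROUP_COLUMN] == "control"]
        yield sex, df[name]


def resolve_transforms(
    cohort: CohortTable,
    policy: str = "catalog_fixed",
    scope: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
) -> TransformPlan:
    """Build the per-parameter transform plan for a cohort.

    ``catalog_fixed`` trusts each parameter's declared transform; ``auto``
    climbs the identity → log → sqrt ladder guided by the omnibus test per
    sex.  A single transform is chosen per parameter (a candidate must
    normalize every analyzed sex).
    """
    if policy not in ("catalog_fixed", "auto"):
        raise PreprocessError(f"unknown policy {policy!r}")
    if scope not in ("pooled", "control"):
        raise PreprocessError(f"unknown scope {scope!r}")
    plan = TransformPlan(policy=policy, alpha=alpha, scope=scope)
    for p in cohort.catalog.all_parameters:
        if p.kind != "continuous":
            plan.entries[p.name] = TransformEntry(parameter=p.name, transform="identity")
            continue
        col = cohort.frame[p.name]
        if policy == "catalog_fixed":
            offset = _log_offset(col) if p.transform == "log" else 0.0
            plan.entries[p.name] = TransformEntry(
                parameter=p.name, transform=p.transform, offset=offset
            )
            continue
        # auto ladder
        evidence = []
        raw_ps = []
        for sex, sample in _sex_samples(cohort, p.name, scope):
            r = dagostino_pearson(sample, p.name, sex, scope)
            evidence.append(("raw", r))
            raw_ps.append(r.p_value)
        if min(raw_ps) >= alpha:
            plan.entries[p.name] = TransformEntry(
                parameter=p.name, transform="identity", evidence=tuple(evidence)
            )
            continue
        chosen = None
        for cand in ("log", "sqrt"):
            offset = _log_offset(col) if cand == "log" else 0.0
            try:
                cand_ps = []
                cand_evidence = []
                for sex, sample in _sex_samples(cohort, p.name, scope):
                    tx = apply_transform(sample, cand, offset, p.name)
                    r = dagostino_pearson(tx, p.name, sex, scope)
                    cand_evidence.append((cand, r))
                    cand_ps.append(r.p_value)
            except PreprocessError:
                continue  # domain violation: transform not applicable
            if min(cand_ps) >= alpha:
                chosen = TransformEntry(
                    parameter=p.name,
                    transform=cand,
                    offset=offset,
                    evidence=tuple(evidence + cand_evidence),
                )
                break
            evidence.extend(cand_evidence)
        if chosen is None:
            chosen = TransformEntry(
                parameter=p.name,
                transform="identity",
                non_normal=True,
                evidence=tuple(evidence),
            )
        plan.entries[p.name] = chosen
    return plan


def transformed_frame(cohort: CohortTable, plan: TransformPlan) -> pd.DataFrame:
    """Continuous parameter columns on the analysis (transformed) scale,
    indexed like the cohort frame, with meta columns retained."""
    out = cohort.frame[["mouse_id", SEX_COLUMN, GROUP_COLUMN]].copy()
    for p in cohort.catalog.all_parameters:
        if p.kind != "continuous":
            continue
        col = cohort.frame[p.name].copy()
        col.index = cohort.frame["mouse_id"]
        tx = plan.apply(p.name, col)
        out[p.name] = np.asarray(tx)
    return out
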