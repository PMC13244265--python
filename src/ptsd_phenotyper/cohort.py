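"""Cohort table: one row per mouse, typed columns, strict CSV ingestion.

The canonical tidy layout is one row per mouse with columns ``mouse_id``,
``sex`` (female/male), ``group`` (control/exposed), optionally
``body_weight`` (grams), and one column per catalog parameter.  Continuous
cells are real numbers (empty = missing); binary cells use the tokens
``pass``/``fail`` (``1``/``0`` accepted on input, 1 = pass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .catalog import CriterionCatalog

SEXES = ("female", "male")
GROUPS = ("control", "exposed")

ID_COLUMN = "mouse_id"
SEX_COLUMN = "sex"
GROUP_COLUMN = "group"
WEIGHT_COLUMN = "body_weight"
_META_COLUMNS = (ID_COLUMN, SEX_COLUMN, GROUP_COLUMN)

_BINARY_TOKENS = {"pass": "pass", "fail": "fail", "1": "pass", "0": "fail"}


class CohortError(ValueError):
    """Raised for malformed cohort tables."""


@dataclass(frozen=True)
class MouseRecord:
    """A single mouse: identity, stratum, and raw parameter values."""

    mouse_id: str
    sex: str
    group: str
    values: dict
    body_weight: Optional[float] = None


@dataclass
class CohortTable:
    """A validated per-mouse behavioral table bound to a criterion catalog.

    Wraps a :class:`pandas.DataFrame` (``.frame``); continuous parameters are
    float columns with NaN for missing, binary parameters are object columns
    holding ``"pass"``/``"fail"``/NA.
    """

    frame: pd.DataFrame
    catalog: CriterionCatalog
    provenance: str = ""
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        df = self.frame
        for col in _META_COLUMNS:
            if col not in df.columns:
                raise CohortError(f"missing required column {col!r}")
        ids = df[ID_COLUMN].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise CohortError(f"duplicate mouse_id {dup.iloc[0]!r}")
        bad_sex = set(df[SEX_COLUMN]) - set(SEXES)
        if bad_sex:
            raise CohortError(f"unknown sex token {sorted(bad_sex)[0]!r}")
        bad_grp = set(df[GROUP_COLUMN]) - set(GROUPS)
        if bad_grp:
            raise CohortError(f"unknown group token {sorted(bad_grp)[0]!r}")
        for p in self.catalog.all_parameters:
            if p.name not in df.columns:
                raise CohortError(f"catalog parameter {p.name!r} absent from table")
            if p.kind == "continuous":
                col = pd.to_numeric(df[p.name], errors="coerce")
                # non-numeric tokens must not masquerade as missing
                bad = df[p.name].notna() & col.isna()
                if isinstance(bad, pd.Series) and bad.any():
                    raise CohortError(
                        f"non-numeric value in continuous column {p.name!r}"
                    )
                if np.isinf(col.to_numpy(dtype=float, na_value=np.nan)).any():
                    raise CohortError(f"non-finite value in column {p.name!r}")
                self.frame[p.name] = col.astype(float)
            else:
                vals = df[p.name]
                ok = vals.isna() | vals.isin(["pass", "fail"])
                if not ok.all():
                    raise CohortError(
                        f"binary column {p.name!r} holds a non pass/fail token"
                    )
        for sex in self.sexes:
            sub = df[df[SEX_COLUMN] == sex]
            for grp in GROUPS:
                if not (sub[GROUP_COLUMN] == grp).any():
                    raise CohortError(f"no {grp} mice of sex {sex!r}")
        if WEIGHT_COLUMN in df.columns:
            w = pd.to_numeric(df[WEIGHT_COLUMN], errors="coerce")
            if (w.dropna() <= 0).any():
                raise CohortError("non-positive body weight")
            self.frame[WEIGHT_COLUMN] = w.astype(float)

    # ------------------------------------------------------------------
    @property
    def sexes(self) -> tuple[str, ...]:
        present = self.frame[SEX_COLUMN].unique().tolist()
        return tuple(s for s in SEXES if s in present)

    @property
    def n_mice(self) -> int:
        return len(self.frame)

    def subset(self, sex: Optional[str] = None, group: Optional[str] = None) -> pd.DataFrame:
        df = self.frame
        if sex is not None:
            df = df[df[SEX_COLUMN] == sex]
        if group is not None:
            df = df[df[GROUP_COLUMN] == group]
        return df

    def records(self) -> Iterator[MouseRecord]:
        params = [p.name for p in self.catalog.all_parameters]
        for _, row in self.frame.iterrows():
            values = {}
            for name in params:
                v = row[name]
                if isinstance(v, float) and math.isnan(v):
                    v = None
                elif v is pd.NA or v is None:
                    v = None
                values[name] = v
            bw = row.get(WEIGHT_COLUMN)
            if bw is not None and isinstance(bw, float) and math.isnan(bw):
                bw = None
            yield MouseRecord(
                mouse_id=str(row[ID_COLUMN]),
                sex=row[SEX_COLUMN],
                group=row[GROUP_COLUMN],
                values=values,
                body_weight=bw,
            )

    # ------------------------------------------------------------------
    def write_csv(self, path) -> None:
        """Write the cohort; continuous cells use repr-round-trip floats so a
        write/load cycle is bit-exact."""
        df = self.frame.copy()
        for p in self.catalog.all_parameters:
            if p.kind == "continuous":
                df[p.name] = df[p.name].map(
                    lambda v: "" if pd.isna(v) else repr(float(v))
                )
        if WEIGHT_COLUMN in df.columns:
            df[WEIGHT_COLUMN] = df[WEIGHT_COLUMN].map(
                lambda v: "" if pd.isna(v) else repr(float(v))
            )
        df.to_csv(path, index=False)


def load_cohort(path, catalog: CriterionCatalog, provenance: str = "") -> CohortTable:
    """Read a tidy per-mouse CSV into a validated :class:`CohortTable`.

    Headers must match catalog parameter names exactly (case-sensitive, to
    avoid silent column mix-ups).  Binary cells accept pass/fail/1/0; empty
    cells are recorded as missing, never as zero.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise CohortError(f"CSV missing required column {col!r}")
    for p in catalog.all_parameters:
        if p.name not in df.columns:
            raise CohortError(f"CSV missing catalog parameter column {p.name!r}")
        if p.kind == "binary":
            def _parse(tok, _n=p.name):
                if tok is None:
                    return None
                t = str(tok).strip().lower()
                if t not in _BINARY_TOKENS:
                    raise CohortError(
                        f"binary column {_n!r}: unrecognized token {tok!r}"
                    )
                return _BINARY_TOKENS[t]

            df[p.name] = df[p.name].map(_parse)
    return CohortTable(frame=df, catalog=catalog, provenance=provenance or str(path))
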