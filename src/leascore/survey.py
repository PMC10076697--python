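"""Survey containers and spreadsheet round-trip.

A survey is a collection of respondents; each respondent carries 20 item
responses (self text + other text per scenario) and optional auxiliary
covariates: age, gender, education level, children, completion time in
minutes, and external scale totals (alexithymia, facial-affect perception,
theory-of-mind, depression and distress inventories) that enter the analyses
only as numeric columns.

Canonical spreadsheet layout (CSV or XLSX, UTF-8): one row per respondent,
header ``respondent_id``, ``item01_self``, ``item01_other``, ...,
``item20_self``, ``item20_other``, plus any auxiliary columns.  Blank item
cells are read as empty texts (logged); absent auxiliary values stay missing
— absent is never coerced to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValidationError
from .lexicon import WordList
from .scoring import (
    ALL_METHODS,
    LEVEL_METHODS,
    N_ITEMS,
    TEXT_METHODS,
    ItemResponse,
    score_item,
    score_protocol,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Respondent",
    "Survey",
    "DEFAULT_AUX_TYPES",
    "read_survey",
    "write_survey",
    "score_survey",
    "write_scores",
    "read_scores",
    "item_columns",
]

#: default typing of well-known auxiliary columns; everything else is kept
#: as text.  A schema_config mapping passed to read_survey overrides these.
DEFAULT_AUX_TYPES: dict[str, str] = {
    "age": "float",
    "education": "float",
    "time_minutes": "float",
    "tas20": "float",
    "pat": "float",
    "mss": "float",
    "bdi": "float",
    "dass": "float",
    "pat_like": "float",
    "gender": "str",
    "children": "str",
}


@dataclass
class Respondent:
    """One complete protocol: 20 item responses plus auxiliary covariates."""

    respondent_id: str
    items: dict[int, ItemResponse] = field(default_factory=dict)
    auxiliary: dict = field(default_factory=dict)

    def item(self, index: int) -> ItemResponse:
        return self.items.get(index, ItemResponse(index=index))


@dataclass
class Survey:
    """A set of respondents with load provenance."""

    respondents: list[Respondent]
    source: str | None = None
    loaded_at: datetime | None = None

    def __post_init__(self) -> None:
        ids = [r.respondent_id for r in self.respondents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate respondent_id(s): {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.respondents)

    def __iter__(self):
        return iter(self.respondents)

    @property
    def ids(self) -> list[str]:
        return [r.respondent_id for r in self.respondents]

    def aux_frame(self) -> pd.DataFrame:
        """Auxiliary covariates as a DataFrame indexed by respondent_id."""
        rows = {r.respondent_id: dict(r.auxiliary) for r in self.respondents}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "respondent_id"
        return df


def item_columns() -> list[str]:
    """The 40 canonical item column names, zero-padded."""
    cols = []
    for i in range(1, N_ITEMS + 1):
        cols.append(f"item{i:02d}_self")
        cols.append(f"item{i:02d}_other")
    return cols


def _coerce_aux(name: str, raw, kind: str, respondent_id: str):
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    if kind == "float":
        try:
            return float(raw)
        except (TypeError, ValueError):
            logger.warning(
                "respondent %s: auxiliary %s=%r is not numeric; treated as missing",
                respondent_id, name, raw,
            )
            return None
    if kind == "int":
        try:
            return int(float(raw))
        except (TypeError, ValueError):
            logger.warning(
                "respondent %s: auxiliary %s=%r is not an integer; treated as missing",
                respondent_id, name, raw,
            )
            return None
    return str(raw)


def read_survey(
    path: str | Path, schema_config: Mapping[str, str] | None = None
) -> Survey:
    """Read a survey spreadsheet (CSV or XLSX) into a :class:`Survey`.

    ``schema_config`` maps auxiliary column names to ``'float'``, ``'int'``
    or ``'str'``; unknown columns default to text.  Blank item cells become
    empty texts with a logged warning; malformed numeric auxiliaries become
    missing values with a per-cell warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path, dtype=object)
    else:
        df = pd.read_csv(path, dtype=object, encoding="utf-8", keep_default_na=False)
        df = df.replace({"": None})
    if "respondent_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'respondent_id'")
    aux_types = dict(DEFAULT_AUX_TYPES)
    if schema_config:
        aux_types.update(schema_config)

    expected_items = item_columns()
    present_items = [c for c in expected_items if c in df.columns]
    absent = sorted(set(expected_items) - set(present_items))
    if absent:
        logger.warning(
            "%s: %d item column(s) absent (e.g. %s); treated as empty texts",
            path, len(absent), absent[0],
        )
    aux_cols = [
        c for c in df.columns if c != "respondent_id" and c not in expected_items
    ]

    respondents: list[Respondent] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        rid = row["respondent_id"]
        if rid is None or str(rid).strip() == "":
            raise ValidationError(f"{path}: blank respondent_id")
        rid = str(rid)
        if rid in seen:
            raise ValidationError(f"{path}: duplicate respondent_id {rid!r}")
        seen.add(rid)
        items: dict[int, ItemResponse] = {}
        for i in range(1, N_ITEMS + 1):
            self_col, other_col = f"item{i:02d}_self", f"item{i:02d}_other"
            self_text = row[self_col] if self_col in df.columns else None
            other_text = row[other_col] if other_col in df.columns else None
            if self_text is None or (isinstance(self_text, float) and np.isnan(self_text)):
                if self_col in df.columns:
                    logger.warning("respondent %s: blank cell %s", rid, self_col)
                self_text = ""
            if other_text is None or (isinstance(other_text, float) and np.isnan(other_text)):
                if other_col in df.columns:
                    logger.warning("respondent %s: blank cell %s", rid, other_col)
                other_text = ""
            items[i] = ItemResponse(index=i, self_text=str(self_text), other_text=str(other_text))
        aux = {}
        for col in aux_cols:
            val = _coerce_aux(col, row[col], aux_types.get(col, "str"), rid)
            if val is not None:
                aux[col] = val
        respondents.append(Respondent(rid, items, aux))
    if not respondents:
        raise ValidationError(f"{path}: survey contains no respondents")
    return Survey(respondents, source=str(path), loaded_at=datetime.now(timezone.utc))


def write_survey(survey: Survey, path: str | Path) -> None:
    """Write a survey to the canonical CSV layout (read→write is idempotent)."""
    aux_cols = sorted({k for r in survey for k in r.auxiliary})
    rows = []
    for r in survey:
        row: dict = {"respondent_id": r.respondent_id}
        for i in range(1, N_ITEMS + 1):
            it = r.item(i)
            row[f"item{i:02d}_self"] = it.self_text
            row[f"item{i:02d}_other"] = it.other_text
        for c in aux_cols:
            row[c] = r.auxiliary.get(c, "")
        rows.append(row)
    cols = ["respondent_id"] + item_columns() + aux_cols
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, encoding="utf-8")


def score_survey(
    survey: Survey,
    wl: WordList | None,
    methods: Iterable[str] = LEVEL_METHODS,
) -> pd.DataFrame:
    """Score every respondent with every requested method.

    Returns the score table: a DataFrame indexed by respondent_id with
    columns ``<method>_item01`` .. ``<method>_item20`` and
    ``<method>_protocol`` per method; the ``time`` method contributes
    ``time_minutes`` and ``time_excluded`` columns instead.
    """
    methods = list(methods)
    unknown = [m for m in methods if m not in ALL_METHODS]
    if unknown:
        raise UsageError(
            f"unknown method(s) {', '.join(unknown)}; valid: {', '.join(ALL_METHODS)}"
        )
    if wl is None and any(m in LEVEL_METHODS for m in methods):
        raise UsageError("level methods require a wordlist")
    rows = []
    for r in survey:
        row: dict = {}
        for m in methods:
            if m == "time":
                ts = score_protocol(r, wl, "time")
                row["time_minutes"] = ts.minutes
                row["time_excluded"] = ts.excluded
                continue
            total = 0
            for i in range(1, N_ITEMS + 1):
                s = score_item(r.item(i), wl, m)
                row[f"{m}_item{i:02d}"] = s
                total += s
            row[f"{m}_protocol"] = total
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(survey.ids, name="respondent_id"))
    return table


def write_scores(
    survey: Survey,
    score_table: pd.DataFrame,
    path: str | Path,
    protocol_only: bool = False,
) -> None:
    """Write scores (plus auxiliary covariates) to CSV.

    The score table must be aligned to the survey's respondents.  With
    ``protocol_only`` only the ``*_protocol`` (and time) columns are kept.
    """
    if list(score_table.index) != survey.ids:
        raise UsageError("score table is not aligned to the survey's respondents")
    aux = survey.aux_frame()
    cols = list(score_table.columns)
    if protocol_only:
        cols = [
            c for c in cols
            if c.endswith("_protocol") or c in ("time_minutes", "time_excluded")
        ]
    # the score table wins where it re-emits an auxiliary column (time_minutes)
    aux = aux.drop(columns=[c for c in cols if c in aux.columns])
    out = aux.join(score_table[cols], how="right")
    out.to_csv(path, index=True, encoding="utf-8")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score file written by :func:`write_scores`."""
    df = pd.read_csv(path, encoding="utf-8")
    if "respondent_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'respondent_id'")
    df["respondent_id"] = df["respondent_id"].astype(str)
    return df.set_index("respondent_id")
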