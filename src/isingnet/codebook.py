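"""Item codebook, recoding rules, and descriptive tables.

Questionnaire items arrive in heterogeneous raw formats — yes/no items,
know/don't-know items, and 4-point Likert items — and are recoded to a
common {0,1} format before network estimation.  Knowledge items are keyed
so that a *correct* answer maps to 1 ("don't know" counts as incorrect);
Likert stigma items are dichotomized with agree / strongly agree coded as
endorsement.  Per-item keying is explicit in the codebook rather than
hard-wired, because published item wordings mix stigma-consistent and
stigma-inconsistent directions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodebookItem",
    "ItemCodebook",
    "BinaryResponseMatrix",
    "recode_item",
    "dichotomize_likert",
    "load_responses",
    "descriptive_table",
]

RESPONSE_TYPES = ("yes_no", "know_dontknow", "likert4")
COMMUNITIES = ("knowledge", "stigma")

# raw string labels accepted for the two binary response types, lowercase
_POLES = {
    "yes_no": {"positive": "yes", "negative": "no"},
    "know_dontknow": {"positive": "know", "negative": "don't know"},
}
_BINARY_DOMAIN = {
    "yes_no": {"yes", "no"},
    "know_dontknow": {"know", "don't know", "dont know", "don’t know"},
}


class CodebookError(ValueError):
    """Configuration problem in a codebook definition."""


class ResponseValidationError(ValueError):
    """Raw response outside its declared domain, or missing."""


@dataclass(frozen=True)
class CodebookItem:
    item_id: str
    wording: str
    community: str
    response_type: str
    key: str = "positive"

    def __post_init__(self) -> None:
        if self.community not in COMMUNITIES:
            raise CodebookError(f"{self.item_id}: unknown community {self.community!r}")
        if self.response_type not in RESPONSE_TYPES:
            raise CodebookError(
                f"{self.item_id}: unknown response_type {self.response_type!r}"
            )
        if self.key not in ("positive", "negative"):
            raise CodebookError(f"{self.item_id}: key must be positive/negative")
        if self.response_type == "likert4" and self.community != "stigma":
            raise CodebookError(
                f"{self.item_id}: likert4 items belong to the stigma community"
            )


@dataclass(frozen=True)
class ItemCodebook:
    """Ordered collection of items; order defines column order downstream."""

    items: tuple[CodebookItem, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise CodebookError("item_ids must be unique")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    @property
    def communities(self) -> tuple[str, ...]:
        return tuple(it.community for it in self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> CodebookItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemCodebook":
        rows = json.loads(Path(path).read_text())
        return cls(tuple(CodebookItem(**row) for row in rows))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ItemCodebook":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(tuple(CodebookItem(**row) for row in rows))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps([it.__dict__ for it in self.items], indent=1))


@dataclass(frozen=True)
class BinaryResponseMatrix:
    """n×p matrix of {0,1} responses with row/column identity.

    ``group`` optionally labels each respondent (e.g. sex) for two-group
    network comparisons.
    """

    values: np.ndarray
    item_ids: tuple[str, ...]
    respondent_ids: tuple = ()
    group: tuple | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ResponseValidationError("values must be 2-D")
        if not np.isin(v, (0, 1)).all():
            raise ResponseValidationError("values must be 0/1 with no missing entries")
        object.__setattr__(self, "values", v.astype(np.int8))
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        if len(self.item_ids) != v.shape[1]:
            raise ResponseValidationError("item_ids must match the number of columns")
        rids = tuple(self.respondent_ids) if self.respondent_ids else tuple(range(v.shape[0]))
        object.__setattr__(self, "respondent_ids", rids)
        if len(rids) != v.shape[0]:
            raise ResponseValidationError("respondent_ids must match the number of rows")
        if self.group is not None:
            object.__setattr__(self, "group", tuple(self.group))
            if len(self.group) != v.shape[0]:
                raise ResponseValidationError("group must match the number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def require_both_classes(self) -> None:
        """Reject zero-variance columns, for which estimation is undefined."""
        means = self.values.mean(axis=0)
        bad = [self.item_ids[j] for j in np.nonzero((means == 0) | (means == 1))[0]]
        if bad:
            raise ResponseValidationError(
                f"zero-variance item(s), both response values required: {bad}"
            )

    def split_by_group(self) -> dict:
        if self.group is None:
            raise ResponseValidationError("matrix has no group labels")
        out = {}
        g = np.asarray(self.group)
        for label in pd.unique(g):
            mask = g == label
            out[label] = BinaryResponseMatrix(
                self.values[mask],
                self.item_ids,
                tuple(np.asarray(self.respondent_ids, dtype=object)[mask]),
            )
        return out

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=list(self.item_ids))
        if self.group is not None:
            df.insert(0, "group", list(self.group))
        df.to_csv(path, index=False)


def dichotomize_likert(
    raw: Sequence[int] | np.ndarray,
    key: str = "positive",
    agree_codes: Iterable[int] = (1, 2),
) -> np.ndarray:
    """Collapse a 4-point Likert vector to endorsement {0,1}.

    ``agree_codes`` declares which numeric codes mean agree / strongly
    agree (default convention: 1 = strongly agree … 4 = strongly
    disagree, so {1, 2} endorse).  ``key='negative'`` flips the result
    for reverse-keyed items.
    """
    arr = np.asarray(raw)
    vals = arr.astype(float)
    if not np.isin(vals, (1, 2, 3, 4)).all():
        bad = vals[~np.isin(vals, (1, 2, 3, 4))]
        raise ResponseValidationError(f"likert4 values must be in 1..4, got {bad[:5]}")
    out = np.isin(vals, list(agree_codes)).astype(np.int8)
    if key == "negative":
        out = (1 - out).astype(np.int8)
    elif key != "positive":
        raise CodebookError(f"unknown key {key!r}")
    return out


def recode_item(
    raw: Sequence,
    response_type: str,
    key: str = "positive",
    agree_codes: Iterable[int] = (1, 2),
) -> np.ndarray:
    """Map a raw response vector to {0,1} per its type and keying.

    For yes/no and know/don't-know items the keyed pole (the *correct*
    answer for knowledge items) maps to 1 and everything else — including
    "don't know" — to 0.  Likert items delegate to
    :func:`dichotomize_likert`.
    """
    if response_type == "likert4":
        return dichotomize_likert(raw, key=key, agree_codes=agree_codes)
    if response_type not in _POLES:
        raise CodebookError(f"unknown response_type {response_type!r}")
    target = _POLES[response_type][key]
    out = np.empty(len(raw), dtype=np.int8)
    for i, v in enumerate(raw):
        s = str(v).strip().lower().replace("’", "'").replace("dont", "don't")
        if s not in _BINARY_DOMAIN[response_type]:
            raise ResponseValidationError(
                f"value {v!r} outside domain of {response_type} item"
            )
        out[i] = 1 if s == target or s.replace("'", "") == target.replace("'", "") else 0
    return out


def load_responses(
    path: str | Path,
    codebook: ItemCodebook,
    group_col: str | None = "group",
    agree_codes: Iterable[int] = (1, 2),
) -> BinaryResponseMatrix:
    """Read a responses CSV and recode every column per the codebook.

    The CSV must have one column per codebook item (extra columns beyond
    an optional group column are an error) and no missing cells; row
    order is preserved.
    """
    df = pd.read_csv(path, dtype=object, keep_default_na=False, na_values=[""])
    missing_cols = [i for i in codebook.item_ids if i not in df.columns]
    if missing_cols:
        raise CodebookError(f"responses file lacks columns: {missing_cols}")
    if df.shape[0] == 0:
        raise ResponseValidationError("responses file has no rows")
    for item_id in codebook.item_ids:
        col = df[item_id]
        if col.isna().any():
            row = int(np.nonzero(col.isna().to_numpy())[0][0])
            raise ResponseValidationError(
                f"missing response at row {row}, item {item_id!r}"
            )
    cols = []
    for it in codebook.items:
        raw = df[it.item_id].to_numpy()
        if it.response_type == "likert4":
            try:
                raw = raw.astype(float)
            except ValueError as exc:
                raise ResponseValidationError(
                    f"non-numeric likert4 value in item {it.item_id!r}"
                ) from exc
        try:
            cols.append(recode_item(raw, it.response_type, it.key, agree_codes))
        except ResponseValidationError as exc:
            raise ResponseValidationError(f"item {it.item_id!r}: {exc}") from exc
    values = np.column_stack(cols)
    group = None
    if group_col is not None and group_col in df.columns:
        group = tuple(df[group_col])
    return BinaryResponseMatrix(values, codebook.item_ids, tuple(df.index), group)


def _pct(endorsed: int, n: int) -> float:
    """Percent endorsed, rounded half-up to 2 decimal places."""
    return float(
        (Decimal(endorsed) * 100 / Decimal(n)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def descriptive_table(X: BinaryResponseMatrix) -> pd.DataFrame:
    """Per-item endorsement counts and percentages (survey-table style).

    Columns: item_id, n_endorsed, n_not_endorsed, pct_endorsed (2 dp,
    half-up rounding, matching how such tables are printed).
    """
    if X.n == 0:
        raise ResponseValidationError("empty response matrix")
    endorsed = X.values.sum(axis=0)
    rows = [
        {
            "item_id": item,
            "n_endorsed": int(e),
            "n_not_endorsed": int(X.n - e),
            "pct_endorsed": _pct(int(e), X.n),
        }
        for item, e in zip(X.item_ids, endorsed)
    ]
    return pd.DataFrame(rows)
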