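"""Long-format ratings container and CSV I/O.

One row per single ordinal grade, keyed by (rater, subject, segment,
item).  The Mayo subscore is a per-examination grade and is stored with
the sentinel segment ``"overall"``; the four EMES items are always tied
to a real colonic segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .scales import EMES_ITEMS, ITEM_SCALES, OVERALL, Segment

CSV_COLUMNS = ["rater_id", "subject_id", "segment", "item", "value"]

_VALID_SEGMENTS = {s.value for s in Segment} | {OVERALL}


class RatingsValidationError(ValueError):
    """The ratings table violates the schema; carries offending row numbers."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        shown = problems[:20]
        more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
        super().__init__("; ".join(shown) + more)


@dataclass(frozen=True)
class RatingRecord:
    """A single ordinal grade assigned by one rater."""

    rater_id: str
    subject_id: str
    segment: str  # a Segment value or "overall" (Mayo only)
    item: str
    value: int


class RatingsTable:
    """Validated long-format collection of :class:`RatingRecord`.

    Wraps a :class:`pandas.DataFrame` with columns
    ``rater_id, subject_id, segment, item, value``.  Construction
    validates the whole table; invalid input raises
    :class:`RatingsValidationError` listing every offending row (1-based,
    counting the header as row 1 when read from CSV).
    """

    def __init__(self, frame: pd.DataFrame):
        self._frame = _validate(frame)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RatingsTable):
            return NotImplemented
        a = self._frame.sort_values(CSV_COLUMNS).reset_index(drop=True)
        b = other._frame.sort_values(CSV_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    @property
    def raters(self) -> list[str]:
        return sorted(self._frame["rater_id"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self._frame["subject_id"].unique())

    @classmethod
    def from_records(cls, records: Iterable[RatingRecord]) -> "RatingsTable":
        rows = [
            (r.rater_id, r.subject_id, r.segment, r.item, r.value)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=CSV_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingsTable":
        df = pd.read_csv(path, dtype={c: str for c in CSV_COLUMNS[:-1]})
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        out = self._frame.sort_values(CSV_COLUMNS).reset_index(drop=True)
        out.to_csv(path, index=False, lineterminator="\n")

    def select(self, item: str, segment: str | Segment | None = None) -> pd.DataFrame:
        """Rows for one item (and segment, unless the item is 'mayo')."""
        df = self._frame
        sel = df[df["item"] == item]
        if item == "mayo":
            return sel
        if segment is None:
            raise ValueError(f"segment required for item {item!r}")
        seg = segment.value if isinstance(segment, Segment) else str(segment)
        return sel[sel["segment"] == seg]


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise RatingsValidationError(
            [f"missing columns: {', '.join(missing)}"]
        )
    df = frame[CSV_COLUMNS].copy()
    for col in CSV_COLUMNS[:-1]:
        df[col] = df[col].astype(str)

    problems: list[str] = []
    # 1-based data row numbers, +1 for a CSV header line
    rownum = pd.RangeIndex(2, len(df) + 2)

    bad_val = pd.to_numeric(df["value"], errors="coerce")
    for i in rownum[bad_val.isna() | (bad_val != bad_val.round())]:
        problems.append(f"row {i}: non-integer value")
    df["value"] = bad_val.fillna(-1).astype(int)

    unknown_item = ~df["item"].isin(ITEM_SCALES)
    for i in rownum[unknown_item.to_numpy()]:
        problems.append(f"row {i}: unknown item")
    unknown_seg = ~df["segment"].isin(_VALID_SEGMENTS)
    for i in rownum[unknown_seg.to_numpy()]:
        problems.append(f"row {i}: unknown segment")

    ok = ~(unknown_item | unknown_seg)
    is_mayo = df["item"] == "mayo"
    is_overall = df["segment"] == OVERALL
    mism = ok & (is_mayo ^ is_overall)
    for i in rownum[mism.to_numpy()]:
        problems.append(
            f"row {i}: item 'mayo' requires segment 'overall' and vice versa"
        )

    for item, scale in ITEM_SCALES.items():
        rows = ok & (df["item"] == item)
        out_of_scale = rows & (
            (df["value"] < 0) | (df["value"] > scale.max_grade)
        )
        for i in rownum[out_of_scale.to_numpy()]:
            problems.append(
                f"row {i}: value outside {item} scale 0..{scale.max_grade}"
            )

    dup = df.duplicated(subset=CSV_COLUMNS[:-1], keep="first")
    for i in rownum[dup.to_numpy()]:
        problems.append(f"row {i}: duplicate (rater, subject, segment, item)")

    if problems:
        raise RatingsValidationError(problems)
    return df.reset_index(drop=True)


__all__ = [
    "RatingRecord",
    "RatingsTable",
    "RatingsValidationError",
    "CSV_COLUMNS",
    "EMES_ITEMS",
]
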