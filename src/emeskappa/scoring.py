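"""EMES segment and global scores, and per-subject across-rater summaries.

A segment score is the plain sum of the four item grades (erythema 0-3,
submucosal vascular pattern 0-2, erosions 0-3, ulcers 0-3), giving 0-11
per segment.  The global score sums the five segment scores (0-55) and
is defined only for complete examinations: a colonoscopy missing a
segment has no global EMES (no rescaling is applied).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .scales import (
    EMES_ITEMS,
    ITEM_SCALES,
    SEGMENTS,
    ScaleError,
    Segment,
)


class IncompleteExaminationError(ValueError):
    """A global score or summary was requested for a partial colonoscopy."""


@dataclass(frozen=True)
class SegmentGrades:
    """The four EMES item grades for one colonic segment."""

    erythema: int
    vascular_pattern: int
    erosions: int
    ulcers: int

    def __post_init__(self) -> None:
        for item in EMES_ITEMS:
            ITEM_SCALES[item].validate(getattr(self, item), context=item)

    def as_dict(self) -> dict[str, int]:
        return {item: getattr(self, item) for item in EMES_ITEMS}


def segment_score(grades: SegmentGrades) -> int:
    """Sum the four item grades of one segment; range 0-11."""
    return sum(getattr(grades, item) for item in EMES_ITEMS)


def global_score(per_segment: Mapping[Segment | str, SegmentGrades]) -> int:
    """Sum the five segment scores; range 0-55.

    Requires grades for all five segments; raises
    :class:`IncompleteExaminationError` listing any that are missing.
    """
    keyed = {Segment(seg): g for seg, g in per_segment.items()}
    missing = [s.value for s in SEGMENTS if s not in keyed]
    if missing:
        raise IncompleteExaminationError(
            "global EMES undefined: missing segments " + ", ".join(missing)
        )
    return sum(segment_score(keyed[s]) for s in SEGMENTS)


def per_rater_scores(table, score: str) -> pd.DataFrame:
    """Per-(subject, rater) derived scores from a ratings table.

    Parameters
    ----------
    table
        A :class:`~emeskappa.ratings.RatingsTable`.
    score
        ``"mayo"``, ``"segment_emes"`` or ``"global_emes"``.  For
        ``segment_emes`` the result has one row per (subject, rater,
        segment); otherwise one row per (subject, rater).

    Returns
    -------
    DataFrame with columns ``subject_id, rater_id[, segment], score``.
    Raters missing any constituent item of a derived score for a subject
    are dropped for that subject (a rater must grade all four items of a
    segment to yield its segment score, and all five segments to yield a
    global score).
    """
    df = table.frame
    if score == "mayo":
        sub = df[df["item"] == "mayo"]
        out = sub[["subject_id", "rater_id", "value"]].rename(
            columns={"value": "score"}
        )
        return out.reset_index(drop=True)

    emes = df[df["item"].isin(EMES_ITEMS)]
    wide = emes.pivot_table(
        index=["subject_id", "rater_id", "segment"],
        columns="item",
        values="value",
        aggfunc="first",
    )
    wide = wide.dropna()  # complete segments only
    seg_scores = wide.reindex(columns=list(EMES_ITEMS)).sum(axis=1).astype(int)
    seg_df = seg_scores.rename("score").reset_index()

    if score == "segment_emes":
        return seg_df
    if score == "global_emes":
        n_seg = seg_df.groupby(["subject_id", "rater_id"])["segment"].nunique()
        totals = seg_df.groupby(["subject_id", "rater_id"])["score"].sum()
        complete = n_seg[n_seg == len(SEGMENTS)].index
        out = totals.loc[complete].rename("score").reset_index()
        return out
    raise ValueError(f"unknown derived score {score!r}")


def summarize_across_raters(
    table, subject_id: str, score: str
) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of per-rater scores for one subject.

    ``score`` is ``"mayo"`` or ``"global_emes"``.  At least two raters
    must have scored the subject on the requested scale; for the global
    EMES each contributing rater must have graded all five segments.
    """
    if score not in ("mayo", "global_emes"):
        raise ValueError(f"score must be 'mayo' or 'global_emes', got {score!r}")
    scores = per_rater_scores(table, score)
    vals = scores.loc[scores["subject_id"] == subject_id, "score"].to_numpy()
    if score == "global_emes":
        # distinguish "no complete examination" from "too few raters"
        any_rating = table.frame[
            (table.frame["subject_id"] == subject_id)
            & (table.frame["item"].isin(EMES_ITEMS))
        ]
        if len(any_rating) and len(vals) == 0:
            raise IncompleteExaminationError(
                f"subject {subject_id!r}: no rater graded all five segments"
            )
    if len(vals) < 2:
        raise ValueError(
            f"subject {subject_id!r}: need >=2 raters on {score!r}, "
            f"got {len(vals)}"
        )
    return float(np.mean(vals)), float(np.std(vals, ddof=1))


def max_segment_grades() -> SegmentGrades:
    """The grade profile with every item at its maximum."""
    return SegmentGrades(
        **{item: ITEM_SCALES[item].max_grade for item in EMES_ITEMS}
    )


__all__ = [
    "SegmentGrades",
    "IncompleteExaminationError",
    "segment_score",
    "global_score",
    "per_rater_scores",
    "summarize_across_raters",
    "max_segment_grades",
    "ScaleError",
]
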