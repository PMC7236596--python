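"""Ordinal scales and colonic segments used by the EMES and Mayo scores.

The Extended Mayo Endoscopic Score (EMES) grades four mucosal features
per colonic segment on small ordinal scales; the Mayo endoscopic subscore
is a single 0-3 grade per examination.  Derived scales (segment EMES
0-11, global EMES 0-55) are also expressed as :class:`OrdinalItemScale`
so that agreement statistics always operate on a closed, fixed category
space rather than on the categories that happen to be observed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class ScaleError(ValueError):
    """A grade falls outside its ordinal scale, or a scale is malformed."""


class Segment(str, Enum):
    """The five colonic segments, ordered proximal to distal."""

    ASCENDING = "ascending"
    TRANSVERSE = "transverse"
    DESCENDING = "descending"
    SIGMOID = "sigmoid"
    RECTUM = "rectum"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed proximal-to-distal ordering of the five segments.
SEGMENTS: tuple[Segment, ...] = tuple(Segment)

#: Sentinel segment value for per-examination (whole-colon) records such
#: as the Mayo endoscopic subscore.
OVERALL = "overall"


@dataclass(frozen=True)
class OrdinalItemScale:
    """A named, contiguous ordinal category set.

    Categories are the consecutive integers ``0 .. len(labels) - 1``;
    ``labels`` carries the clinical meaning of each grade.
    """

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ScaleError(
                f"scale {self.name!r} needs at least 2 categories, "
                f"got {len(self.labels)}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    @property
    def categories(self) -> range:
        return range(len(self.labels))

    @property
    def max_grade(self) -> int:
        return len(self.labels) - 1

    def validate(self, value: int, context: str = "") -> int:
        """Return ``value`` as int if it is a grade of this scale, else raise."""
        try:
            iv = int(value)
        except (TypeError, ValueError):
            iv = None
        if iv is None or iv != value or not 0 <= iv <= self.max_grade:
            where = f" ({context})" if context else ""
            raise ScaleError(
                f"grade {value!r} outside scale {self.name!r} "
                f"[0..{self.max_grade}]{where}"
            )
        return iv


def _numeric_scale(name: str, maximum: int) -> OrdinalItemScale:
    return OrdinalItemScale(name, tuple(str(i) for i in range(maximum + 1)))


ERYTHEMA = OrdinalItemScale(
    "erythema", ("absent", "mild", "moderate", "severe")
)
VASCULAR_PATTERN = OrdinalItemScale(
    "vascular_pattern", ("normal", "reduction", "disappearance")
)
EROSIONS = OrdinalItemScale(
    "erosions", ("absent", "1-5 lesions", "6-10 lesions", ">10 lesions")
)
ULCERS = OrdinalItemScale(
    "ulcers", ("absent", "1-5 lesions", "6-10 lesions", ">10 lesions")
)
MAYO = OrdinalItemScale(
    "mayo",
    (
        "normal",
        "erythema, decreased vascular pattern, mild friability",
        "marked erythema, absent vascular pattern, friability, erosions",
        "ulceration, spontaneous bleeding",
    ),
)

#: Derived per-segment EMES score: sum of the four item grades, 0-11.
SEGMENT_EMES = _numeric_scale("segment_emes", 11)
#: Derived global EMES score: sum of the five segment scores, 0-55.
GLOBAL_EMES = _numeric_scale("global_emes", 55)

#: The four per-segment EMES items, in reporting order.
EMES_ITEMS: tuple[str, ...] = (
    "erythema",
    "vascular_pattern",
    "erosions",
    "ulcers",
)

#: All directly rated items (EMES items plus the Mayo subscore).
ITEM_SCALES: dict[str, OrdinalItemScale] = {
    "erythema": ERYTHEMA,
    "vascular_pattern": VASCULAR_PATTERN,
    "erosions": EROSIONS,
    "ulcers": ULCERS,
    "mayo": MAYO,
}

#: Every scale addressable by name, including derived score scales.
ALL_SCALES: dict[str, OrdinalItemScale] = {
    **ITEM_SCALES,
    "segment_emes": SEGMENT_EMES,
    "global_emes": GLOBAL_EMES,
}
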