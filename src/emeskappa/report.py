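"""Whole-study agreement analysis and its tabular report.

``analyze_study`` runs one kappa analysis per reporting cell of a
complete rating study:

* each of the four EMES items in each of the five segments (20 cells),
* the derived segment EMES score (0-11) per segment (5 cells),
* the global EMES score (0-55),
* the Mayo endoscopic subscore (optional).

Cells that cannot be estimated (a constant item, or fewer than two
usable subjects) are flagged and reported with NaN estimates; the rest
of the report is still computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .agreement import (
    KappaResult,
    build_count_matrix,
    kappa_analysis,
    make_weights,
)
from .scales import ALL_SCALES, EMES_ITEMS, SEGMENTS

REPORT_COLUMNS = [
    "scale", "segment", "item", "kappa", "se", "ci_low", "ci_high",
    "p_value", "label", "n_subjects", "n_raters_min", "n_raters_max",
    "scheme", "flag",
]


@dataclass(frozen=True)
class ReportEntry:
    """One reporting cell: which scale/segment/item, and its result."""

    scale: str      # item | segment_emes | global_emes | mayo
    segment: str    # segment name, or "" for whole-colon scales
    item: str       # item name, or "" for derived scores
    result: KappaResult


@dataclass
class AgreementReport:
    """Ordered collection of per-cell kappa results plus run metadata."""

    entries: list[ReportEntry]
    scheme: str
    ci_method: str
    seed: int
    version: str = field(default_factory=lambda: __version__)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, scale: str, segment: str = "", item: str = "") -> KappaResult:
        for e in self.entries:
            if (e.scale, e.segment, e.item) == (scale, segment, item):
                return e.result
        raise KeyError(f"no entry for ({scale!r}, {segment!r}, {item!r})")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"scale": e.scale, "segment": e.segment, "item": e.item}
            row.update(e.result.as_dict())
            row.pop("pa"), row.pop("pe")
            rows.append(row)
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, lineterminator="\n")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "metadata": {
                "scheme": self.scheme,
                "ci_method": self.ci_method,
                "seed": self.seed,
                "version": self.version,
            },
            "entries": [
                {
                    "scale": e.scale,
                    "segment": e.segment,
                    "item": e.item,
                    **e.result.as_dict(),
                }
                for e in self.entries
            ],
        }
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def forest_data(self) -> pd.DataFrame:
        """Entry label, kappa and CI bounds, ready for a forest plot."""
        rows = []
        for e in self.entries:
            name = e.scale if not e.segment else f"{e.segment}"
            if e.item:
                name = f"{e.segment}:{e.item}" if e.segment else e.item
            elif e.scale == "segment_emes":
                name = f"{e.segment}:emes"
            rows.append(
                {
                    "entry": name,
                    "kappa": e.result.kappa,
                    "ci_low": e.result.ci_low,
                    "ci_high": e.result.ci_high,
                }
            )
        return pd.DataFrame(rows, columns=["entry", "kappa", "ci_low", "ci_high"])


def _cell(table, item, segment, scheme, ci_method, B, seed) -> KappaResult:
    scale = ALL_SCALES[item]
    weights = make_weights(scheme, scale.n_categories)
    try:
        counts = build_count_matrix(table, item, segment)
        if counts.n_subjects < 2:
            raise ValueError("fewer than 2 usable subjects")
    except ValueError as exc:
        return KappaResult(
            kappa=float("nan"), se=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p_value=float("nan"), pa=float("nan"),
            pe=float("nan"), n_subjects=0, n_raters_min=0, n_raters_max=0,
            scheme=scheme, label="", flag=f"unusable: {exc}",
        )
    return kappa_analysis(
        counts, weights, ci_method=ci_method, B=B, seed=seed
    )


def analyze_study(
    table,
    scheme: str = "linear",
    ci_method: str = "asymptotic",
    B: int = 2000,
    seed: int = 0,
    include_mayo: bool = True,
) -> AgreementReport:
    """Run the full per-cell agreement analysis on a ratings table.

    Returns 26 entries (20 item-level, 5 segment-level, 1 global EMES),
    plus the Mayo subscore entry when ``include_mayo`` is true.
    """
    entries: list[ReportEntry] = []
    for seg in SEGMENTS:
        for item in EMES_ITEMS:
            res = _cell(table, item, seg.value, scheme, ci_method, B, seed)
            entries.append(ReportEntry("item", seg.value, item, res))
    for seg in SEGMENTS:
        res = _cell(table, "segment_emes", seg.value, scheme, ci_method, B, seed)
        entries.append(ReportEntry("segment_emes", seg.value, "", res))
    res = _cell(table, "global_emes", None, scheme, ci_method, B, seed)
    entries.append(ReportEntry("global_emes", "", "", res))
    if include_mayo:
        res = _cell(table, "mayo", None, scheme, ci_method, B, seed)
        entries.append(ReportEntry("mayo", "", "", res))
    return AgreementReport(
        entries=entries, scheme=scheme, ci_method=ci_method, seed=seed
    )


__all__ = ["AgreementReport", "ReportEntry", "analyze_study", "REPORT_COLUMNS"]
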