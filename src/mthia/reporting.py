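"""End-to-end report assembly: a classification table plus summary counts.

Rows are grouped by category in the published order (not-enough-evidence,
unlikely, undetermined, likely, expectedly, proven) and sorted by rRNA
residue within each group; printed labels are preserved verbatim next to
canonical machine labels so every row stays traceable to its source table.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .conservation import ConservationScore
from .errors import InputError
from .fixtures import FixtureRow, load_fixture
from .hia_rubric import CATEGORY_ORDER, Category, classify, classify_all
from .variant_model import MtVariant, ResidueEquivalence, format_variant

_GROUP_RANK = {cat: i for i, cat in enumerate(CATEGORY_ORDER)}

COLUMNS = [
    "category", "rrna_label", "mt_label", "label_as_printed",
    "rrna_position", "mt_position", "human_partner",
    "bacterial_equivalent", "bacterial_partner", "tunnel",
    "conservation_codes", "cv", "note",
]


@dataclass(frozen=True)
class ClassifiedVariant:
    """A variant with its structural annotations and assigned category."""

    variant: MtVariant
    equivalence: ResidueEquivalence
    category: Category
    code_strings: tuple[str, ...] = ()
    cv: Optional[ConservationScore] = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.equivalence.human_residue != self.variant.rrna_position:
            raise InputError(
                f"equivalence residue {self.equivalence.human_residue} does not "
                f"match variant position {self.variant.rrna_position}"
            )


def classify_fixture(rows: Sequence[FixtureRow] | None = None
                     ) -> list[ClassifiedVariant]:
    """Run the rubric over fixture rows (the packaged table by default)."""
    if rows is None:
        rows = load_fixture()
    return [
        ClassifiedVariant(
            variant=row.variant,
            equivalence=row.equivalence,
            category=classify(row.profile),
            note=row.equivalence.note,
        )
        for row in rows
    ]


def build_report(
    classified: Sequence[ClassifiedVariant],
) -> tuple[pd.DataFrame, Counter]:
    """Assemble the report table and the category histogram."""
    if not classified:
        raise InputError("nothing to report")
    records = []
    for cv in classified:
        var, eq = cv.variant, cv.equivalence
        records.append({
            "category": cv.category.value,
            "rrna_label": format_variant(var, "rrna"),
            "mt_label": format_variant(var, "mtdna"),
            "label_as_printed": var.label_as_printed or "",
            "rrna_position": var.rrna_position,
            "mt_position": var.mt_position,
            "human_partner": eq.human_partner_raw or (
                str(eq.human_partner) if eq.human_partner else ""),
            "bacterial_equivalent": eq.bacterial_residue or "",
            "bacterial_partner": eq.bacterial_partner or "",
            "tunnel": "Y" if eq.tunnel_flag else "",
            "conservation_codes": ";".join(cv.code_strings),
            "cv": f"{cv.cv.cv:.3f}" if cv.cv is not None else "",
            "note": cv.note,
        })
    frame = pd.DataFrame.from_records(records, columns=COLUMNS)
    frame = frame.sort_values(
        by=["category", "rrna_position"],
        key=lambda col: col.map(lambda v: _GROUP_RANK[Category(v)])
        if col.name == "category" else col,
        kind="stable",
    ).reset_index(drop=True)
    histogram = Counter({c: 0 for c in Category})
    histogram.update(cv.category for cv in classified)
    return frame, histogram


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a bit-stable TSV: fixed column order, LF endings, no trailing
    whitespace; re-reading reproduces the table."""
    path = Path(path)
    text = report.to_csv(sep="\t", index=False, lineterminator="\n")
    path.write_text(text, newline="")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False).astype(
        {"rrna_position": int, "mt_position": int}
    )


def histogram_to_json(histogram: Counter) -> str:
    return json.dumps(
        {cat.value: histogram.get(cat, 0) for cat in Category},
        indent=1, sort_keys=True,
    )
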