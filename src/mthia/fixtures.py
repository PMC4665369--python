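"""Loader for the packaged curated-variant table.

The packaged TSV transcribes the published classification table of 64 rare
16S mt-rRNA variants: the printed labels in both numbering dialects, the
canonical base-pair partners (human and bacterial), the peptide-exit-tunnel
flag, and the evidence profile distilled from the accompanying case
narratives.  Cells left blank in print stay blank here; typographic quirks
of the printed table are kept verbatim and noted in the ``note`` column.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .errors import InputError
from .hia_rubric import Category, EvidenceProfile, Support
from .variant_model import (
    CoordinateMapper,
    MtVariant,
    ResidueEquivalence,
    calibrate_mapper,
    parse_variant_label,
)

_COLUMNS = [
    "category", "rrna_label", "mt_label", "human_partner",
    "bacterial_equivalent", "bacterial_partner", "tunnel",
    "placeable", "het_data", "direct", "indirect", "mito_biochem", "note",
]


@dataclass(frozen=True)
class FixtureRow:
    """One curated variant with its annotations and evidence profile."""

    category: Category
    rrna_label: str
    mt_label: str
    variant: MtVariant
    equivalence: ResidueEquivalence
    profile: EvidenceProfile


def _parse_partner(cell: str) -> Optional[int]:
    m = re.match(r"(\d+)[ACGU]?$", cell.strip())
    return int(m.group(1)) if m else None


def _flag(cell: str) -> bool:
    return cell.strip().upper() == "Y"


def default_fixture_path() -> Path:
    return Path(resources.files("mthia").joinpath("data/table1.tsv"))  # type: ignore[arg-type]


def load_fixture(
    path: str | Path | None = None,
    mapper: CoordinateMapper | None = None,
) -> list[FixtureRow]:
    """Read a curated-variant TSV into fixture rows.

    The variant labels are parsed with the standard gene mapper so every
    row carries both numberings; rows violating the constant-offset
    invariant surface as range/parse errors here rather than downstream.
    """
    path = Path(path) if path is not None else default_fixture_path()
    rows: list[FixtureRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[: len(_COLUMNS) - 1] != _COLUMNS[:-1]:
            raise InputError(f"unexpected fixture header in {path}")
        for raw in reader:
            if not raw or not any(cell.strip() for cell in raw):
                continue
            raw = (raw + [""] * len(_COLUMNS))[: len(_COLUMNS)]
            rec = dict(zip(_COLUMNS, raw))
            variant = parse_variant_label(rec["rrna_label"], mapper=mapper)
            equivalence = ResidueEquivalence(
                human_residue=variant.rrna_position,
                mt_label=rec["mt_label"],
                human_partner=_parse_partner(rec["human_partner"]),
                human_partner_raw=rec["human_partner"].strip(),
                bacterial_residue=rec["bacterial_equivalent"].strip() or None,
                bacterial_partner=rec["bacterial_partner"].strip() or None,
                tunnel_flag=_flag(rec["tunnel"]),
                note=rec["note"].strip(),
            )
            profile = EvidenceProfile(
                placeable_on_structure=_flag(rec["placeable"]),
                heterologous_data_exists=_flag(rec["het_data"]),
                direct_heterologous=Support(rec["direct"].strip()),
                indirect_heterologous=Support(rec["indirect"].strip()),
                direct_mito_biochemical=_flag(rec["mito_biochem"]),
            )
            rows.append(
                FixtureRow(
                    category=Category(rec["category"].strip()),
                    rrna_label=rec["rrna_label"].strip(),
                    mt_label=rec["mt_label"].strip(),
                    variant=variant,
                    equivalence=equivalence,
                    profile=profile,
                )
            )
    return rows


def fixture_mapper(rows: list[FixtureRow] | None = None) -> CoordinateMapper:
    """Calibrate the coordinate mapper from the fixture's double numbering."""
    if rows is None:
        rows = load_fixture()
    # Calibrate from printed mt labels against printed rRNA positions.
    equivalences = []
    for row in rows:
        equivalences.append(
            ResidueEquivalence(
                human_residue=row.variant.rrna_position, mt_label=row.mt_label
            )
        )
    return calibrate_mapper(equivalences)
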