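"""Variant representation and coordinate mapping for the human 16S mt-rRNA.

The large-subunit mitochondrial rRNA (gene *MT-RNR2*) is described in two
numbering systems: 1-based residue indices within the mature rRNA, and
"m." coordinates on the revised Cambridge Reference Sequence (rCRS,
NC_012920.1).  The two differ by a single constant offset over the whole
gene, which this module calibrates from curated variant tables and applies
as a bijection on the gene span.

Variant labels occur in several dialects in the curated literature
(``122G > A``, ``m.2074delA``, ``478-479 dupAG``, ``1328 InsU``,
``449 3T > 4T``); :func:`parse_variant_label` accepts all of them and
normalizes alleles to the RNA alphabet internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .errors import CalibrationError, RangeError, VariantParseError

#: rCRS coordinate minus rRNA residue index, constant over the 16S gene.
DEFAULT_OFFSET = 1670
#: Annotated rCRS interval of the 16S (MT-RNR2) gene, inclusive, 1-based.
DEFAULT_GENE_SPAN = (1671, 3229)
#: Length of the mature 16S mt-rRNA implied by the annotated span.
GENE_LENGTH = DEFAULT_GENE_SPAN[1] - DEFAULT_GENE_SPAN[0] + 1

_RNA = "ACGU"
_DNA2RNA = str.maketrans("Tt", "Uu")


class Event(str, Enum):
    """Kind of sequence change recorded for a variant."""

    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    HOMOPOLYMER_LENGTH_CHANGE = "homopolymer_length_change"


@dataclass(frozen=True)
class CoordinateMapper:
    """Bijective mapping between rRNA residue indices and m. coordinates.

    Attributes
    ----------
    offset:
        ``mt_position - rrna_position``, constant over the gene.
    gene_span:
        Inclusive 1-based rCRS interval covered by the gene.
    """

    offset: int = DEFAULT_OFFSET
    gene_span: tuple[int, int] = DEFAULT_GENE_SPAN

    @property
    def rrna_span(self) -> tuple[int, int]:
        return (self.gene_span[0] - self.offset, self.gene_span[1] - self.offset)

    def to_mtdna(self, rrna_position: int) -> int:
        lo, hi = self.rrna_span
        if not lo <= rrna_position <= hi:
            raise RangeError(
                f"rRNA residue {rrna_position} outside gene span {lo}..{hi}"
            )
        return rrna_position + self.offset

    def to_rrna(self, mt_position: int) -> int:
        lo, hi = self.gene_span
        if not lo <= mt_position <= hi:
            raise RangeError(
                f"m.{mt_position} outside 16S gene span m.{lo}..m.{hi}"
            )
        return mt_position - self.offset


@dataclass(frozen=True)
class MtVariant:
    """One mitochondrial 16S rRNA variant.

    Alleles are stored in the RNA alphabet regardless of the dialect the
    label was written in; ``alt_allele`` is empty for deletions.  For
    duplications ``ref_allele`` is the duplicated unit and ``alt_allele``
    the doubled unit; for homopolymer-length changes the two alleles are
    the old and new runs.
    """

    rrna_position: int
    mt_position: Optional[int]
    ref_allele: str
    alt_allele: str
    event: Event
    heteroplasmy: Optional[float] = None
    source_context: Optional[str] = None
    label_as_printed: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event is Event.SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise VariantParseError(
                    f"substitution alleles must be single bases: "
                    f"{self.ref_allele!r}>{self.alt_allele!r}"
                )
            if self.ref_allele == self.alt_allele:
                raise VariantParseError(
                    f"substitution with identical alleles {self.ref_allele!r}"
                )
        if self.event is Event.DELETION and self.alt_allele:
            raise VariantParseError("deletion must have an empty alt allele")
        if self.heteroplasmy is not None and not 0.0 <= self.heteroplasmy <= 1.0:
            raise VariantParseError(
                f"heteroplasmy fraction {self.heteroplasmy} outside [0, 1]"
            )

    @property
    def signature(self) -> tuple:
        """Identity key used when counting appearances across sequences."""
        return (self.rrna_position, self.event.value, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class ResidueEquivalence:
    """Cross-kingdom equivalence record for one curated variant site.

    Houses the curated-table columns: the human residue and its canonical
    base-pair partner, the bacterial (E. coli-numbered) equivalent and its
    partner, and whether the site lines the peptide exit tunnel.  Bacterial
    fields are absent where the printed table leaves them blank.
    """

    human_residue: int
    mt_label: str
    human_partner: Optional[int] = None
    human_partner_raw: str = ""
    bacterial_residue: Optional[str] = None
    bacterial_partner: Optional[str] = None
    tunnel_flag: bool = False
    note: str = ""

    @property
    def mt_position(self) -> Optional[int]:
        m = re.search(r"m\.[ACGTUacgtu]?(\d+)", self.mt_label)
        return int(m.group(1)) if m else None


def _normalize(label: str) -> str:
    """Fold typographic variants: en-dash/minus to '-', '≥' to '>'."""
    out = label.strip()
    for dash in ("–", "—", "−"):
        out = out.replace(dash, "-")
    out = out.replace("≥", ">")
    return re.sub(r"\s+", " ", out)


# Dialect grammar.  A stray base letter between "m." and the position occurs
# in printed tables (e.g. "m.C1905C > A") and is tolerated.
_PREFIX = r"(?P<mt>m\.)?[ACGTUacgtu]?(?=\d)"
_RE_HOMOPOLYMER = re.compile(
    _PREFIX + r"(?P<pos>\d+) ?(?P<n1>\d+)(?P<b1>[ACGTUacgtu]) ?> ?"
    r"(?P<n2>\d+)(?P<b2>[ACGTUacgtu])$"
)
_RE_SUBSTITUTION = re.compile(
    _PREFIX + r"(?P<pos>\d+) ?(?P<ref>[A-Za-z]) ?> ?(?P<alt>[A-Za-z])$"
)
_RE_DELETION = re.compile(
    _PREFIX + r"(?P<pos>\d+)(?:-(?P<pos2>\d+))? ?[Dd][Ee][Ll](?P<bases>[ACGTUacgtu]+)$"
)
_RE_INSERTION = re.compile(
    _PREFIX + r"(?P<pos>\d+) ?[Ii][Nn][Ss](?P<bases>[ACGTUacgtu]+)$"
)
_RE_DUPLICATION = re.compile(
    _PREFIX + r"(?P<pos>\d+)-(?P<pos2>\d+) ?[Dd][Uu][Pp](?P<bases>[ACGTUacgtu]+)$"
)


def _to_rna(bases: str) -> str:
    out = bases.translate(_DNA2RNA).upper()
    bad = set(out) - set(_RNA)
    if bad:
        raise VariantParseError(f"invalid nucleotide token {''.join(sorted(bad))!r}")
    return out


def parse_variant_label(
    label: str, mapper: CoordinateMapper | None = None
) -> MtVariant:
    """Parse a variant label in any of the curated-table dialects.

    rRNA-numbered labels gain their m. coordinate through ``mapper`` and
    vice versa.  Raises :class:`VariantParseError` on an unparseable label
    and :class:`RangeError` when the position falls outside the gene span.
    """
    if mapper is None:
        mapper = CoordinateMapper()
    text = _normalize(label)
    if not text:
        raise VariantParseError("empty variant label")

    m = _RE_HOMOPOLYMER.match(text)
    if m:
        base = _to_rna(m.group("b1"))
        if _to_rna(m.group("b2")) != base:
            raise VariantParseError(
                f"homopolymer label changes base identity: {label!r}"
            )
        n1, n2 = int(m.group("n1")), int(m.group("n2"))
        if n1 == n2 or n1 < 1 or n2 < 1:
            raise VariantParseError(f"homopolymer run lengths invalid: {label!r}")
        rrna, mt = _positions(int(m.group("pos")), m.group("mt"), mapper)
        return MtVariant(rrna, mt, base * n1, base * n2,
                         Event.HOMOPOLYMER_LENGTH_CHANGE, label_as_printed=label)

    m = _RE_DUPLICATION.match(text)
    if m:
        unit = _to_rna(m.group("bases"))
        pos, pos2 = int(m.group("pos")), int(m.group("pos2"))
        if pos2 - pos + 1 != len(unit):
            raise VariantParseError(
                f"duplication span {pos}-{pos2} does not match unit {unit!r}"
            )
        rrna, mt = _positions(pos, m.group("mt"), mapper)
        return MtVariant(rrna, mt, unit, unit * 2, Event.DUPLICATION,
                         label_as_printed=label)

    m = _RE_DELETION.match(text)
    if m:
        bases = _to_rna(m.group("bases"))
        pos = int(m.group("pos"))
        if m.group("pos2") and int(m.group("pos2")) - pos + 1 != len(bases):
            raise VariantParseError(
                f"deletion span does not match deleted bases in {label!r}"
            )
        rrna, mt = _positions(pos, m.group("mt"), mapper)
        return MtVariant(rrna, mt, bases, "", Event.DELETION, label_as_printed=label)

    m = _RE_INSERTION.match(text)
    if m:
        rrna, mt = _positions(int(m.group("pos")), m.group("mt"), mapper)
        return MtVariant(rrna, mt, "", _to_rna(m.group("bases")), Event.INSERTION,
                         label_as_printed=label)

    m = _RE_SUBSTITUTION.match(text)
    if m:
        ref, alt = _to_rna(m.group("ref")), _to_rna(m.group("alt"))
        rrna, mt = _positions(int(m.group("pos")), m.group("mt"), mapper)
        return MtVariant(rrna, mt, ref, alt, Event.SUBSTITUTION,
                         label_as_printed=label)

    raise VariantParseError(f"unparseable variant label: {label!r}")


def _positions(
    pos: int, mt_prefix: Optional[str], mapper: CoordinateMapper
) -> tuple[int, int]:
    if mt_prefix:
        return mapper.to_rrna(pos), pos
    return pos, mapper.to_mtdna(pos)


def format_variant(variant: MtVariant, numbering: str = "rrna") -> str:
    """Render a canonical label in rRNA (``U``) or mtDNA (``m.``/``T``) style."""
    if numbering == "rrna":
        pos, prefix, tr = variant.rrna_position, "", str.maketrans("", "")
    elif numbering == "mtdna":
        if variant.mt_position is None:
            raise RangeError("variant has no m. coordinate")
        pos, prefix, tr = variant.mt_position, "m.", str.maketrans("Uu", "Tt")
    else:
        raise ValueError(f"unknown numbering {numbering!r}")
    ref = variant.ref_allele.translate(tr)
    alt = variant.alt_allele.translate(tr)
    if variant.event is Event.SUBSTITUTION:
        return f"{prefix}{pos}{ref}>{alt}"
    if variant.event is Event.DELETION:
        if len(ref) > 1:
            return f"{prefix}{pos}-{pos + len(ref) - 1}del{ref}"
        return f"{prefix}{pos}del{ref}"
    if variant.event is Event.INSERTION:
        return f"{prefix}{pos}ins{alt}"
    if variant.event is Event.DUPLICATION:
        return f"{prefix}{pos}-{pos + len(ref) - 1}dup{ref}"
    # homopolymer length change
    return f"{prefix}{pos} {len(ref)}{ref[0]}>{len(alt)}{alt[0]}"


def calibrate_mapper(
    rows: Iterable[ResidueEquivalence],
    gene_length: int = GENE_LENGTH,
) -> CoordinateMapper:
    """Derive the single rRNA→mtDNA offset from double-numbered rows.

    Every row carrying both numberings must give the same difference;
    disagreeing rows are listed in the :class:`CalibrationError`.
    """
    offsets: dict[int, list[int]] = {}
    for row in rows:
        mt = row.mt_position
        if mt is None:
            continue
        offsets.setdefault(mt - row.human_residue, []).append(row.human_residue)
    if not offsets:
        raise CalibrationError("no double-numbered rows to calibrate from")
    if len(offsets) > 1:
        detail = "; ".join(
            f"offset {off} from residues {res}" for off, res in sorted(offsets.items())
        )
        raise CalibrationError(f"inconsistent numbering offsets: {detail}")
    offset = next(iter(offsets))
    return CoordinateMapper(offset=offset, gene_span=(offset + 1, offset + gene_length))


def rrna_to_mtdna(pos: int, mapper: CoordinateMapper | None = None) -> int:
    """Map a 16S rRNA residue index to its rCRS m. coordinate."""
    return (mapper or CoordinateMapper()).to_mtdna(pos)


def mtdna_to_rrna(pos: int, mapper: CoordinateMapper | None = None) -> int:
    """Map an rCRS m. coordinate to its 16S rRNA residue index."""
    return (mapper or CoordinateMapper()).to_rrna(pos)
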