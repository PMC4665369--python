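"""Population-frequency filter for candidate rRNA variants.

Candidate disruptive variants must be rare: each population sequence is
globally aligned to the reference gene segment, variants are called and
counted across the population, and a variant is retained only when it has
at most ``threshold`` total appearances (default 15) and none of them is
*novel*, i.e. every appearance traces back to a sequence already tagged as
coming from a known reporting source (the publications that described the
variant as potentially pathogenic).  Appearances in untagged population
sequences disqualify the variant.

Alignment is global with affine gap penalties; ties between co-optimal gap
placements are broken toward the leftmost position, and called indels are
additionally left-normalized against the reference, so homopolymer indels
are always reported at the run's 5' edge.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align, SeqIO

from .errors import InputError
from .variant_model import CoordinateMapper, Event, MtVariant

KNOWN_SOURCE = "known_reporting_source"
POPULATION = "population"

_VALID = set("ACGTN")


@dataclass(frozen=True)
class AlignerParams:
    """Scores for the global affine-gap aligner."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0


@dataclass
class PopulationSet:
    """A reference segment plus a set of population sequences.

    ``provenance`` maps sequence ids to either ``known_reporting_source``
    (the sequence belongs to a publication already reporting the variant)
    or ``population``.
    """

    reference: tuple[str, str]
    sequences: list[tuple[str, str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reference[1]:
            raise InputError("reference sequence is empty")
        ids = [sid for sid, _ in self.sequences]
        dupes = [sid for sid, k in Counter(ids).items() if k > 1]
        if dupes:
            raise InputError(f"duplicate sequence ids: {dupes}")
        for sid, seq in [self.reference, *self.sequences]:
            bad = set(seq.upper()) - _VALID
            if bad:
                raise InputError(
                    f"sequence {sid!r} contains unsupported symbols {sorted(bad)}; "
                    "only A/C/G/T/N are accepted"
                )

    def tag(self, sequence_id: str) -> str:
        return self.provenance.get(sequence_id, POPULATION)


@dataclass(frozen=True)
class VariantCount:
    variant: MtVariant
    total: int
    novel: int

    def __post_init__(self) -> None:
        if self.novel > self.total:
            raise InputError("novel appearances exceed total appearances")


@dataclass(frozen=True)
class RarityDecision:
    variant: MtVariant
    retained: bool
    reason: str  # retained | above_threshold | novel_appearances


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of one sequence against the reference."""

    ref_aligned: str
    seq_aligned: str

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.seq_aligned):
            raise InputError("aligned rows have different lengths")


def _left_shift_gaps(top: str, bottom: str) -> tuple[str, str]:
    """Shift every gap run to its leftmost score-equivalent position.

    A gap at column i may swap with the preceding non-gap column when the
    opposite row carries the same character in both columns; repeating this
    to a fixed point places homopolymer gaps at the run's 5' end.
    """
    a, b = list(top), list(bottom)
    for row, other in ((a, b), (b, a)):
        changed = True
        while changed:
            changed = False
            for i in range(1, len(row)):
                if row[i] == "-" and row[i - 1] != "-" and other[i - 1] == other[i] \
                        and other[i] != "-":
                    row[i - 1], row[i] = row[i], row[i - 1]
                    changed = True
    return "".join(a), "".join(b)


def align_to_reference(
    seq: str,
    reference: str,
    params: AlignerParams | None = None,
) -> PairwiseAlignment:
    """Globally align ``seq`` to ``reference`` with affine gap penalties."""
    if not seq or not reference:
        raise InputError("cannot align an empty sequence")
    params = params or AlignerParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    alignment = aligner.align(reference.upper(), seq.upper())[0]
    ref_aligned, seq_aligned = _left_shift_gaps(alignment[0], alignment[1])
    return PairwiseAlignment(ref_aligned=ref_aligned, seq_aligned=seq_aligned)


def _left_normalize(reference: str, pos: int, bases: str) -> tuple[int, str]:
    """Shift an indel (1-based start ``pos``, inserted/deleted ``bases``)
    left while the base preceding it equals the last base of the event."""
    while pos > 1 and bases and reference[pos - 2] == bases[-1]:
        bases = reference[pos - 2] + bases[:-1]
        pos -= 1
    return pos, bases


def call_variants(
    alignment: PairwiseAlignment,
    mapper: CoordinateMapper | None = None,
) -> list[MtVariant]:
    """Extract variants in reference (m.) coordinates from an alignment.

    Substitutions are reported per column; gap runs become deletions or
    insertions anchored at their leftmost reference position.  Columns
    containing ``N`` in either row call nothing.
    """
    mapper = mapper or CoordinateMapper()
    ref_row, seq_row = alignment.ref_aligned, alignment.seq_aligned
    reference = ref_row.replace("-", "")
    gene_start = mapper.gene_span[0]
    variants: list[MtVariant] = []

    def emit(ref_pos: int, ref: str, alt: str, event: Event) -> None:
        mt = gene_start + ref_pos - 1
        variants.append(
            MtVariant(
                rrna_position=mapper.to_rrna(mt),
                mt_position=mt,
                ref_allele=ref.replace("T", "U"),
                alt_allele=alt.replace("T", "U"),
                event=event,
            )
        )

    ref_pos = 0  # 1-based position of the last consumed reference base
    i = 0
    ncols = len(ref_row)
    while i < ncols:
        r, s = ref_row[i], seq_row[i]
        if r != "-" and s != "-":
            ref_pos += 1
            if r != s and r != "N" and s != "N":
                emit(ref_pos, r, s, Event.SUBSTITUTION)
            i += 1
        elif s == "-":
            start = ref_pos + 1
            deleted = ""
            while i < ncols and seq_row[i] == "-":
                deleted += ref_row[i]
                ref_pos += 1
                i += 1
            if "N" not in deleted:
                pos, bases = _left_normalize(reference, start, deleted)
                emit(pos, bases, "", Event.DELETION)
        else:  # r == "-": insertion relative to the reference
            inserted = ""
            while i < ncols and ref_row[i] == "-":
                inserted += seq_row[i]
                i += 1
            if "N" not in inserted:
                pos, bases = _left_normalize(reference, ref_pos + 1, inserted)
                emit(pos, "", bases, Event.INSERTION)
    return variants


def count_appearances(
    population: PopulationSet,
    mapper: CoordinateMapper | None = None,
    params: AlignerParams | None = None,
) -> list[VariantCount]:
    """Align every population sequence to the reference and count each
    distinct variant's appearances, splitting off novel ones by provenance."""
    if not population.sequences:
        raise InputError("population contains no sequences")
    mapper = mapper or CoordinateMapper()
    totals: dict[tuple, int] = defaultdict(int)
    novels: dict[tuple, int] = defaultdict(int)
    exemplar: dict[tuple, MtVariant] = {}
    for sid, seq in population.sequences:
        alignment = align_to_reference(seq, population.reference[1], params)
        for variant in call_variants(alignment, mapper):
            key = variant.signature
            totals[key] += 1
            if population.tag(sid) != KNOWN_SOURCE:
                novels[key] += 1
            exemplar.setdefault(key, variant)
    return [
        VariantCount(variant=exemplar[key], total=totals[key], novel=novels[key])
        for key in sorted(totals)
    ]


def apply_rarity_filter(
    counts: Iterable[VariantCount],
    threshold: int = 15,
) -> list[RarityDecision]:
    """Retain variants with ``total <= threshold`` and zero novel appearances."""
    if threshold < 0:
        raise InputError("threshold must be non-negative")
    decisions = []
    for count in counts:
        if count.total > threshold:
            decisions.append(RarityDecision(count.variant, False, "above_threshold"))
        elif count.novel > 0:
            decisions.append(RarityDecision(count.variant, False, "novel_appearances"))
        else:
            decisions.append(RarityDecision(count.variant, True, "retained"))
    return decisions


def read_population(
    reference_fasta: str | Path,
    population_fasta: str | Path,
    provenance_tsv: str | Path | None = None,
) -> PopulationSet:
    """Assemble a :class:`PopulationSet` from FASTA files plus an optional
    two-column (id, tag) provenance TSV."""
    ref_records = list(SeqIO.parse(str(reference_fasta), "fasta"))
    if len(ref_records) != 1:
        raise InputError("reference FASTA must contain exactly one record")
    sequences = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(population_fasta), "fasta")
    ]
    provenance: dict[str, str] = {}
    if provenance_tsv is not None:
        for line in Path(provenance_tsv).read_text().splitlines():
            if not line.strip():
                continue
            sid, tag = line.split("\t")[:2]
            provenance[sid.strip()] = tag.strip()
    return PopulationSet(
        reference=(ref_records[0].id, str(ref_records[0].seq).upper()),
        sequences=sequences,
        provenance=provenance,
    )
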