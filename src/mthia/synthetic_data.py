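"""Ground-truth generators for every pipeline stage.

Nothing here is downloaded: populations of mtDNA-like gene segments with
planted variants, idealized A-form RNA duplexes with canonical base-pair
geometry, alignment columns of exact composition, and the exhaustive set
of evidence profiles all come with machine-readable ground truth so tests
never re-derive expectations from prose.

Duplex geometry
---------------
Base atoms are laid out in the standard base-pair reference frame used in
fibre-diffraction/idealized nucleic-acid model building: the paired base
is obtained by a 180-degree rotation about the frame's x axis, successive
pairs by a helical twist about z (default 32.7 degrees/residue) plus a
rise along z (default 2.81 Angstrom/residue), after displacing the frame
so the helix axis does not pierce the bases.  Wobble partners are the
flipped pyrimidine/purine shifted within the pair plane to realize the
G O6...U N3 / G N1...U O2 bond pattern.  Each residue carries its base
atoms plus C1', an O4' placed at the anti glycosidic torsion (chi = -160
degrees by default), a phosphate, and an O3' positioned 1.6 Angstrom from
the following residue's phosphate (covalent backbone link).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .conservation import BASES, GAP, AlignmentColumn
from .errors import SpecError
from .hia_rubric import EvidenceProfile, Support
from .rarity_filter import KNOWN_SOURCE, POPULATION, PopulationSet
from .structure_context import (
    Atom,
    Chain,
    PairGeometry,
    Residue,
    StructureModel,
)
from .variant_model import Event, MtVariant

# --------------------------------------------------------------------------
# populations with planted variants

_RNA2DNA = str.maketrans("Uu", "Tt")


@dataclass(frozen=True)
class PlantedVariant:
    """A variant planted into ``count`` sequences, ``n_known`` of which are
    tagged as coming from a known reporting source."""

    variant: MtVariant
    count: int
    n_known: int = 0

    def __post_init__(self) -> None:
        if self.count < 0 or not 0 <= self.n_known <= self.count:
            raise SpecError("invalid planted-variant counts")


@dataclass(frozen=True)
class PopulationSpec:
    reference_length: int = 2000
    n_sequences: int = 100
    planted: tuple[PlantedVariant, ...] = ()
    seed: int = 0
    reference: Optional[str] = None  # explicit DNA sequence, overrides length


def gen_population(spec: PopulationSpec) -> PopulationSet:
    """Deterministically generate a population with exact planted counts.

    Positions are 1-based indices into the reference segment (equal to
    rRNA residue indices when the segment stands in for the gene).  Two
    planted events may not touch the same position of the same sequence.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.reference is not None:
        reference = list(spec.reference.upper())
    else:
        reference = list(
            rng.choice(list("ACGT"), size=spec.reference_length)
        )
    for planted in spec.planted:
        variant = planted.variant
        if planted.count > spec.n_sequences:
            raise SpecError(
                f"planted count {planted.count} exceeds population size "
                f"{spec.n_sequences}"
            )
        pos = variant.rrna_position
        ref_dna = variant.ref_allele.translate(_RNA2DNA)
        if variant.event is not Event.INSERTION:
            if pos < 1 or pos + len(ref_dna) - 1 > len(reference):
                raise SpecError(f"planted position {pos} outside reference")
            reference[pos - 1: pos - 1 + len(ref_dna)] = list(ref_dna)
        elif not 1 <= pos <= len(reference) + 1:
            raise SpecError(f"planted insertion point {pos} outside reference")

    # choose carrier sequences per variant; detect per-sequence conflicts
    carriers: list[tuple[PlantedVariant, np.ndarray]] = []
    occupied: dict[int, set[int]] = {}
    for planted in spec.planted:
        chosen = rng.choice(spec.n_sequences, size=planted.count, replace=False)
        span = range(
            planted.variant.rrna_position,
            planted.variant.rrna_position
            + max(1, len(planted.variant.ref_allele)),
        )
        for sidx in chosen:
            taken = occupied.setdefault(int(sidx), set())
            if taken & set(span):
                raise SpecError(
                    f"conflicting planted variants at position "
                    f"{planted.variant.rrna_position} in sequence {sidx}"
                )
            taken.update(span)
        carriers.append((planted, chosen))

    ref_str = "".join(reference)
    sequences: list[tuple[str, str]] = []
    provenance: dict[str, str] = {}
    events_by_seq: dict[int, list[tuple[PlantedVariant, bool]]] = {}
    for planted, chosen in carriers:
        for rank, sidx in enumerate(sorted(int(s) for s in chosen)):
            events_by_seq.setdefault(sidx, []).append(
                (planted, rank < planted.n_known)
            )
    for sidx in range(spec.n_sequences):
        seq = ref_str
        known = False
        for planted, is_known in sorted(
            events_by_seq.get(sidx, []),
            key=lambda item: -item[0].variant.rrna_position,
        ):
            seq = _apply_variant(seq, planted.variant)
            known = known or is_known
        sid = f"seq{sidx:04d}"
        sequences.append((sid, seq))
        provenance[sid] = KNOWN_SOURCE if known else POPULATION
    return PopulationSet(
        reference=("reference", ref_str),
        sequences=sequences,
        provenance=provenance,
    )


def _apply_variant(seq: str, variant: MtVariant) -> str:
    pos = variant.rrna_position
    ref = variant.ref_allele.translate(_RNA2DNA)
    alt = variant.alt_allele.translate(_RNA2DNA)
    if variant.event is Event.SUBSTITUTION:
        if seq[pos - 1] != ref:
            raise SpecError(f"reference base mismatch at {pos}")
        return seq[: pos - 1] + alt + seq[pos:]
    if variant.event is Event.DELETION:
        if seq[pos - 1: pos - 1 + len(ref)] != ref:
            raise SpecError(f"reference bases mismatch at {pos}")
        return seq[: pos - 1] + seq[pos - 1 + len(ref):]
    if variant.event is Event.INSERTION:
        # alt inserted immediately before reference position pos
        return seq[: pos - 1] + alt + seq[pos - 1:]
    if variant.event in (Event.DUPLICATION, Event.HOMOPOLYMER_LENGTH_CHANGE):
        if seq[pos - 1: pos - 1 + len(ref)] != ref:
            raise SpecError(f"reference bases mismatch at {pos}")
        return seq[: pos - 1] + alt + seq[pos - 1 + len(ref):]
    raise SpecError(f"unsupported planted event {variant.event}")


def population_to_fasta(population: PopulationSet) -> str:
    """Byte-stable FASTA rendering (reference first)."""
    lines = [f">{population.reference[0]}", population.reference[1]]
    for sid, seq in population.sequences:
        lines.append(f">{sid}")
        lines.append(seq)
    return "\n".join(lines) + "\n"


def write_population(
    population: PopulationSet, spec: PopulationSpec, path: str | Path
) -> None:
    """Write population FASTA plus a JSON ground-truth sidecar."""
    path = Path(path)
    path.write_text(population_to_fasta(population))
    truth = {
        "seed": spec.seed,
        "n_sequences": spec.n_sequences,
        "planted": [
            {
                "position": p.variant.rrna_position,
                "event": p.variant.event.value,
                "ref": p.variant.ref_allele,
                "alt": p.variant.alt_allele,
                "count": p.count,
                "n_known": p.n_known,
            }
            for p in spec.planted
        ],
        "provenance": population.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(truth, indent=1, sort_keys=True) + "\n"
    )


# --------------------------------------------------------------------------
# idealized duplexes

#: In-plane base atom templates (standard base-pair reference frame, Angstrom).
BASE_FRAMES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.0), "C8": (0.024, 4.897, 0.0),
        "N7": (0.877, 3.902, 0.0), "C5": (0.071, 2.771, 0.0),
        "C6": (0.369, 1.398, 0.0), "N6": (1.611, 0.909, 0.0),
        "N1": (-0.668, 0.532, 0.0), "C2": (-1.912, 1.023, 0.0),
        "N3": (-2.320, 2.290, 0.0), "C4": (-1.267, 3.124, 0.0),
        "C1'": (-2.479, 5.346, 0.0),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.0), "C8": (0.023, 4.962, 0.0),
        "N7": (0.870, 3.969, 0.0), "C5": (0.071, 2.833, 0.0),
        "C6": (0.424, 1.460, 0.0), "O6": (1.554, 0.955, 0.0),
        "N1": (-0.700, 0.641, 0.0), "C2": (-1.999, 1.087, 0.0),
        "N2": (-2.949, 0.139, 0.0), "N3": (-2.342, 2.364, 0.0),
        "C4": (-1.265, 3.177, 0.0),
        "C1'": (-2.477, 5.399, 0.0),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.0), "C2": (-1.472, 3.158, 0.0),
        "O2": (-2.628, 2.709, 0.0), "N3": (-0.391, 2.344, 0.0),
        "C4": (0.837, 2.868, 0.0), "N4": (1.875, 2.027, 0.0),
        "C5": (1.056, 4.275, 0.0), "C6": (-0.023, 5.068, 0.0),
        "C1'": (-2.477, 5.402, 0.0),
    },
    "U": {
        "N1": (-1.284, 4.500, 0.0), "C2": (-1.462, 3.131, 0.0),
        "O2": (-2.563, 2.608, 0.0), "N3": (-0.302, 2.397, 0.0),
        "C4": (0.989, 2.884, 0.0), "O4": (1.935, 2.094, 0.0),
        "C5": (1.089, 4.311, 0.0), "C6": (-0.024, 5.053, 0.0),
        "C1'": (-2.481, 5.354, 0.0),
    },
}

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: 180-degree rotation about x: places the paired base opposite the first.
_FLIP = np.diag([1.0, -1.0, -1.0])
#: In-plane shift of the flipped pyrimidine realizing G.U wobble geometry.
_WOBBLE_SHIFT = np.array([2.176, 0.452, 0.0])
#: Frame displacement keeping the helix axis clear of the bases.
_AXIS_OFFSET = np.array([-4.4, 0.0, 0.0])
#: Phosphate template in the pair frame (strand I).
_P_TEMPLATE = np.array([-1.5, 7.3, 2.4])

DEFAULT_TWIST = 32.7   # degrees per residue
DEFAULT_RISE = 2.81    # Angstrom per residue
DEFAULT_CHI = -160.0   # anti glycosidic torsion, degrees


@dataclass(frozen=True)
class DuplexSpec:
    sequence: str
    twist: float = DEFAULT_TWIST
    rise: float = DEFAULT_RISE
    chi: float = DEFAULT_CHI
    noncanonical: Mapping[int, str] = field(default_factory=dict)
    second_strand: Optional[str] = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 4:
            raise SpecError("duplex sequence must be at least 4 nt")
        if set(seq) - set("ACGU"):
            raise SpecError(f"invalid duplex sequence {self.sequence!r}")
        if not 0.0 < self.twist <= 45.0:
            raise SpecError("helical twist must lie in (0, 45] degrees")
        if self.rise <= 0:
            raise SpecError("rise must be positive")
        for pos, kind in self.noncanonical.items():
            if not 1 <= pos <= len(seq):
                raise SpecError(f"planted pair position {pos} outside duplex")
            if kind != "wobble":
                raise SpecError(f"unsupported planted pair kind {kind!r}")


def _rz(degrees: float) -> np.ndarray:
    t = math.radians(degrees)
    return np.array([
        [math.cos(t), -math.sin(t), 0.0],
        [math.sin(t), math.cos(t), 0.0],
        [0.0, 0.0, 1.0],
    ])


def place_by_torsion(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Place atom d with given c-d bond, b-c-d angle and a-b-c-d torsion."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        -bond * math.sin(ang) * math.cos(tor),
        -bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_duplex(spec: DuplexSpec) -> tuple[StructureModel, list[dict]]:
    """Build an idealized duplex; returns (model, planted ground truth).

    Chain A carries ``spec.sequence`` 5'->3'; chain B the antiparallel
    partner strand (complement unless a wobble is planted, or an explicit
    ``second_strand`` is given).  Ground truth lists each planted pair as
    ``{"a": residue, "b": residue, "class": geometry}`` with chain-B
    residue numbering 1..n running 5'->3' on that strand.
    """
    seq = spec.sequence
    n = len(seq)
    partner = []
    truth = []
    for i, base in enumerate(seq, start=1):
        kind = spec.noncanonical.get(i)
        if kind == "wobble":
            if base == "G":
                partner.append("U")
            elif base == "U":
                partner.append("G")
            else:
                raise SpecError(
                    f"wobble planted at position {i} requires G or U, got {base}"
                )
        else:
            partner.append(COMPLEMENT[base])
    if spec.second_strand is not None:
        given = spec.second_strand.upper().replace("T", "U")
        if len(given) != n:
            raise SpecError("second strand length differs from first")
        # second_strand is written 5'->3' on chain B: position j faces i=n+1-j
        faced = given[::-1]
        for i in range(n):
            if faced[i] != partner[i]:
                if (i + 1) not in spec.noncanonical:
                    raise SpecError(
                        f"non-complementary base at pair {i + 1} without a "
                        "planted noncanonical pair"
                    )
        partner = list(faced)

    chain_a = Chain(chain_id="A")
    chain_b = Chain(chain_id="B")
    identity = _AffineTransform(np.eye(3), np.zeros(3))
    for i in range(n):
        rot = _rz(spec.twist * i)
        trans = np.array([0.0, 0.0, spec.rise * i])
        chain_a.residues.append(
            _build_residue_affine(seq[i], identity, rot, trans, i + 1, spec.chi)
        )
        kind = spec.noncanonical.get(i + 1)
        if kind == "wobble":
            shift = _WOBBLE_SHIFT if seq[i] == "G" else _FLIP @ -_WOBBLE_SHIFT
            transform_b = _AffineTransform(_FLIP, shift)
            pair_class = PairGeometry.WOBBLE
        else:
            transform_b = _AffineTransform(_FLIP, np.zeros(3))
            pair_class = PairGeometry.CIS_WATSON_CRICK
        res_b = _build_residue_affine(
            partner[i], transform_b, rot, trans, n - i, spec.chi
        )
        chain_b.residues.append(res_b)
        truth.append({
            "a": i + 1,
            "b": n - i,
            "class": pair_class.value,
        })
    chain_b.residues.sort(key=lambda r: r.index)
    model = StructureModel(chains=[chain_a, chain_b], name="synthetic_duplex")
    _add_backbone(model, spec)
    return model, truth


class _AffineTransform:
    def __init__(self, matrix: np.ndarray, shift: np.ndarray):
        self.matrix = matrix
        self.shift = shift

    def __call__(self, coord: np.ndarray) -> np.ndarray:
        return self.matrix @ coord + self.shift


def _build_residue_affine(
    base: str, transform: _AffineTransform, rotation: np.ndarray,
    translation: np.ndarray, index: int, chi: float,
) -> Residue:
    atoms = []
    for name, coord in BASE_FRAMES[base].items():
        pos = rotation @ (transform(np.array(coord)) + _AXIS_OFFSET) + translation
        element = name[0] if name[0] in "CNOP" else "C"
        atoms.append(Atom(name=name, pos=pos, element=element))
    res = Residue(index=index, name=base, atoms=atoms)
    glyc_n = "N9" if base in "AG" else "N1"
    ref_atom = "C4" if base in "AG" else "C2"
    o4 = place_by_torsion(
        res.atom(ref_atom).pos, res.atom(glyc_n).pos, res.atom("C1'").pos,
        bond=1.414, angle_deg=108.2, torsion_deg=chi,
    )
    res.atoms.append(Atom(name="O4'", pos=o4, element="O"))
    return res


def _add_backbone(model: StructureModel, spec: DuplexSpec) -> None:
    """Attach P to every residue and O3' 1.6 A from the next residue's P."""
    n = len(spec.sequence)
    step = _rz(spec.twist)
    rise_vec = np.array([0.0, 0.0, spec.rise])
    for chain in model.chains:
        strand_two = chain.chain_id == "B"
        p_template = (_FLIP @ _P_TEMPLATE) if strand_two else _P_TEMPLATE
        p_positions = {}
        for res in chain.residues:
            pair_idx = (n - res.index) if strand_two else (res.index - 1)
            rot = _rz(spec.twist * pair_idx)
            pos = rot @ (p_template + _AXIS_OFFSET) + rise_vec * pair_idx
            res.atoms.append(Atom(name="P", pos=pos, element="P"))
            p_positions[res.index] = pos
        for res in chain.residues:
            if res.index + 1 in p_positions:
                next_p = p_positions[res.index + 1]
            else:  # virtual next phosphate beyond the strand end
                own = p_positions[res.index]
                if strand_two:
                    next_p = step.T @ own - rise_vec
                else:
                    next_p = step @ own + rise_vec
            c1 = res.atom("C1'").pos
            direction = c1 - next_p
            direction = direction / np.linalg.norm(direction)
            res.atoms.append(
                Atom(name="O3'", pos=next_p + 1.6 * direction, element="O")
            )


def perturb_structure(
    model: StructureModel,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> StructureModel:
    """Rigidly transform a model, then add i.i.d. Gaussian coordinate noise."""
    if noise_sigma < 0:
        raise SpecError("noise_sigma must be non-negative")
    rotation = np.eye(3) if rotation is None else np.asarray(rotation, float)
    translation = np.zeros(3) if translation is None else np.asarray(translation, float)
    rng = np.random.default_rng(seed)
    chains = []
    for chain in model.chains:
        residues = []
        for res in chain.residues:
            atoms = [
                Atom(
                    name=a.name,
                    pos=rotation @ a.pos + translation
                    + rng.normal(0.0, noise_sigma, size=3)
                    if noise_sigma > 0
                    else rotation @ a.pos + translation,
                    element=a.element,
                )
                for a in res.atoms
            ]
            residues.append(Residue(index=res.index, name=res.name, atoms=atoms))
        chains.append(Chain(chain_id=chain.chain_id, residues=residues))
    return StructureModel(chains=chains, name=model.name)


# --------------------------------------------------------------------------
# alignment columns

def gen_column(composition: Mapping[str, float], n: int) -> AlignmentColumn:
    """Column of exactly ``n`` symbols realizing ``composition`` by
    largest-remainder rounding (deterministic, symbol order A,C,G,U,-)."""
    if n < 1:
        raise SpecError("column size must be >= 1")
    symbols = [*BASES, GAP]
    fractions = {s: float(composition.get(s, 0.0)) for s in symbols}
    if set(composition) - set(symbols):
        raise SpecError(f"unknown symbols in composition: {sorted(set(composition) - set(symbols))}")
    if any(f < 0 for f in fractions.values()) or \
            abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise SpecError("composition fractions must be non-negative and sum to 1")
    exact = {s: fractions[s] * n for s in symbols}
    counts = {s: math.floor(exact[s]) for s in symbols}
    remainder = n - sum(counts.values())
    by_frac = sorted(symbols, key=lambda s: (-(exact[s] - counts[s]), symbols.index(s)))
    for s in by_frac[:remainder]:
        counts[s] += 1
    column = []
    for s in symbols:
        column.extend([s] * counts[s])
    return AlignmentColumn(symbols=tuple(column))


# --------------------------------------------------------------------------
# evidence profiles

def gen_evidence_profiles() -> list[EvidenceProfile]:
    """Every valid combination of the five evidence fields."""
    profiles = []
    for placeable, het, direct, indirect, mito in itertools.product(
        (False, True), (False, True), Support, Support, (False, True)
    ):
        if direct is not Support.NONE and not het:
            continue  # violates the profile invariant
        profiles.append(
            EvidenceProfile(
                placeable_on_structure=placeable,
                heterologous_data_exists=het,
                direct_heterologous=direct,
                indirect_heterologous=indirect,
                direct_mito_biochemical=mito,
            )
        )
    return profiles
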