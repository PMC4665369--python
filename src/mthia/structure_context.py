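"""Structural inspection of rRNA models.

Provides coordinate I/O (PDB and mmCIF via gemmi), atom-to-atom contact
listing below a strict distance cutoff, geometric base-pair detection and
classification (Watson-Crick, wobble, reverse Hoogsteen, sheared),
glycosidic syn/anti assignment from the chi torsion, least-squares (Kabsch)
superposition with iterative outlier pruning, cross-structure residue
equivalence by nearest transformed C1', and rendering of the
interaction-conservation code strings used to annotate interactions across
the bacterial (b), eukaryotic (e), archaeal (a), mammalian-mitochondrial
(m) and yeast-mitochondrial (M) ribosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateSuperpositionError,
    InputError,
    ResidueLookupError,
    StructureParseError,
)

# --------------------------------------------------------------------------
# model containers

AtomAddress = tuple[str, int, str]  # (chain_id, residue_index, atom_name)
ResidueAddress = tuple[str, int]


@dataclass
class Atom:
    name: str
    pos: np.ndarray  # shape (3,), Angstrom
    element: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise InputError(f"atom {self.name!r} has invalid coordinates")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H" or (
            not self.element and self.name.lstrip("0123456789").startswith("H")
        )


@dataclass
class Residue:
    index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def base_letter(self) -> Optional[str]:
        """One-letter nucleotide code, or None for non-nucleotides."""
        name = self.name.strip().upper()
        table = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
                 "DA": "A", "DC": "C", "DG": "G", "DT": "U", "DU": "U",
                 "RA": "A", "RC": "C", "RG": "G", "RU": "U"}
        return table.get(name)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        indices = [r.index for r in self.residues]
        if len(indices) != len(set(indices)):
            raise InputError(f"duplicate residue indices in chain {self.chain_id!r}")

    def residue(self, index: int) -> Residue:
        for res in self.residues:
            if res.index == index:
                return res
        raise ResidueLookupError(f"{self.chain_id}:{index}")


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    name: str = ""

    def chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise ResidueLookupError(f"chain {chain_id!r}")

    def residue(self, address: ResidueAddress) -> Residue:
        return self.chain(address[0]).residue(address[1])

    def iter_residues(self) -> Iterator[tuple[ResidueAddress, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield (chain.chain_id, res.index), res

    def iter_atoms(self) -> Iterator[tuple[AtomAddress, Atom]]:
        for (cid, ridx), res in self.iter_residues():
            for atom in res.atoms:
                yield (cid, ridx, atom.name), atom

    def get_atom(self, address: AtomAddress) -> Atom:
        atom = self.residue(address[:2]).atom(address[2])
        if atom is None:
            raise ResidueLookupError(f"{address[0]}:{address[1]}:{address[2]}")
        return atom


# --------------------------------------------------------------------------
# chemistry tables

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

#: Ring atoms used to fit the base plane.
RING_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "U": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: Base nitrogen/oxygen atoms able to donate or accept hydrogen bonds.
POLAR_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("N3", "N4", "O2"),
    "U": ("N3", "O2", "O4"),
}


class PairGeometry(str, Enum):
    CIS_WATSON_CRICK = "cis_watson_crick"
    WOBBLE = "wobble"
    REVERSE_HOOGSTEEN = "reverse_hoogsteen"
    SHEARED = "sheared"
    OTHER_NONCANONICAL = "other_noncanonical"


@dataclass(frozen=True)
class Contact:
    atom_a: AtomAddress
    atom_b: AtomAddress
    distance: float


@dataclass(frozen=True)
class BasePair:
    residue_i: ResidueAddress
    residue_j: ResidueAddress
    geometry_class: PairGeometry
    hbonds: tuple[Contact, ...]


@dataclass(frozen=True)
class PairCriteria:
    """Geometric thresholds for hydrogen-bonded base-pair detection."""

    hbond_min: float = 2.4          # donor-acceptor distance window, Angstrom
    hbond_max: float = 3.4
    max_plane_angle: float = 35.0   # angle between base-plane normals, degrees
    max_plane_separation: float = 2.0  # center offset along either normal
    c1_min: float = 8.0             # C1'-C1' window for WC/wobble pairs
    c1_max: float = 11.5
    candidate_c1_cutoff: float = 12.5
    min_hbonds_canonical: int = 2


# --------------------------------------------------------------------------
# coordinate I/O

def _validate_pdb_text(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip()) < 54:
            raise StructureParseError(
                f"{path.name}:{lineno}: truncated coordinate record"
            )


def load_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used.  Alternative locations are resolved to
    the highest-occupancy conformer (first listed on ties).  Residue
    numbering is preserved verbatim.
    """
    import gemmi

    path = Path(path)
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt == "pdb":
        _validate_pdb_text(path)
    try:
        if fmt == "cif":
            structure = gemmi.make_structure_from_block(
                gemmi.cif.read(str(path)).sole_block()
            )
        else:
            structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path.name}: {exc}") from exc
    return from_gemmi(structure)


def from_gemmi(structure) -> StructureModel:
    """Convert a ``gemmi.Structure`` (first model only) to a StructureModel."""
    model = structure[0]
    chains = []
    for gchain in model:
        residues = []
        for gres in gchain:
            # altloc resolution: best occupancy per atom name, first on ties
            chosen: dict[str, object] = {}
            for gatom in gres:
                prev = chosen.get(gatom.name)
                if prev is None or gatom.occ > prev.occ:
                    chosen[gatom.name] = gatom
            atoms = [
                Atom(
                    name=ga.name,
                    pos=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    element=ga.element.name,
                )
                for ga in chosen.values()
            ]
            residues.append(
                Residue(index=gres.seqid.num, name=gres.name.strip(), atoms=atoms)
            )
        chains.append(Chain(chain_id=gchain.name, residues=residues))
    return StructureModel(chains=chains, name=structure.name)


def to_gemmi(model: StructureModel, name: str = "mthia"):
    import gemmi

    structure = gemmi.Structure()
    structure.name = name or model.name or "mthia"
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.pos = gemmi.Position(*atom.pos)
                gatom.element = gemmi.Element(atom.element or atom.name[0])
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    return structure


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write PDB (``.pdb``) or mmCIF (``.cif``) depending on the extension."""
    path = Path(path)
    structure = to_gemmi(model)
    if path.suffix.lower() in {".cif", ".mmcif"}:
        structure.make_mmcif_document().write_file(str(path))
    else:
        structure.write_pdb(str(path))


# --------------------------------------------------------------------------
# contacts

def _is_backbone_covalent(addr_a: AtomAddress, addr_b: AtomAddress) -> bool:
    """O3'(i)-P(i+1) pairs between adjacent residues of one chain."""
    (ca, ra, na), (cb, rb, nb) = addr_a, addr_b
    if ca != cb or abs(ra - rb) != 1:
        return False
    lower, upper = ((na, nb) if ra < rb else (nb, na))
    return lower == "O3'" and upper == "P"


def find_contacts(
    model: StructureModel,
    residue_address: ResidueAddress,
    cutoff: float = 3.0,
) -> list[Contact]:
    """All heavy-atom contacts of one residue strictly below ``cutoff`` Å.

    Intra-residue pairs and covalently bonded backbone neighbours are
    excluded; contacts come back sorted by distance.
    """
    if cutoff <= 0:
        raise InputError("contact cutoff must be positive")
    query = model.residue(residue_address)  # raises ResidueLookupError
    others: list[tuple[AtomAddress, np.ndarray]] = []
    for addr, atom in model.iter_atoms():
        if atom.is_hydrogen or addr[:2] == residue_address:
            continue
        others.append((addr, atom.pos))
    if not others:
        return []
    tree = cKDTree(np.array([pos for _, pos in others]))
    contacts = []
    for atom in query.atoms:
        if atom.is_hydrogen:
            continue
        addr_a = (*residue_address, atom.name)
        for j in tree.query_ball_point(atom.pos, r=cutoff):
            addr_b, pos = others[j]
            dist = float(np.linalg.norm(atom.pos - pos))
            if dist >= cutoff:  # strict "below"
                continue
            if _is_backbone_covalent(addr_a, addr_b):
                continue
            contacts.append(Contact(atom_a=addr_a, atom_b=addr_b, distance=dist))
    contacts.sort(key=lambda c: (c.distance, c.atom_a, c.atom_b))
    return contacts


# --------------------------------------------------------------------------
# base-pair geometry

def base_plane(res: Residue) -> tuple[np.ndarray, np.ndarray]:
    """Base plane with a chemically oriented normal.

    Returns (ring centroid, unit normal).  The normal is computed by
    Newell's method over the ordered ring perimeter and sign-fixed per
    base type so that it points off the same face of every base — two
    bases of an antiparallel pair therefore have normals with a negative
    dot product, regardless of how the model is oriented in space.
    """
    letter = res.base_letter
    if letter is None:
        raise InputError(f"residue {res.name!r} is not a nucleotide")
    coords = []
    for name in RING_ATOMS[letter]:
        atom = res.atom(name)
        if atom is not None:
            coords.append(atom.pos)
    if len(coords) < 3:
        raise InputError(f"residue {res.index} lacks ring atoms for a plane fit")
    arr = np.array(coords)
    center = arr.mean(axis=0)
    v = arr - center
    normal = np.zeros(3)
    for i in range(len(v)):
        normal += np.cross(v[i], v[(i + 1) % len(v)])
    if letter in PURINES:  # perimeter runs the other way round for purines
        normal = -normal
    norm = np.linalg.norm(normal)
    if norm == 0.0:
        raise InputError(f"degenerate ring geometry in residue {res.index}")
    return center, normal / norm


def _pair_hbonds(
    addr_i: ResidueAddress, res_i: Residue,
    addr_j: ResidueAddress, res_j: Residue,
    criteria: PairCriteria,
) -> list[Contact]:
    bonds = []
    for name_i in POLAR_ATOMS[res_i.base_letter]:
        atom_i = res_i.atom(name_i)
        if atom_i is None:
            continue
        for name_j in POLAR_ATOMS[res_j.base_letter]:
            atom_j = res_j.atom(name_j)
            if atom_j is None:
                continue
            dist = float(np.linalg.norm(atom_i.pos - atom_j.pos))
            if criteria.hbond_min <= dist <= criteria.hbond_max:
                bonds.append(Contact((*addr_i, name_i), (*addr_j, name_j), dist))
    bonds.sort(key=lambda c: c.distance)
    return bonds


def _planarity_ok(res_i: Residue, res_j: Residue, criteria: PairCriteria
                  ) -> tuple[bool, float]:
    """Coplanarity gate; returns (ok, normal dot product).

    The normal-angle test is orientation-free (folded to <=90 deg); the
    center-offset test rejects stacked bases that satisfy the distance
    window vertically rather than edge-on.
    """
    center_i, normal_i = base_plane(res_i)
    center_j, normal_j = base_plane(res_j)
    ndot = float(np.dot(normal_i, normal_j))
    angle = math.degrees(math.acos(min(1.0, abs(ndot))))
    if angle > criteria.max_plane_angle:
        return False, ndot
    sep = center_j - center_i
    if abs(float(np.dot(sep, normal_i))) > criteria.max_plane_separation:
        return False, ndot
    if abs(float(np.dot(sep, normal_j))) > criteria.max_plane_separation:
        return False, ndot
    return True, ndot


def _match_pattern(
    base_i: str, base_j: str, hbonds: Sequence[Contact],
    base_x: str, base_y: str, pattern: set[tuple[str, str]],
) -> set[tuple[str, str]]:
    """Pattern atoms present among the h-bonds, testing both orientations."""
    pairs = {(c.atom_a[2], c.atom_b[2]) for c in hbonds}
    if (base_i, base_j) == (base_x, base_y):
        return pattern & pairs
    if (base_i, base_j) == (base_y, base_x):
        return {(x, y) for x, y in pattern if (y, x) in pairs}
    return set()


_WC_AU = {("N1", "N3"), ("N6", "O4")}
_WC_GC = {("N1", "N3"), ("O6", "N4"), ("N2", "O2")}
_WOBBLE_GU = {("O6", "N3"), ("N1", "O2")}
_WOBBLE_AC = {("N1", "N3"), ("N1", "O2"), ("N6", "N3"), ("N6", "O2")}
_RHOOGSTEEN_AU = {("N7", "N3"), ("N6", "O2")}
_SHEARED_GA = {("N3", "N6"), ("N2", "N7")}


def classify_pair_geometry(
    res_i: Residue,
    res_j: Residue,
    hbonds: Sequence[Contact],
    normal_dot: float,
    c1_distance: Optional[float] = None,
    criteria: PairCriteria = PairCriteria(),
) -> PairGeometry:
    """Assign a geometry class from the h-bonded edges and orientation.

    Antiparallel base normals (negative dot product) characterise the cis
    Watson-Crick and wobble families; parallel normals with a WC-edge to
    Hoogsteen-edge bond give reverse Hoogsteen.  Anything hydrogen bonded
    but unmatched is other_noncanonical.
    """
    if not hbonds:
        raise InputError("a base pair requires at least one hydrogen bond")
    bi, bj = res_i.base_letter, res_j.base_letter
    antiparallel = normal_dot < 0.0
    c1_ok = c1_distance is None or (
        criteria.c1_min <= c1_distance <= criteria.c1_max
    )

    if antiparallel and c1_ok:
        au = _match_pattern(bi, bj, hbonds, "A", "U", _WC_AU)
        if len(au) >= 2:
            return PairGeometry.CIS_WATSON_CRICK
        gc = _match_pattern(bi, bj, hbonds, "G", "C", _WC_GC)
        if ("N1", "N3") in gc and len(gc) >= criteria.min_hbonds_canonical:
            return PairGeometry.CIS_WATSON_CRICK
        gu = _match_pattern(bi, bj, hbonds, "G", "U", _WOBBLE_GU)
        if len(gu) >= 2:
            return PairGeometry.WOBBLE
        ac = _match_pattern(bi, bj, hbonds, "A", "C", _WOBBLE_AC)
        if len(ac) >= 2:
            return PairGeometry.WOBBLE
    if not antiparallel:
        rh = _match_pattern(bi, bj, hbonds, "A", "U", _RHOOGSTEEN_AU)
        if ("N7", "N3") in rh:
            return PairGeometry.REVERSE_HOOGSTEEN
    sheared = _match_pattern(bi, bj, hbonds, "G", "A", _SHEARED_GA)
    if sheared:
        return PairGeometry.SHEARED
    return PairGeometry.OTHER_NONCANONICAL


def detect_base_pairs(
    model: StructureModel,
    chain_id: str | None = None,
    criteria: PairCriteria = PairCriteria(),
) -> list[BasePair]:
    """Report every hydrogen-bonded, coplanar base pair once.

    Candidate pairs come from a C1'-C1' neighbour search; each candidate
    must pass the coplanarity gate and carry at least one (two for the
    canonical classes) base-to-base hydrogen bond in the donor-acceptor
    distance window.  When ``chain_id`` is given, only pairs involving
    that chain are reported.
    """
    entries: list[tuple[ResidueAddress, Residue, np.ndarray]] = []
    for addr, res in model.iter_residues():
        if res.base_letter is None:
            continue
        c1 = res.atom("C1'")
        if c1 is None:
            continue
        entries.append((addr, res, c1.pos))
    if len(entries) < 2:
        return []
    tree = cKDTree(np.array([pos for _, _, pos in entries]))
    pairs: list[BasePair] = []
    for i, j in sorted(tree.query_pairs(r=criteria.candidate_c1_cutoff)):
        addr_i, res_i, c1_i = entries[i]
        addr_j, res_j, c1_j = entries[j]
        if chain_id is not None and chain_id not in (addr_i[0], addr_j[0]):
            continue
        if addr_j < addr_i:
            addr_i, res_i, c1_i, addr_j, res_j, c1_j = (
                addr_j, res_j, c1_j, addr_i, res_i, c1_i)
        hbonds = _pair_hbonds(addr_i, res_i, addr_j, res_j, criteria)
        if not hbonds:
            continue
        ok, ndot = _planarity_ok(res_i, res_j, criteria)
        if not ok:
            continue
        c1_dist = float(np.linalg.norm(c1_i - c1_j))
        geometry = classify_pair_geometry(
            res_i, res_j, hbonds, ndot, c1_dist, criteria
        )
        if geometry in (PairGeometry.CIS_WATSON_CRICK, PairGeometry.WOBBLE) \
                and len(hbonds) < criteria.min_hbonds_canonical:
            geometry = PairGeometry.OTHER_NONCANONICAL
        pairs.append(
            BasePair(
                residue_i=addr_i,
                residue_j=addr_j,
                geometry_class=geometry,
                hbonds=tuple(hbonds),
            )
        )
    return pairs


# --------------------------------------------------------------------------
# glycosidic conformation

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
             ) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


UNDETERMINED = "undetermined_conformation"


def glycosidic_conformation(model: StructureModel, address: ResidueAddress) -> str:
    """``syn`` when chi (O4'-C1'-N9-C4 purines, O4'-C1'-N1-C2 pyrimidines)
    lies in [-90, +90] degrees; ``anti`` otherwise."""
    res = model.residue(address)
    letter = res.base_letter
    if letter is None:
        return UNDETERMINED
    names = ("O4'", "C1'", "N9", "C4") if letter in PURINES else \
            ("O4'", "C1'", "N1", "C2")
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        return UNDETERMINED
    chi = dihedral(*(a.pos for a in atoms))
    return "syn" if -90.0 <= chi <= 90.0 else "anti"


def chi_torsion(model: StructureModel, address: ResidueAddress) -> float:
    res = model.residue(address)
    letter = res.base_letter
    names = ("O4'", "C1'", "N9", "C4") if letter in PURINES else \
            ("O4'", "C1'", "N1", "C2")
    atoms = [res.atom(n) for n in names]
    if any(a is None for a in atoms):
        raise ResidueLookupError(f"{address}: chi atoms missing")
    return dihedral(*(a.pos for a in atoms))


# --------------------------------------------------------------------------
# superposition

@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper rotation, applied to mobile
    translation: np.ndarray   # 3-vector
    rmsd: float               # over retained pairs, Angstrom
    retained_pairs: int
    initial_pairs: int
    retained_mask: np.ndarray  # boolean over the initial pairing

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to (..., 3) coordinates."""
        return np.asarray(coords) @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, target: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation+translation mapping mobile onto target."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ct - rotation @ cm
    return rotation, translation


def superpose_coords(
    mobile: np.ndarray,
    target: np.ndarray,
    prune_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Kabsch fit with iterative pruning of poorly fitting pairs.

    After each fit, the single worst pair whose post-fit distance exceeds
    ``prune_cutoff`` is dropped and the fit repeated; convergence is the
    iteration in which no pair exceeds the cutoff.  Pruning one pair at a
    time keeps the procedure stable even when gross outliers drag the
    initial fit far from the majority solution.  Fewer than three
    surviving pairs is an error.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InputError("pairing must give two equal (n, 3) coordinate sets")
    n = mobile.shape[0]
    mask = np.ones(n, dtype=bool)
    while True:
        if mask.sum() < 3:
            raise DegenerateSuperpositionError(
                f"only {int(mask.sum())} atom pairs remain (need >= 3)"
            )
        rotation, translation = _kabsch(mobile[mask], target[mask])
        dists = np.linalg.norm(
            mobile[mask] @ rotation.T + translation - target[mask], axis=1
        )
        worst = int(np.argmax(dists))
        if dists[worst] <= prune_cutoff:
            rmsd = float(np.sqrt(np.mean(dists**2)))
            return SuperpositionResult(
                rotation=rotation,
                translation=translation,
                rmsd=rmsd,
                retained_pairs=int(mask.sum()),
                initial_pairs=n,
                retained_mask=mask,
            )
        mask[np.flatnonzero(mask)[worst]] = False


def superpose(
    mobile: StructureModel,
    target: StructureModel,
    pairing: Sequence[tuple[AtomAddress, AtomAddress]],
    prune_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Superpose ``mobile`` onto ``target`` over an explicit atom pairing."""
    if len(pairing) < 3:
        raise DegenerateSuperpositionError("pairing must contain >= 3 atom pairs")
    mob = np.array([mobile.get_atom(a).pos for a, _ in pairing])
    tgt = np.array([target.get_atom(b).pos for _, b in pairing])
    return superpose_coords(mob, tgt, prune_cutoff=prune_cutoff)


def pairing_from_sequence_alignment(
    mobile: StructureModel,
    target: StructureModel,
    mobile_chain: str,
    target_chain: str,
    atom_name: str = "C1'",
) -> list[tuple[AtomAddress, AtomAddress]]:
    """Pair equivalent atoms through a global alignment of chain sequences.

    Convenience mode for real structures where an explicit pair list is
    not available; matched (non-gap) columns whose residues both carry
    ``atom_name`` become atom pairs.
    """
    from Bio import Align

    def chain_seq(model: StructureModel, cid: str) -> tuple[str, list[int]]:
        chain = model.chain(cid)
        letters, indices = [], []
        for res in chain.residues:
            if res.base_letter and res.atom(atom_name) is not None:
                letters.append(res.base_letter)
                indices.append(res.index)
        return "".join(letters), indices

    seq_m, idx_m = chain_seq(mobile, mobile_chain)
    seq_t, idx_t = chain_seq(target, target_chain)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(seq_m, seq_t)[0]
    pairs = []
    for (ms, me), (ts, te) in zip(*alignment.aligned):
        for k in range(me - ms):
            pairs.append((
                (mobile_chain, idx_m[ms + k], atom_name),
                (target_chain, idx_t[ts + k], atom_name),
            ))
    return pairs


def map_equivalent_residue(
    query_residue: ResidueAddress,
    query_model: StructureModel,
    other_model: StructureModel,
    superposition: SuperpositionResult,
    max_dist: float = 4.0,
) -> Optional[ResidueAddress]:
    """Residue of ``other_model`` whose C1' lies nearest the query's
    transformed C1'; None when nothing lies within ``max_dist`` Å.

    ``superposition`` must map query-model coordinates into the other
    model's frame.
    """
    res = query_model.residue(query_residue)
    c1 = res.atom("C1'")
    if c1 is None:
        raise ResidueLookupError(f"{query_residue}: no C1' atom")
    probe = superposition.transform(c1.pos)
    best: tuple[float, ResidueAddress] | None = None
    for addr, other in other_model.iter_residues():
        if other.base_letter is None:
            continue
        other_c1 = other.atom("C1'")
        if other_c1 is None:
            continue
        dist = float(np.linalg.norm(other_c1.pos - probe))
        if best is None or dist < best[0]:
            best = (dist, addr)
    if best is None or best[0] > max_dist:
        return None
    return best[1]


# --------------------------------------------------------------------------
# interaction-conservation codes

class SourceStatus(str, Enum):
    OBSERVED = "observed"
    UNMODELLED_PARTNERS_PRESENT = "unmodelled_partners_present"
    PARTNER_ABSENT = "partner_absent"
    NOT_OBSERVED = "not_observed"


#: Source order: bacterial, eukaryotic, archaeal, mammalian-mito, yeast-mito.
SOURCE_LETTERS = "beamM"

_STATUS_GLYPH = {
    SourceStatus.UNMODELLED_PARTNERS_PRESENT: "+",
    SourceStatus.PARTNER_ABSENT: "-",
    SourceStatus.NOT_OBSERVED: "?",
}


@dataclass(frozen=True)
class ConservationCode:
    """Per-source interaction status over the five ribosomal sources."""

    statuses: tuple[SourceStatus, SourceStatus, SourceStatus,
                    SourceStatus, SourceStatus]

    def render(self) -> str:
        glyphs = []
        any_observed = False
        for letter, status in zip(SOURCE_LETTERS, self.statuses):
            if status is SourceStatus.OBSERVED:
                glyphs.append(letter)
                any_observed = True
            else:
                glyphs.append(_STATUS_GLYPH[status])
        prefix = "C" if any_observed else ""
        return prefix + "".join(glyphs)


def conservation_code(statuses: Sequence[str | SourceStatus]) -> str:
    """Render the code string for five source statuses in b,e,a,m,M order."""
    if len(statuses) != 5:
        raise InputError("exactly five source statuses (b,e,a,m,M) required")
    parsed = []
    for status in statuses:
        try:
            parsed.append(SourceStatus(status))
        except ValueError as exc:
            raise InputError(f"unknown status token {status!r}") from exc
    return ConservationCode(statuses=tuple(parsed)).render()
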