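"""Structure I/O, contacts, base-pair geometry, chi, superposition, codes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mthia.errors import (
    DegenerateSuperpositionError,
    InputError,
    ResidueLookupError,
    StructureParseError,
)
from mthia.structure_context import (
    Atom,
    Chain,
    PairGeometry,
    Residue,
    StructureModel,
    SourceStatus,
    base_plane,
    chi_torsion,
    classify_pair_geometry,
    conservation_code,
    detect_base_pairs,
    find_contacts,
    glycosidic_conformation,
    load_structure,
    map_equivalent_residue,
    superpose,
    superpose_coords,
    write_structure,
    _pair_hbonds,
    PairCriteria,
)
from mthia.synthetic_data import BASE_FRAMES, DuplexSpec, gen_duplex, perturb_structure


# --------------------------------------------------------------------------
# coordinate I/O

def test_duplex_file_round_trip_counts(tmp_path, wc_duplex):
    model, _ = wc_duplex
    path = tmp_path / "duplex.pdb"
    write_structure(model, path)
    loaded = load_structure(path)
    assert len(loaded.chains) == 2
    assert sum(len(c.residues) for c in loaded.chains) == 16


def test_pdb_and_mmcif_serializations_agree(tmp_path, wc_duplex):
    model, _ = wc_duplex
    pdb, cif = tmp_path / "m.pdb", tmp_path / "m.cif"
    write_structure(model, pdb)
    write_structure(model, cif)
    from_pdb = {k: a.pos for k, a in load_structure(pdb).iter_atoms()}
    from_cif = {k: a.pos for k, a in load_structure(cif).iter_atoms()}
    assert set(from_pdb) == set(from_cif)
    for key in from_pdb:
        assert np.allclose(from_pdb[key], from_cif[key], atol=1e-3)


def test_truncated_atom_record_raises_with_line_number(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text("ATOM      1  C1'   G A   1      11.0\n")
    with pytest.raises(StructureParseError, match="bad.pdb:1"):
        load_structure(bad)


# --------------------------------------------------------------------------
# contacts

def _toy_model(*atom_specs):
    """Build chains/residues from (chain, resi, resname, atom, element, xyz)."""
    chains: dict[str, dict[int, Residue]] = {}
    for chain_id, resi, resname, atom, element, xyz in atom_specs:
        res = chains.setdefault(chain_id, {}).setdefault(
            resi, Residue(index=resi, name=resname)
        )
        res.atoms.append(Atom(name=atom, pos=np.array(xyz), element=element))
    return StructureModel(
        chains=[
            Chain(chain_id=cid, residues=[r for _, r in sorted(resmap.items())])
            for cid, resmap in sorted(chains.items())
        ]
    )


def test_contact_below_cutoff_reported_strictly():
    model = _toy_model(
        ("A", 1, "G", "N1", "N", (0.0, 0.0, 0.0)),
        ("A", 2, "C", "O2", "O", (2.9, 0.0, 0.0)),
        ("A", 3, "U", "O4", "O", (3.0, 0.0, 0.0)),
    )
    contacts = find_contacts(model, ("A", 1), cutoff=3.0)
    assert [(c.atom_b[:2], round(c.distance, 2)) for c in contacts] == [
        (("A", 2), 2.9)
    ]  # the 3.0-A atom is excluded: strictly below


def test_covalent_backbone_pair_excluded():
    model = _toy_model(
        ("A", 1, "G", "O3'", "O", (0.0, 0.0, 0.0)),
        ("A", 2, "C", "P", "P", (1.6, 0.0, 0.0)),
        ("A", 2, "C", "N3", "N", (2.5, 0.0, 0.0)),
    )
    contacts = find_contacts(model, ("A", 1), cutoff=3.0)
    assert [c.atom_b[2] for c in contacts] == ["N3"]


def test_hydrogens_ignored():
    model = _toy_model(
        ("A", 1, "G", "N1", "N", (0.0, 0.0, 0.0)),
        ("A", 2, "C", "H42", "H", (1.9, 0.0, 0.0)),
    )
    assert find_contacts(model, ("A", 1), cutoff=3.0) == []


def test_contacts_symmetric(wc_duplex):
    model, _ = wc_duplex
    forward = {
        (c.atom_a, c.atom_b): c.distance
        for c in find_contacts(model, ("A", 2))
        if c.atom_b[:2] == ("B", 7)
    }
    backward = {
        (c.atom_b, c.atom_a): c.distance
        for c in find_contacts(model, ("B", 7))
        if c.atom_b[:2] == ("A", 2)
    }
    assert forward.keys() == backward.keys()
    for key in forward:
        assert forward[key] == pytest.approx(backward[key])


def test_unknown_residue_raises(wc_duplex):
    model, _ = wc_duplex
    with pytest.raises(ResidueLookupError):
        find_contacts(model, ("A", 99))


# --------------------------------------------------------------------------
# base pairs: detection against a brute-force oracle

def _oracle_pairs(model, criteria=PairCriteria()):
    """Naive all-pairs geometric base-pair search (independent loops)."""
    from mthia.structure_context import _planarity_ok

    residues = [
        (addr, res) for addr, res in model.iter_residues()
        if res.base_letter is not None and res.atom("C1'") is not None
    ]
    found = set()
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            addr_i, res_i = residues[i]
            addr_j, res_j = residues[j]
            hbonds = _pair_hbonds(addr_i, res_i, addr_j, res_j, criteria)
            if not hbonds:
                continue
            ok, ndot = _planarity_ok(res_i, res_j, criteria)
            if not ok:
                continue
            c1 = float(np.linalg.norm(
                res_i.atom("C1'").pos - res_j.atom("C1'").pos))
            if c1 > criteria.candidate_c1_cutoff:
                continue
            geometry = classify_pair_geometry(
                res_i, res_j, hbonds, ndot, c1, criteria)
            if geometry in (PairGeometry.CIS_WATSON_CRICK, PairGeometry.WOBBLE) \
                    and len(hbonds) < criteria.min_hbonds_canonical:
                geometry = PairGeometry.OTHER_NONCANONICAL
            found.add((addr_i, addr_j, geometry))
    return found


def test_detector_recovers_planted_pairs_on_random_duplexes(rng):
    """Planted pairs (and only those) are detected over random duplexes."""
    for _ in range(12):
        n = int(rng.integers(4, 31))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        wobble_sites = {
            int(i) + 1: "wobble"
            for i in np.flatnonzero([b in "GU" for b in seq])
            if rng.random() < 0.2
        }
        model, truth = gen_duplex(DuplexSpec(sequence=seq,
                                             noncanonical=wobble_sites))
        detected = {
            (p.residue_i, p.residue_j, p.geometry_class)
            for p in detect_base_pairs(model)
        }
        planted = {
            (("A", t["a"]), ("B", t["b"]), PairGeometry(t["class"]))
            for t in truth
        }
        assert detected == planted
        assert detected == _oracle_pairs(model)


def test_known_partner_recovered_from_generated_duplex():
    model, _ = gen_duplex(DuplexSpec(sequence="GGCAUGCCAUGC"))
    partners = {p.residue_i[1]: p.residue_j[1]
                for p in detect_base_pairs(model, chain_id="A")}
    assert partners[3] == 10  # complementarity across antiparallel strands


# --------------------------------------------------------------------------
# pair geometry classification

def _residue_from_frame(base, index, matrix=None, shift=None):
    matrix = np.eye(3) if matrix is None else matrix
    shift = np.zeros(3) if shift is None else np.asarray(shift, float)
    atoms = [
        Atom(name=name, pos=matrix @ np.array(coord) + shift,
             element=name[0] if name[0] in "CNOP" else "C")
        for name, coord in BASE_FRAMES[base].items()
    ]
    return Residue(index=index, name=base, atoms=atoms)


def test_watson_crick_pattern_is_definitional():
    res_a = _residue_from_frame("A", 1)
    res_u = _residue_from_frame("U", 2, matrix=np.diag([1.0, -1.0, -1.0]))
    hbonds = _pair_hbonds(("A", 1), res_a, ("B", 2), res_u, PairCriteria())
    assert {(c.atom_a[2], c.atom_b[2]) for c in hbonds} == {
        ("N1", "N3"), ("N6", "O4")
    }
    _, n_a = base_plane(res_a)
    _, n_u = base_plane(res_u)
    geometry = classify_pair_geometry(
        res_a, res_u, hbonds, float(np.dot(n_a, n_u)), 10.7)
    assert geometry is PairGeometry.CIS_WATSON_CRICK


def test_reverse_hoogsteen_pattern_with_parallel_strands():
    """U's WC edge (N3) bonded to A's Hoogsteen edge (N7), normals parallel."""
    res_a = _residue_from_frame("A", 1)
    flip_z = Rotation.from_euler("z", 180, degrees=True).as_matrix()
    res_u = _residue_from_frame("U", 2, matrix=flip_z,
                                shift=(2.257, 8.660, 0.0))
    hbonds = _pair_hbonds(("A", 1), res_a, ("B", 2), res_u, PairCriteria())
    assert ("N7", "N3") in {(c.atom_a[2], c.atom_b[2]) for c in hbonds}
    _, n_a = base_plane(res_a)
    _, n_u = base_plane(res_u)
    ndot = float(np.dot(n_a, n_u))
    assert ndot > 0  # parallel
    geometry = classify_pair_geometry(res_a, res_u, hbonds, ndot, None)
    assert geometry is PairGeometry.REVERSE_HOOGSTEEN


def test_single_unpatterned_contact_is_other_noncanonical():
    from mthia.structure_context import Contact

    res_g = _residue_from_frame("G", 1)
    res_g2 = _residue_from_frame("G", 2, shift=(0.0, -5.0, 0.0))
    bond = Contact(("A", 1, "N2"), ("A", 2, "O6"), 3.0)
    geometry = classify_pair_geometry(res_g, res_g2, [bond], -1.0, 9.0)
    assert geometry is PairGeometry.OTHER_NONCANONICAL


def test_pair_without_hbond_rejected():
    res_a = _residue_from_frame("A", 1)
    res_u = _residue_from_frame("U", 2)
    with pytest.raises(InputError):
        classify_pair_geometry(res_a, res_u, [], -1.0, 10.0)


# --------------------------------------------------------------------------
# glycosidic conformation

def test_ideal_duplex_residue_is_anti(wc_duplex):
    model, _ = wc_duplex
    assert chi_torsion(model, ("A", 1)) == pytest.approx(-160.0, abs=1e-6)
    assert glycosidic_conformation(model, ("A", 1)) == "anti"


def test_rotation_about_glycosidic_bond_gives_syn():
    model, _ = gen_duplex(DuplexSpec(sequence="GGCAUGCC"))
    res = model.residue(("A", 1))
    c1, n9 = res.atom("C1'").pos, res.atom("N9").pos
    axis = (n9 - c1) / np.linalg.norm(n9 - c1)
    spin = Rotation.from_rotvec(np.radians(190.0) * axis).as_matrix()
    o4 = res.atom("O4'")
    o4.pos = spin @ (o4.pos - c1) + c1
    chi = chi_torsion(model, ("A", 1))
    assert -90.0 <= chi <= 90.0
    assert glycosidic_conformation(model, ("A", 1)) == "syn"


def test_missing_base_atoms_undetermined():
    model = _toy_model(
        ("A", 1, "G", "O4'", "O", (0.0, 0.0, 0.0)),
        ("A", 1, "G", "C1'", "C", (1.4, 0.0, 0.0)),
    )
    assert glycosidic_conformation(model, ("A", 1)) == "undetermined_conformation"


# --------------------------------------------------------------------------
# superposition

def test_self_superposition_is_identity(wc_duplex):
    model, _ = wc_duplex
    coords = np.array([a.pos for _, a in model.iter_atoms()])
    result = superpose_coords(coords, coords)
    assert result.rmsd == pytest.approx(0.0, abs=1e-12)
    assert result.retained_pairs == result.initial_pairs


def test_rigid_transform_recovered_exactly(rng, wc_duplex):
    model, _ = wc_duplex
    rotation = Rotation.random(random_state=7).as_matrix()
    translation = rng.normal(0, 10, 3)
    moved = perturb_structure(model, rotation, translation)
    coords = np.array([a.pos for _, a in model.iter_atoms()])
    moved_coords = np.array([a.pos for _, a in moved.iter_atoms()])
    result = superpose_coords(coords, moved_coords)
    assert result.rmsd < 1e-9
    assert np.allclose(result.rotation, rotation, atol=1e-9)
    assert np.allclose(result.translation, translation, atol=1e-8)
    assert np.linalg.det(result.rotation) == pytest.approx(1.0)


def test_gaussian_noise_rmsd_matches_expectation(rng):
    """For sigma = 0.3 A of isotropic noise the RMSD approaches sigma*sqrt(3)."""
    mobile = rng.normal(0, 15, (500, 3))
    rotation = Rotation.random(random_state=11).as_matrix()
    target = mobile @ rotation.T + np.array([3.0, -7.0, 1.0]) \
        + rng.normal(0, 0.3, (500, 3))
    result = superpose_coords(mobile, target)
    expected = 0.3 * np.sqrt(3.0)
    assert result.rmsd <= expected * 1.1
    assert abs(result.rmsd - expected) <= 0.1 * expected


def test_rmsd_invariant_under_common_rigid_motion(rng, wc_duplex):
    model, _ = wc_duplex
    coords = np.array([a.pos for _, a in model.iter_atoms()])
    noisy = coords + rng.normal(0, 0.2, coords.shape)
    base = superpose_coords(coords, noisy).rmsd
    common = Rotation.random(random_state=3).as_matrix()
    shift = np.array([12.0, -4.0, 9.0])
    moved = superpose_coords(coords @ common.T + shift,
                             noisy @ common.T + shift).rmsd
    assert moved == pytest.approx(base, abs=1e-9)


def test_outliers_pruned_and_counts_monotone(rng):
    good = rng.normal(0, 10, (20, 3))
    outliers = good[:3] + np.array([50.0, 0.0, 0.0])
    mobile = np.vstack([good, good[:3]])
    target = np.vstack([good, outliers])
    result = superpose_coords(mobile, target, prune_cutoff=2.0)
    assert result.initial_pairs == 23
    assert result.retained_pairs == 20
    assert result.rmsd < 1e-9
    unpruned = superpose_coords(mobile, target, prune_cutoff=1e9)
    assert result.rmsd <= unpruned.rmsd


def test_degenerate_pruning_raises(rng):
    mobile = rng.normal(0, 5, (4, 3))
    target = mobile.copy()
    target[2:] += 500.0
    with pytest.raises(DegenerateSuperpositionError):
        superpose_coords(mobile, target, prune_cutoff=2.0)


def test_kabsch_agrees_with_scipy_align_vectors(rng):
    mobile = rng.normal(0, 8, (40, 3))
    rotation = Rotation.random(random_state=5).as_matrix()
    target = mobile @ rotation.T + rng.normal(0, 0.1, (40, 3))
    ours = superpose_coords(mobile, target, prune_cutoff=1e9)
    ref, _ = Rotation.align_vectors(target - target.mean(0),
                                    mobile - mobile.mean(0))
    assert np.allclose(ours.rotation, ref.as_matrix(), atol=1e-8)


def test_superpose_models_by_atom_pairing(wc_duplex):
    model, _ = wc_duplex
    moved = perturb_structure(
        model, Rotation.from_euler("y", 40, degrees=True).as_matrix(),
        np.array([1.0, 2.0, 3.0]))
    pairing = [((  "A", i, "C1'"), ("A", i, "C1'")) for i in range(1, 9)]
    result = superpose(model, moved, pairing)
    assert result.rmsd < 1e-9


# --------------------------------------------------------------------------
# residue equivalence mapping

def test_equivalence_mapping_symmetric(wc_duplex):
    model, _ = wc_duplex
    rotation = Rotation.from_euler("xz", [25, -60], degrees=True).as_matrix()
    moved = perturb_structure(model, rotation, np.array([4.0, 4.0, -2.0]))
    pairing = [(("A", i, "C1'"), ("A", i, "C1'")) for i in range(1, 9)]
    forward = superpose(model, moved, pairing)
    backward = superpose(moved, model,
                         [(b, a) for a, b in pairing])
    assert map_equivalent_residue(("A", 3), model, moved, forward) == ("A", 3)
    assert map_equivalent_residue(("A", 3), moved, model, backward) == ("A", 3)


def test_equivalence_unmapped_when_neighbourhood_missing(wc_duplex):
    model, _ = wc_duplex
    pruned = perturb_structure(model)  # deep copy
    chain_a = pruned.chain("A")
    chain_a.residues = [r for r in chain_a.residues if r.index != 3]
    pairing = [(("A", i, "C1'"), ("A", i, "C1'")) for i in (1, 2, 5, 6, 7, 8)]
    sup = superpose(model, pruned, pairing)
    assert map_equivalent_residue(("A", 3), model, pruned, sup) is None


# --------------------------------------------------------------------------
# interaction-conservation codes

@pytest.mark.parametrize(
    "statuses, rendered",
    [
        (["observed"] * 5, "CbeamM"),
        (["observed"] * 4 + ["partner_absent"], "Cbeam-"),
        (["observed"] * 4 + ["not_observed"], "Cbeam?"),
        (["observed"] * 4 + ["unmodelled_partners_present"], "Cbeam+"),
        (["not_observed"] * 5, "?????"),
        (["observed", "partner_absent", "observed", "observed", "observed"],
         "Cb-amM"),
    ],
)
def test_conservation_code_rendering(statuses, rendered):
    assert conservation_code(statuses) == rendered


def test_conservation_code_rejects_bad_input():
    with pytest.raises(InputError):
        conservation_code(["observed"] * 4)
    with pytest.raises(InputError):
        conservation_code(["observed"] * 4 + ["sometimes"])
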