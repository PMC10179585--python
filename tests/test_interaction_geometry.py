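"""Ring perception, hydrogen bonds, and aromatic interaction classifiers."""

import numpy as np
import pytest

from ensdock import synthetic_fixtures as sf
from ensdock.interaction_geometry import (
    HBondCriteria,
    InteractionCriteria,
    MoleculeAnnotation,
    audit_record,
    build_protein_annotation,
    classify_aromatic,
    classify_complex,
    classify_lonepair_pi,
    classify_xh_pi,
    detect_hbonds,
    detect_rings,
)
from ensdock.structure_io import Atom, Structure

from conftest import make_atom


def ideal_phe(resnum=1, center=(0, 0, 0), normal=(0, 0, 1)):
    from ensdock.synthetic_fixtures import _hexagon

    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    coords = _hexagon(center, normal)
    return [make_atom(serial=i + 1, name=n, element="C", resname="PHE",
                      resnum=resnum, coords=c)
            for i, (n, c) in enumerate(zip(names, coords))]


def test_phe_template_ring_detected():
    rings = detect_rings(Structure(ideal_phe(), "phe"))
    assert len(rings) == 1
    assert rings[0].source == "PHE1"
    np.testing.assert_allclose(rings[0].centroid, [0, 0, 0], atol=1e-9)
    np.testing.assert_allclose(abs(rings[0].normal[2]), 1.0, atol=1e-9)


def test_distorted_ring_rejected_by_planarity():
    atoms = ideal_phe()
    lifted = atoms[2].moved_to(atoms[2].coords + np.array([0, 0, 1.0]))
    atoms[2] = lifted
    assert detect_rings(Structure(atoms, "bent")) == []


def test_trp_contributes_two_rings():
    # five- and six-membered TRP rings built as two fused planar templates
    from ensdock.synthetic_fixtures import _hexagon

    five_names = ["CG", "CD1", "NE1", "CE2", "CD2"]
    ang = np.radians(np.arange(5) * 72.0)
    five = np.column_stack([1.2 * np.cos(ang), 1.2 * np.sin(ang), np.zeros(5)])
    six_names = ["CE3", "CZ3", "CH2", "CZ2"]
    six = _hexagon((2.2, 0, 0), (0, 0, 1))[:4]
    atoms = [make_atom(serial=i + 1, name=n, element=n[0], resname="TRP",
                       resnum=3, coords=c)
             for i, (n, c) in enumerate(zip(five_names + six_names,
                                            list(five) + list(six)))]
    rings = detect_rings(Structure(atoms, "trp"))
    assert len(rings) == 2
    assert sorted(len(r.member_indices) for r in rings) == [5, 6]


def test_ligand_ring_annotation_and_missing_atom_error(ligand_with_annotation):
    ligand, annotation = ligand_with_annotation
    rings = detect_rings(ligand, ligand_rings=annotation.rings)
    assert len(rings) == 2
    with pytest.raises(ValueError, match="missing atom"):
        detect_rings(ligand, ligand_rings=[[0, 1, 2, 3, 4, 99]])


def test_cycle_perception_matches_rdkit_aromatic_ring_count():
    """Catechin-class molecules: planar 5/6-cycles found from connectivity
    must equal RDKit's aromatic ring count (2 for catechin, 3 with a
    gallate ester), with the puckered pyran ring rejected by planarity."""
    Chem = pytest.importorskip("rdkit.Chem")
    from rdkit.Chem import AllChem

    smiles = {
        "catechin": "OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1",
        "gallate_ester": "O=C(OC1Cc2c(O)cc(O)cc2OC1c1cc(O)c(O)c(O)c1)"
                         "c1cc(O)c(O)c(O)c1",
    }
    expected = {"catechin": 2, "gallate_ester": 3}
    for name, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        params = AllChem.ETKDGv3()
        params.randomSeed = 7
        assert AllChem.EmbedMolecule(mol, params) == 0
        AllChem.MMFFOptimizeMolecule(mol)
        conf = mol.GetConformer()
        atoms = [make_atom(serial=i + 1, name=f"{a.GetSymbol()}{i + 1}",
                           element=a.GetSymbol().upper(), resname="LIG",
                           resnum=1, chain="L",
                           coords=np.array(conf.GetAtomPosition(i)))
                 for i, a in enumerate(mol.GetAtoms())]
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
        rings = detect_rings(Structure(atoms, name), connectivity=bonds)
        n_aromatic_rdkit = sum(
            all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
            for ring in mol.GetRingInfo().AtomRings())
        assert n_aromatic_rdkit == expected[name]
        assert len(rings) == expected[name]


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hbond_pair(d=2.9, angle_deg=180.0):
    """Donor O-H ... acceptor O with given D...A distance and D-H-A angle."""
    donor = make_atom(serial=1, name="OG", element="O", resname="SER",
                      coords=(0, 0, 0))
    h = make_atom(serial=2, name="HG", element="H", resname="SER",
                  coords=(0.95, 0, 0))
    # place acceptor so that angle(D-H-A) = angle_deg at distance d from D
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    acc_pos = h.coords + (d - 0.95 if angle_deg == 180 else d) * direction
    # for non-colinear cases just rotate around H keeping |D-A| approx d
    acceptor = make_atom(serial=3, name="O1", element="O", resname="LIG",
                         chain="L", coords=acc_pos)
    a = Structure([donor, h], "don")
    b = Structure([acceptor], "acc")
    ann_a = MoleculeAnnotation(donors=[(0, 1)], acceptors=[], label="A")
    ann_b = MoleculeAnnotation(donors=[], acceptors=[0], label="B")
    return a, b, ann_a, ann_b


def test_ideal_colinear_hbond_detected():
    a, b, ann_a, ann_b = hbond_pair(d=2.9, angle_deg=180.0)
    records = detect_hbonds(a, b, ann_a, ann_b)
    assert len(records) == 1
    assert records[0].geometry["d_donor_acceptor"] == pytest.approx(2.9)
    assert records[0].geometry["theta_dha"] == pytest.approx(180.0)


def test_hbond_distance_criterion():
    a, b, ann_a, ann_b = hbond_pair(d=3.6, angle_deg=180.0)
    assert detect_hbonds(a, b, ann_a, ann_b) == []
    # boundary is inclusive
    a, b, ann_a, ann_b = hbond_pair(d=3.5, angle_deg=180.0)
    assert len(detect_hbonds(a, b, ann_a, ann_b)) == 1


def test_hbond_angle_criterion():
    a, b, ann_a, ann_b = hbond_pair(d=2.9, angle_deg=90.0)
    assert detect_hbonds(a, b, ann_a, ann_b) == []


def test_hbond_symmetric_over_molecule_labels():
    a, b, ann_a, ann_b = hbond_pair()
    forward = detect_hbonds(a, b, ann_a, ann_b)
    backward = detect_hbonds(b, a, ann_b, ann_a)
    assert len(forward) == len(backward) == 1
    assert forward[0].geometry == backward[0].geometry


def test_missing_hydrogen_errors_unless_distance_only():
    a, b, ann_a, ann_b = hbond_pair()
    ann_no_h = MoleculeAnnotation(donors=[(0, None)], acceptors=[])
    with pytest.raises(ValueError, match="hydrogen"):
        detect_hbonds(a, b, ann_no_h, ann_b)
    records = detect_hbonds(a, b, ann_no_h, ann_b,
                            HBondCriteria(distance_only=True))
    assert len(records) == 1 and "theta_dha" not in records[0].geometry


def test_hbond_set_matches_brute_force_scan(rng):
    """Random donor/acceptor placements: detector must equal the O(N^2)
    criteria scan."""
    criteria = HBondCriteria()
    for _ in range(50):
        n_d, n_a = int(rng.integers(1, 5)), int(rng.integers(1, 6))
        donors, hydrogens = [], []
        atoms_a = []
        for i in range(n_d):
            x = rng.uniform(-5, 5, 3)
            h = x + rng.uniform(-1, 1, 3) * 0.6 + [0.6, 0, 0]
            atoms_a.append(make_atom(serial=2 * i + 1, name="OG", element="O",
                                     resnum=i + 1, coords=x))
            atoms_a.append(make_atom(serial=2 * i + 2, name="HG", element="H",
                                     resnum=i + 1, coords=h))
            donors.append((2 * i, 2 * i + 1))
        atoms_b = [make_atom(serial=j + 1, name="O1", element="O", resname="LIG",
                             chain="L", resnum=1, coords=rng.uniform(-5, 5, 3))
                   for j in range(n_a)]
        a = Structure(atoms_a, "a")
        b = Structure(atoms_b, "b")
        records = detect_hbonds(a, b, MoleculeAnnotation(donors=donors),
                                MoleculeAnnotation(acceptors=list(range(n_a))),
                                criteria)
        brute = 0
        for x_i, h_i in donors:
            for acc in atoms_b:
                d = np.linalg.norm(atoms_a[x_i].coords - acc.coords)
                v1 = atoms_a[x_i].coords - atoms_a[h_i].coords
                v2 = acc.coords - atoms_a[h_i].coords
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if d <= criteria.d_max and theta >= criteria.theta_min:
                    brute += 1
        assert len(records) == brute


# ---------------------------------------------------------------------------
# Aromatic classifiers
# ---------------------------------------------------------------------------

def ring_at(center, normal, source="r"):
    rings = detect_rings(Structure(ideal_phe(center=center, normal=normal), source))
    assert len(rings) == 1
    return rings[0]


def test_parallel_stack_classification():
    rec = classify_aromatic(ring_at((0, 0, 0), (0, 0, 1)),
                            ring_at((0, 0, 3.5), (0, 0, 1)))
    assert rec is not None and rec.kind == "pi_pi_parallel"
    assert rec.geometry["d_centroid"] == pytest.approx(3.5)
    assert rec.geometry["alpha_interplanar"] == pytest.approx(0.0, abs=1e-9)


def test_tshaped_classification():
    rec = classify_aromatic(ring_at((0, 0, 0), (0, 0, 1)),
                            ring_at((0, 0, 5.0), (1, 0, 0)))
    assert rec is not None and rec.kind == "pi_pi_tshaped"
    assert rec.geometry["alpha_interplanar"] == pytest.approx(90.0)


def test_distant_rings_unclassified():
    assert classify_aromatic(ring_at((0, 0, 0), (0, 0, 1)),
                             ring_at((0, 0, 8.0), (0, 0, 1))) is None


def test_interplanar_angle_folding():
    # flipping one normal must not change the classification
    rec1 = classify_aromatic(ring_at((0, 0, 0), (0, 0, 1)),
                             ring_at((0, 0, 3.5), (0, 0, -1)))
    assert rec1 is not None and rec1.kind == "pi_pi_parallel"


def test_xh_pi_above_centroid():
    ring = ring_at((0, 0, 0), (0, 0, 1))
    h = make_atom(serial=7, name="H1", element="H", coords=(0, 0, 2.6))
    x = make_atom(serial=8, name="C7", element="C", coords=(0, 0, 3.69))
    rec = classify_xh_pi(x, h, ring)
    assert rec is not None
    assert rec.geometry["d_h_centroid"] == pytest.approx(2.6)


def test_xh_pi_lateral_displacement_rejected():
    ring = ring_at((0, 0, 0), (0, 0, 1))
    h = make_atom(serial=7, name="H1", element="H", coords=(3.0, 0, 1.0))
    x = make_atom(serial=8, name="C7", element="C", coords=(3.0, 0, 2.09))
    # H-centroid distance sqrt(10) > 3.0 and lateral 3.0 > radius + 0.5
    assert classify_xh_pi(x, h, ring) is None


def test_oh_pi_accepted_like_ch_pi():
    ring = ring_at((0, 0, 0), (0, 0, 1))
    h = make_atom(serial=7, name="HO", element="H", coords=(0, 0, 2.6))
    x = make_atom(serial=8, name="O7", element="O", coords=(0, 0, 3.56))
    assert classify_xh_pi(x, h, ring) is not None


def test_xh_pi_requires_cno_donor():
    ring = ring_at((0, 0, 0), (0, 0, 1))
    h = make_atom(serial=7, name="HS", element="H", coords=(0, 0, 2.6))
    s = make_atom(serial=8, name="SG", element="S", coords=(0, 0, 3.9))
    with pytest.raises(ValueError, match="C, N or O"):
        classify_xh_pi(s, h, ring)


def test_lonepair_pi_on_axis():
    ring = ring_at((0, 0, 0), (0, 0, 1))
    o = make_atom(serial=7, name="O1", element="O", coords=(0, 0, 3.0))
    rec = classify_lonepair_pi(o, ring)
    assert rec is not None
    assert rec.geometry["axial_angle"] == pytest.approx(0.0, abs=1e-9)
    assert classify_lonepair_pi(
        make_atom(serial=8, name="O2", element="O", coords=(0, 0, 4.5)), ring) is None


def test_lonepair_pi_matches_brute_force_scan(rng):
    ring = ring_at((0, 0, 0), (0, 0, 1))
    criteria = InteractionCriteria()
    for _ in range(30):
        pos = rng.uniform(-4, 4, 3)
        o = make_atom(serial=7, name="O1", element="O", coords=pos)
        rec = classify_lonepair_pi(o, ring, criteria)
        d = np.linalg.norm(pos)
        ang = np.degrees(np.arccos(np.clip(abs(pos[2]) / d, -1, 1))) if d > 0 else 0.0
        expected = d <= criteria.lonepair_pi_d_max and ang <= criteria.lonepair_pi_axial_max
        assert (rec is not None) == expected


# ---------------------------------------------------------------------------
# Self-consistency, invariance, protein annotation
# ---------------------------------------------------------------------------

def random_rigid_motion(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


def test_classification_invariant_under_rigid_motion(rng):
    for kind in sf.INTERACTION_KINDS:
        fx = sf.make_interaction_fixture(kind)
        for _ in range(5):
            R, t = random_rigid_motion(rng)
            moved = fx.structure.with_coords(fx.structure.coords @ R.T + t)
            records = _run_fixture_classifier(kind, fx, moved)
            assert len(records) == 1, f"{kind} lost under rigid motion"
            base = _run_fixture_classifier(kind, fx, fx.structure)[0]
            for key, value in base.geometry.items():
                assert records[0].geometry[key] == pytest.approx(value, abs=1e-6)


def _run_fixture_classifier(kind, fx, structure):
    rings = [r for r in detect_rings(structure, ligand_rings=fx.rings)
             if r.source.startswith("LIG:")]
    if kind in ("pi_pi_parallel", "pi_pi_tshaped"):
        rec = classify_aromatic(rings[0], rings[1])
        return [rec] if rec is not None and rec.kind == kind else []
    if kind == "hbond":
        x_i, h_i = fx.donor
        ann_d = MoleculeAnnotation(donors=[(x_i, h_i)])
        ann_a = MoleculeAnnotation(acceptors=[fx.acceptor])
        return detect_hbonds(structure, structure, ann_d, ann_a)
    if kind == "xh_pi":
        x_i, h_i = fx.donor
        rec = classify_xh_pi(structure.atoms[x_i], structure.atoms[h_i], rings[0])
        return [rec] if rec is not None else []
    rec = classify_lonepair_pi(structure.atoms[fx.acceptor], rings[0])
    return [rec] if rec is not None else []


def test_every_emitted_record_passes_audit(extended_peptide, ligand_with_annotation,
                                           rng):
    ligand, lig_ann = ligand_with_annotation
    criteria = InteractionCriteria()
    receptor_atoms = ideal_phe(resnum=19, center=(0, 0, 0))
    receptor = Structure(receptor_atoms, "rec")
    rec_ann = MoleculeAnnotation(rings=[[0, 1, 2, 3, 4, 5]], label="rec")
    n_emitted = 0
    for _ in range(20):
        R, t = random_rigid_motion(rng)
        t = rng.uniform(-6, 6, 3)
        moved = ligand.with_coords(ligand.coords @ R.T + t)
        for record in classify_complex(receptor, moved, rec_ann, lig_ann, criteria):
            n_emitted += 1
            assert audit_record(record, criteria)
    assert n_emitted > 0  # placements close enough that something fires


def test_protein_annotation_tables(extended_peptide):
    ann = build_protein_annotation(extended_peptide)
    # bead model: no N/O atoms at all -> no donors/acceptors, no rings
    assert ann.donors == [] and ann.acceptors == [] and ann.rings == []
    atoms = ideal_phe(resnum=19)
    atoms.append(make_atom(serial=7, name="N", element="N", resnum=19,
                           coords=(3, 0, 0)))
    atoms.append(make_atom(serial=8, name="O", element="O", resnum=19,
                           coords=(4, 0, 0)))
    ann2 = build_protein_annotation(Structure(atoms, "phe"))
    assert len(ann2.rings) == 1
    assert ann2.acceptors and ann2.donors
    assert ann2.donors[0][1] is None  # no hydrogen present
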