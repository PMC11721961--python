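"""Unit tests for featurization: descriptors, contacts, fingerprints, I/O."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allokin._errors import ParseError, SelectionError
from allokin.featurize import (
    GeometricRules,
    backbone_dihedrals,
    contact_matrix,
    contact_matrix_brute,
    contact_table,
    frequency_filter,
    group_distance,
    hbond_count,
    interaction_fingerprint,
    radius_of_gyration,
    read_structures,
    rmsd,
    sasa,
    write_structures_pdb,
)
from allokin.featurize.descriptors import MissingRadiusError
from allokin.featurize.structure import FrameMismatchError, element_from_name

from helpers import make_structure, water_dimer


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------


def _random_frame(n=12, seed=0):
    rng = np.random.default_rng(seed)
    return make_structure(["C"] * n, rng.normal(0, 3, (n, 3)))


def test_rmsd_identity_is_zero():
    f = _random_frame()
    assert rmsd(f, f) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_superposition_removes_rigid_motion():
    ref = _random_frame(seed=1)
    rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
    moved = ref.transformed(rot, np.array([5.0, -2.0, 1.0]))
    assert rmsd(moved, ref) == pytest.approx(0.0, abs=1e-8)
    assert rmsd(moved, ref, superpose=False) > 1.0


def test_rmsd_without_superposition_known_value():
    ref = make_structure(["C"] * 3, [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    # every atom displaced by (0, 2, 0): plain RMSD is exactly 2
    moved = make_structure(["C"] * 3, [[0, 2, 0], [1, 2, 0], [2, 2, 0]])
    assert rmsd(moved, ref, superpose=False) == pytest.approx(2.0)


def test_rmsd_validation():
    f = _random_frame(n=12)
    with pytest.raises(SelectionError):
        rmsd(f, _random_frame(n=10))
    with pytest.raises(SelectionError):
        rmsd(f, f, selection=[0, 1])


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------


def test_rg_two_equal_masses():
    # two equal masses 2 A apart: each 1 A from the COM -> Rg = 1
    f = make_structure(["C", "C"], [[0, 0, 0], [2, 0, 0]])
    assert radius_of_gyration(f) == pytest.approx(1.0)


def test_rg_axis_decomposition_identity():
    f = _random_frame(seed=4)
    total = radius_of_gyration(f)
    comps = [radius_of_gyration(f, axis=ax) for ax in "XYZ"]
    assert total**2 == pytest.approx(sum(c**2 for c in comps))
    with pytest.raises(SelectionError):
        radius_of_gyration(f, axis="Q")


def test_rg_mass_weighting():
    # unequal masses shift the COM toward the heavy atom
    f = make_structure(
        ["C", "C"], [[0, 0, 0], [2, 0, 0]]
    )
    f.masses = np.array([3.0, 1.0])
    # COM at x=0.5; msd = (3*0.25 + 1*2.25)/4 = 0.75
    assert radius_of_gyration(f) == pytest.approx(math.sqrt(0.75))


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------


def test_sasa_isolated_sphere_exact():
    f = make_structure(["C"], [[0, 0, 0]])
    per_atom, total = sasa(f)
    r = 1.70 + 1.4
    assert total == pytest.approx(4 * math.pi * r * r, rel=1e-9)
    assert per_atom[0] == total


def test_sasa_two_far_spheres_additive():
    f = make_structure(["C", "O"], [[0, 0, 0], [50, 0, 0]])
    _, total = sasa(f)
    expected = 4 * math.pi * ((1.70 + 1.4) ** 2 + (1.52 + 1.4) ** 2)
    assert total == pytest.approx(expected, rel=1e-9)


def test_sasa_coincident_duplicates_counted_once():
    single = make_structure(["C"], [[0, 0, 0]])
    doubled = make_structure(["C", "C"], [[0, 0, 0], [0, 0, 0]])
    _, area1 = sasa(single)
    _, area2 = sasa(doubled)
    assert area2 == pytest.approx(area1, rel=1e-9)


def test_sasa_buried_atom_has_no_area():
    # a small sphere fully inside a much larger override-radius sphere
    f = make_structure(["H", "C"], [[0, 0, 0], [0, 0, 0.1]])
    per_atom, _ = sasa(f, radii={"C": 8.0})
    assert per_atom[0] == 0.0


def test_sasa_missing_radius():
    f = make_structure(["ZN"], [[0, 0, 0]])
    with pytest.raises(MissingRadiusError):
        sasa(f)
    _, total = sasa(f, radii={"ZN": 1.39})
    assert total == pytest.approx(4 * math.pi * (1.39 + 1.4) ** 2, rel=1e-9)


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def test_dihedral_trans_backbone_is_180():
    # three residues with a planar zigzag backbone: phi/psi = 180
    names, elements, res_ids, coords = [], [], [], []
    x = 0.0
    for rid in (1, 2, 3):
        for k, name in enumerate(("N", "CA", "C")):
            names.append(name)
            elements.append(name[0])
            res_ids.append(rid)
            coords.append([x, 0.4 * ((len(coords)) % 2), 0.0])
            x += 1.0
    f = make_structure(
        elements,
        coords,
        names=names,
        res_ids=res_ids,
        res_names=["ALA"] * 9,
    )
    di = backbone_dihedrals(f)
    phi2, psi2 = di[2]
    assert abs(phi2) == pytest.approx(180.0, abs=1e-6)
    assert abs(psi2) == pytest.approx(180.0, abs=1e-6)
    # terminal residues have undefined phi (first) / psi (last)
    assert math.isnan(di[1][0])
    assert math.isnan(di[3][1])


def test_dihedral_degenerate_geometry_is_nan():
    # collinear N-CA-C within each residue -> undefined normals
    names = ["N", "CA", "C"] * 2
    res_ids = [1, 1, 1, 2, 2, 2]
    coords = [[i, 0, 0] for i in range(6)]
    f = make_structure(
        ["N", "C", "C", "N", "C", "C"], coords, names=names, res_ids=res_ids
    )
    di = backbone_dihedrals(f)
    assert math.isnan(di[1][1])
    assert math.isnan(di[2][0])


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def test_hbond_water_dimer():
    count, pairs = hbond_count(water_dimer(2.8))
    assert count == 1
    assert pairs == [(0, 3)]  # O1 donates to O2


def test_hbond_stretched_dimer_rejected():
    count, _ = hbond_count(water_dimer(4.2))
    assert count == 0


def test_hbond_bent_geometry_rejected():
    f = water_dimer(2.8)
    # move the donor hydrogen perpendicular to the O-O axis: the
    # D-H...A angle collapses well below 120 degrees
    f.coords[1] = [0.0, 0.96, 0.0]
    count, _ = hbond_count(f)
    assert count == 0
    # proxy mode ignores the hydrogen geometry
    count_proxy, _ = hbond_count(f, proxy=True)
    assert count_proxy == 1


def test_hbond_between_masks():
    f = water_dimer(2.8)
    a = np.zeros(len(f), dtype=bool)
    b = np.zeros(len(f), dtype=bool)
    a[:3] = True
    b[3:] = True
    count, _ = hbond_count(f, between=(a, b))
    assert count == 1
    # both sides on the same molecule: nothing crosses the interface
    count, _ = hbond_count(f, between=(a, a))
    assert count == 0


# ---------------------------------------------------------------------------
# Group distances
# ---------------------------------------------------------------------------


def test_group_distance_modes():
    f = make_structure(
        ["C", "C", "H", "C"],
        [[0, 0, 0], [2, 0, 0], [5, 0, 0], [10, 0, 0]],
    )
    assert group_distance(f, [0], [3], mode="com") == pytest.approx(10.0)
    # COM of equal-mass carbons 0,1 is at x=1
    assert group_distance(f, [0, 1], [3], mode="com") == pytest.approx(9.0)
    # hydrogen is skipped by min-heavy-atom
    assert group_distance(f, [2, 3], [0], mode="min-heavy-atom") == pytest.approx(10.0)
    with pytest.raises(SelectionError):
        group_distance(f, [2], [0], mode="min-heavy-atom")
    with pytest.raises(SelectionError):
        group_distance(f, [0], [1], mode="bogus")


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------


def _protein_blob(n_res=8, atoms_per_res=3, seed=2):
    rng = np.random.default_rng(seed)
    elements, res_ids, res_names, coords = [], [], [], []
    aa = ["ALA", "SER", "GLY", "VAL"]
    for r in range(n_res):
        center = rng.uniform(0, 12, 3)
        for _ in range(atoms_per_res):
            elements.append("C")
            res_ids.append(r + 1)
            res_names.append(aa[r % 4])
            coords.append(center + rng.normal(0, 0.8, 3))
    return make_structure(elements, coords, res_ids=res_ids, res_names=res_names)


def test_contact_matrix_kdtree_equals_brute():
    for seed in range(5):
        f = _protein_blob(seed=seed)
        fast = contact_matrix(f)
        slow = contact_matrix_brute(f)
        assert fast.contacts.keys() == slow.contacts.keys()
        for k in fast.contacts:
            assert fast.contacts[k] == pytest.approx(slow.contacts[k])


def test_contact_matrix_excludes_adjacent_when_asked():
    f = _protein_blob(seed=3)
    with_adj = contact_matrix(f, include_adjacent=True)
    without = contact_matrix(f, include_adjacent=False)
    for (a, b) in without.contacts:
        ra, rb = int(a[:-3]), int(b[:-3])
        assert abs(ra - rb) > 1
    assert set(without.contacts) <= set(with_adj.contacts)


def test_contact_matrix_hand_distances():
    f = make_structure(
        ["C", "C", "C"],
        [[0, 0, 0], [3, 0, 0], [30, 0, 0]],
        res_ids=[1, 2, 3],
        res_names=["ALA", "GLY", "SER"],
    )
    row = contact_matrix(f, cutoff=6.5)
    assert row.contacts == {("1ALA", "2GLY"): pytest.approx(3.0)}


def test_contact_table_fill_and_columns():
    f1 = make_structure(
        ["C", "C"],
        [[0, 0, 0], [3, 0, 0]],
        res_ids=[1, 2],
        res_names=["ALA", "GLY"],
    )
    f2 = make_structure(
        ["C", "C"],
        [[0, 0, 0], [30, 0, 0]],
        res_ids=[1, 2],
        res_names=["ALA", "GLY"],
    )
    table = contact_table([f1, f2], cutoff=6.5)
    assert list(table.columns) == ["1ALA-2GLY"]
    assert table.iloc[0, 0] == pytest.approx(3.0)
    assert table.iloc[1, 0] == pytest.approx(6.5)  # saturates at the cutoff


def test_contact_matrix_no_heavy_protein_atoms():
    f = make_structure(["H"], [[0, 0, 0]])
    with pytest.raises(SelectionError):
        contact_matrix(f)


# ---------------------------------------------------------------------------
# Interaction fingerprints
# ---------------------------------------------------------------------------


def _benzene(center, z=0.0):
    """Hexagonal C6 ring (bond length 1.39) in the z=``z`` plane."""
    pts = []
    for k in range(6):
        a = math.pi / 3 * k
        pts.append([center[0] + 1.39 * math.cos(a), center[1] + 1.39 * math.sin(a), z])
    return pts


def _frame(prot, lig, waters=(), lig_charges=None):
    """prot: list of (name, element, res_id, res_name, xyz); lig: (element, xyz)."""
    names = [p[0] for p in prot] + [l[0] for l in lig]
    elements = [p[1] for p in prot] + [l[0] for l in lig]
    res_ids = [p[2] for p in prot] + [900] * len(lig)
    res_names = [p[3] for p in prot] + ["LIG"] * len(lig)
    coords = [p[4] for p in prot] + [l[1] for l in lig]
    is_ligand = [False] * len(prot) + [True] * len(lig)
    for w_xyz, w_rid in waters:
        names.append("O")
        elements.append("O")
        res_ids.append(w_rid)
        res_names.append("HOH")
        coords.append(w_xyz)
        is_ligand.append(False)
    charges = None
    if lig_charges is not None:
        charges = [0] * len(prot) + list(lig_charges) + [0] * len(waters)
    return make_structure(
        elements,
        coords,
        names=names,
        res_ids=res_ids,
        res_names=res_names,
        is_ligand=is_ligand,
        formal_charges=charges,
    )


def test_fingerprint_hydrophobic_contact():
    f = _frame(
        prot=[("CB", "C", 10, "LEU", [0.0, 0.0, 0.0])],
        lig=[("C", [3.5, 0.0, 0.0])],
    )
    fp = interaction_fingerprint(f)
    assert fp.get("10LEU", "HPI") == 1
    # beyond 4.0 A: no contact
    far = _frame(
        prot=[("CB", "C", 10, "LEU", [0.0, 0.0, 0.0])],
        lig=[("C", [4.5, 0.0, 0.0])],
    )
    assert interaction_fingerprint(far).bits == {}


def test_fingerprint_hbond_proxy():
    f = _frame(
        prot=[("OG", "O", 11, "SER", [0.0, 0.0, 0.0])],
        lig=[("N", [3.0, 0.0, 0.0])],
    )
    fp = interaction_fingerprint(f)
    assert fp.get("11SER", "HB") == 1


def test_fingerprint_halogen_bond():
    # C-Cl ... O roughly linear (angle at Cl ~ 180)
    f = _frame(
        prot=[("OD1", "O", 12, "ASP", [4.5, 0.0, 0.0])],
        lig=[("C", [0.0, 0.0, 0.0]), ("CL", [1.7, 0.0, 0.0])],
    )
    fp = interaction_fingerprint(f)
    assert fp.get("12ASP", "XB") == 1
    # bent arrangement fails the angle test
    bent = _frame(
        prot=[("OD1", "O", 12, "ASP", [1.7, 2.5, 0.0])],
        lig=[("C", [0.0, 0.0, 0.0]), ("CL", [1.7, 0.0, 0.0])],
    )
    assert interaction_fingerprint(bent).get("12ASP", "XB") == 0


def test_fingerprint_pi_stacking_parallel():
    phe_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    ring = _benzene((0.0, 0.0))
    prot = [(n, "C", 13, "PHE", xyz) for n, xyz in zip(phe_names, ring)]
    lig = [("C", xyz) for xyz in _benzene((0.0, 0.0), z=3.5)]
    fp = interaction_fingerprint(_frame(prot, lig))
    assert fp.get("13PHE", "PST") == 1


def test_fingerprint_pi_cation_both_directions():
    # protein cation (ARG CZ) over a ligand ring
    prot = [("CZ", "C", 14, "ARG", [0.0, 0.0, 3.0])]
    lig = [("C", xyz) for xyz in _benzene((0.0, 0.0))]
    fp = interaction_fingerprint(_frame(prot, lig))
    assert fp.get("14ARG", "PIC") == 1
    # ligand cation (quaternary N) over a protein ring
    phe_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    prot2 = [(n, "C", 15, "PHE", xyz) for n, xyz in zip(phe_names, _benzene((0.0, 0.0)))]
    nq = [("N", [0.0, 0.0, 3.0])] + [
        ("C", [1.4, 0.0, 3.0]),
        ("C", [-1.4, 0.0, 3.0]),
        ("C", [0.0, 1.4, 3.0]),
        ("C", [0.0, -1.4, 3.0]),
    ]
    fp2 = interaction_fingerprint(_frame(prot2, nq))
    assert fp2.get("15PHE", "PIC") == 1


def test_fingerprint_salt_bridge_with_formal_charges():
    prot = [("NZ", "N", 16, "LYS", [0.0, 0.0, 0.0])]
    lig = [("O", [3.0, 0.0, 0.0])]
    fp = interaction_fingerprint(_frame(prot, lig, lig_charges=[-1]))
    assert fp.get("16LYS", "SB") == 1


def test_fingerprint_salt_bridge_carboxylate_heuristic():
    # ligand carboxylate (C with two terminal O) against LYS NZ
    prot = [("NZ", "N", 17, "LYS", [0.0, 0.0, 0.0])]
    lig = [
        ("C", [3.5, 0.0, 0.0]),
        ("O", [2.9, 1.1, 0.0]),
        ("O", [2.9, -1.1, 0.0]),
    ]
    fp = interaction_fingerprint(_frame(prot, lig))
    assert fp.get("17LYS", "SB") == 1


def test_fingerprint_water_bridge():
    prot = [("OG", "O", 18, "SER", [6.0, 0.0, 0.0])]
    lig = [("O", [0.0, 0.0, 0.0])]
    fp = interaction_fingerprint(
        _frame(prot, lig, waters=(([3.0, 0.0, 0.0], 500),))
    )
    assert fp.get("18SER", "WB") == 1
    # direct ligand-protein distance is 6 A: too far for a plain HB
    assert fp.get("18SER", "HB") == 0


def test_fingerprint_requires_ligand():
    f = make_structure(["C"], [[0, 0, 0]])
    with pytest.raises(SelectionError):
        interaction_fingerprint(f)


def test_frequency_filter_strictly_greater():
    from allokin.featurize import FingerprintRow

    rows = []
    for i in range(5):
        bits = {}
        if i < 2:
            bits[("10LEU", "HPI")] = 1  # 2/5 = 0.4, NOT kept at 0.40
        if i < 3:
            bits[("11SER", "HB")] = 1  # 3/5 = 0.6, kept
        rows.append(FingerprintRow(frame_index=i, bits=bits))
    kept = frequency_filter(rows, threshold=0.40)
    assert kept == {("11SER", "HB"): pytest.approx(0.6)}
    with pytest.raises(SelectionError):
        frequency_filter([])


# ---------------------------------------------------------------------------
# Structure I/O
# ---------------------------------------------------------------------------


def test_pdb_roundtrip(tmp_path):
    frames = [
        make_structure(
            ["C", "N", "O"],
            [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]],
            names=["CA", "N", "O"],
            res_ids=[1, 1, 2],
            res_names=["ALA", "ALA", "GLY"],
        )
        for _ in range(3)
    ]
    for k, f in enumerate(frames):
        f.coords = f.coords + 0.5 * k
    p = tmp_path / "mini.pdb"
    write_structures_pdb(frames, p)
    back = read_structures(p)
    assert len(back) == 3
    for orig, rb in zip(frames, back):
        np.testing.assert_allclose(rb.coords, orig.coords, atol=1e-2)
        assert list(rb.res_ids) == list(orig.res_ids)
        assert list(rb.elements) == list(orig.elements)


def test_xyz_parse(tmp_path):
    p = tmp_path / "mol.xyz"
    p.write_text("2\nframe 1\nC 0 0 0\nO 1.2 0 0\n2\nframe 2\nC 0 0 0\nO 1.3 0 0\n")
    frames = read_structures(p)
    assert len(frames) == 2
    assert list(frames[0].elements) == ["C", "O"]
    assert frames[1].coords[1][0] == pytest.approx(1.3)


def test_xyz_errors(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("not-a-count\n")
    with pytest.raises(ParseError):
        read_structures(p)
    p2 = tmp_path / "mismatch.xyz"
    p2.write_text("2\nc\nC 0 0 0\nO 1 0 0\n3\nc\nC 0 0 0\nO 1 0 0\nN 2 0 0\n")
    with pytest.raises(FrameMismatchError):
        read_structures(p2)
    p3 = tmp_path / "short.xyz"
    p3.write_text("1\nc\nC 0 0\n")
    with pytest.raises(ParseError):
        read_structures(p3)


def test_element_from_name():
    assert element_from_name("CA") == "C"
    assert element_from_name("CL1") == "CL"
    assert element_from_name("1HB") == "H"
    with pytest.raises(ParseError):
        element_from_name("123")


def test_structure_masks():
    f = make_structure(
        ["C", "O", "C"],
        [[0, 0, 0], [1, 0, 0], [2, 0, 0]],
        res_ids=[1, 2, 3],
        res_names=["ALA", "HOH", "LIG"],
        is_ligand=[False, False, True],
    )
    assert list(f.is_water) == [False, True, False]
    assert list(f.is_protein) == [True, False, False]
    assert f.residue_keys() == ["1ALA"]
    assert list(f.select_residues([2, 3])) == [False, True, True]
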