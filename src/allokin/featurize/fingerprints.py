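"""Geometric ligand–receptor interaction fingerprints.

Seven binary interaction classes per (protein residue, class) pair:

* HPI — hydrophobic: ligand carbon within 4.0 A of a residue carbon,
* HB  — hydrogen bond (shared geometric criterion with
  :func:`allokin.featurize.descriptors.hbond_count`),
* XB  — halogen bond: ligand halogen to protein N/O acceptor <= 3.5 A
  with a C–X...A angle >= 140 deg,
* PST — pi-stacking: ring centroids <= 5.5 A with plane normals within
  30 deg (parallel) or 60–90 deg (T-shaped),
* PIC — pi-cation: cation to ring centroid <= 6.0 A,
* SB  — salt bridge: opposite formal charges <= 5.5 A,
* WB  — water bridge: a water oxygen hydrogen-bonded (distance
  criterion) to both ligand and residue polar atoms.

These are documented re-implementations of common practice; they are
not a clone of any particular fingerprinting program, and every
threshold is configurable through :class:`GeometricRules`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import math
import numpy as np

from allokin._errors import SelectionError
from allokin.featurize.structure import HALOGENS, Structure

CLASSES = ("HPI", "HB", "XB", "PST", "PIC", "SB", "WB")

_RING_TEMPLATES = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIE": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HID": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIP": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

_CATION_ATOMS = {("ARG", "CZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ"), ("HIP", "NE2")}
_ANION_ATOMS = {
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
}


@dataclass(frozen=True)
class GeometricRules:
    """Distance/angle thresholds for the seven interaction classes."""

    hpi_cutoff: float = 4.0
    hb_distance: float = 3.5
    hb_angle: float = 120.0
    xb_distance: float = 3.5
    xb_angle: float = 140.0
    pst_centroid: float = 5.5
    pst_parallel_angle: float = 30.0
    pst_tshape_range: tuple[float, float] = (60.0, 90.0)
    pic_cutoff: float = 6.0
    sb_cutoff: float = 5.5
    wb_leg_distance: float = 3.5
    covalent_cutoff: float = 1.9


@dataclass
class FingerprintRow:
    """Binary (residue, class) presence map for one frame."""

    frame_index: int
    bits: dict[tuple[str, str], int] = field(default_factory=dict)

    def get(self, residue_key: str, cls: str) -> int:
        return self.bits.get((residue_key, cls), 0)


# ---------------------------------------------------------------------------
# Ligand perception helpers
# ---------------------------------------------------------------------------


def _ligand_bonds(frame: Structure, lig_idx: np.ndarray, cutoff: float) -> dict[int, list[int]]:
    bonds: dict[int, list[int]] = {i: [] for i in lig_idx}
    for ii, i in enumerate(lig_idx):
        for j in lig_idx[ii + 1 :]:
            if np.linalg.norm(frame.coords[i] - frame.coords[j]) <= cutoff:
                bonds[i].append(j)
                bonds[j].append(i)
    return bonds


def _ligand_rings(frame: Structure, lig_idx: np.ndarray, bonds) -> list[np.ndarray]:
    """5/6-membered C/N cycles in the ligand bond graph."""
    import networkx as nx

    g = nx.Graph()
    for i in lig_idx:
        if frame.elements[i].upper() in ("C", "N"):
            g.add_node(int(i))
    for i in g.nodes:
        for j in bonds[i]:
            if j in g.nodes:
                g.add_edge(int(i), int(j))
    rings = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) in (5, 6):
            rings.append(np.array(cyc))
    return rings


def _ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _angle_between_normals(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)))
    return math.degrees(math.acos(min(1.0, c)))


def _ligand_charges(frame: Structure, lig_idx: np.ndarray, bonds) -> tuple[list[int], list[int]]:
    """(cation_atoms, anion_atoms) by formal charge or heuristics.

    Heuristics: N with 4 heavy neighbors -> cation (quaternary /
    protonated amine); carboxylate O (O with one C neighbor that binds
    two terminal O) -> anion.
    """
    if frame.formal_charges is not None:
        q = np.asarray(frame.formal_charges)
        return (
            [int(i) for i in lig_idx if q[i] > 0],
            [int(i) for i in lig_idx if q[i] < 0],
        )
    cations, anions = [], []
    elem = lambda i: frame.elements[i].upper()
    for i in lig_idx:
        if elem(i) == "N" and len(bonds[i]) >= 4:
            cations.append(int(i))
        if elem(i) == "O" and len(bonds[i]) == 1:
            c = bonds[i][0]
            if elem(c) == "C":
                terminal_os = [
                    j for j in bonds[c] if elem(j) == "O" and len(bonds[j]) == 1
                ]
                if len(terminal_os) == 2:
                    anions.append(int(i))
    return cations, anions


# ---------------------------------------------------------------------------
# Fingerprint
# ---------------------------------------------------------------------------


def interaction_fingerprint(
    frame: Structure,
    rules: GeometricRules = GeometricRules(),
    frame_index: int = 0,
) -> FingerprintRow:
    """Binary interaction fingerprint of the flagged ligand vs protein."""
    lig_idx = np.flatnonzero(frame.is_ligand & frame.heavy)
    if lig_idx.size == 0:
        raise SelectionError("no ligand atoms flagged in this frame")
    prot_idx = np.flatnonzero(frame.is_protein & frame.heavy)
    water_o = np.flatnonzero(
        frame.is_water & (np.char.upper(frame.elements.astype(str)) == "O")
    )
    coords = frame.coords
    elem = np.array([e.upper() for e in frame.elements])
    reskey = {
        int(i): f"{frame.res_ids[i]}{frame.res_names[i]}" for i in prot_idx
    }

    bonds = _ligand_bonds(frame, lig_idx, rules.covalent_cutoff)
    rings_lig = [
        c for c in _ligand_rings(frame, lig_idx, bonds)
    ]
    lig_cations, lig_anions = _ligand_charges(frame, lig_idx, bonds)

    bits: dict[tuple[str, str], int] = {}

    def mark(res: str, cls: str) -> None:
        bits[(res, cls)] = 1

    # --- HPI: carbon-carbon proximity -----------------------------------
    lig_c = [i for i in lig_idx if elem[i] == "C"]
    for p in prot_idx:
        if elem[p] != "C":
            continue
        for l in lig_c:
            if np.linalg.norm(coords[p] - coords[l]) <= rules.hpi_cutoff:
                mark(reskey[p], "HPI")
                break

    # --- HB: shared hydrogen-bond criterion ------------------------------
    from allokin.featurize.descriptors import hbond_count

    has_h = (elem == "H").any()
    lig_mask = frame.is_ligand & frame.heavy
    prot_mask = frame.is_protein & frame.heavy
    _, hb_pairs = hbond_count(
        frame,
        distance_cutoff=rules.hb_distance,
        angle_cutoff=rules.hb_angle,
        proxy=not has_h,
        between=(lig_mask, prot_mask),
    )
    for d, a in hb_pairs:
        p = a if frame.is_protein[a] else d
        if frame.is_protein[p]:
            mark(reskey[int(p)], "HB")

    # --- XB: halogen bonds -----------------------------------------------
    for x in lig_idx:
        if elem[x] not in HALOGENS:
            continue
        carbons = [j for j in bonds[x] if elem[j] == "C"]
        if not carbons:
            continue
        c = carbons[0]
        for a in prot_idx:
            if elem[a] not in ("N", "O"):
                continue
            d = np.linalg.norm(coords[x] - coords[a])
            if d > rules.xb_distance:
                continue
            v1 = coords[c] - coords[x]
            v2 = coords[a] - coords[x]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = math.degrees(math.acos(np.clip(cosang, -1, 1)))
            if ang >= rules.xb_angle:
                mark(reskey[a], "XB")

    # --- rings: PST and PIC ----------------------------------------------
    prot_rings = []  # (residue_key, centroid, normal)
    by_res: dict[int, dict[str, int]] = {}
    for p in prot_idx:
        by_res.setdefault(int(frame.res_ids[p]), {})[frame.names[p].strip().upper()] = int(p)
    for rid, atoms in by_res.items():
        rname = None
        for p in prot_idx:
            if int(frame.res_ids[p]) == rid:
                rname = frame.res_names[p].upper()
                break
        for template in _RING_TEMPLATES.get(rname, []):
            if set(template) <= atoms.keys():
                ring_xyz = np.array([coords[atoms[n]] for n in template])
                centroid, normal = _ring_geometry(ring_xyz)
                prot_rings.append((f"{rid}{rname}", centroid, normal))

    lig_ring_geo = [
        _ring_geometry(coords[r]) for r in rings_lig
    ]
    for res, pc, pn in prot_rings:
        for lc, ln in lig_ring_geo:
            if np.linalg.norm(pc - lc) > rules.pst_centroid:
                continue
            ang = _angle_between_normals(pn, ln)
            lo, hi = rules.pst_tshape_range
            if ang <= rules.pst_parallel_angle or lo <= ang <= hi:
                mark(res, "PST")

    # protein cation vs ligand ring; ligand cation vs protein ring
    prot_cations = [
        int(p)
        for p in prot_idx
        if (frame.res_names[p].upper(), frame.names[p].strip().upper())
        in _CATION_ATOMS
    ]
    for p in prot_cations:
        for lc, _ in lig_ring_geo:
            if np.linalg.norm(coords[p] - lc) <= rules.pic_cutoff:
                mark(reskey[p], "PIC")
    for res, pc, _ in prot_rings:
        for l in lig_cations:
            if np.linalg.norm(coords[l] - pc) <= rules.pic_cutoff:
                mark(res, "PIC")

    # --- SB: salt bridges --------------------------------------------------
    prot_anions = [
        int(p)
        for p in prot_idx
        if (frame.res_names[p].upper(), frame.names[p].strip().upper())
        in _ANION_ATOMS
    ]
    for p, lig_side in ((prot_cations, lig_anions), (prot_anions, lig_cations)):
        for pp in p:
            for l in lig_side:
                if np.linalg.norm(coords[pp] - coords[l]) <= rules.sb_cutoff:
                    mark(reskey[pp], "SB")

    # --- WB: water bridges -------------------------------------------------
    lig_polar = [i for i in lig_idx if elem[i] in ("N", "O")]
    prot_polar = [int(p) for p in prot_idx if elem[p] in ("N", "O")]
    for w in water_o:
        lig_leg = any(
            np.linalg.norm(coords[w] - coords[l]) <= rules.wb_leg_distance
            for l in lig_polar
        )
        if not lig_leg:
            continue
        for p in prot_polar:
            if np.linalg.norm(coords[w] - coords[p]) <= rules.wb_leg_distance:
                mark(reskey[p], "WB")

    return FingerprintRow(frame_index=frame_index, bits=bits)


def frequency_filter(
    rows: list[FingerprintRow], threshold: float = 0.40
) -> dict[tuple[str, str], float]:
    """Keep (residue, class) bits whose occurrence fraction strictly
    exceeds ``threshold``; returns the surviving bits with their
    frequencies."""
    if not rows:
        raise SelectionError("need at least one fingerprint row")
    counts: dict[tuple[str, str], int] = {}
    for r in rows:
        for key, v in r.bits.items():
            if v:
                counts[key] = counts.get(key, 0) + 1
    n = len(rows)
    return {k: c / n for k, c in counts.items() if c / n > threshold}
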