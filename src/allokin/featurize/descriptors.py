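"""Per-frame geometric descriptors.

All distances in Angstrom, angles in degrees. RMSD uses optimal
(Kabsch) superposition; the radius-of-gyration axis components follow
the coordinate-decomposition convention Rg^2 = Rg[X]^2+Rg[Y]^2+Rg[Z]^2
in the lab frame; SASA is Shrake–Rupley with a deterministic Fibonacci
sphere.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from allokin._errors import AllokinError, SelectionError
from allokin.featurize.structure import BONDI_RADII, Structure


class MissingRadiusError(AllokinError):
    """An element has no van der Waals radius and no override was given."""


def _resolve_selection(frame: Structure, selection) -> np.ndarray:
    if selection is None:
        return np.arange(len(frame))
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if sel.size == 0:
        raise SelectionError("empty selection")
    return sel


# ---------------------------------------------------------------------------
# RMSD and Rg
# ---------------------------------------------------------------------------


def rmsd(
    frame: Structure,
    reference: Structure,
    selection=None,
    superpose: bool = True,
) -> float:
    """Optimal-superposition RMSD between matched selections, A."""
    sel = _resolve_selection(frame, selection)
    if len(sel) < 3:
        raise SelectionError("RMSD needs at least 3 atoms")
    if len(frame) != len(reference):
        raise SelectionError("frame and reference atom counts differ")
    a = reference.coords[sel]
    b = frame.coords[sel]
    if not superpose:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a0, b0)
    return float(rssd / math.sqrt(len(sel)))


def radius_of_gyration(
    frame: Structure, selection=None, axis: str = "all"
) -> float:
    """Mass-weighted radius of gyration about the center of mass, A.

    ``axis`` in {"all", "X", "Y", "Z"}: the per-axis component uses the
    squared coordinate displacement along that lab-frame axis, so that
    Rg(all)^2 equals the sum of the three axis components squared.
    """
    sel = _resolve_selection(frame, selection)
    xyz = frame.coords[sel]
    m = frame.atom_masses[sel]
    com = np.average(xyz, axis=0, weights=m)
    d = xyz - com
    if axis == "all":
        msd = np.average(np.sum(d * d, axis=1), weights=m)
    else:
        try:
            ax = "XYZ".index(axis.upper())
        except ValueError:
            raise SelectionError(f"axis must be all/X/Y/Z, got {axis!r}")
        msd = np.average(d[:, ax] ** 2, weights=m)
    return float(np.sqrt(msd))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    frame: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    selection=None,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area.

    Returns (per_atom_area, total_area) in A^2 for the selected atoms.
    Element radii default to the Bondi set; unknown elements raise
    :class:`MissingRadiusError` unless overridden via ``radii``.
    Exactly coincident equal-radius atoms are counted once (the later
    duplicate is scored fully buried) so unions of degenerate spheres
    behave geometrically.
    """
    sel = _resolve_selection(frame, selection)
    table = dict(BONDI_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    try:
        r_atom = np.array([table[frame.elements[i].upper()] for i in sel])
    except KeyError as exc:
        raise MissingRadiusError(f"no vdW radius for element {exc}") from exc
    xyz = frame.coords[sel]
    r_ext = r_atom + probe_radius
    sphere = _fibonacci_sphere(n_sphere_points)
    tree = cKDTree(xyz)
    areas = np.zeros(len(sel))
    dup_tol = 1e-9
    for i in range(len(sel)):
        # degenerate duplicates: only the first copy carries area
        neighbors = tree.query_ball_point(xyz[i], r_ext[i] + r_ext.max())
        dup = False
        for j in neighbors:
            if j == i:
                continue
            if (
                j < i
                and np.linalg.norm(xyz[j] - xyz[i]) < dup_tol
                and abs(r_atom[j] - r_atom[i]) < dup_tol
            ):
                dup = True
                break
        if dup:
            continue
        pts = xyz[i] + r_ext[i] * sphere
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            d = np.linalg.norm(pts - xyz[j], axis=1)
            exposed &= d >= r_ext[j] - dup_tol
        frac = exposed.mean()
        areas[i] = frac * 4.0 * math.pi * r_ext[i] ** 2
    return areas, float(areas.sum())


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees, (-180, 180]; NaN when degenerate."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return float("nan")
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def backbone_dihedrals(frame: Structure) -> dict[int, tuple[float, float]]:
    """phi/psi per residue id; terminal/undefined angles are NaN."""
    backbone: dict[int, dict[str, np.ndarray]] = {}
    order: list[int] = []
    for i in range(len(frame)):
        if not frame.is_protein[i]:
            continue
        rid = int(frame.res_ids[i])
        name = frame.names[i].strip().upper()
        if name in ("N", "CA", "C"):
            if rid not in backbone:
                backbone[rid] = {}
                order.append(rid)
            backbone[rid][name] = frame.coords[i]
    out: dict[int, tuple[float, float]] = {}
    for k, rid in enumerate(order):
        res = backbone[rid]
        phi = psi = float("nan")
        if {"N", "CA", "C"} <= res.keys():
            if k > 0 and "C" in backbone[order[k - 1]]:
                phi = _dihedral(
                    backbone[order[k - 1]]["C"], res["N"], res["CA"], res["C"]
                )
            if k + 1 < len(order) and "N" in backbone[order[k + 1]]:
                psi = _dihedral(
                    res["N"], res["CA"], res["C"], backbone[order[k + 1]]["N"]
                )
        out[rid] = (phi, psi)
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds and group distances
# ---------------------------------------------------------------------------


def hbond_count(
    frame: Structure,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
    proxy: bool = False,
    between: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[int, list[tuple[int, int]]]:
    """Count donor–acceptor hydrogen bonds.

    Criteria: donor-heavy-atom (N/O with a covalent H) to acceptor
    (N/O) distance <= ``distance_cutoff`` and D-H...A angle at the
    hydrogen >= ``angle_cutoff``. With ``proxy=True`` (structures
    without hydrogens) only the N/O–N/O distance criterion is applied.
    Pairs within the same residue are excluded. ``between`` restricts
    donors to the first and acceptors to the second atom mask (both
    directions are tried). Returns (count, donor–acceptor index pairs).
    """
    elements = np.array([e.upper() for e in frame.elements])
    polar = np.isin(elements, ["N", "O"])
    coords = frame.coords
    hyd = np.flatnonzero(elements == "H")
    attached: dict[int, list[int]] = {}
    if hyd.size and polar.any():
        ptree = cKDTree(coords[polar])
        polar_idx = np.flatnonzero(polar)
        for h in hyd:
            for j in ptree.query_ball_point(coords[h], 1.25):
                attached.setdefault(polar_idx[j], []).append(h)

    if between is not None:
        mask_a = np.asarray(between[0], dtype=bool)
        mask_b = np.asarray(between[1], dtype=bool)
    else:
        mask_a = mask_b = np.ones(len(frame), dtype=bool)

    pairs = []
    polar_idx = np.flatnonzero(polar)
    tree = cKDTree(coords[polar_idx])
    for ia, ja in tree.query_pairs(distance_cutoff):
        for d, a in ((polar_idx[ia], polar_idx[ja]), (polar_idx[ja], polar_idx[ia])):
            if frame.res_ids[d] == frame.res_ids[a] and frame.chain_ids[d] == frame.chain_ids[a]:
                continue
            if between is not None:
                if not (
                    (mask_a[d] and mask_b[a]) or (mask_b[d] and mask_a[a])
                ):
                    continue
            if proxy:
                pairs.append((int(d), int(a)))
                break
            ok = False
            for h in attached.get(d, []):
                v1 = coords[d] - coords[h]
                v2 = coords[a] - coords[h]
                cosang = np.dot(v1, v2) / (
                    np.linalg.norm(v1) * np.linalg.norm(v2)
                )
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) >= angle_cutoff:
                    ok = True
                    break
            if ok:
                pairs.append((int(d), int(a)))
                break
    return len(pairs), pairs


def group_distance(
    frame: Structure,
    selection_a,
    selection_b,
    mode: str = "com",
) -> float:
    """Distance between two atom groups: center of mass or minimum
    heavy-atom distance."""
    sa = _resolve_selection(frame, selection_a)
    sb = _resolve_selection(frame, selection_b)
    if mode == "com":
        ma, mb = frame.atom_masses[sa], frame.atom_masses[sb]
        ca = np.average(frame.coords[sa], axis=0, weights=ma)
        cb = np.average(frame.coords[sb], axis=0, weights=mb)
        return float(np.linalg.norm(ca - cb))
    if mode == "min-heavy-atom":
        heavy = frame.heavy
        ha = [i for i in sa if heavy[i]]
        hb = [i for i in sb if heavy[i]]
        if not ha or not hb:
            raise SelectionError("no heavy atoms in selection")
        d = np.linalg.norm(
            frame.coords[ha][:, None, :] - frame.coords[hb][None, :, :], axis=-1
        )
        return float(d.min())
    raise SelectionError(f"unknown mode {mode!r}")
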