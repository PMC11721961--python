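"""Shared builders for the test suite."""

from __future__ import annotations

import numpy as np

from allokin.featurize.structure import Structure


def make_structure(
    elements,
    coords,
    names=None,
    res_ids=None,
    res_names=None,
    chain_ids=None,
    is_ligand=None,
    formal_charges=None,
) -> Structure:
    """Structure with per-array defaults: one protein residue per atom."""
    n = len(elements)
    coords = np.asarray(coords, dtype=float)
    return Structure(
        names=np.array(names if names is not None else elements),
        elements=np.array(elements),
        res_ids=np.array(
            res_ids if res_ids is not None else range(1, n + 1), dtype=int
        ),
        res_names=np.array(res_names if res_names is not None else ["ALA"] * n),
        chain_ids=np.array(chain_ids if chain_ids is not None else ["A"] * n),
        coords=coords,
        is_ligand=np.array(
            is_ligand if is_ligand is not None else [False] * n, dtype=bool
        ),
        formal_charges=(
            np.array(formal_charges) if formal_charges is not None else None
        ),
    )


def water(origin, res_id, res_name="HOH", oh=0.96, angle_deg=104.5):
    """One water molecule (O, H1, H2) with O at ``origin``."""
    import math

    origin = np.asarray(origin, dtype=float)
    a = math.radians(angle_deg)
    h1 = origin + np.array([oh, 0.0, 0.0])
    h2 = origin + oh * np.array([math.cos(a), math.sin(a), 0.0])
    return (
        ["O", "H", "H"],
        [origin, h1, h2],
        ["O", "H1", "H2"],
        [res_id] * 3,
        [res_name] * 3,
    )


def water_dimer(o_o_distance=2.8):
    """Two waters, donor H of the first pointing at the second oxygen.

    Built so the D-H...A angle at the hydrogen is ~180 degrees.
    """
    o1 = np.array([0.0, 0.0, 0.0])
    o2 = np.array([o_o_distance, 0.0, 0.0])
    h_donor = np.array([0.96, 0.0, 0.0])  # on the O1->O2 axis
    h_other = np.array([-0.24, 0.93, 0.0])
    h3 = o2 + np.array([0.24, 0.93, 0.0])
    h4 = o2 + np.array([0.24, -0.93, 0.0])
    elements = ["O", "H", "H", "O", "H", "H"]
    coords = [o1, h_donor, h_other, o2, h3, h4]
    names = ["O", "H1", "H2", "O", "H1", "H2"]
    res_ids = [1, 1, 1, 2, 2, 2]
    res_names = ["HOH"] * 6
    return make_structure(
        elements, coords, names=names, res_ids=res_ids, res_names=res_names
    )
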