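"""Residue contact matrices.

A contact row maps each protein residue pair (i < j) to the minimum
heavy-atom distance, kept only when it is within the cutoff (default
6.5 A). Waters and ligand atoms are excluded. The KD-tree accelerated
search is required to agree exactly with the brute-force double loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from allokin._errors import SelectionError
from allokin.featurize.structure import Structure


@dataclass
class ContactRow:
    """Sparse residue-pair -> minimum heavy-atom distance map (A)."""

    frame_index: int
    contacts: dict[tuple[str, str], float] = field(default_factory=dict)


def _residue_atoms(frame: Structure) -> tuple[list[str], np.ndarray]:
    """Residue key per heavy protein atom plus the atom indices used."""
    mask = frame.is_protein & frame.heavy
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectionError("no heavy protein atoms")
    keys = [f"{frame.res_ids[i]}{frame.res_names[i]}" for i in idx]
    return keys, idx


def contact_matrix(
    frame: Structure,
    cutoff: float = 6.5,
    frame_index: int = 0,
    include_adjacent: bool = True,
) -> ContactRow:
    """KD-tree accelerated minimum heavy-atom residue-pair distances."""
    keys, idx = _residue_atoms(frame)
    coords = frame.coords[idx]
    rid = frame.res_ids[idx]
    tree = cKDTree(coords)
    best: dict[tuple[str, str], float] = {}
    for a, b in tree.query_pairs(cutoff):
        ra, rb = int(rid[a]), int(rid[b])
        if ra == rb:
            continue
        if not include_adjacent and abs(ra - rb) == 1:
            continue
        pair = (keys[a], keys[b]) if ra < rb else (keys[b], keys[a])
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d < best.get(pair, np.inf):
            best[pair] = d
    return ContactRow(frame_index=frame_index, contacts=best)


def contact_matrix_brute(
    frame: Structure,
    cutoff: float = 6.5,
    frame_index: int = 0,
    include_adjacent: bool = True,
) -> ContactRow:
    """Reference double-loop implementation (test oracle)."""
    keys, idx = _residue_atoms(frame)
    coords = frame.coords[idx]
    rid = frame.res_ids[idx]
    best: dict[tuple[str, str], float] = {}
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            ra, rb = int(rid[a]), int(rid[b])
            if ra == rb:
                continue
            if not include_adjacent and abs(ra - rb) == 1:
                continue
            d = float(np.linalg.norm(coords[a] - coords[b]))
            if d > cutoff:
                continue
            pair = (keys[a], keys[b]) if ra < rb else (keys[b], keys[a])
            if d < best.get(pair, np.inf):
                best[pair] = d
    return ContactRow(frame_index=frame_index, contacts=best)


def contact_table(
    frames: list[Structure],
    cutoff: float = 6.5,
    fill_value: float | None = None,
) -> pd.DataFrame:
    """Wide per-frame contact feature table.

    Columns are ``"58ASN-506GLN"``-style pair labels; cells hold the
    minimum distance, with absent contacts filled by ``fill_value``
    (default: the cutoff, so "no contact" saturates at the cutoff).
    """
    if fill_value is None:
        fill_value = cutoff
    rows = [contact_matrix(f, cutoff, i) for i, f in enumerate(frames)]
    cols = sorted({f"{a}-{b}" for r in rows for a, b in r.contacts})
    data = np.full((len(rows), len(cols)), float(fill_value))
    pos = {c: k for k, c in enumerate(cols)}
    for i, r in enumerate(rows):
        for (a, b), d in r.contacts.items():
            data[i, pos[f"{a}-{b}"]] = d
    return pd.DataFrame(data, columns=cols)
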