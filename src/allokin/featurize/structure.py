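"""The in-memory structure container and multi-model file I/O.

PDB files are read and written through biotite; XYZ (which carries no
topology) is parsed directly. A :class:`Structure` is a flat
struct-of-arrays over atoms; ligand atoms are flagged (HETATM records
that are not water).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from allokin._errors import AllokinError, ParseError

WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}

ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
}

#: Bondi van der Waals radii, A.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

HALOGENS = {"F", "CL", "BR", "I"}


class FrameMismatchError(AllokinError):
    """Models in a multi-model file have differing atom counts."""


def element_from_name(name: str) -> str:
    """Infer the element from an atom name (first alphabetic run)."""
    stripped = name.strip()
    if stripped[:2].upper() in {"CL", "BR", "NA", "MG", "ZN", "FE"} and len(
        stripped
    ) <= 3:
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ParseError(f"cannot infer element from atom name {name!r}")


@dataclass
class Structure:
    """One frame: flat arrays over atoms.

    ``coords`` in Angstrom, shape (n, 3). ``is_ligand`` marks HETATM
    (non-water) atoms; waters are identified by residue name.
    """

    names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    is_ligand: np.ndarray
    masses: np.ndarray | None = None
    formal_charges: np.ndarray | None = None
    _mass_cache: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ParseError("coordinates must be finite")
        n = len(self.coords)
        for arr_name in ("names", "elements", "res_ids", "res_names", "chain_ids", "is_ligand"):
            if len(getattr(self, arr_name)) != n:
                raise ParseError(f"array {arr_name} length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def atom_masses(self) -> np.ndarray:
        """Per-atom masses; element lookup with unit-mass fallback."""
        if self.masses is not None:
            return np.asarray(self.masses, dtype=float)
        if self._mass_cache is None:
            self._mass_cache = np.array(
                [ELEMENT_MASSES.get(e.upper(), 1.0) for e in self.elements]
            )
        return self._mass_cache

    @property
    def heavy(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    @property
    def is_water(self) -> np.ndarray:
        return np.array([rn.upper() in WATER_NAMES for rn in self.res_names])

    @property
    def is_protein(self) -> np.ndarray:
        return ~self.is_ligand & ~self.is_water

    def select_residues(self, res_ids, chain: str | None = None) -> np.ndarray:
        """Boolean mask of atoms whose residue id is in ``res_ids``."""
        wanted = set(int(r) for r in np.atleast_1d(res_ids))
        mask = np.array([int(r) in wanted for r in self.res_ids])
        if chain is not None:
            mask &= self.chain_ids == chain
        return mask

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with coordinates rotated then translated."""
        return Structure(
            self.names, self.elements, self.res_ids, self.res_names,
            self.chain_ids, self.coords @ rotation.T + translation,
            self.is_ligand, self.masses, self.formal_charges,
        )

    def residue_keys(self) -> list[str]:
        """Ordered unique residue labels like ``111ARG`` (protein only)."""
        seen, out = set(), []
        for rid, rname, prot in zip(self.res_ids, self.res_names, self.is_protein):
            if prot and rid not in seen:
                seen.add(rid)
                out.append(f"{rid}{rname}")
        return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_structures(path, fmt: str | None = None) -> list[Structure]:
    """Read a multi-model PDB or multi-frame XYZ into Structures.

    ``fmt`` is inferred from the suffix when not given
    (``pdb-multimodel`` or ``xyz``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb-multimodel"
    if fmt in ("pdb", "pdb-multimodel"):
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ParseError(f"unknown format {fmt!r}")


def _read_pdb(path: Path) -> list[Structure]:
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise FrameMismatchError(f"{path}: {exc}") from exc
    arr0 = stack[0]
    elements = np.array(
        [
            e if e else element_from_name(n)
            for e, n in zip(arr0.element, arr0.atom_name)
        ]
    )
    res_names = np.array([rn.upper() for rn in arr0.res_name])
    is_water = np.isin(res_names, list(WATER_NAMES))
    is_ligand = arr0.hetero & ~is_water
    frames = []
    for model in stack:
        frames.append(
            Structure(
                names=np.array(arr0.atom_name),
                elements=elements,
                res_ids=np.array(arr0.res_id, dtype=int),
                res_names=res_names,
                chain_ids=np.array(arr0.chain_id),
                coords=np.array(model.coord, dtype=float),
                is_ligand=np.array(is_ligand, dtype=bool),
            )
        )
    return frames


def _read_xyz(path: Path) -> list[Structure]:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    natoms_ref = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: expected atom count") from exc
        if natoms_ref is None:
            natoms_ref = natoms
        elif natoms != natoms_ref:
            raise FrameMismatchError(
                f"{path}:{i + 1}: frame has {natoms} atoms, expected {natoms_ref}"
            )
        if i + 1 + natoms + 1 > len(lines) + 1:
            raise ParseError(f"{path}: truncated frame at line {i + 1}")
        block = lines[i + 2 : i + 2 + natoms]
        elements, coords = [], []
        for k, raw in enumerate(block):
            parts = raw.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{i + 3 + k}: expected 'element x y z'"
                )
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 3 + k}: {exc}") from exc
            elements.append(parts[0].upper())
        n = len(elements)
        frames.append(
            Structure(
                names=np.array(elements),
                elements=np.array(elements),
                res_ids=np.ones(n, dtype=int),
                res_names=np.array(["MOL"] * n),
                chain_ids=np.array(["A"] * n),
                coords=np.array(coords),
                is_ligand=np.zeros(n, dtype=bool),
            )
        )
        i += 2 + natoms
    return frames


def write_structures_pdb(frames: list[Structure], path) -> None:
    """Write frames as a multi-model PDB via biotite."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    first = frames[0]
    n = len(first)
    stack = struc.AtomArrayStack(len(frames), n)
    stack.coord = np.stack([f.coords for f in frames]).astype(np.float32)
    stack.atom_name = np.array(first.names)
    stack.element = np.array(first.elements)
    stack.res_id = np.array(first.res_ids, dtype=int)
    stack.res_name = np.array(first.res_names)
    stack.chain_id = np.array(first.chain_ids)
    stack.set_annotation("hetero", np.array(first.is_ligand | first.is_water))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
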