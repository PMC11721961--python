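"""Synthetic-data generators with known ground truth.

Because no trajectories are deposited for the system this package
models, every pipeline stage is exercised on generated inputs whose
truth is known by construction: planted-feature tables for the ML
stage, inhibitor panels whose potency follows the composite descriptor
relation, two-state bead trajectories with designed contact
differences, and free-energy surfaces with prescribed critical points.
Every generator is a pure function of its spec and seed, and emits its
ground truth alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from allokin._errors import InvalidParameterError
from allokin.fes import FESGrid
from allokin.featurize.structure import Structure, write_structures_pdb
from allokin.ml import STRONG, WEAK, label_activity


# ---------------------------------------------------------------------------
# Planted-feature tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedTableSpec:
    """A frames-by-features table with known informative features.

    Non-planted features are standard normal noise. For binary labels
    the planted features are mean-shifted by ``effect_size`` standard
    deviations between classes; for continuous labels they are linearly
    coupled to the label with coefficient ``effect_size``.
    """

    n_samples: int = 2000
    n_features: int = 200
    planted: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 1.0
    label_type: str = "binary"  # or "continuous"
    noise_sd: float = 1.0
    n_groups: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p < 0 or p >= self.n_features for p in self.planted):
            raise InvalidParameterError("planted index out of range")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise InvalidParameterError("effect size and noise sd must be >= 0")


def gen_feature_table(spec: PlantedTableSpec) -> pd.DataFrame:
    """Generate the table; columns f000..fNNN plus label and group."""
    rng = np.random.default_rng(spec.seed)
    X = rng.standard_normal((spec.n_samples, spec.n_features)) * spec.noise_sd
    names = [f"f{i:03d}" for i in range(spec.n_features)]
    if spec.label_type == "binary":
        y_num = rng.integers(0, 2, spec.n_samples)
        for p in spec.planted:
            X[:, p] += spec.effect_size * y_num
        label = np.where(y_num == 1, STRONG, WEAK)
    elif spec.label_type == "continuous":
        y = rng.standard_normal(spec.n_samples)
        for p in spec.planted:
            X[:, p] += spec.effect_size * y
        label = y
    else:
        raise InvalidParameterError(f"unknown label type {spec.label_type!r}")
    df = pd.DataFrame(X, columns=names)
    df["label"] = label
    df["group"] = rng.integers(0, spec.n_groups, spec.n_samples)
    return df


# ---------------------------------------------------------------------------
# Inhibitor panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSpec:
    """An inhibitor panel linking potency to the composite descriptor.

    ln IC50 = intercept + slope * ln(Ki'*Ka') + noise. The default
    slope is positive so that the regression of dG_exp on
    log10(1/(Ki'*Ka')) comes out negative, mirroring the qualitative
    trend of the measured panel (more negative dG_exp at larger
    composite descriptor).
    """

    n_inhibitors: int = 5
    log10_ki_range: tuple[float, float] = (-35.0, -25.0)
    log10_ka_range: tuple[float, float] = (-18.0, -2.0)
    slope: float = 0.25
    intercept: float = 6.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError("noise sd must be >= 0")


def gen_inhibitor_panel(spec: PanelSpec) -> pd.DataFrame:
    """Panel with columns name, Ki_prime, Ka_prime, IC50_uM (plus the
    noiseless ln IC50 as ground truth)."""
    rng = np.random.default_rng(spec.seed)
    l_ki = rng.uniform(*spec.log10_ki_range, spec.n_inhibitors)
    l_ka = rng.uniform(*spec.log10_ka_range, spec.n_inhibitors)
    ln_prod = (l_ki + l_ka) * np.log(10.0)
    ln_ic50_true = spec.intercept + spec.slope * ln_prod
    ln_ic50 = ln_ic50_true + rng.normal(0, spec.noise_sd, spec.n_inhibitors)
    return pd.DataFrame(
        {
            "name": [f"inh{i:02d}" for i in range(spec.n_inhibitors)],
            "Ki_prime": 10.0**l_ki,
            "Ka_prime": 10.0**l_ka,
            "IC50_uM": np.exp(ln_ic50),
            "ln_ic50_true": ln_ic50_true,
        }
    )


# ---------------------------------------------------------------------------
# Two-state bead trajectories
# ---------------------------------------------------------------------------


def gen_two_state_trajectory(
    n_frames: int,
    state_sequence: np.ndarray | list[int],
    n_residues: int = 12,
    contact_delta_pairs: tuple[tuple[int, int], ...] = ((1, 8), (3, 10)),
    noise: float = 0.3,
    seed: int = 0,
    displacement: float = 4.0,
    out_path: str | Path | None = None,
) -> tuple[list[Structure], np.ndarray]:
    """Bead-per-residue toy protein with state-dependent contacts.

    State A keeps the designated residue pairs within the 6.5 A contact
    cutoff; in state B those residues are displaced by ``displacement``
    so the pair leaves the cutoff. Gaussian coordinate noise is added
    to every atom. Returns the frames and the per-frame state labels
    (and writes a multi-model PDB plus a JSON truth sidecar when
    ``out_path`` is given).
    """
    state_sequence = np.asarray(state_sequence, dtype=int)
    if len(state_sequence) != n_frames:
        raise InvalidParameterError("state_sequence length must equal n_frames")
    if n_residues < 2:
        raise InvalidParameterError("need >= 2 residues")
    for i, j in contact_delta_pairs:
        if not (0 <= i < n_residues and 0 <= j < n_residues):
            raise InvalidParameterError("contact pair residue out of range")
    if displacement <= 3 * noise:
        import warnings

        warnings.warn(
            "displacement is within the noise floor; state labels may be "
            "unrecoverable",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # base fold: a loose helix-ish curve that brings the designated pairs close
    t = np.linspace(0, 3 * np.pi, n_residues)
    base = np.column_stack([4 * np.cos(t), 4 * np.sin(t), 1.5 * t])
    for i, j in contact_delta_pairs:
        # pull pair partners to within ~5 A in state A
        mid = 0.5 * (base[i] + base[j])
        base[i] = mid + np.array([2.5, 0, 0])
        base[j] = mid - np.array([2.5, 0, 0])
    frames = []
    aa = ["ALA", "GLY", "SER", "VAL", "LEU", "THR"]
    res_names = np.array([aa[k % len(aa)] for k in range(n_residues)])
    for f in range(n_frames):
        coords = base.copy()
        if state_sequence[f] == 1:  # state B: break designated contacts
            for i, j in contact_delta_pairs:
                direction = coords[j] - coords[i]
                direction /= np.linalg.norm(direction)
                coords[j] = coords[j] + displacement * direction
        coords = coords + rng.normal(0, noise, coords.shape)
        frames.append(
            Structure(
                names=np.array(["CA"] * n_residues),
                elements=np.array(["C"] * n_residues),
                res_ids=np.arange(1, n_residues + 1),
                res_names=res_names,
                chain_ids=np.array(["A"] * n_residues),
                coords=coords,
                is_ligand=np.zeros(n_residues, dtype=bool),
            )
        )
    if out_path is not None:
        out_path = Path(out_path)
        write_structures_pdb(frames, out_path)
        truth = {
            "state_labels": state_sequence.tolist(),
            "contact_delta_pairs": [list(p) for p in contact_delta_pairs],
            "noise": noise,
            "seed": seed,
        }
        out_path.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))
    return frames, state_sequence


# ---------------------------------------------------------------------------
# Prescribed free-energy surfaces
# ---------------------------------------------------------------------------


def gen_fes(
    minima: list[tuple[tuple[float, float], float]],
    saddles: list[tuple[tuple[float, float], float]],
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0, 10), (0, 10)),
    shape: tuple[int, int] = (81, 81),
    width: float | None = None,
    temperature: float = 310.0,
) -> FESGrid:
    """Surface whose minimax barriers equal the prescribed saddles.

    Each saddle defines a smooth valley (trench) running from its
    nearest minimum through the saddle to its second-nearest minimum:
    the valley floor interpolates the three prescribed energies with a
    cosine profile and the surface rises quadratically transverse to
    the valley, capped at a high background. The grid value at a point
    is the lowest trench value there, so the lowest crossing between
    two basins is exactly the smallest prescribed saddle connecting
    them (up to grid discretisation). At least one minimum must sit at
    energy 0 and every saddle must exceed its two flanking minima.
    """
    if len(minima) < 2:
        raise InvalidParameterError("need >= 2 minima")
    energies = [e for _, e in minima]
    if min(energies) != 0 or any(e < 0 for e in energies):
        raise InvalidParameterError("minima energies must be >= 0 with one 0")
    mpts = [np.array(c, dtype=float) for c, _ in minima]
    for k in range(len(mpts)):
        for l in range(k + 1, len(mpts)):
            if np.linalg.norm(mpts[k] - mpts[l]) < 1e-9:
                raise InvalidParameterError("duplicate minimum coordinates")
    routes = []  # (polyline points (m,2), floor energies (m,))
    for sc, se in saddles:
        sc = np.array(sc, dtype=float)
        order = np.argsort([np.linalg.norm(sc - p) for p in mpts])
        a, b = order[0], order[1]
        if se <= max(energies[a], energies[b]):
            raise InvalidParameterError(
                "saddle energy must exceed its two flanking minima"
            )
        for end, e_end in ((a, energies[a]), (b, energies[b])):
            # cosine ramp from the minimum energy up to the saddle energy
            t = np.linspace(0.0, 1.0, 120)[:, None]
            pts = (1 - t) * mpts[end][None, :] + t * sc[None, :]
            floor = e_end + (se - e_end) * 0.5 * (1 - np.cos(np.pi * t[:, 0]))
            routes.append((pts, floor))
    if not routes:  # no saddles: isolated basins in a high background
        for p, e in zip(mpts, energies):
            routes.append((p[None, :], np.array([e])))
    background = max([e for _, e in saddles] + energies) + 15.0
    if width is None:
        width = 0.8
    (xlo, xhi), (ylo, yhi) = bounds
    nrow, ncol = shape
    xs = np.linspace(xlo, xhi, ncol)
    ys = np.linspace(ylo, yhi, nrow)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    F = np.full(len(nodes), background)
    wall = background + 5.0  # transverse rise scale over one width
    for pts, floor in routes:
        d2 = (
            (nodes[:, 0, None] - pts[None, :, 0]) ** 2
            + (nodes[:, 1, None] - pts[None, :, 1]) ** 2
        )
        trench = floor[None, :] + (wall - floor[None, :]) * np.minimum(
            d2 / width**2, 1.0
        )
        F = np.minimum(F, trench.min(axis=1))
    F = np.minimum(F, background).reshape(nrow, ncol)
    F -= F.min()
    return FESGrid(
        values=F,
        origin=(xlo, ylo),
        spacing=(xs[1] - xs[0], ys[1] - ys[0]),
        temperature=temperature,
        metadata=f"synthetic surface with {len(minima)} minima, {len(saddles)} saddles",
    )
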