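"""Analysis of 2-D free-energy surfaces.

A :class:`FESGrid` holds free energies F(cv1, cv2) on a regular grid,
zero-anchored at the global minimum. The module detects basins, labels
the inactive/active states, extracts minimum free energy paths (MFEPs)
with a Dijkstra-type search, and emits 1-D profiles along a path.

Two path-cost functionals are provided because the literature's
"Dijkstra on the landscape" leaves the edge cost open:

* ``minimax`` (default) — minimise the highest free energy visited
  (widest-path Dijkstra); the path's top node is the transition state
  and directly yields the activation barrier, and
* ``boltzmann-sum`` — minimise the accumulated Boltzmann-weighted
  length  sum exp(F/kBT) * step_length.

Grid conventions: row index = CV2, column index = CV1, 0-based;
8-connectivity by default.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import numpy as np

from allokin._errors import (
    AllokinError,
    GridMismatchError,
    InvalidParameterError,
    NoPathError,
)
from allokin.constants import DEFAULT_TEMPERATURE, R_KJ

_NEIGHBORS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_NEIGHBORS_8 = _NEIGHBORS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


class LabelingConflictError(AllokinError):
    """Both state references resolve to the same single minimum."""


@dataclass
class FESGrid:
    """Free energies (kJ/mol) on a regular 2-D collective-variable grid.

    ``values[row, col]`` with row along CV2 and col along CV1;
    ``origin``/``spacing`` give the CV coordinates of cell centers.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    spacing: tuple[float, float] = (1.0, 1.0)
    temperature: float = DEFAULT_TEMPERATURE
    metadata: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("FESGrid values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("FESGrid values must be finite")

    def anchored(self) -> "FESGrid":
        """Copy with the global minimum shifted to exactly 0."""
        return FESGrid(
            self.values - self.values.min(),
            self.origin,
            self.spacing,
            self.temperature,
            self.metadata,
        )

    def coords(self, index: tuple[int, int]) -> tuple[float, float]:
        """(cv1, cv2) coordinates of a (row, col) cell center."""
        r, c = index
        return (
            self.origin[0] + c * self.spacing[0],
            self.origin[1] + r * self.spacing[1],
        )

    def lookup(self, cv1: float, cv2: float) -> float:
        """Free energy at the nearest grid node to (cv1, cv2)."""
        c = int(round((cv1 - self.origin[0]) / self.spacing[0]))
        r = int(round((cv2 - self.origin[1]) / self.spacing[1]))
        r = min(max(r, 0), self.values.shape[0] - 1)
        c = min(max(c, 0), self.values.shape[1] - 1)
        return float(self.values[r, c])

    # -- I/O: CSV matrix plus JSON sidecar ---------------------------------

    def write(self, csv_path: str | FilePath) -> None:
        csv_path = FilePath(csv_path)
        np.savetxt(csv_path, self.values, delimiter=",")
        sidecar = {
            "origin": list(self.origin),
            "spacing": list(self.spacing),
            "temperature": self.temperature,
            "metadata": self.metadata,
            "axes": {"row": "CV2", "col": "CV1"},
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read(cls, csv_path: str | FilePath) -> "FESGrid":
        csv_path = FilePath(csv_path)
        values = np.loadtxt(csv_path, delimiter=",")
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(
            values,
            tuple(meta["origin"]),
            tuple(meta["spacing"]),
            meta.get("temperature", DEFAULT_TEMPERATURE),
            meta.get("metadata", ""),
        )


@dataclass(frozen=True)
class StatePoint:
    """A labeled critical point on the grid."""

    index: tuple[int, int]
    coords: tuple[float, float]
    energy: float
    label: str = "intermediate"  # inactive | active | intermediate | transition


@dataclass
class Path:
    """A grid path between two basins with its barrier bookkeeping."""

    nodes: list[tuple[int, int]]
    energies: list[float]
    barrier_forward: float = field(init=False)
    barrier_reverse: float = field(init=False)
    transition_states: list[int] = field(init=False)
    intermediates: list[int] = field(init=False)

    def __post_init__(self) -> None:
        e = self.energies
        top = max(e)
        self.barrier_forward = top - e[0]
        self.barrier_reverse = top - e[-1]
        self.transition_states = [
            i for i in range(1, len(e) - 1) if e[i] >= e[i - 1] and e[i] >= e[i + 1]
        ]
        self.intermediates = [
            i for i in range(1, len(e) - 1) if e[i] < e[i - 1] and e[i] < e[i + 1]
        ]

    @property
    def top_index(self) -> int:
        """Index (into nodes) of the highest-energy node."""
        return int(np.argmax(self.energies))


# ---------------------------------------------------------------------------
# Basin detection and labeling
# ---------------------------------------------------------------------------


def find_minima(grid: FESGrid, energy_cap: float = np.inf) -> list[StatePoint]:
    """Strict interior local minima (8-neighborhood) with F <= cap.

    Sorted ascending by energy, ties broken by (row, col).
    """
    v = grid.values
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise InvalidParameterError("grid must be at least 3x3")
    out = []
    for r in range(1, v.shape[0] - 1):
        for c in range(1, v.shape[1] - 1):
            e = v[r, c]
            if e > energy_cap:
                continue
            if all(e < v[r + dr, c + dc] for dr, dc in _NEIGHBORS_8):
                out.append(
                    StatePoint(index=(r, c), coords=grid.coords((r, c)), energy=float(e))
                )
    out.sort(key=lambda p: (p.energy, p.index))
    return out


def label_states(
    minima: list[StatePoint],
    reference_coords: dict[str, tuple[float, float]],
) -> list[StatePoint]:
    """Assign ``inactive``/``active`` labels by CV-space proximity.

    The minimum nearest each reference coordinate gets that label
    (nearest-wins; if both references claim the same minimum, the closer
    claim wins and the other reference falls to its next-nearest, with
    ties broken by lower free energy). Remaining minima are labeled
    ``intermediate``.
    """
    if len(minima) < 2:
        if len(minima) == 1 and len(reference_coords) > 1:
            raise LabelingConflictError(
                "only one minimum but two state references; cannot label"
            )
        raise InvalidParameterError("need >= 2 minima to label states")

    def dist(p: StatePoint, ref: tuple[float, float]) -> float:
        return float(np.hypot(p.coords[0] - ref[0], p.coords[1] - ref[1]))

    assignment: dict[int, str] = {}
    # Greedy by increasing distance; ties broken by lower free energy.
    claims = []
    for label, ref in reference_coords.items():
        for i, p in enumerate(minima):
            claims.append((dist(p, ref), p.energy, label, i))
    claims.sort()
    used_labels: set[str] = set()
    for _, _, label, i in claims:
        if label in used_labels or i in assignment:
            continue
        assignment[i] = label
        used_labels.add(label)
    labeled = []
    for i, p in enumerate(minima):
        labeled.append(
            StatePoint(p.index, p.coords, p.energy, assignment.get(i, "intermediate"))
        )
    return labeled


# ---------------------------------------------------------------------------
# Minimum free energy path
# ---------------------------------------------------------------------------


def _neighbors(connectivity: int):
    if connectivity == 4:
        return _NEIGHBORS_4
    if connectivity == 8:
        return _NEIGHBORS_8
    raise InvalidParameterError("connectivity must be 4 or 8")


def mfep(
    grid: FESGrid,
    source: StatePoint | tuple[int, int],
    target: StatePoint | tuple[int, int],
    mode: str = "minimax",
    connectivity: int = 8,
    mask: np.ndarray | None = None,
    energy_cap: float | None = None,
) -> Path:
    """Minimum free energy path between two grid nodes.

    ``mode="minimax"`` minimises the maximum node energy along the path
    (the natural notion of "lowest crossing"); ``mode="boltzmann-sum"``
    minimises sum exp(F/kBT)*step_length. Deterministic tie-break:
    among equal-cost frontier nodes, lower F first, then (row, col).
    ``mask`` marks nodes as unreachable (True = masked); nodes with
    F >= ``energy_cap`` (when given) are likewise excluded, restricting
    the search to passages below that energy.
    """
    src = source.index if isinstance(source, StatePoint) else tuple(source)
    tgt = target.index if isinstance(target, StatePoint) else tuple(target)
    if src == tgt:
        raise InvalidParameterError("source and target must differ")
    v = grid.values
    if energy_cap is not None:
        capped = v >= energy_cap
        mask = capped if mask is None else (mask | capped)
    nrow, ncol = v.shape
    for idx in (src, tgt):
        if not (0 <= idx[0] < nrow and 0 <= idx[1] < ncol):
            raise InvalidParameterError(f"node {idx} outside grid")
    if mask is not None and (mask[src] or mask[tgt]):
        raise NoPathError("source or target is masked")

    neigh = _neighbors(connectivity)
    kT = R_KJ * grid.temperature

    def edge_cost(cur_cost: float, nr: int, nc: int, dr: int, dc: int) -> float:
        if mode == "minimax":
            return max(cur_cost, v[nr, nc])
        if mode == "boltzmann-sum":
            step = float(np.hypot(dr * grid.spacing[1], dc * grid.spacing[0]))
            return cur_cost + float(np.exp(v[nr, nc] / kT)) * step
        raise InvalidParameterError(f"unknown mode {mode!r}")

    start_cost = v[src] if mode == "minimax" else 0.0
    best = {src: start_cost}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    # heap entries: (cost, F, row, col) -> deterministic tie-break
    heap = [(start_cost, float(v[src]), src[0], src[1])]
    done: set[tuple[int, int]] = set()
    while heap:
        cost, _, r, c = heapq.heappop(heap)
        if (r, c) in done:
            continue
        done.add((r, c))
        if (r, c) == tgt:
            break
        for dr, dc in neigh:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrow and 0 <= nc < ncol):
                continue
            if mask is not None and mask[nr, nc]:
                continue
            ncost = edge_cost(cost, nr, nc, dr, dc)
            if ncost < best.get((nr, nc), np.inf):
                best[(nr, nc)] = ncost
                prev[(nr, nc)] = (r, c)
                heapq.heappush(heap, (ncost, float(v[nr, nc]), nr, nc))
    if tgt not in done:
        raise NoPathError(f"target {tgt} unreachable from {src}")
    nodes = [tgt]
    while nodes[-1] != src:
        nodes.append(prev[nodes[-1]])
    nodes.reverse()
    return Path(nodes=nodes, energies=[float(v[n]) for n in nodes])


def second_path(
    grid: FESGrid,
    first: Path,
    source: StatePoint | tuple[int, int],
    target: StatePoint | tuple[int, int],
    exclusion_radius: int = 2,
    mode: str = "minimax",
    connectivity: int = 8,
    energy_cap: float | None = None,
) -> Path:
    """Alternative pathway found by masking the first transition state.

    Nodes within ``exclusion_radius`` cells (Chebyshev) of the first
    path's highest-energy node become unreachable and the search is
    re-run. Raises :class:`NoPathError` if the mask disconnects the
    endpoints.
    """
    if exclusion_radius < 1:
        raise InvalidParameterError("exclusion_radius must be >= 1")
    ts = first.nodes[first.top_index]
    mask = np.zeros_like(grid.values, dtype=bool)
    r0, c0 = ts
    nrow, ncol = grid.values.shape
    rlo, rhi = max(0, r0 - exclusion_radius), min(nrow, r0 + exclusion_radius + 1)
    clo, chi = max(0, c0 - exclusion_radius), min(ncol, c0 + exclusion_radius + 1)
    mask[rlo:rhi, clo:chi] = True
    src = source.index if isinstance(source, StatePoint) else tuple(source)
    tgt = target.index if isinstance(target, StatePoint) else tuple(target)
    mask[src] = mask[tgt] = False
    try:
        return mfep(grid, src, tgt, mode=mode, connectivity=connectivity,
                    mask=mask, energy_cap=energy_cap)
    except NoPathError as exc:
        raise NoPathError(
            f"no second path: masking the transition state {ts} disconnects "
            f"{src} from {tgt}"
        ) from exc


def profile_1d(path: Path, grid: FESGrid) -> np.ndarray:
    """1-D free-energy profile: (arc_length, F) per node, shape (n, 2)."""
    arcs = [0.0]
    for a, b in zip(path.nodes[:-1], path.nodes[1:]):
        dr, dc = b[0] - a[0], b[1] - a[1]
        arcs.append(
            arcs[-1]
            + float(np.hypot(dr * grid.spacing[1], dc * grid.spacing[0]))
        )
    return np.column_stack([arcs, path.energies])


# ---------------------------------------------------------------------------
# Independent oracles (used by tests and the acceptance script)
# ---------------------------------------------------------------------------


def brute_force_minimax_barrier(
    grid: FESGrid,
    source: tuple[int, int],
    target: tuple[int, int],
    connectivity: int = 8,
) -> float:
    """Exact minimax path cost by exhaustive simple-path search.

    Depth-first enumeration of simple paths with two optimum-preserving
    prunes: a branch is abandoned when its running maximum already
    meets or exceeds the incumbent, or when a breadth-first feasibility
    check shows no remaining unvisited route to the target stays below
    the incumbent. Neither prune can discard a strictly improving
    path, so the result equals the full enumeration. Only for small
    grids.
    """
    v = grid.values
    nrow, ncol = v.shape
    neigh = _neighbors(connectivity)
    best = [np.inf]
    visited = np.zeros((nrow, ncol), dtype=bool)

    def reachable_below(r: int, c: int, bound: float) -> bool:
        # BFS through unvisited nodes with energy < bound; the target
        # itself must also lie below the bound, since its energy counts
        # toward the path maximum
        seen = {(r, c)}
        stack = [(r, c)]
        while stack:
            cr, cc = stack.pop()
            if (cr, cc) == target:
                return True
            for dr, dc in neigh:
                nr, nc = cr + dr, cc + dc
                if (
                    0 <= nr < nrow
                    and 0 <= nc < ncol
                    and not visited[nr, nc]
                    and (nr, nc) not in seen
                    and v[nr, nc] < bound
                ):
                    seen.add((nr, nc))
                    stack.append((nr, nc))
        return False

    def dfs(r: int, c: int, cur_max: float) -> None:
        if cur_max >= best[0]:
            return
        if (r, c) == target:
            best[0] = cur_max
            return
        if not reachable_below(r, c, best[0]):
            return
        visited[r, c] = True
        # lower-energy neighbors first: tightens the incumbent early
        options = []
        for dr, dc in neigh:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrow and 0 <= nc < ncol and not visited[nr, nc]:
                options.append((v[nr, nc], nr, nc))
        options.sort()
        for val, nr, nc in options:
            dfs(nr, nc, max(cur_max, val))
        visited[r, c] = False

    dfs(source[0], source[1], float(v[source]))
    if not np.isfinite(best[0]):
        raise NoPathError("target unreachable")
    return float(best[0])


def threshold_minimax_barrier(
    grid: FESGrid,
    source: tuple[int, int],
    target: tuple[int, int],
    connectivity: int = 8,
) -> float:
    """Minimax cost via the percolation threshold: the smallest level T
    such that source and target are connected within {F <= T}.

    Independent of the Dijkstra route; used as a cross-check oracle.
    """
    v = grid.values
    levels = np.unique(v[v >= max(v[source], v[target])])
    levels = np.concatenate(([max(v[source], v[target])], levels))
    neigh = _neighbors(connectivity)
    for T in np.unique(levels):
        # BFS within the sublevel set
        ok = v <= T
        if not (ok[source] and ok[target]):
            continue
        stack = [source]
        seen = {source}
        while stack:
            r, c = stack.pop()
            if (r, c) == target:
                return float(T)
            for dr, dc in neigh:
                nr, nc = r + dr, c + dc
                if (
                    0 <= nr < v.shape[0]
                    and 0 <= nc < v.shape[1]
                    and ok[nr, nc]
                    and (nr, nc) not in seen
                ):
                    seen.add((nr, nc))
                    stack.append((nr, nc))
    raise NoPathError("target unreachable")


# ---------------------------------------------------------------------------
# Convergence checking across FES checkpoints
# ---------------------------------------------------------------------------


def convergence_check(
    checkpoints: list[FESGrid],
    energy_cap: float = 30.0,
    tolerance: float = 2.0,
) -> tuple[list[float], bool]:
    """Max |dF| between consecutive re-anchored checkpoints.

    Deviations are measured over the union low-energy region
    (F < ``energy_cap`` in either grid of a pair). Returns the per-pair
    deviations and a converged flag (last deviation <= ``tolerance``).
    """
    if len(checkpoints) < 2:
        raise InvalidParameterError("need >= 2 checkpoints")
    shape = checkpoints[0].values.shape
    spacing = checkpoints[0].spacing
    for g in checkpoints[1:]:
        if g.values.shape != shape or g.spacing != spacing:
            raise GridMismatchError("checkpoints must share grid geometry")
    anchored = [g.values - g.values.min() for g in checkpoints]
    devs = []
    for a, b in zip(anchored[:-1], anchored[1:]):
        region = (a < energy_cap) | (b < energy_cap)
        devs.append(float(np.abs(a - b)[region].max()) if region.any() else 0.0)
    return devs, devs[-1] <= tolerance
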