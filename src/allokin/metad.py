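"""Toy well-tempered metadynamics in a 2-D collective-variable space.

The physical system behind the study — an all-atom protein switching
between an autoinhibited and an active conformation — is replaced here
by overdamped Langevin (Brownian) dynamics of a point in the plane of
the two collective variables (CVs), moving on an analytic model
potential. This preserves exactly the mathematics under test: Gaussian
hill deposition, well-tempered height scaling

    w_k = w0 * exp(-V_bias(s_k) / ((gamma - 1) * kB * T)),

bias accumulation, and the free-energy estimate

    F(s) = -(gamma / (gamma - 1)) * V_bias(s),   min F = 0.

Defaults mirror the reference setup: T = 310 K, CV domain 0–10 with
reflecting boundaries, hill width 0.30 CV-units, initial hill height
1.20 kJ/mol; the bias factor (not stated in the source) defaults to 10
and the deposition pace is expressed in sampler steps (default 500).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from allokin._errors import AllokinError, InvalidParameterError, ParseError
from allokin.constants import DEFAULT_TEMPERATURE, R_KJ
from allokin.fes import FESGrid, convergence_check  # noqa: F401  (re-export)


class UnstableStepError(AllokinError):
    """A single integrator move exceeded the domain size."""


class EmptyBiasError(AllokinError):
    """A free-energy reconstruction was requested from zero hills."""


# ---------------------------------------------------------------------------
# Model potentials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianTerm:
    """One 2-D Gaussian well (amplitude < 0) or bump (amplitude > 0)."""

    center: tuple[float, float]
    sigma: tuple[float, float]
    amplitude: float  # kJ/mol


@dataclass
class ModelPotential:
    """Analytic 2-D potential: Gaussian terms + optional harmonic + offset.

    ``harmonic_k`` confines each CV about ``harmonic_center`` (a zero
    spring constant disables confinement along that axis). Critical
    points located at construction time are stored in ``minima`` and
    ``saddles`` as ``(coords, energy)`` pairs for use as test oracles.
    """

    terms: list[GaussianTerm]
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 10.0), (0.0, 10.0))
    harmonic_k: tuple[float, float] = (0.0, 0.0)
    harmonic_center: tuple[float, float] = (5.0, 5.0)
    offset: float = 0.0
    minima: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    saddles: list[tuple[tuple[float, float], float]] = field(default_factory=list)

    def energy(self, x: float, y: float) -> float:
        e = self.offset
        for t in self.terms:
            dx = (x - t.center[0]) / t.sigma[0]
            dy = (y - t.center[1]) / t.sigma[1]
            e += t.amplitude * math.exp(-0.5 * (dx * dx + dy * dy))
        e += 0.5 * self.harmonic_k[0] * (x - self.harmonic_center[0]) ** 2
        e += 0.5 * self.harmonic_k[1] * (y - self.harmonic_center[1]) ** 2
        return e

    def gradient(self, x: float, y: float) -> tuple[float, float]:
        gx = self.harmonic_k[0] * (x - self.harmonic_center[0])
        gy = self.harmonic_k[1] * (y - self.harmonic_center[1])
        for t in self.terms:
            dx = (x - t.center[0]) / t.sigma[0]
            dy = (y - t.center[1]) / t.sigma[1]
            g = t.amplitude * math.exp(-0.5 * (dx * dx + dy * dy))
            gx += -g * dx / t.sigma[0]
            gy += -g * dy / t.sigma[1]
        return gx, gy

    def energy_grid(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Vectorised energy on coordinate arrays (same shape)."""
        e = np.full_like(X, self.offset, dtype=float)
        for t in self.terms:
            dx = (X - t.center[0]) / t.sigma[0]
            dy = (Y - t.center[1]) / t.sigma[1]
            e += t.amplitude * np.exp(-0.5 * (dx * dx + dy * dy))
        e += 0.5 * self.harmonic_k[0] * (X - self.harmonic_center[0]) ** 2
        e += 0.5 * self.harmonic_k[1] * (Y - self.harmonic_center[1]) ** 2
        return e


def make_double_well(
    separation: float = 4.0,
    barrier: float = 20.0,
    asymmetry: float = 0.0,
    bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 10.0),
        (0.0, 10.0),
    ),
    confinement_k: float = 10.0,
) -> ModelPotential:
    """Two-basin model potential with prescribed energetics.

    Two Gaussian wells sit on the CV1 axis, ``separation`` apart and
    centered in the domain, with harmonic confinement along CV2. The
    well depths and a constant offset are solved numerically so that
    the *actual* critical-point energies are exactly: deeper minimum 0,
    shallower minimum ``asymmetry``, saddle ``barrier`` (measured from
    the deeper minimum). The located minima/saddle are stored on the
    returned potential for use as oracles.
    """
    if separation <= 0 or barrier <= 0:
        raise InvalidParameterError("separation and barrier must be positive")
    if asymmetry < 0 or asymmetry >= barrier:
        raise InvalidParameterError("need 0 <= asymmetry < barrier")
    (xlo, xhi), (ylo, yhi) = bounds
    xc, yc = 0.5 * (xlo + xhi), 0.5 * (ylo + yhi)
    x1, x2 = xc - separation / 2.0, xc + separation / 2.0
    sigma = separation / 6.0  # wells overlap weakly at the saddle

    def u_line(x: float, p: np.ndarray) -> float:
        d1, d2, off = p
        g1 = math.exp(-0.5 * ((x - x1) / sigma) ** 2)
        g2 = math.exp(-0.5 * ((x - x2) / sigma) ** 2)
        return off - d1 * g1 - d2 * g2

    def du_line(x: float, p: np.ndarray) -> float:
        d1, d2, off = p
        g1 = math.exp(-0.5 * ((x - x1) / sigma) ** 2)
        g2 = math.exp(-0.5 * ((x - x2) / sigma) ** 2)
        return d1 * g1 * (x - x1) / sigma**2 + d2 * g2 * (x - x2) / sigma**2

    def critical_points(p: np.ndarray) -> tuple[float, float, float] | None:
        # locate all sign changes of du on a fine scan; a proper double
        # well has exactly three (min, saddle, min)
        xs = np.linspace(x1 - 2 * sigma, x2 + 2 * sigma, 600)
        du = np.array([du_line(x, p) for x in xs])
        sign_flips = np.flatnonzero(np.sign(du[:-1]) * np.sign(du[1:]) < 0)
        if len(sign_flips) != 3:
            return None
        roots = [
            optimize.brentq(du_line, xs[i], xs[i + 1], args=(p,))
            for i in sign_flips
        ]
        return roots[0], roots[1], roots[2]

    def residuals(p: np.ndarray) -> list[float]:
        cp = critical_points(p)
        if cp is None:  # degenerate trial: steer the solver back
            return [1e3, 1e3, 1e3]
        m1, s, m2 = cp
        return [
            u_line(m1, p) - 0.0,
            u_line(m2, p) - asymmetry,
            u_line(s, p) - barrier,
        ]

    p0 = np.array([barrier * 1.2, barrier * 1.2 - asymmetry, barrier * 0.95])
    sol = optimize.root(residuals, p0, method="hybr", tol=1e-13)
    # hybr's progress heuristic can report failure even when the residuals
    # are at machine precision, so gate on the residuals themselves
    if max(abs(r) for r in residuals(sol.x)) > 1e-9:
        raise RuntimeError("double-well construction failed to converge")
    d1, d2, off = sol.x
    cp = critical_points(sol.x)
    assert cp is not None
    m1, s, m2 = cp
    pot = ModelPotential(
        terms=[
            GaussianTerm((x1, yc), (sigma, sigma), -float(d1)),
            GaussianTerm((x2, yc), (sigma, sigma), -float(d2)),
        ],
        bounds=bounds,
        harmonic_k=(0.0, confinement_k),
        harmonic_center=(xc, yc),
        offset=float(off),
    )
    pot.minima = [((m1, yc), pot.energy(m1, yc)), ((m2, yc), pot.energy(m2, yc))]
    pot.saddles = [((s, yc), pot.energy(s, yc))]
    return pot


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerConfig:
    """Overdamped-Langevin sampler settings.

    ``step_size`` is the RMS thermal displacement per step per CV at the
    configured temperature; the drift mobility follows from the Einstein
    relation (mobility*dt = step_size^2 / (2*kB*T)), so at T = 0 the
    walker is frozen. Boundaries are reflecting.
    """

    temperature: float = DEFAULT_TEMPERATURE
    step_size: float = 0.05
    n_steps: int = 1000
    seed: int = 0
    start: tuple[float, float] | None = None
    sample_stride: int = 1

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise InvalidParameterError("temperature must be >= 0 K")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.step_size <= 0:
            raise InvalidParameterError("step_size must be positive")


@dataclass
class CVTrajectory:
    """Sampled CV positions, their step indices, and instantaneous bias."""

    frames: np.ndarray  # (n, 2)
    step_indices: np.ndarray  # (n,)
    bias_energies: np.ndarray  # (n,)


def _reflect(x: float, lo: float, hi: float) -> float:
    # Repeated fold into [lo, hi]; converges because moves << domain.
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
    return x


# ---------------------------------------------------------------------------
# Hills and bias state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianHill:
    """One deposited bias hill."""

    time_index: int
    center: tuple[float, float]
    sigma: tuple[float, float]
    height: float  # kJ/mol, after well-tempered scaling
    bias_factor: float

    def __post_init__(self) -> None:
        if self.sigma[0] <= 0 or self.sigma[1] <= 0:
            raise InvalidParameterError("hill sigma must be positive")
        if self.height <= 0:
            raise InvalidParameterError("hill height must be positive")


@dataclass
class BiasState:
    """Ordered hill list defining the accumulated bias potential."""

    hills: list[GaussianHill] = field(default_factory=list)
    deposition_interval: int = 500
    bias_factor: float = 10.0

    def bias_potential(self, x: float, y: float) -> float:
        if not self.hills:
            return 0.0
        c = np.array([h.center for h in self.hills])
        s = np.array([h.sigma for h in self.hills])
        w = np.array([h.height for h in self.hills])
        dx = (x - c[:, 0]) / s[:, 0]
        dy = (y - c[:, 1]) / s[:, 1]
        return float(np.sum(w * np.exp(-0.5 * (dx * dx + dy * dy))))

    def bias_grid(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Vectorised V_bias over coordinate arrays (chunked over hills)."""
        V = np.zeros_like(X, dtype=float)
        for h in self.hills:
            dx = (X - h.center[0]) / h.sigma[0]
            dy = (Y - h.center[1]) / h.sigma[1]
            V += h.height * np.exp(-0.5 * (dx * dx + dy * dy))
        return V


@dataclass(frozen=True)
class HillParams:
    """Deposition settings for well-tempered metadynamics."""

    sigma: tuple[float, float] = (0.30, 0.30)
    initial_height: float = 1.20
    deposition_interval: int = 500
    bias_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise InvalidParameterError("bias_factor must be > 1")
        if self.initial_height <= 0 or min(self.sigma) <= 0:
            raise InvalidParameterError("hill height and sigma must be positive")
        if self.deposition_interval < 1:
            raise InvalidParameterError("deposition interval must be >= 1")


# ---------------------------------------------------------------------------
# Internal cached bias (grid-accumulated, bilinear interpolation)
# ---------------------------------------------------------------------------


class _BiasCache:
    """Bias energy/force on a fine grid, updated per deposited hill.

    Keeps the per-step force evaluation O(1) regardless of hill count;
    grid spacing of sigma/3 keeps interpolation error far below kB*T.
    """

    def __init__(self, bounds, spacing: float):
        (xlo, xhi), (ylo, yhi) = bounds
        self.xlo, self.ylo = xlo, ylo
        self.h = spacing
        nx = int(math.ceil((xhi - xlo) / spacing)) + 1
        ny = int(math.ceil((yhi - ylo) / spacing)) + 1
        self.xs = xlo + spacing * np.arange(nx)
        self.ys = ylo + spacing * np.arange(ny)
        self.X, self.Y = np.meshgrid(self.xs, self.ys)
        self.V = np.zeros((ny, nx))
        self.Gx = np.zeros((ny, nx))
        self.Gy = np.zeros((ny, nx))

    def add_hill(self, h: GaussianHill) -> None:
        dx = (self.X - h.center[0]) / h.sigma[0]
        dy = (self.Y - h.center[1]) / h.sigma[1]
        g = h.height * np.exp(-0.5 * (dx * dx + dy * dy))
        self.V += g
        self.Gx += -g * dx / h.sigma[0]
        self.Gy += -g * dy / h.sigma[1]

    def _bilinear(self, A: np.ndarray, x: float, y: float) -> float:
        fx = (x - self.xlo) / self.h
        fy = (y - self.ylo) / self.h
        i = min(int(fx), A.shape[1] - 2)
        j = min(int(fy), A.shape[0] - 2)
        tx, ty = fx - i, fy - j
        return float(
            A[j, i] * (1 - tx) * (1 - ty)
            + A[j, i + 1] * tx * (1 - ty)
            + A[j + 1, i] * (1 - tx) * ty
            + A[j + 1, i + 1] * tx * ty
        )

    def energy(self, x: float, y: float) -> float:
        return self._bilinear(self.V, x, y)

    def force(self, x: float, y: float) -> tuple[float, float]:
        return self._bilinear(self.Gx, x, y), self._bilinear(self.Gy, x, y)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_langevin(
    potential: ModelPotential,
    config: SamplerConfig,
    bias: BiasState | None = None,
) -> CVTrajectory:
    """Unbiased or statically-biased Brownian dynamics on the potential.

    Deterministic for a fixed seed; positions reflect at the bounds.
    """
    cache = None
    if bias is not None and bias.hills:
        sig = min(min(h.sigma) for h in bias.hills)
        cache = _BiasCache(potential.bounds, spacing=sig / 3.0)
        for h in bias.hills:
            cache.add_hill(h)
    traj, _ = _propagate(potential, config, cache, hill_params=None)
    return traj


def run_metadynamics(
    potential: ModelPotential,
    config: SamplerConfig,
    hill_params: HillParams = HillParams(),
) -> tuple[CVTrajectory, BiasState]:
    """Well-tempered metadynamics run; returns trajectory and hills.

    Hills are deposited every ``deposition_interval`` steps at the
    current CV position with height w0*exp(-V_bias/((gamma-1)*kB*T)).
    """
    if config.temperature <= 0:
        raise InvalidParameterError("metadynamics requires temperature > 0")
    cache = _BiasCache(potential.bounds, spacing=min(hill_params.sigma) / 3.0)
    return _propagate(potential, config, cache, hill_params)


def _propagate(
    potential: ModelPotential,
    config: SamplerConfig,
    cache: _BiasCache | None,
    hill_params: HillParams | None,
) -> tuple[CVTrajectory, BiasState]:
    (xlo, xhi), (ylo, yhi) = potential.bounds
    domain = max(xhi - xlo, yhi - ylo)
    if config.start is not None:
        x, y = config.start
    elif potential.minima:
        (x, y), _ = min(potential.minima, key=lambda m: m[1])
    else:
        x, y = 0.5 * (xlo + xhi), 0.5 * (ylo + yhi)

    kT = R_KJ * config.temperature
    noise_amp = config.step_size if config.temperature > 0 else 0.0
    # Einstein relation: mobility*dt such that <dx^2> = step_size^2.
    mob_dt = config.step_size**2 / (2.0 * kT) if config.temperature > 0 else 0.0
    rng = np.random.default_rng(config.seed)

    interval = hill_params.deposition_interval if hill_params else 0
    gamma = hill_params.bias_factor if hill_params else 1.0
    bias = BiasState(
        hills=[],
        deposition_interval=interval or 500,
        bias_factor=gamma if hill_params else 10.0,
    )

    n = config.n_steps
    stride = config.sample_stride
    n_out = n // stride
    frames = np.empty((n_out, 2))
    steps_out = np.empty(n_out, dtype=int)
    bias_e = np.empty(n_out)
    k = 0
    # Pre-draw noise in manageable blocks for speed and determinism.
    block = 8192
    noise = rng.standard_normal((block, 2))
    bi = 0
    for step in range(1, n + 1):
        gx, gy = potential.gradient(x, y)
        if cache is not None:
            bgx, bgy = cache.force(x, y)
            gx += bgx
            gy += bgy
        if bi == block:
            noise = rng.standard_normal((block, 2))
            bi = 0
        nx_, ny_ = noise[bi]
        bi += 1
        dx = -mob_dt * gx + noise_amp * nx_
        dy = -mob_dt * gy + noise_amp * ny_
        if abs(dx) > domain or abs(dy) > domain:
            raise UnstableStepError(
                f"step {step}: move ({dx:.3g},{dy:.3g}) exceeds domain size"
            )
        x = _reflect(x + dx, xlo, xhi)
        y = _reflect(y + dy, ylo, yhi)
        if hill_params and step % interval == 0:
            vb = cache.energy(x, y)
            height = hill_params.initial_height * math.exp(
                -vb / ((gamma - 1.0) * kT)
            )
            hill = GaussianHill(
                time_index=step,
                center=(x, y),
                sigma=hill_params.sigma,
                height=height,
                bias_factor=gamma,
            )
            bias.hills.append(hill)
            cache.add_hill(hill)
        if step % stride == 0:
            frames[k] = (x, y)
            steps_out[k] = step
            bias_e[k] = cache.energy(x, y) if cache is not None else 0.0
            k += 1
    traj = CVTrajectory(frames=frames, step_indices=steps_out, bias_energies=bias_e)
    return traj, bias


# ---------------------------------------------------------------------------
# FES reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Target grid for FES reconstruction."""

    bounds: tuple[tuple[float, float], tuple[float, float]]
    shape: tuple[int, int]  # (n_rows along CV2, n_cols along CV1)

    def mesh(self) -> tuple[np.ndarray, np.ndarray, tuple[float, float], tuple[float, float]]:
        (xlo, xhi), (ylo, yhi) = self.bounds
        nrow, ncol = self.shape
        xs = np.linspace(xlo, xhi, ncol)
        ys = np.linspace(ylo, yhi, nrow)
        X, Y = np.meshgrid(xs, ys)
        spacing = (xs[1] - xs[0], ys[1] - ys[0])
        return X, Y, (xlo, ylo), spacing


def reconstruct_fes(
    bias: BiasState,
    grid_spec: GridSpec,
    temperature: float = DEFAULT_TEMPERATURE,
) -> FESGrid:
    """Well-tempered free-energy estimate from accumulated hills.

    F(s) = -(gamma/(gamma-1)) * V_bias(s), shifted so min F = 0.
    """
    if not bias.hills:
        raise EmptyBiasError("cannot reconstruct a FES from an empty bias")
    X, Y, origin, spacing = grid_spec.mesh()
    V = bias.bias_grid(X, Y)
    gamma = bias.bias_factor
    F = -(gamma / (gamma - 1.0)) * V
    F -= F.min()
    return FESGrid(
        values=F,
        origin=origin,
        spacing=spacing,
        temperature=temperature,
        metadata=f"well-tempered reconstruction from {len(bias.hills)} hills",
    )


# ---------------------------------------------------------------------------
# HILLS-style text I/O
# ---------------------------------------------------------------------------

_HILLS_HEADER = "# time center1 center2 sigma1 sigma2 height bias_factor"


def write_hills(bias: BiasState, path) -> None:
    """Write hills as whitespace text, one hill per line."""
    lines = [_HILLS_HEADER]
    for h in bias.hills:
        lines.append(
            f"{h.time_index} {h.center[0]:.17g} {h.center[1]:.17g} "
            f"{h.sigma[0]:.17g} {h.sigma[1]:.17g} {h.height:.17g} "
            f"{h.bias_factor:.17g}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_hills(path) -> BiasState:
    """Parse a HILLS-style file; '#' lines are comments.

    Malformed lines raise :class:`ParseError` naming the line number;
    a file with only comments yields an empty bias with a warning.
    """
    hills = []
    bias_factor = 10.0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                t = int(float(parts[0]))
                vals = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            bias_factor = vals[5]
            hills.append(
                GaussianHill(
                    time_index=t,
                    center=(vals[0], vals[1]),
                    sigma=(vals[2], vals[3]),
                    height=vals[4],
                    bias_factor=vals[5],
                )
            )
    if not hills:
        warnings.warn(f"{path}: no hills found", RuntimeWarning, stacklevel=2)
    return BiasState(hills=hills, bias_factor=bias_factor)
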