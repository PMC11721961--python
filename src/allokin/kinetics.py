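"""Kinetics of the allosteric conformational switch.

Converts free-energy barriers of the inactive<->active transition into
transition-state-theory (TST) rate constants and equilibrium constants,
links inhibitor potency (IC50) to free energy, forms the composite
potency descriptor 1/(Ki'*Ka'), and implements the allosteric
Michaelis–Menten model in which only the active conformation is
catalytically competent and the inhibitor shifts the conformational
equilibrium.

Conventions
-----------
* Energies in kJ/mol, concentrations in mol/L except IC50 in uM,
  rates in s^-1, temperature in K (default 310).
* The TST rate uses a *unit* prefactor, ``k = 1 s^-1 * exp(-dG/RT)``:
  this is the convention under which the published kinetic table for
  the SHP2 switch is internally consistent (the Eyring prefactor
  k_B*T/h is available via ``prefactor="eyring"`` but does not
  reproduce that table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

from allokin._errors import InsufficientDataError, InvalidParameterError
from allokin.constants import DEFAULT_TEMPERATURE, GAMMA_SASA, R_KJ

# Boltzmann and Planck constants for the optional Eyring prefactor.
_KB = 1.380649e-23  # J/K
_H = 6.62607015e-34  # J s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BarrierSet:
    """Forward/backward activation barriers of the conformational switch.

    ``dG_active_barrier`` is the barrier from the inactive to the active
    state; ``dG_inactive_barrier`` the reverse barrier, both in kJ/mol
    measured from the respective basin minimum.
    """

    dG_active_barrier: float
    dG_inactive_barrier: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.dG_active_barrier < 0 or self.dG_inactive_barrier < 0:
            raise InvalidParameterError("barriers must be >= 0 kJ/mol")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be > 0 K")


@dataclass
class KineticRecord:
    """Derived kinetic quantities for one system (one table row)."""

    system: str
    barriers: BarrierSet
    k_active: float = field(init=False)
    k_inactive: float = field(init=False)
    Ka_prime: float = field(init=False)
    Ki_prime: float | None = None
    dG_exp: float | None = None
    composite: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        T = self.barriers.temperature
        self.k_active = tst_rate(self.barriers.dG_active_barrier, T)
        self.k_inactive = tst_rate(self.barriers.dG_inactive_barrier, T)
        self.Ka_prime = equilibrium_constant(self.k_active, self.k_inactive)
        if self.Ki_prime is not None:
            self.composite = composite_potency(self.Ki_prime, self.Ka_prime)


@dataclass(frozen=True)
class AllostericModelParams:
    """Parameters of the allosteric Michaelis–Menten model.

    ``Ka`` and ``Ka_prime`` are the active/inactive conformational
    equilibrium constants of the free and inhibitor-bound enzyme;
    ``Ki_prime`` (and ``Ki``) are inhibitor dissociation constants.
    """

    Vmax: float
    KM: float
    Ki_prime: float
    Ka: float
    Ka_prime: float
    Ki: float = math.inf  # enters alpha only under the "conventional" variant

    def __post_init__(self) -> None:
        for name in ("Vmax", "KM", "Ki_prime", "Ka", "Ka_prime", "Ki"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class InteractionConstants:
    """Interaction constants alpha and alpha' of mixed inhibition."""

    alpha: float
    alpha_prime: float


@dataclass(frozen=True)
class EnergyDecomposition:
    """End-point (MM/GBSA-style) binding free-energy bookkeeping, kJ/mol."""

    dE_vdw: float
    dE_ele: float
    dG_GB: float
    dG_SA: float
    entropy_term: float = 0.0  # -T*dS contribution, omitted by default

    @property
    def dG_bind(self) -> float:
        return (
            self.dE_vdw + self.dE_ele + self.dG_GB + self.dG_SA - self.entropy_term
        )


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------


def tst_rate(
    dG_barrier: float,
    temperature: float = DEFAULT_TEMPERATURE,
    prefactor: Literal["unit", "eyring"] = "unit",
) -> float:
    """Rate constant (s^-1) from an activation barrier (kJ/mol)."""
    if dG_barrier < 0:
        raise InvalidParameterError("barrier must be >= 0 kJ/mol")
    if temperature <= 0:
        raise InvalidParameterError("temperature must be > 0 K")
    pref = 1.0 if prefactor == "unit" else _KB * temperature / _H
    return pref * math.exp(-dG_barrier / (R_KJ * temperature))


def equilibrium_constant(k_active: float, k_inactive: float) -> float:
    """Dimensionless active/inactive equilibrium constant k_act/k_inact."""
    if k_active <= 0 or k_inactive <= 0:
        raise InvalidParameterError("rates must be positive")
    return k_active / k_inactive


def dg_exp_from_ic50(
    ic50_uM: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Experimental binding free energy (kJ/mol) from IC50 in uM.

    dG_exp = R*T*ln(IC50 / 1 uM); potent (sub-uM) inhibitors map to
    negative values.
    """
    if ic50_uM <= 0:
        raise InvalidParameterError("IC50 must be positive")
    return R_KJ * temperature * math.log(ic50_uM)


def ic50_from_dg_exp(
    dG_exp: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Inverse of :func:`dg_exp_from_ic50`; returns IC50 in uM."""
    return math.exp(dG_exp / (R_KJ * temperature))


def ki_from_binding_energy(
    dG_bind: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Dissociation constant Ki' (mol/L) from a binding free energy."""
    return math.exp(dG_bind / (R_KJ * temperature))


def composite_potency(ki_prime: float, ka_prime: float) -> float:
    """Composite potency descriptor 1/(Ki'*Ka'), L/mol.

    Large values mean tight binding (small Ki') *and* a strongly
    suppressed activation equilibrium (small Ka').
    """
    if ki_prime <= 0 or ka_prime <= 0:
        raise InvalidParameterError("Ki' and Ka' must be positive")
    return 1.0 / (ki_prime * ka_prime)


# ---------------------------------------------------------------------------
# Allosteric Michaelis–Menten model
# ---------------------------------------------------------------------------


def interaction_constants(
    params: AllostericModelParams,
    inhibitor_conc: float,
    variant: Literal["as-published", "conventional"] = "as-published",
) -> InteractionConstants:
    """Interaction constants for inhibitor concentration [I] (mol/L).

    alpha  = 1 + [I]/Ki' + 1/Ka + [I]/(Ki'*Ka')
    alpha' = 1 + [I]/Ki'

    ``variant="conventional"`` adds the textbook mixed-inhibition term
    [I]/Ki to alpha (the published formula omits Ki even though it is
    listed among the model's symbols).
    """
    if inhibitor_conc < 0:
        raise InvalidParameterError("[I] must be >= 0")
    I = inhibitor_conc
    alpha = 1.0 + I / params.Ki_prime + 1.0 / params.Ka + I / (
        params.Ki_prime * params.Ka_prime
    )
    if variant == "conventional" and math.isfinite(params.Ki):
        alpha += I / params.Ki
    alpha_prime = 1.0 + I / params.Ki_prime
    return InteractionConstants(alpha=alpha, alpha_prime=alpha_prime)


def velocity(
    S: float,
    I: float,
    params: AllostericModelParams,
    variant: Literal["as-published", "conventional"] = "as-published",
) -> float:
    """Reaction velocity V = Vmax*[S] / (alpha*KM + alpha'*[S])."""
    if S <= 0:
        raise InvalidParameterError("[S] must be positive")
    c = interaction_constants(params, I, variant)
    return params.Vmax * S / (c.alpha * params.KM + c.alpha_prime * S)


def apparent_parameters(
    params: AllostericModelParams,
    I: float,
    variant: Literal["as-published", "conventional"] = "as-published",
) -> tuple[float, float]:
    """Apparent (KM_app, Vmax_app) at inhibitor concentration [I]:
    KM_app = alpha*KM/alpha', Vmax_app = Vmax/alpha'."""
    c = interaction_constants(params, I, variant)
    return c.alpha * params.KM / c.alpha_prime, params.Vmax / c.alpha_prime


def classify_inhibition(
    alpha: float, alpha_prime: float, tolerance: float = 1e-6
) -> str:
    """Classify the inhibition mode from the interaction constants."""
    if alpha < 1 - tolerance or alpha_prime < 1 - tolerance:
        raise InvalidParameterError("alpha and alpha' must be >= 1")
    if alpha < alpha_prime - tolerance:
        import warnings

        warnings.warn(
            "alpha < alpha' violates the allosteric model (alpha should "
            "exceed alpha'); classification may be meaningless",
            RuntimeWarning,
            stacklevel=2,
        )
    near_one_a = abs(alpha - 1.0) <= tolerance
    near_one_ap = abs(alpha_prime - 1.0) <= tolerance
    if near_one_a and near_one_ap:
        return "no inhibition"
    if near_one_ap:
        return "competitive-like"
    if abs(alpha - alpha_prime) <= tolerance:
        return "pure noncompetitive"
    return "noncompetitive (mixed), prefers free enzyme"


# ---------------------------------------------------------------------------
# Correlation and MM/GBSA bookkeeping
# ---------------------------------------------------------------------------


def potency_correlation(
    records: list[KineticRecord],
) -> tuple[float, float, float, float]:
    """OLS of dG_exp against log10(composite) over the given records.

    Returns ``(slope, intercept, r, r_squared)``. Records lacking either
    quantity are skipped; fewer than 3 usable points raise
    :class:`InsufficientDataError`. A constant response raises too
    (degenerate correlation).
    """
    xs, ys = [], []
    for rec in records:
        if rec.composite is not None and rec.dG_exp is not None:
            xs.append(math.log10(rec.composite))
            ys.append(rec.dG_exp)
    if len(xs) < 3:
        raise InsufficientDataError(
            f"need >= 3 records with dG_exp and composite, got {len(xs)}"
        )
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise InsufficientDataError("degenerate (constant) variable in correlation")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return float(slope), float(intercept), r, r * r


def mmgbsa_total(decomp: EnergyDecomposition) -> float:
    """Total binding free energy from the end-point decomposition."""
    return decomp.dG_bind


def nonpolar_term(delta_sasa: float, gamma: float = GAMMA_SASA) -> float:
    """Nonpolar solvation term gamma * dSASA (kJ/mol; dSASA in A^2)."""
    return gamma * delta_sasa


# ---------------------------------------------------------------------------
# Table-driven pipeline
# ---------------------------------------------------------------------------


def load_table_inputs(path: str | None = None) -> pd.DataFrame:
    """Load a per-system barrier/affinity input table.

    Columns: ``system, dG_active_barrier, dG_inactive_barrier, Ki_prime,
    IC50_uM, dG_exp`` (the last three optional per row). Without a path,
    the packaged fixture with the published switch barriers and
    inhibitor affinities is used.
    """
    if path is None:
        with resources.files("allokin.data").joinpath(
            "table1_inputs.csv"
        ).open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def kinetic_report(
    table: pd.DataFrame, temperature: float = DEFAULT_TEMPERATURE
) -> pd.DataFrame:
    """Recompute all derived kinetic quantities from an input table.

    For each row: TST rates from the barriers, the conformational
    equilibrium constant, dG_exp from IC50 when IC50 is given, and the
    composite descriptor when Ki' is given.
    """
    rows = []
    for _, row in table.iterrows():
        barriers = BarrierSet(
            float(row["dG_active_barrier"]),
            float(row["dG_inactive_barrier"]),
            temperature,
        )
        ki = row.get("Ki_prime")
        ki = None if pd.isna(ki) else float(ki)
        dg_exp = row.get("dG_exp")
        dg_exp = None if pd.isna(dg_exp) else float(dg_exp)
        ic50 = row.get("IC50_uM")
        if not pd.isna(ic50):
            dg_exp = dg_exp_from_ic50(float(ic50), temperature)
        rec = KineticRecord(
            system=str(row["system"]), barriers=barriers, Ki_prime=ki, dG_exp=dg_exp
        )
        rows.append(
            {
                "system": rec.system,
                "dG_active_barrier": barriers.dG_active_barrier,
                "dG_inactive_barrier": barriers.dG_inactive_barrier,
                "k_active": rec.k_active,
                "k_inactive": rec.k_inactive,
                "Ka_prime": rec.Ka_prime,
                "Ki_prime": rec.Ki_prime,
                "dG_exp": rec.dG_exp,
                "composite": rec.composite,
            }
        )
    return pd.DataFrame(rows)
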