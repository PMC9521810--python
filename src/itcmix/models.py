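"""Deterministic forward models for ITC injection heats.

Three binding models are supported:

* ``2C`` — two-component binding: a single ligand species in the syringe.
* ``RM`` — racemic mixture: two competing ligands at a fixed 1:1 ratio.
* ``EM`` — enantiomeric mixture: two competing ligands with the syringe
  mole fraction of ligand 1, ``rho``, as a free parameter (RM is the
  special case ``rho = 0.5``).

Internal units are mol/L for concentrations, cal for heats, kelvin for
temperature and litres for volumes.  Free energies and enthalpies are
accepted in kcal/mol and converted at the boundary.  The dissociation
constant follows the 1 M standard-state convention,
``Kd = exp(dG / (R_GAS * T))``, so a negative binding free energy gives
``Kd < 1`` M.

Ligand 1 is, by convention, the higher-affinity species: the free-energy
gap ``ddG = dG2 - dG1`` is constrained to be non-negative, which resolves
the label-switching degeneracy of the mixture models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R_GAS",
    "DEFAULT_CELL_VOLUME",
    "DEFAULT_TEMPERATURE",
    "TitrationProtocol",
    "CellState",
    "Parameters2C",
    "ParametersRM",
    "ParametersEM",
    "MODEL_PARAMETER_NAMES",
    "n_free_parameters",
    "dilution_factors",
    "cell_concentrations",
    "equilibrium_2c",
    "equilibrium_competitive",
    "heats",
    "ddg_to_fold",
]

#: Gas constant in kcal/(mol K).
R_GAS = 1.9872e-3

#: Sample-cell volume of the MicroCal MCS/VP-ITC instruments, litres.
DEFAULT_CELL_VOLUME = 1.3513e-3

#: Analysis temperature, kelvin.
DEFAULT_TEMPERATURE = 300.0


class InvalidProtocolError(ValueError):
    """Raised when an injection schedule is physically impossible."""


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium solver cannot meet its residual tolerance."""


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule and fixed experimental conditions.

    Parameters
    ----------
    injection_volumes : array-like
        Volume of each injection, litres.
    cell_volume : float
        Active cell volume, litres.
    temperature : float
        Temperature assumed for the analysis, kelvin.
    """

    injection_volumes: np.ndarray
    cell_volume: float = DEFAULT_CELL_VOLUME
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        dv = np.atleast_1d(np.asarray(self.injection_volumes, dtype=float))
        object.__setattr__(self, "injection_volumes", dv)
        if dv.size == 0:
            raise InvalidProtocolError("at least one injection is required")
        if np.any(dv < 0):
            raise InvalidProtocolError("injection volumes must be non-negative")
        if self.cell_volume <= 0:
            raise InvalidProtocolError("cell volume must be positive")
        if self.temperature <= 0:
            raise InvalidProtocolError("temperature must be positive")
        if np.any(dv >= self.cell_volume):
            raise InvalidProtocolError(
                "an injection volume equals or exceeds the cell volume"
            )

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes.size)


@dataclass(frozen=True)
class CellState:
    """Total (bound + free) concentrations in the cell after one injection."""

    total_receptor: float
    total_ligand1: float
    total_ligand2: float


@dataclass(frozen=True)
class Parameters2C:
    """Two-component model parameters: (dG, dH, dH0, R0, Ls, sigma)."""

    dG: float  # binding free energy, kcal/mol
    dH: float  # binding enthalpy, kcal/mol
    dH0: float  # heat of dilution/stirring per injection, cal
    R0: float  # initial cell receptor concentration, mol/L
    Ls: float  # syringe ligand concentration, mol/L
    sigma: float  # measurement noise s.d., cal

    model = "2C"

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.Ls <= 0:
            raise ValueError("concentrations must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ParametersRM:
    """Racemic-mixture parameters: (dG1, ddG, dH1, dH2, dH0, R0, Ls, sigma).

    ``ddG = dG2 - dG1 >= 0`` labels ligand 1 as the tighter binder.
    """

    dG1: float
    ddG: float
    dH1: float
    dH2: float
    dH0: float
    R0: float
    Ls: float
    sigma: float

    model = "RM"
    rho = 0.5  # fixed mixture composition

    def __post_init__(self) -> None:
        if self.ddG < 0:
            raise ValueError("ddG must be non-negative (ligand 1 binds tighter)")
        if self.R0 <= 0 or self.Ls <= 0:
            raise ValueError("concentrations must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ParametersEM:
    """Enantiomeric-mixture parameters: RM plus the free mole fraction rho."""

    dG1: float
    ddG: float
    dH1: float
    dH2: float
    dH0: float
    R0: float
    Ls: float
    rho: float
    sigma: float

    model = "EM"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.ddG < 0:
            raise ValueError("ddG must be non-negative (ligand 1 binds tighter)")
        if self.R0 <= 0 or self.Ls <= 0:
            raise ValueError("concentrations must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


ParameterSet = Parameters2C | ParametersRM | ParametersEM

MODEL_PARAMETER_NAMES = {
    "2C": ("dG", "dH", "dH0", "R0", "Ls", "sigma"),
    "RM": ("dG1", "ddG", "dH1", "dH2", "dH0", "R0", "Ls", "sigma"),
    "EM": ("dG1", "ddG", "dH1", "dH2", "dH0", "R0", "Ls", "rho", "sigma"),
}

_PARAM_CLASSES = {"2C": Parameters2C, "RM": ParametersRM, "EM": ParametersEM}


def n_free_parameters(model: str) -> int:
    """Number of free parameters k of a model (2C: 6, RM: 8, EM: 9)."""
    return len(MODEL_PARAMETER_NAMES[_norm(model)])


def make_parameters(model: str, values: Sequence[float] | dict) -> ParameterSet:
    """Build the parameter dataclass for ``model`` from a vector or mapping."""
    model = _norm(model)
    names = MODEL_PARAMETER_NAMES[model]
    if isinstance(values, dict):
        values = [values[n] for n in names]
    if len(values) != len(names):
        raise ValueError(f"{model} expects {len(names)} parameters {names}")
    return _PARAM_CLASSES[model](**dict(zip(names, values)))


def parameter_vector(theta: ParameterSet) -> np.ndarray:
    """Flatten a parameter dataclass into the model's canonical order."""
    return np.array(
        [getattr(theta, n) for n in MODEL_PARAMETER_NAMES[theta.model]], dtype=float
    )


def _norm(model: str) -> str:
    m = str(model).upper()
    if m not in _PARAM_CLASSES:
        raise ValueError(f"unknown model {model!r}; expected one of 2C, RM, EM")
    return m


def dilution_factors(protocol: TitrationProtocol) -> np.ndarray:
    """Cumulative perfusion dilution multipliers d_n.

    Each injection of volume dV displaces a fraction dV/V0 of the cell
    contents, so material present before injection n is diluted by
    ``d_n = prod_{i<=n} (1 - dV_i / V0)``.
    """
    dv = protocol.injection_volumes
    return np.cumprod(1.0 - dv / protocol.cell_volume)


def cell_concentrations(
    protocol: TitrationProtocol, R0: float, Ls: float, rho: float = 1.0
) -> list[CellState]:
    """Total cell concentrations after each injection under perfusion.

    The receptor only dilutes (``R0 * d_n``); the titrant accumulates to
    ``Ls * (1 - d_n)`` and keeps the syringe composition, so ligand 1 is a
    fraction ``rho`` of the total ligand at every injection.
    """
    if R0 <= 0 or Ls <= 0:
        raise ValueError("concentrations must be positive")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    d = dilution_factors(protocol)
    lig = Ls * (1.0 - d)
    return [
        CellState(R0 * dn, rho * ln, (1.0 - rho) * ln) for dn, ln in zip(d, lig)
    ]


def equilibrium_2c(Rt, Lt, Kd):
    """Complex concentration for single-ligand binding, R + L <-> RL.

    Solves ``RL^2 - (Rt + Lt + Kd) RL + Rt Lt = 0`` for the physically
    admissible root, in the numerically stable form that avoids
    catastrophic cancellation for small complexes.  Accepts scalars or
    arrays broadcast against each other.
    """
    Rt = np.asarray(Rt, dtype=float)
    Lt = np.asarray(Lt, dtype=float)
    if np.any(Rt < 0) or np.any(Lt < 0) or np.any(np.asarray(Kd) <= 0):
        raise ValueError("totals must be non-negative and Kd positive")
    s = Rt + Lt + Kd
    disc = s * s - 4.0 * Rt * Lt
    rl = 2.0 * Rt * Lt / (s + np.sqrt(np.maximum(disc, 0.0)))
    return rl if rl.ndim else float(rl)


def _competitive_free_receptor(Rt, L1t, L2t, Kd1, Kd2):
    """Free-receptor concentration of the two-ligand competition.

    The exact root of the cubic in free receptor R,

        R^3 + a R^2 + b R + c = 0,
        a = Kd1 + Kd2 + L1t + L2t - Rt,
        b = Kd2 (L1t - Rt) + Kd1 (L2t - Rt) + Kd1 Kd2,
        c = -Kd1 Kd2 Rt,

    via the trigonometric solution, then polished by safeguarded Newton on
    the (monotone) total-receptor balance
    ``g(R) = R (1 + L1t/(Kd1+R) + L2t/(Kd2+R)) - Rt``.
    """
    a = Kd1 + Kd2 + L1t + L2t - Rt
    b = Kd2 * (L1t - Rt) + Kd1 * (L2t - Rt) + Kd1 * Kd2
    c = -Kd1 * Kd2 * Rt
    p = a * a - 3.0 * b
    p = np.maximum(p, 0.0)
    sqrt_p = np.sqrt(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_arg = (-2.0 * a**3 + 9.0 * a * b - 27.0 * c) / (2.0 * p * sqrt_p)
    cos_arg = np.where(np.isfinite(cos_arg), cos_arg, 1.0)
    theta = np.arccos(np.clip(cos_arg, -1.0, 1.0))
    R = -a / 3.0 + (2.0 / 3.0) * sqrt_p * np.cos(theta / 3.0)
    R = np.clip(R, 0.0, Rt)

    def g_and_dg(R):
        f1 = L1t / (Kd1 + R)
        f2 = L2t / (Kd2 + R)
        g = R * (1.0 + f1 + f2) - Rt
        dg = 1.0 + L1t * Kd1 / (Kd1 + R) ** 2 + L2t * Kd2 / (Kd2 + R) ** 2
        return g, dg

    for _ in range(6):
        g, dg = g_and_dg(R)
        R = np.clip(R - g / dg, 0.0, Rt)
    return R


def equilibrium_competitive(Rt, L1t, L2t, Kd1, Kd2, rtol: float = 1e-10):
    """Complex concentrations (RL1, RL2) for two ligands competing for R.

    Uses the exact cubic solution for the free receptor concentration with
    Newton polishing, and verifies the three mass balances and both
    mass-action laws to relative tolerance ``rtol``.  Accepts scalars or
    broadcastable arrays.
    """
    Rt = np.asarray(Rt, dtype=float)
    L1t = np.asarray(L1t, dtype=float)
    L2t = np.asarray(L2t, dtype=float)
    if (
        np.any(Rt < 0)
        or np.any(L1t < 0)
        or np.any(L2t < 0)
        or Kd1 <= 0
        or Kd2 <= 0
    ):
        raise ValueError("totals must be non-negative and Kd values positive")
    Rt, L1t, L2t = np.broadcast_arrays(Rt, L1t, L2t)
    scalar = Rt.ndim == 0
    Rt = np.atleast_1d(Rt).astype(float)
    L1t = np.atleast_1d(L1t).astype(float)
    L2t = np.atleast_1d(L2t).astype(float)

    R = _competitive_free_receptor(Rt, L1t, L2t, Kd1, Kd2)
    resid = np.abs(R * (1.0 + L1t / (Kd1 + R) + L2t / (Kd2 + R)) - Rt)
    scale = np.maximum(Rt, 1e-300)
    bad = resid / scale > rtol
    if np.any(bad):
        # fall back to bisection on the monotone receptor balance
        for i in np.flatnonzero(bad):
            rt, l1, l2 = Rt[i], L1t[i], L2t[i]
            if rt == 0.0:
                R[i] = 0.0
                continue
            f = lambda r: r * (1.0 + l1 / (Kd1 + r) + l2 / (Kd2 + r)) - rt
            R[i] = brentq(f, 0.0, rt, xtol=1e-300, rtol=1e-15)
        resid = np.abs(R * (1.0 + L1t / (Kd1 + R) + L2t / (Kd2 + R)) - Rt)
        if np.any(resid / scale > rtol):
            raise EquilibriumError("competitive equilibrium residual above tolerance")

    RL1 = L1t * R / (Kd1 + R)
    RL2 = L2t * R / (Kd2 + R)
    if scalar:
        return float(RL1[0]), float(RL2[0])
    return RL1, RL2


def _complex_trajectories(theta: ParameterSet, protocol: TitrationProtocol):
    """Per-injection complex concentrations ([RL1]_n, [RL2]_n) in the cell."""
    T = protocol.temperature
    d = dilution_factors(protocol)
    lig = (1.0 - d) * theta.Ls
    Rtot = d * theta.R0
    if theta.model == "2C":
        Kd = float(np.exp(theta.dG / (R_GAS * T)))
        rl1 = equilibrium_2c(Rtot, lig, Kd)
        rl2 = np.zeros_like(np.atleast_1d(rl1))
        return np.atleast_1d(rl1), rl2
    rho = theta.rho
    Kd1 = float(np.exp(theta.dG1 / (R_GAS * T)))
    Kd2 = float(np.exp((theta.dG1 + theta.ddG) / (R_GAS * T)))
    rl1, rl2 = equilibrium_competitive(Rtot, rho * lig, (1.0 - rho) * lig, Kd1, Kd2)
    return np.atleast_1d(rl1), np.atleast_1d(rl2)


def heats(theta: ParameterSet, protocol: TitrationProtocol, model: str | None = None):
    """Theoretical integrated injection heats q*_n in cal.

    The heat of injection n differences the post-equilibration complex
    content of the cell against the previous content diluted once by that
    injection (``d'_n = 1 - dV_n / V0``):

        q*_n = V0 * sum_i dH_i * ([RL_i]_n - d'_n [RL_i]_{n-1}) + dH0

    with the enthalpies converted from kcal/mol to cal/mol.  The first
    injection is treated like every other (no discarded half-injection).
    """
    if model is not None and _norm(model) != theta.model:
        raise ValueError(f"parameters are for {theta.model}, not {model}")
    V0 = protocol.cell_volume
    dprime = 1.0 - protocol.injection_volumes / V0
    rl1, rl2 = _complex_trajectories(theta, protocol)
    prev1 = np.concatenate(([0.0], rl1[:-1]))
    prev2 = np.concatenate(([0.0], rl2[:-1]))
    if theta.model == "2C":
        dh1_cal, dh2_cal = theta.dH * 1000.0, 0.0
    else:
        dh1_cal, dh2_cal = theta.dH1 * 1000.0, theta.dH2 * 1000.0
    q = V0 * (
        dh1_cal * (rl1 - dprime * prev1) + dh2_cal * (rl2 - dprime * prev2)
    )
    return q + theta.dH0


def ddg_to_fold(ddG: float, T: float = 298.0) -> float:
    """Affinity fold-ratio implied by a binding free-energy gap.

    ``exp(ddG / (R_GAS T))`` is the ratio Kd2/Kd1 of dissociation
    constants, i.e. how many times weaker the second ligand binds.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(np.exp(ddG / (R_GAS * T)))
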