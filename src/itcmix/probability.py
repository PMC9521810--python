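"""Likelihood, priors and posterior kernels for the three binding models.

The observation model treats each integrated heat as the theoretical heat
plus i.i.d. Gaussian noise of unknown standard deviation ``sigma``.

Priors (all mutually independent):

* binding free energies ``dG``/``dG1`` ~ Uniform(-40, 40) kcal/mol,
  ``ddG`` ~ Uniform(0, 40);
* enthalpies ``dH``/``dH1``/``dH2`` ~ Uniform(-100, 100) kcal/mol;
* ``dH0`` ~ Uniform(q_min - dq, q_max + dq) in cal, with the bounds taken
  from the observed heats (dq = q_max - q_min);
* cell/syringe concentrations: lognormal centred on the stated value with
  a 10% multiplicative width when a stated value exists, otherwise uniform
  over instrument-plausible ranges (0.001-1 mM for the cell, 0.01-10 mM
  for the syringe);
* ``rho`` ~ Uniform(0, 1);
* ``sigma``: Jeffreys, p(sigma) ∝ sigma0 / sigma with sigma0 = 1 cal.

All proper priors carry their normalization constants so that ratios of
posterior normalizers (Bayes factors) across models are meaningful; the
improper Jeffreys factor is identical in every model and cancels.

Samplers and the bridge-sampling machinery operate on an unconstrained
reparameterization (log for sigma and concentrations, logit for rho, log
for ddG) with the Jacobians folded in; densities reported to users are
always in the original parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .models import (
    MODEL_PARAMETER_NAMES,
    ParameterSet,
    TitrationProtocol,
    heats,
    make_parameters,
)

__all__ = [
    "Dataset",
    "PriorSpec",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "ParameterSpace",
    "build_parameter_space",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Uniform fallback ranges for concentrations, mol/L (spec'd in mM).
R0_UNIFORM_BOUNDS = (0.001e-3, 1.0e-3)
LS_UNIFORM_BOUNDS = (0.01e-3, 10.0e-3)


@dataclass(frozen=True)
class Dataset:
    """Observed injection heats plus protocol and stated concentrations.

    ``heats`` are in cal; ``stated_R0``/``stated_Ls`` in mol/L or ``None``
    when the experimenter did not report them.
    """

    heats: np.ndarray
    protocol: TitrationProtocol
    stated_R0: float | None = None
    stated_Ls: float | None = None

    def __post_init__(self) -> None:
        q = np.atleast_1d(np.asarray(self.heats, dtype=float))
        object.__setattr__(self, "heats", q)
        if q.size != self.protocol.n_injections:
            raise ValueError(
                f"{q.size} heats but {self.protocol.n_injections} injections"
            )
        if not np.all(np.isfinite(q)):
            raise ValueError("heats must be finite")

    @property
    def n(self) -> int:
        return int(self.heats.size)

    def dh0_bounds(self) -> tuple[float, float]:
        """Data-driven uniform prior bounds for the per-injection offset."""
        qmin, qmax = float(self.heats.min()), float(self.heats.max())
        dq = qmax - qmin
        return qmin - dq, qmax + dq


@dataclass(frozen=True)
class PriorSpec:
    """Choice of concentration priors and the shared bound constants.

    ``r0_prior``/``ls_prior`` are ``"lognormal"``, ``"uniform"`` or
    ``"auto"`` (lognormal when a stated value exists, else uniform).
    """

    r0_prior: str = "auto"
    ls_prior: str = "auto"
    concentration_cv: float = 0.10  # s.d. of ln(concentration)
    dg_bounds: tuple[float, float] = (-40.0, 40.0)
    ddg_bounds: tuple[float, float] = (0.0, 40.0)
    dh_bounds: tuple[float, float] = (-100.0, 100.0)
    r0_uniform_bounds: tuple[float, float] = R0_UNIFORM_BOUNDS
    ls_uniform_bounds: tuple[float, float] = LS_UNIFORM_BOUNDS

    def resolve(self, which: str, stated: float | None) -> str:
        choice = {"r0": self.r0_prior, "ls": self.ls_prior}[which]
        if choice == "auto":
            return "lognormal" if stated is not None else "uniform"
        if choice == "lognormal" and stated is None:
            raise ValueError(
                f"lognormal {which} prior requested but no stated concentration"
            )
        return choice


def log_likelihood(theta: ParameterSet, data: Dataset, model: str | None = None):
    """Gaussian i.i.d. log-likelihood of the observed heats."""
    q_model = heats(theta, data.protocol, model)
    resid = data.heats - q_model
    n = data.n
    s = theta.sigma
    return float(
        -0.5 * n * _LOG_2PI - n * np.log(s) - 0.5 * np.dot(resid, resid) / (s * s)
    )


def _log_uniform(x: float, lo: float, hi: float) -> float:
    if not lo <= x <= hi:
        return -np.inf
    return -np.log(hi - lo)


def _log_lognormal(x: float, stated: float, sd_log: float) -> float:
    if x <= 0:
        return -np.inf
    z = (np.log(x) - np.log(stated)) / sd_log
    return float(-np.log(x) - np.log(sd_log) - 0.5 * _LOG_2PI - 0.5 * z * z)


def log_prior(
    theta: ParameterSet,
    spec: PriorSpec,
    data: Dataset,
    model: str | None = None,
) -> float:
    """Sum of independent component log-priors (normalized where proper)."""
    if model is not None and str(model).upper() != theta.model:
        raise ValueError(f"parameters are for {theta.model}, not {model}")
    lp = 0.0
    if theta.model == "2C":
        lp += _log_uniform(theta.dG, *spec.dg_bounds)
        lp += _log_uniform(theta.dH, *spec.dh_bounds)
    else:
        lp += _log_uniform(theta.dG1, *spec.dg_bounds)
        lp += _log_uniform(theta.ddG, *spec.ddg_bounds)
        lp += _log_uniform(theta.dH1, *spec.dh_bounds)
        lp += _log_uniform(theta.dH2, *spec.dh_bounds)
    lp += _log_uniform(theta.dH0, *data.dh0_bounds())
    for which, value, stated, ubounds in (
        ("r0", theta.R0, data.stated_R0, spec.r0_uniform_bounds),
        ("ls", theta.Ls, data.stated_Ls, spec.ls_uniform_bounds),
    ):
        kind = spec.resolve(which, stated)
        if kind == "lognormal":
            lp += _log_lognormal(value, stated, spec.concentration_cv)
        else:
            lp += _log_uniform(value, *ubounds)
    if theta.model == "EM":
        lp += _log_uniform(theta.rho, 0.0, 1.0)
    if theta.sigma <= 0:
        return -np.inf
    lp += -np.log(theta.sigma)  # Jeffreys, sigma0 = 1 cal
    return float(lp)


def log_posterior(
    theta: ParameterSet,
    data: Dataset,
    spec: PriorSpec,
    model: str | None = None,
) -> float:
    """Unnormalized log-posterior; -inf outside the prior support."""
    lp = log_prior(theta, spec, data, model)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(theta, data, model)


# ---------------------------------------------------------------------------
# Unconstrained reparameterization for samplers and bridge sampling
# ---------------------------------------------------------------------------

class _Identity:
    def forward(self, v):  # constrained -> unconstrained
        return v

    def inverse(self, x):
        return x

    def log_jac(self, x):  # log |d constrained / d unconstrained|
        return 0.0


class _Log:
    def forward(self, v):
        return np.log(v)

    def inverse(self, x):
        return np.exp(x)

    def log_jac(self, x):
        return x


class _Logit:
    def forward(self, v):
        return np.log(v) - np.log1p(-v)

    def inverse(self, x):
        return 1.0 / (1.0 + np.exp(-x))

    def log_jac(self, x):
        v = self.inverse(x)
        return np.log(v) + np.log1p(-v)


#: Transform assigned to each parameter name (shared across models so that
#: nested-model bridging uses identical coordinates for shared parameters).
_TRANSFORMS: dict[str, object] = {
    "dG": _Identity(),
    "dG1": _Identity(),
    "ddG": _Log(),
    "dH": _Identity(),
    "dH1": _Identity(),
    "dH2": _Identity(),
    "dH0": _Identity(),
    "R0": _Log(),
    "Ls": _Log(),
    "rho": _Logit(),
    "sigma": _Log(),
}


def transform_for(name: str):
    """The bijection used for one named parameter in unconstrained space."""
    return _TRANSFORMS[name]


@dataclass
class ParameterSpace:
    """A model's sampling space: names, bijections and the posterior kernel.

    ``log_density(x)`` is the unnormalized posterior density *of the
    unconstrained vector x*, i.e. including the log-Jacobian of the map
    back to the constrained parameters.
    """

    model: str
    names: tuple[str, ...]
    data: Dataset
    spec: PriorSpec

    @property
    def ndim(self) -> int:
        return len(self.names)

    def to_unconstrained(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return np.array(
            [transform_for(n).forward(v) for n, v in zip(self.names, values.T)]
        ).T

    def to_constrained(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.array(
            [transform_for(n).inverse(xi) for n, xi in zip(self.names, x.T)]
        ).T

    def log_jacobian(self, x: np.ndarray) -> float:
        return float(
            sum(transform_for(n).log_jac(xi) for n, xi in zip(self.names, x))
        )

    def log_density(self, x: np.ndarray) -> float:
        try:
            theta = make_parameters(self.model, self.to_constrained(x))
        except (ValueError, OverflowError):
            return -np.inf
        lp = log_posterior(theta, self.data, self.spec)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_jacobian(x)


def build_parameter_space(model: str, data: Dataset, spec: PriorSpec) -> ParameterSpace:
    """Sampling space of ``model`` for one dataset and prior choice."""
    model = str(model).upper()
    return ParameterSpace(model, MODEL_PARAMETER_NAMES[model], data, spec)
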