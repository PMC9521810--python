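"""Model selection: AIC, BIC and bridge-sampling Bayes factors.

The three binding models are nested (2C ⊂ RM ⊂ EM once the shared
parameters are identified: dG↔dG1, dH↔dH1).  The Bayes factor between a
nested pair is the ratio of posterior normalizing constants.  To equalize
integration dimensions, the smaller model's posterior samples are
augmented with i.i.d. draws of the extra parameters γ from a moment-
matched Gaussian proposal f(γ) fitted to the larger model's samples (in
the unconstrained sampling space, so a Gaussian is admissible for bounded
parameters such as ρ).  The log-ratio of normalizers is then estimated
from the two sample sets with the Bennett acceptance ratio, solved
self-consistently by bracketed root finding, with bootstrap standard
errors from resampling the potential-energy differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import multivariate_normal

from .models import MODEL_PARAMETER_NAMES, ParameterSet, make_parameters
from .probability import (
    Dataset,
    PriorSpec,
    build_parameter_space,
    log_likelihood,
    transform_for,
)
from .sampling import PosteriorSamples, SamplerConfig, sample_posterior

__all__ = [
    "aic",
    "bic",
    "max_likelihood",
    "ProposalDistribution",
    "fit_proposal",
    "bar_solve",
    "BayesFactorResult",
    "bridge_log10_ratio",
    "bayes_factor_nested",
    "ModelComparison",
    "compare_models",
    "nested_parameter_mapping",
]

logger = logging.getLogger(__name__)

LOG10 = float(np.log(10.0))


class EstimatorFailure(RuntimeError):
    """Raised when the BAR root cannot be bracketed (insufficient overlap)."""


def aic(max_loglik: float, k: int) -> float:
    """Akaike information criterion, -2 ln L_max + 2k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return -2.0 * max_loglik + 2.0 * k


def bic(max_loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion, -2 ln L_max + k ln N."""
    if k < 1 or n < 1:
        raise ValueError("require k >= 1 and N >= 1")
    return -2.0 * max_loglik + k * np.log(n)


def _unconstrained_bounds(space, data: Dataset):
    """Box bounds for bounded optimization in unconstrained coordinates."""
    qlo, qhi = data.dh0_bounds()
    spec = space.spec
    out = []
    for name in space.names:
        if name in ("dG", "dG1"):
            out.append(spec.dg_bounds)
        elif name == "ddG":
            out.append((np.log(1e-9), np.log(spec.ddg_bounds[1])))
        elif name in ("dH", "dH1", "dH2"):
            out.append(spec.dh_bounds)
        elif name == "dH0":
            out.append((qlo, qhi))
        elif name == "R0":
            stated = data.stated_R0
            lo, hi = spec.r0_uniform_bounds
            if spec.resolve("r0", stated) == "lognormal":
                lo, hi = stated * np.exp(-8 * spec.concentration_cv), stated * np.exp(
                    8 * spec.concentration_cv
                )
            out.append((np.log(lo), np.log(hi)))
        elif name == "Ls":
            stated = data.stated_Ls
            lo, hi = spec.ls_uniform_bounds
            if spec.resolve("ls", stated) == "lognormal":
                lo, hi = stated * np.exp(-8 * spec.concentration_cv), stated * np.exp(
                    8 * spec.concentration_cv
                )
            out.append((np.log(lo), np.log(hi)))
        elif name == "rho":
            out.append((-12.0, 12.0))
        elif name == "sigma":
            scale = max(float(np.std(data.heats)), 1e-12)
            out.append((np.log(scale) - 14.0, np.log(scale) + 5.0))
    return out


def max_likelihood(
    data: Dataset,
    spec: PriorSpec,
    model: str,
    starts: Sequence[ParameterSet] | PosteriorSamples,
    method: str = "L-BFGS-B",
) -> tuple[ParameterSet, float]:
    """Multi-start bounded maximization of the log-likelihood.

    ``starts`` may be explicit parameter sets or posterior samples, in
    which case the top-10 draws by likelihood plus the MAP draw seed the
    local optimizations (posteriors here can be multimodal, so a single
    start is unsafe).
    """
    space = build_parameter_space(model, data, spec)
    if isinstance(starts, PosteriorSamples):
        ll = np.array(
            [
                log_likelihood(make_parameters(model, row), data)
                for row in starts.values
            ]
        )
        idx = list(np.argsort(ll)[-10:]) + [int(np.argmax(starts.log_post))]
        start_list = [make_parameters(model, starts.values[i]) for i in idx]
    else:
        start_list = list(starts)
    if not start_list:
        raise ValueError("at least one start point is required")

    bounds = _unconstrained_bounds(space, data)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    # optimize in coordinates normalized by the bound widths; the raw
    # unconstrained variables span ~8 orders of magnitude (dH0 vs dG)
    width = hi - lo

    def neg_ll(z):
        x = lo + z * width
        try:
            theta = make_parameters(model, space.to_constrained(x))
        except (ValueError, OverflowError):
            return 1e12
        v = log_likelihood(theta, data)
        return -v if np.isfinite(v) else 1e12

    zbounds = [(0.0, 1.0)] * len(bounds)
    best = None
    for theta0 in start_list:
        x0 = space.to_unconstrained(
            np.array([getattr(theta0, n) for n in space.names])
        )
        z0 = np.clip((x0 - lo) / width, 1e-9, 1 - 1e-9)
        try:
            options = (
                {"ftol": 1e-13, "gtol": 1e-10, "maxfun": 50000}
                if method == "L-BFGS-B"
                else {"maxiter": 20000}
            )
            res = minimize(neg_ll, z0, method=method, bounds=zbounds,
                           options=options)
        except Exception:  # pragma: no cover - optimizer backend failure
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("all optimization starts failed")
    theta_ml = make_parameters(model, space.to_constrained(lo + best.x * width))
    return theta_ml, float(-best.fun)


@dataclass
class ProposalDistribution:
    """Moment-matched Gaussian over the extra parameters γ (unconstrained)."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        self._mvn = multivariate_normal(self.mean, self.cov)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return self._mvn.logpdf(x)

    def rvs(self, size: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        out = self._mvn.rvs(size=size, random_state=rng)
        return out.reshape(size, self.mean.size)

    def inflate(self, factor: float) -> "ProposalDistribution":
        return ProposalDistribution(self.mean, self.cov * factor, self.names)


def fit_proposal(
    samples2: PosteriorSamples, gamma_names: Sequence[str]
) -> ProposalDistribution:
    """Fit f(γ) to the larger model's samples by moment matching.

    Means and (unbiased) covariances are taken in the unconstrained space
    of each γ coordinate.  A singular covariance is jittered with a logged
    warning.
    """
    cols = []
    for name in gamma_names:
        t = transform_for(name)
        cols.append(t.forward(samples2.column(name)))
    X = np.column_stack(cols)
    mean = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        logger.warning("singular proposal covariance; adding jitter")
        cov = cov + 1e-10 * np.eye(cov.shape[0]) * max(np.trace(cov), 1.0)
    return ProposalDistribution(mean, cov, tuple(gamma_names))


def bar_solve(
    forward_deltas: np.ndarray,
    reverse_deltas: np.ndarray,
    tol: float = 1e-10,
) -> float:
    """Bennett-acceptance-ratio estimate of ln(Z2/Z1).

    ``forward_deltas`` are Δu = u2 - u1 evaluated on samples from
    distribution 1 and ``reverse_deltas`` the same quantity on samples
    from distribution 2, where u_i = -ln of the unnormalized density of
    distribution i.  Solves the self-consistent equation

        Σ_1 1/(1 + e^{M + Δu - c}) = Σ_2 1/(1 + e^{-(M + Δu - c)}),

    with the sample-size offset M = ln(n1/n2), by bracketed root finding;
    the root c is the free-energy difference -ln(Z2/Z1), so the returned
    estimate is -c.
    """
    wf = np.asarray(forward_deltas, dtype=float)
    wr = np.asarray(reverse_deltas, dtype=float)
    if wf.size == 0 or wr.size == 0:
        raise ValueError("both sample sets must be nonempty")
    M = np.log(wf.size / wr.size)

    def h(s):
        a = np.logaddexp(0.0, M + wf - s)  # ln(1 + e^x)
        b = np.logaddexp(0.0, -(M + wr - s))
        return np.sum(np.exp(-a)) - np.sum(np.exp(-b))

    # h is strictly increasing in the root variable, so a valid bracket has
    # h(lo) < 0 < h(hi); a flat zero everywhere signals non-overlapping sets
    mid = float(np.median(np.concatenate([wf, wr])))
    lo, hi = mid - 1.0, mid + 1.0
    for _ in range(200):
        if h(lo) < 0.0 < h(hi):
            break
        lo, hi = mid + (lo - mid) * 2.0, mid + (hi - mid) * 2.0
        if hi - lo > 1e8:
            raise EstimatorFailure(
                "no sign change when bracketing the BAR root; the two sample "
                "sets do not overlap — increase samples or proposal overlap"
            )
    else:  # pragma: no cover
        raise EstimatorFailure("failed to bracket the BAR root")
    return -float(brentq(h, lo, hi, xtol=tol))


@dataclass
class BayesFactorResult:
    """log10 Bayes factor with bootstrap SE and a convergence trace."""

    log10_bf: float
    se: float
    n1: int
    n2: int
    trace: pd.DataFrame | None = None
    model_pair: tuple[str, str] = ("", "")


def nested_parameter_mapping(model1: str, model2: str) -> dict[str, str]:
    """Identify the smaller model's parameters inside the larger model.

    Returns ``{name_in_model2: name_in_model1}`` for the shared block; the
    remaining model-2 names are the extra parameters γ.
    """
    model1, model2 = model1.upper(), model2.upper()
    order = {"2C": 0, "RM": 1, "EM": 2}
    if order[model1] >= order[model2]:
        raise ValueError(f"{model1} is not nested in {model2}")
    mapping = {}
    rename = {"dG1": "dG", "dH1": "dH"} if model1 == "2C" else {}
    names1 = set(MODEL_PARAMETER_NAMES[model1])
    for name2 in MODEL_PARAMETER_NAMES[model2]:
        name1 = rename.get(name2, name2)
        if name1 in names1:
            mapping[name2] = name1
    return mapping


def _unconstrained_matrix(samples: PosteriorSamples, names: Sequence[str]):
    cols = [transform_for(n).forward(samples.column(n)) for n in names]
    return np.column_stack(cols)


def bridge_log10_ratio(
    logp1: Callable[[np.ndarray], float],
    logp2: Callable[[np.ndarray], float],
    X1: np.ndarray,
    X2: np.ndarray,
    proposal: ProposalDistribution,
    seed: int = 0,
    n_bootstrap: int = 1000,
    trace_fractions: Sequence[float] = tuple(np.linspace(0.1, 1.0, 10)),
) -> BayesFactorResult:
    """Generic nested bridge-sampling estimate of log10(Z2/Z1).

    ``X1`` holds samples of the smaller distribution (n1 x d1); ``X2``
    samples of the larger one (n2 x (d1 + dg)) with the shared block in
    the *same coordinates and order* as ``X1`` followed by the extra
    coordinates γ.  ``logp1``/``logp2`` are the unnormalized log-densities
    of the two distributions over their own vectors.  The smaller set is
    augmented with i.i.d. γ from ``proposal``, the potentials
    u1 = -ln[p1(θ1) f(γ)] and u2 = -ln p2(θ1, γ) are evaluated on both
    sets, and the ratio of normalizers is estimated with BAR.  The
    bootstrap SE resamples the Δu arrays; the trace re-estimates the
    ratio on leading fractions of both sets.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n1, d1 = X1.shape
    n2 = X2.shape[0]

    # forward set: p1 draws augmented with i.i.d. proposal variates
    G1 = proposal.rvs(n1, seed)
    lp1_theta = np.array([logp1(x) for x in X1])
    lf1 = np.atleast_1d(proposal.logpdf(G1))
    X2_aug = np.column_stack([X1, G1])
    lp2_aug = np.array([logp2(x) for x in X2_aug])
    forward = -(lp2_aug) - (-(lp1_theta + lf1))  # Δu = u2 - u1

    # reverse set: the larger distribution's own draws
    lp1_on2 = np.array([logp1(x) for x in X2[:, :d1]])
    lf_on2 = np.atleast_1d(proposal.logpdf(X2[:, d1:]))
    lp2_on2 = np.array([logp2(x) for x in X2])
    reverse = -(lp2_on2) - (-(lp1_on2 + lf_on2))

    ln_bf = bar_solve(forward, reverse)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        fb = forward[rng.integers(0, n1, size=n1)]
        rb = reverse[rng.integers(0, n2, size=n2)]
        try:
            boots[b] = bar_solve(fb, rb)
        except EstimatorFailure:
            boots[b] = np.nan
    se = float(np.nanstd(boots, ddof=1)) / LOG10

    rows = []
    for frac in trace_fractions:
        m1 = max(2, int(round(frac * n1)))
        m2 = max(2, int(round(frac * n2)))
        try:
            est = bar_solve(forward[:m1], reverse[:m2]) / LOG10
        except EstimatorFailure:
            est = np.nan
        rows.append({"fraction": frac, "log10_bf": est})

    return BayesFactorResult(
        log10_bf=float(ln_bf / LOG10),
        se=se,
        n1=n1,
        n2=n2,
        trace=pd.DataFrame(rows),
    )


def bayes_factor_nested(
    samples1: PosteriorSamples,
    samples2: PosteriorSamples,
    data: Dataset,
    spec: PriorSpec,
    seed: int = 0,
    n_bootstrap: int = 1000,
    trace_fractions: Sequence[float] = tuple(np.linspace(0.1, 1.0, 10)),
    proposal: ProposalDistribution | None = None,
) -> BayesFactorResult:
    """Bridge-sampling log10 Bayes factor of model 2 over nested model 1.

    Wraps :func:`bridge_log10_ratio` with the binding-model parameter
    mapping (2C→RM/EM: dG↔dG1, dH↔dH1; extra parameters γ are the
    remaining columns), working in the shared unconstrained coordinates
    with Jacobians folded into the potentials.
    """
    model1, model2 = samples1.model, samples2.model
    mapping = nested_parameter_mapping(model1, model2)
    gamma_names = [n for n in samples2.names if n not in mapping]
    space1 = build_parameter_space(model1, data, spec)
    space2 = build_parameter_space(model2, data, spec)

    if proposal is None:
        proposal = fit_proposal(samples2, gamma_names)

    X1 = _unconstrained_matrix(samples1, samples1.names)
    # reorder the larger model's draws to (shared block in model-1 order, γ)
    X2_full = _unconstrained_matrix(samples2, samples2.names)
    inv_mapping = {v: k for k, v in mapping.items()}
    shared_cols = [samples2.names.index(inv_mapping[n]) for n in samples1.names]
    gamma_cols = [samples2.names.index(g) for g in gamma_names]
    X2 = X2_full[:, shared_cols + gamma_cols]

    # model-2 density over the reordered coordinates
    order2 = shared_cols + gamma_cols

    def logp2(x):
        full = np.empty(len(samples2.names))
        full[order2] = x
        return space2.log_density(full)

    result = bridge_log10_ratio(
        space1.log_density,
        logp2,
        X1,
        X2,
        proposal,
        seed=seed,
        n_bootstrap=n_bootstrap,
        trace_fractions=trace_fractions,
    )
    result.model_pair = (model1, model2)
    return result


@dataclass
class ModelComparison:
    """Per-model AIC/BIC and per-pair log10 Bayes factors with SEs."""

    aic: dict[str, float]
    bic: dict[str, float]
    max_loglik: dict[str, float]
    bayes_factors: dict[tuple[str, str], BayesFactorResult]
    n_injections: int

    def log10_bf(self, model2: str, model1: str) -> float:
        key = (model1.upper(), model2.upper())
        if key in self.bayes_factors:
            return self.bayes_factors[key].log10_bf
        rev = (model2.upper(), model1.upper())
        return -self.bayes_factors[rev].log10_bf

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (m1, m2), res in self.bayes_factors.items():
            rows.append(
                {
                    "pair": f"{m2} vs {m1}",
                    "log10_bf": res.log10_bf,
                    "se": res.se,
                }
            )
        return pd.DataFrame(rows)

    def report(self) -> str:
        lines = ["model   AIC          BIC          max_loglik"]
        for m in self.aic:
            lines.append(
                f"{m:<6} {self.aic[m]:>12.3f} {self.bic[m]:>12.3f} "
                f"{self.max_loglik[m]:>12.3f}"
            )
        lines.append("")
        lines.append("pair          log10_BF      SE")
        for (m1, m2), res in self.bayes_factors.items():
            lines.append(
                f"{m2 + ' vs ' + m1:<12} {res.log10_bf:>10.2f} {res.se:>8.2f}"
            )
        return "\n".join(lines)


def compare_models(
    data: Dataset,
    spec: PriorSpec,
    config: SamplerConfig | None = None,
    models: Sequence[str] = ("2C", "RM", "EM"),
    seed: int = 0,
    n_bootstrap: int = 1000,
    fits: dict[str, PosteriorSamples] | None = None,
) -> ModelComparison:
    """Fit the requested models and compute AIC, BIC and Bayes factors.

    ``fits`` may supply pre-computed posterior samples keyed by model tag;
    missing models are sampled with ``config``.
    """
    config = config or SamplerConfig()
    models = [m.upper() for m in models]
    fits = dict(fits or {})
    for m in models:
        if m not in fits:
            fits[m] = sample_posterior(data, spec, m, config)

    aics, bics, mlls = {}, {}, {}
    for m in models:
        theta_ml, mll = max_likelihood(data, spec, m, fits[m])
        k = len(MODEL_PARAMETER_NAMES[m])
        aics[m] = aic(mll, k)
        bics[m] = bic(mll, k, data.n)
        mlls[m] = mll

    order = {"2C": 0, "RM": 1, "EM": 2}
    bfs = {}
    for i, m1 in enumerate(models):
        for m2 in models[i + 1 :]:
            a, b = sorted((m1, m2), key=order.get)
            try:
                bfs[(a, b)] = bayes_factor_nested(
                    fits[a], fits[b], data, spec, seed=seed, n_bootstrap=n_bootstrap
                )
            except EstimatorFailure as err:
                logger.warning("Bayes factor %s vs %s failed: %s", b, a, err)
    return ModelComparison(aics, bics, mlls, bfs, data.n)
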