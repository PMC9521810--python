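"""scikit-learn-style estimator front end.

:class:`ITCRegressor` wraps the Bayesian fitting pipeline as a regressor:
``X`` holds the per-injection volumes (litres, shape ``(n, 1)`` or
``(n,)``) and ``y`` the integrated heats (cal).  After ``fit``, posterior
draws, summaries and the MAP estimate are available as fitted attributes,
and ``predict`` evaluates the MAP heat curve, so the estimator composes
with sklearn pipelines and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .models import DEFAULT_CELL_VOLUME, DEFAULT_TEMPERATURE, TitrationProtocol, heats
from .probability import Dataset, PriorSpec
from .sampling import SamplerConfig, sample_posterior, summarize

__all__ = ["ITCRegressor"]


class ITCRegressor(RegressorMixin, BaseEstimator):
    """Bayesian binding-model regression for one titration.

    Parameters
    ----------
    model : {"2C", "RM", "EM"}
        Binding model: single ligand, racemic two-ligand mixture, or
        two-ligand mixture with free composition.
    r0_prior, ls_prior : {"auto", "lognormal", "uniform"}
        Concentration priors; "auto" selects lognormal when a stated
        concentration is given, else uniform.
    stated_r0, stated_ls : float or None
        Stated cell/syringe concentrations, mol/L.
    cell_volume, temperature : float
        Cell volume (litres) and analysis temperature (kelvin).
    warmup, draws, thin, seed, init, n_walkers
        Sampler settings; see :class:`~itcmix.sampling.SamplerConfig`.

    Attributes
    ----------
    samples_ : PosteriorSamples
        Retained posterior draws.
    summary_ : pandas.DataFrame
        Posterior means, s.d. and 95% credible intervals.
    theta_map_ : ParameterSet
        Best retained draw by posterior density.
    """

    def __init__(
        self,
        model: str = "EM",
        r0_prior: str = "auto",
        ls_prior: str = "auto",
        stated_r0: float | None = None,
        stated_ls: float | None = None,
        cell_volume: float = DEFAULT_CELL_VOLUME,
        temperature: float = DEFAULT_TEMPERATURE,
        warmup: int = 2000,
        draws: int = 20000,
        thin: int = 10,
        seed: int = 0,
        init="prior",
        n_walkers: int | None = None,
    ):
        self.model = model
        self.r0_prior = r0_prior
        self.ls_prior = ls_prior
        self.stated_r0 = stated_r0
        self.stated_ls = stated_ls
        self.cell_volume = cell_volume
        self.temperature = temperature
        self.warmup = warmup
        self.draws = draws
        self.thin = thin
        self.seed = seed
        self.init = init
        self.n_walkers = n_walkers

    def _volumes(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must have a single column of injection volumes")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-D or a single-column 2-D array")
        return X

    def fit(self, X, y):
        """Sample the posterior given injection volumes X and heats y."""
        vols = self._volumes(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != vols.size:
            raise ValueError("X and y must have one row per injection")
        protocol = TitrationProtocol(
            injection_volumes=vols,
            cell_volume=self.cell_volume,
            temperature=self.temperature,
        )
        data = Dataset(
            heats=y,
            protocol=protocol,
            stated_R0=self.stated_r0,
            stated_Ls=self.stated_ls,
        )
        spec = PriorSpec(r0_prior=self.r0_prior, ls_prior=self.ls_prior)
        config = SamplerConfig(
            warmup=self.warmup,
            draws=self.draws,
            thin=self.thin,
            seed=self.seed,
            init=self.init,
            n_walkers=self.n_walkers,
        )
        self.samples_ = sample_posterior(data, spec, self.model, config)
        self.summary_ = summarize(self.samples_)
        self.theta_map_ = self.samples_.map_estimate()
        self.data_ = data
        self.prior_spec_ = spec
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Theoretical heats (cal) at the MAP estimate for a protocol X."""
        check_is_fitted(self, "theta_map_")
        vols = self._volumes(X)
        protocol = TitrationProtocol(
            injection_volumes=vols,
            cell_volume=self.cell_volume,
            temperature=self.temperature,
        )
        return heats(self.theta_map_, protocol)

    def posterior_mean(self, parameter: str) -> float:
        check_is_fitted(self, "samples_")
        return float(self.samples_.column(parameter).mean())
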