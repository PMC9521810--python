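"""Credible-interval coverage validation.

If a posterior is well calibrated, its equal-tailed x% credible interval
should contain the true parameter value in x% of replicated experiments.
Plotting observed containment rate against the stated level should give
the diagonal; points below the diagonal mean the intervals understate the
uncertainty, points above that they overstate it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ParameterSet
from .sampling import PosteriorSamples

__all__ = ["CoverageResult", "coverage_curve", "DEFAULT_LEVELS"]

#: Stated confidence levels (%) of the default grid.
DEFAULT_LEVELS = (10, 20, 30, 40, 50, 60, 70, 80, 90, 95)


@dataclass
class CoverageResult:
    """Observed vs predicted containment rates, with bootstrap SDs."""

    table: pd.DataFrame  # columns: parameter, level, observed, bootstrap_sd
    n_replicates: int
    tag: str = ""

    def observed(self, parameter: str, level: float) -> float:
        t = self.table
        row = t[(t.parameter == parameter) & (t.level == level)]
        return float(row.observed.iloc[0])


def coverage_curve(
    fits: Sequence[PosteriorSamples],
    truths: Sequence[ParameterSet] | Sequence[dict] | np.ndarray,
    levels: Sequence[float] = DEFAULT_LEVELS,
    parameters: Sequence[str] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    tag: str = "",
) -> CoverageResult:
    """Observed rate at which equal-tailed intervals contain the truth.

    ``truths`` holds the realized parameter values of each replicate
    (parameter sets, dicts, or an array in the fit's column order).  The
    bootstrap SD resamples replicates with replacement (default 1000).
    """
    if len(fits) != len(truths):
        raise ValueError("fits and truths must be aligned")
    if len(fits) < 2:
        raise ValueError("need at least two replicates")
    names = parameters or list(fits[0].names)
    n_rep = len(fits)

    def truth_value(t, name):
        if isinstance(t, dict):
            return t[name]
        if hasattr(t, name):
            return getattr(t, name)
        return np.asarray(t)[list(fits[0].names).index(name)]

    rng = np.random.default_rng(seed)
    rows = []
    for name in names:
        # containment indicator per (replicate, level)
        contain = np.empty((n_rep, len(levels)), dtype=bool)
        for i, fit in enumerate(fits):
            col = fit.column(name)
            tv = truth_value(truths[i], name)
            for j, level in enumerate(levels):
                alpha = 1.0 - level / 100.0
                lo, hi = np.quantile(col, [alpha / 2.0, 1.0 - alpha / 2.0])
                contain[i, j] = lo <= tv <= hi
        observed = contain.mean(axis=0) * 100.0
        idx = rng.integers(0, n_rep, size=(n_bootstrap, n_rep))
        boot = contain[idx].mean(axis=1) * 100.0  # (n_bootstrap, len(levels))
        sds = boot.std(axis=0, ddof=1)
        for j, level in enumerate(levels):
            rows.append(
                {
                    "parameter": name,
                    "level": float(level),
                    "observed": float(observed[j]),
                    "bootstrap_sd": float(sds[j]),
                }
            )
    return CoverageResult(pd.DataFrame(rows), n_rep, tag)
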