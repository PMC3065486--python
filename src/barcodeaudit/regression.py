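"""Sampling-bias regression: mean intraspecific divergence vs sample size.

If sparsely sampled species systematically under-represent their true
genetic variation, per-species mean intraspecific divergence should rise
with the number of individuals analyzed.  An ordinary least-squares fit of
mean divergence on sample size tests this: a non-significant slope
indicates the sampling strategy captured variation comparably across taxa.
Only species with >= 2 specimens enter (a singleton has no intraspecific
mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import DivergenceSummary
from .errors import DegenerateDesignError, ValidationError


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float        # two-sided t-test on the slope, n - 2 df
    stderr: float
    n_points: int


def fit_ols(x, y) -> RegressionResult:
    """Closed-form OLS of y on x with the usual slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError(f"need >= 3 points for a regression, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("constant predictor: slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n_points=int(x.size),
    )


def sampling_bias_regression(
    summary: DivergenceSummary,
) -> tuple[RegressionResult, pd.DataFrame]:
    """Fit mean intraspecific divergence (%) against specimens per species.

    Returns the fit plus the scatter table (one row per multi-specimen
    species) for plotting.
    """
    scatter = summary.per_species[["species", "n", "mean_intra_pct"]].copy()
    result = fit_ols(scatter["n"].to_numpy(), scatter["mean_intra_pct"].to_numpy())
    return result, scatter
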