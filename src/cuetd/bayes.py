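"""Posterior summaries and Bayes-factor inference.

Covers the hypothesis-evaluation toolkit used on the fitted shift
parameters: highest density intervals, Savage-Dickey density-ratio Bayes
factors against a point null, directional Bayes factors (posterior mass
below vs. above zero), default-prior Bayesian correlations, and pooled
two-sample t-tests from summary statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "HdiInterval",
    "BfResult",
    "CorrelationResult",
    "SummaryStatsGroup",
    "hdi",
    "savage_dickey_bf01",
    "directional_bf",
    "bayes_correlation",
    "pooled_two_sample_t",
    "evidence_label",
    "shift_report",
]

log = logging.getLogger(__name__)

MIN_DRAWS = 100


@dataclass
class HdiInterval:
    mass: float
    lower: float
    upper: float

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass
class BfResult:
    parameter: str
    mean: float
    sd: float
    bf01: float
    dbf: float
    hdi85: HdiInterval
    hdi95: HdiInterval


@dataclass
class CorrelationResult:
    r: float
    bf01: float
    ci_lower: float
    ci_upper: float
    n: int


@dataclass
class SummaryStatsGroup:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


def hdi(draws, mass: float) -> HdiInterval:
    """Shortest contiguous interval containing ``mass`` of the draws.

    Computed exactly on the sorted sample: the narrowest window spanning
    ceil(mass * n) consecutive order statistics.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    if x.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws for an HDI")
    m = int(math.ceil(mass * x.size))
    widths = x[m - 1:] - x[: x.size - m + 1]
    i = int(np.argmin(widths))
    return HdiInterval(mass=mass, lower=float(x[i]), upper=float(x[i + m - 1]))


def savage_dickey_bf01(posterior_draws, prior_density_at_null: float,
                       null_value: float = 0.0, method: str = "kde") -> float:
    """Savage-Dickey density-ratio Bayes factor for a point null.

    BF01 = posterior density at the null / prior density at the null; values
    above 1 favour the restricted (null) model.  The posterior density is a
    Gaussian kernel estimate with Silverman bandwidth (``method="kde"``) or
    a moment-matched normal (``method="normal"``).
    """
    if prior_density_at_null <= 0:
        raise ValueError("prior density at the null must be positive")
    x = np.asarray(posterior_draws, dtype=float)
    if method == "kde":
        post = float(stats.gaussian_kde(x, bw_method="silverman")(null_value)[0])
    elif method == "normal":
        post = float(stats.norm.pdf(null_value, x.mean(), x.std(ddof=1)))
    else:
        raise ValueError(f"unknown density method {method!r}")
    if post <= 0:
        log.warning("posterior density ~0 at the null; returning machine floor")
        post = np.finfo(float).tiny
    return post / prior_density_at_null


def directional_bf(posterior_draws) -> float:
    """Ratio of posterior mass below zero to posterior mass above zero.

    Exact zeros count to neither side.  If one side is empty the ratio is
    capped by counting that side as a single draw, with a warning.
    """
    x = np.asarray(posterior_draws, dtype=float)
    if x.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} draws")
    below = int((x < 0).sum())
    above = int((x > 0).sum())
    if below == 0 or above == 0:
        log.warning("one-sided posterior (below=%d, above=%d); ratio capped",
                    below, above)
        below, above = max(below, 1), max(above, 1)
    return below / above


def _correlation_kernel(rho, r, n):
    # marginal likelihood kernel of the sample correlation, normalised so
    # that rho = 0 gives 1
    return (1 - rho ** 2) ** ((n - 1) / 2) / (1 - rho * r) ** (n - 1.5)


def bayes_correlation(x, y, ci_mass: float = 0.95) -> CorrelationResult:
    """Pearson correlation with a default-prior Bayes factor for the null.

    The prior on the population correlation rho is uniform on (-1, 1) (the
    stretched-beta default with kappa = 1); BF01 is obtained by numerical
    integration of the correlation likelihood over that prior.  The credible
    interval comes from the grid posterior of rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("x and y must have equal length >= 5")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    n = x.size
    r = float(stats.pearsonr(x, y)[0])
    with warnings.catch_warnings():
        # the likelihood kernel diverges as |r| -> 1; the BF is then
        # effectively infinite and BF01 ~ 0, which is the right answer
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        bf10, _ = integrate.quad(
            lambda rho: 0.5 * _correlation_kernel(rho, r, n), -1, 1)
    grid = np.linspace(-0.9999, 0.9999, 4001)
    dens = _correlation_kernel(grid, r, n)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    lo = float(np.interp((1 - ci_mass) / 2, cdf, grid))
    hi = float(np.interp(1 - (1 - ci_mass) / 2, cdf, grid))
    return CorrelationResult(r=r, bf01=1.0 / bf10, ci_lower=lo, ci_upper=hi,
                             n=n)


def pooled_two_sample_t(a: SummaryStatsGroup, b: SummaryStatsGroup):
    """Pooled-variance two-sample t statistic from summary statistics.

    Returns ``(t, df)`` with df = n_a + n_b - 2.
    """
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                     equal_var=True)
    return float(res.statistic), a.n + b.n - 2


def evidence_label(bf01: float) -> str:
    """Verbal evidence category: (1,3] anecdotal, (3,10] moderate, >10 strong,
    mirrored via reciprocals for evidence against the null."""
    if bf01 <= 0:
        raise ValueError("Bayes factor must be positive")
    favours = "null" if bf01 >= 1 else "alternative"
    b = bf01 if bf01 >= 1 else 1.0 / bf01
    if b > 10:
        strength = "strong"
    elif b > 3:
        strength = "moderate"
    elif b > 1:
        strength = "anecdotal"
    else:
        return "no evidence"
    return f"{strength} ({favours})"


def shift_report(draws, priors=None) -> pd.DataFrame:
    """Posterior summary table for the group-mean condition-shift parameters.

    One row per shift parameter (on its native model scale: log-k units for
    the k shift, inverse-temperature units for the beta shift, logit units
    for the omega shift): posterior mean, SD, directional BF, Savage-Dickey
    BF01 against a zero shift, and 85%/95% HDIs.
    """
    from .inference import PosteriorDraws, PriorSpec  # cycle-free at runtime

    priors = priors or (draws.priors if isinstance(draws, PosteriorDraws)
                        else PriorSpec())
    prior_sds = {
        "mu_s_ero_k": priors.s_ero_k,
        "mu_s_ero_beta": priors.s_ero_beta,
        "mu_s_ero_logit_omega": priors.s_ero_omega,
    }
    rows = []
    for name, prior in prior_sds.items():
        if name not in draws.params:
            continue
        x = draws.stacked(name)
        if np.ptp(x) == 0:
            continue  # shifts fixed at zero (single-condition fit)
        prior_at_null = stats.norm.pdf(0.0, prior[0], prior[1])
        rows.append({
            "parameter": name,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "dBF": directional_bf(x),
            "BF01": savage_dickey_bf01(x, prior_at_null, 0.0),
            "hdi85_lower": hdi(x, 0.85).lower,
            "hdi85_upper": hdi(x, 0.85).upper,
            "hdi95_lower": hdi(x, 0.95).lower,
            "hdi95_upper": hdi(x, 0.95).upper,
        })
    return pd.DataFrame(rows)
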