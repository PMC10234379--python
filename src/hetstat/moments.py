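"""Nonparametric uncertainty for heteroplasmy variance.

When individual measurements exist but no parametric model (Kimura or
otherwise) is trusted, the uncertainty of the sample variance s^2 can
still be estimated.  The population identity is

    V(s^2) = (1/n) ( mu_4 - (n-3)/(n-1) sigma^4 )

which needs the fourth central moment mu_4.  The unique unbiased
symmetric estimator of mu_4 from sample moments is the h-statistic

    h_4 = ( 3(3-2n) n^2 m_2^2 + n^2 (n^2-2n+3) m_4 )
          / ( (n-3)(n-2)(n-1) n )

with m_k the 1/n-denominator sample central moments.  Plugging h_4 and
s^4 into the identity gives the estimator V-hat(s^2).  Unbiasedness, not
positivity, is what h-statistics guarantee, so small samples can yield
negative estimates; these are returned raw and flagged so that averages
across simulations stay unbiased.

Resampling alternatives: the bootstrap mean of resample variances is
biased low by a factor (n-1)/n (resamples repeat observations), so the
corrected point estimate multiplies by n/(n-1); the jackknife gives a
standard error for s^2 from leave-one-out replicates.

The historical D_4 expression sometimes quoted as an unbiased mu_4
estimator is not one — it is the expectation of the sample moment m_4,
written in terms of population quantities — and is deliberately not
implemented here; use :func:`h4`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kimura import as_sample

__all__ = [
    "VarianceUncertainty",
    "sample_moments",
    "h4",
    "var_of_sample_variance",
    "bootstrap_variance",
    "jackknife_variance",
    "d4",
]


@dataclass
class VarianceUncertainty:
    """Uncertainty summary for a sample variance."""

    s2: float
    estimate: float                  # V-hat(s^2), or corrected bootstrap variance
    method: str                      # "h_statistic" | "bootstrap" | "jackknife"
    spread: float | None = None      # resampling spread (s.e.-style), if any
    B: int | None = None
    seed: int | None = None
    negative: bool = False           # h-statistic estimate below zero


def sample_moments(sample) -> tuple[float, float, float, float]:
    """(mean, m2, m4, s2): 1/n central moments and the (n-1) variance."""
    v = as_sample(sample).values
    n = v.size
    hbar = float(np.mean(v))
    d = v - hbar
    m2 = float(np.mean(d**2))
    m4 = float(np.mean(d**4))
    if n < 2:
        raise ValueError("sample variance requires n >= 2")
    s2 = float(np.var(v, ddof=1))
    return hbar, m2, m4, s2


def h4(sample) -> float:
    """Unbiased estimate of the fourth central moment mu_4 (needs n >= 4)."""
    v = as_sample(sample).values
    n = v.size
    if n < 4:
        raise ValueError("h4 requires at least 4 observations")
    _, m2, m4, _ = sample_moments(v)
    num = 3.0 * (3.0 - 2.0 * n) * n**2 * m2**2 + n**2 * (n**2 - 2.0 * n + 3.0) * m4
    den = (n - 3.0) * (n - 2.0) * (n - 1.0) * n
    return num / den


def var_of_sample_variance(sample) -> VarianceUncertainty:
    """V-hat(s^2) = (1/n)(h4 - (n-3)/(n-1) s^4), possibly negative (flagged)."""
    s = as_sample(sample)
    n = s.n
    est_mu4 = h4(s)
    s2 = s.s2
    est = (est_mu4 - (n - 3.0) / (n - 1.0) * s2**2) / n
    return VarianceUncertainty(
        s2=s2, estimate=est, method="h_statistic", negative=est < 0.0
    )


def bootstrap_variance(sample, B: int = 1000, seed: int = 0) -> VarianceUncertainty:
    """Bias-corrected bootstrap estimate of sigma^2 and its resampling spread.

    estimate = n/(n-1) * mean over B resamples of the resample variance;
    spread   = standard deviation of the corrected resample variances.
    """
    s = as_sample(sample)
    n = s.n
    if n < 2:
        raise ValueError("bootstrap variance requires n >= 2")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    res_var = np.var(s.values[idx], axis=1, ddof=1)
    corrected = n / (n - 1.0) * res_var
    return VarianceUncertainty(
        s2=s.s2,
        estimate=float(np.mean(corrected)),
        spread=float(np.std(corrected, ddof=1)),
        method="bootstrap",
        B=B,
        seed=seed,
    )


def jackknife_variance(sample) -> VarianceUncertainty:
    """Jackknife standard error of the sample variance (n leave-one-out sets)."""
    s = as_sample(sample)
    n = s.n
    if n < 3:
        raise ValueError("jackknife requires n >= 3")
    v = s.values
    total = v.sum()
    sq = (v**2).sum()
    # leave-one-out variances in closed form: each omits one element
    loo_mean = (total - v) / (n - 1)
    loo_s2 = (sq - v**2 - (n - 1) * loo_mean**2) / (n - 2)
    theta_bar = loo_s2.mean()
    se2 = (n - 1.0) / n * np.sum((loo_s2 - theta_bar) ** 2)
    return VarianceUncertainty(
        s2=s.s2, estimate=s.s2, spread=float(np.sqrt(se2)), method="jackknife"
    )


def d4(*_args, **_kwargs):
    """Not implemented: the quoted D_4 expression is E[m_4], not an estimator.

    Its right-hand side involves the population mu_4 itself and so cannot
    be computed from a sample.  Use :func:`h4`, the unbiased h-statistic.
    """
    raise NotImplementedError(
        "D_4 is the expectation of the sample moment m_4, not an estimator "
        "of mu_4; use hetstat.moments.h4 instead"
    )
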