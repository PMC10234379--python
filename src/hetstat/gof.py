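"""Kolmogorov-Smirnov goodness-of-fit testing against the Kimura model.

The KS distance here is the sup-norm distance between the sample ECDF and
the *mixed* theoretical CDF (atoms at 0 and 1 plus a continuous part), so
candidate maximizers are evaluated both before and after every jump.

Because the Kimura parameters are in practice estimated from the very
data being tested, no analytic KS null distribution applies; p-values
come from Monte Carlo simulation under the fitted parameters.  Even then,
testing against a same-data fit is statistically generous — a small
p-value is meaningful, a large one is not a clean "accept" — and every
p-value is reported together with its binomial uncertainty interval
rather than as a single fixed number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .kimura import (
    B_DEGENERATE,
    KimuraParams,
    _cdf_arr,
    _continuous_inverse_table,
    _n_terms,
    _sample_values,
    _series_weights,
    _shape_fn,
    kimura_point_masses,
    kimura_sample,
    as_sample,
)
from scipy.special import eval_legendre

__all__ = ["KSResult", "ecdf", "ks_distance", "ks_monte_carlo_test", "ks_test_with_fit"]


@dataclass
class KSResult:
    """Monte Carlo KS test outcome."""

    distance: float
    p_value: float
    p_value_interval: tuple[float, float]
    n_replicates: int
    seed: int | None
    fit_method: str
    params: KimuraParams

    def __post_init__(self) -> None:
        lo, hi = self.p_value_interval
        assert 0.0 <= self.distance <= 1.0
        assert lo <= self.p_value <= hi


def ecdf(sample, x) -> np.ndarray | float:
    """Right-continuous empirical CDF of the sample evaluated at x."""
    values = np.sort(as_sample(sample).values)
    xarr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.searchsorted(values, xarr, side="right") / values.size
    return out if np.ndim(x) else float(out[0])


def _ks_distances_many(values2d: np.ndarray, params: KimuraParams) -> np.ndarray:
    """KS distance of each row of values2d against the theoretical CDF.

    Rows are independent samples of common size n.  The sup over [0, 1]
    of |ECDF - F| is attained at a data point, at an atom of F, or at
    the left limit of either; candidates therefore are every data value
    plus {0, 1}, each checked before and after its jump.
    """
    v = np.sort(np.asarray(values2d, dtype=float), axis=1)
    nrep, n = v.shape
    if params.degenerate:
        # point mass at p: D = max(ECDF left limit at p, 1 - ECDF at p)
        p = params.p
        E_at = (v <= p).sum(axis=1) / n
        E_before = (v < p).sum(axis=1) / n
        return np.maximum(E_before, 1.0 - E_at)
    m0, m1 = kimura_point_masses(params)
    # candidate points: data values and the two atoms
    ones = np.ones((nrep, 1))
    cand = np.concatenate([np.zeros((nrep, 1)), v, ones], axis=1)
    flat = cand.ravel()
    F = _cdf_arr(params, flat).reshape(cand.shape)
    atom = np.where(cand <= 0.0, m0, np.where(cand >= 1.0, m1, 0.0))
    F_left = F - atom
    # ECDF at/below each candidate within its own row
    idx_right = np.empty_like(cand, dtype=np.int64)
    idx_left = np.empty_like(cand, dtype=np.int64)
    for r in range(nrep):
        idx_right[r] = np.searchsorted(v[r], cand[r], side="right")
        idx_left[r] = np.searchsorted(v[r], cand[r], side="left")
    E = idx_right / n
    E_left = idx_left / n
    d = np.maximum(np.abs(E - F), np.abs(E_left - F_left))
    return d.max(axis=1)


def ks_distance(sample, params: KimuraParams) -> float:
    """Sup-norm distance between the sample ECDF and the Kimura CDF."""
    values = as_sample(sample).values
    return float(_ks_distances_many(values[None, :], params)[0])


def _ks_grid(values: np.ndarray, p_arr: np.ndarray, b_arr: np.ndarray) -> np.ndarray:
    """KS distance of one sample over a (p, b) grid, shape (len(p), len(b)).

    Shares the series/Gegenbauer factors across the grid the same way
    the log-likelihood grid does; this is what makes the minimum-KS fit
    a practical grid search.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    p_arr = np.asarray(p_arr, dtype=float)
    b_arr = np.asarray(b_arr, dtype=float)
    cand = np.unique(np.concatenate([[0.0], v, [1.0]]))
    E = np.searchsorted(v, cand, side="right") / n
    E_left = np.searchsorted(v, cand, side="left") / n
    inner = (cand > 0.0) & (cand < 1.0)
    at0 = cand == 0.0
    at1 = cand == 1.0

    kmax = max(_n_terms(b) for b in b_arr)
    i = np.arange(1, kmax + 1)
    fp = _shape_fn(i, p_arr)                                  # (K, P)
    leg1m = 1.0 - eval_legendre(i[:, None], 1.0 - 2.0 * cand[inner][None, :])
    sign = (-1.0) ** i
    q_arr = 1.0 - p_arr
    pq = p_arr * q_arr

    out = np.empty((p_arr.size, b_arr.size))
    for jb, b in enumerate(b_arr):
        if 1.0 - b < B_DEGENERATE:
            # point mass at p: compare step CDFs directly
            for ip, p in enumerate(p_arr):
                F = (cand >= p).astype(float)
                F_left = (cand > p).astype(float)
                out[ip, jb] = np.max(
                    np.maximum(np.abs(E - F), np.abs(E_left - F_left))
                )
            continue
        kb = _n_terms(b)
        ib = i[:kb]
        w = _series_weights(b, ib)
        c = (2 * ib + 1) * w
        m0 = np.clip(q_arr - pq * (fp[:kb].T @ c), 0.0, 1.0)
        m1 = np.clip(p_arr + pq * (fp[:kb].T @ (sign[:kb] * c)), 0.0, 1.0)
        F = np.empty((p_arr.size, cand.size))
        F[:, at0] = m0[:, None]
        F[:, at1] = 1.0
        F[:, inner] = m0[:, None] + pq[:, None] * ((fp[:kb] * c[:, None]).T @ leg1m[:kb])
        F = np.clip(F, 0.0, 1.0)
        F_left = F.copy()
        F_left[:, at0] = 0.0
        F_left[:, at1] = (1.0 - m1)[:, None]
        d = np.maximum(np.abs(E[None, :] - F), np.abs(E_left[None, :] - F_left))
        out[:, jb] = d.max(axis=1)
    return out


def _binom_interval(k: int, B: int, p_value: float, level: float = 0.95):
    ci = binomtest(k, B).proportion_ci(confidence_level=level, method="exact")
    return (min(float(ci.low), p_value), max(float(ci.high), p_value))


def ks_monte_carlo_test(
    sample,
    params: KimuraParams,
    B: int = 5000,
    seed: int = 0,
    fit_method: str = "fixed",
    mode: str = "one_sample",
) -> KSResult:
    """Monte Carlo KS test of the sample against a Kimura parameterization.

    B datasets of the same size are simulated under ``params``; the
    p-value is (#{D_sim >= D_obs} + 1)/(B + 1), ties counting toward
    rejection.  ``mode="two_sample"`` instead compares every ECDF with
    the ECDF of a large reference sample drawn once from ``params``
    (the historical ensemble-based formulation); ``one_sample`` uses the
    exact theoretical CDF and is the default.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    s = as_sample(sample)
    n = s.n
    rng = np.random.default_rng(seed)
    table = (None if params.degenerate
             else _continuous_inverse_table(params))
    sims = _sample_values(params, (B, n), rng, table=table)
    if mode == "one_sample":
        d_obs = ks_distance(s, params)
        d_sim = _ks_distances_many(sims, params)
    elif mode == "two_sample":
        ref = np.sort(kimura_sample(params, max(10 * n, 10000), rng).values)
        d_obs = _two_sample_ks(np.sort(s.values), ref)
        d_sim = np.array([_two_sample_ks(np.sort(row), ref) for row in sims])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    k = int(np.sum(d_sim >= d_obs - 1e-12))
    p = (k + 1) / (B + 1)
    return KSResult(
        distance=float(d_obs),
        p_value=p,
        p_value_interval=_binom_interval(k, B, p),
        n_replicates=B,
        seed=seed,
        fit_method=fit_method,
        params=params,
    )


def _two_sample_ks(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    grid = np.concatenate([a_sorted, b_sorted])
    Ea = np.searchsorted(a_sorted, grid, side="right") / a_sorted.size
    Eb = np.searchsorted(b_sorted, grid, side="right") / b_sorted.size
    return float(np.abs(Ea - Eb).max())


def ks_test_with_fit(
    sample,
    fit_method: str = "min_ks",
    B: int = 5000,
    seed: int = 0,
    fixed_p: float | None = None,
    mode: str = "one_sample",
) -> KSResult:
    """Fit the Kimura distribution by the chosen method, then KS-test it.

    fit_method is one of {"mom", "mle", "min_ks"}.  Note the caveat:
    the parameters are estimated from the same data being tested, so the
    standard KS null does not hold and the Monte Carlo p-value must be
    read as a diagnostic, not an exact test ("must be corrected").  The
    min_ks method gives the most charitable (largest-p) assessment of
    whether *any* Kimura distribution is compatible with the data.
    """
    from . import fitting  # local import: fitting depends on ks_distance

    s = as_sample(sample)
    if fit_method == "mom":
        fit = fitting.fit_mom(s)
    elif fit_method == "mle":
        fit = fitting.fit_ml(s, fixed_p=fixed_p)
    elif fit_method == "min_ks":
        fit = fitting.fit_min_ks(s, fixed_p=fixed_p)
    else:
        raise ValueError(f"unknown fit method {fit_method!r}")
    return ks_monte_carlo_test(
        s, fit.params, B=B, seed=seed, fit_method=fit_method, mode=mode
    )
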