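"""Estimating the Kimura parameters (p, b) from a heteroplasmy sample.

Three estimators are provided, mirroring the three ways practitioners
fit this distribution:

* method-of-moments (``fit_mom``): p = sample mean, b solved from the
  variance identity.  Cheap, but not optimal for finite samples.
* maximum likelihood (``fit_ml``): maximizes the mixed point-mass /
  density likelihood over (p, b), optionally with p fixed at a known
  reference heteroplasmy.  The recommended estimator.
* minimum KS distance (``fit_min_ks``): the parameterization whose CDF
  is closest to the sample ECDF in sup-norm; the right estimator when
  the downstream question is itself a KS goodness-of-fit question.

Optimization is a deterministic coarse grid (0.01 steps over
[0.001, 0.999]^2) followed by nested grid refinement, so repeated fits
are bit-identical.  Confidence intervals for b come from the profile
likelihood (default), the observed Fisher information, or a seeded
bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kimura import (
    HeteroplasmySample,
    KimuraParams,
    _loglik_grid,
    as_sample,
    bottleneck_from_b,
    kimura_loglik,
)
from .gof import _ks_grid, ks_distance

__all__ = [
    "FitResult",
    "ClassicBottleneck",
    "fit_mom",
    "fit_ml",
    "fit_min_ks",
    "confint_b",
    "bottleneck_classic",
]

GRID_STEP = 0.01
GRID_LO, GRID_HI = 0.001, 0.999
REFINE_ROUNDS = 3          # each round shrinks the step by 10x -> ~1e-5 final
# upper bound keeps the series within its term cap (n_b up to 10^4)
BOUND_LO, BOUND_HI = 1e-5, 1.0 - 1e-4


@dataclass
class FitResult:
    """Fitted Kimura parameterization with provenance."""

    params: KimuraParams
    method: str                      # "mom" | "mle" | "min_ks"
    loglik: float | None = None
    ks_distance: float | None = None
    fixed_p: float | None = None
    converged: bool = True
    clamped: bool = False            # MoM estimate fell outside [0,1]
    degenerate: bool = False         # boundary/point-mass fit
    ci_b: tuple[float, float] | None = None
    ci_p: tuple[float, float] | None = None
    ci_method: str = "none"
    ci_level: float | None = None

    @property
    def n_b(self) -> float:
        return self.params.n_b

    @property
    def ci_n_b(self) -> tuple[float, float] | None:
        """Bottleneck-size interval by the monotone transform of ci_b."""
        if self.ci_b is None:
            return None
        lo, hi = self.ci_b
        return bottleneck_from_b(lo), bottleneck_from_b(hi)


@dataclass
class ClassicBottleneck:
    """The textbook estimator n_b = p(1-p)/V with its sanity flag."""

    n_b: float
    p_used: float
    variance_used: float
    p_source: str
    variance_kind: str
    sub_unit: bool = False           # "nonsensical: below one segregating unit"


# -- method of moments ---------------------------------------------------

def fit_mom(sample) -> FitResult:
    """p = sample mean; b = 1 - s^2/(mean(1-mean)), clamped into [0, 1]."""
    s = as_sample(sample)
    if s.n < 2:
        raise ValueError("method of moments requires n >= 2")
    hbar = s.mean
    if hbar <= 0.0 or hbar >= 1.0:
        raise ValueError("MoM undefined for homoplasmic mean")
    raw_b = 1.0 - s.s2 / (hbar * (1.0 - hbar))
    clamped = not (0.0 <= raw_b <= 1.0)
    b = min(max(raw_b, 0.0), 1.0)
    params = KimuraParams(hbar, b)
    return FitResult(
        params=params,
        method="mom",
        loglik=kimura_loglik(params, s),
        clamped=clamped,
    )


# -- deterministic grid + zoom optimizer ---------------------------------

def _zoom_maximize(objective_grid, p0: float | None, seed_points=()):
    """Maximize over (p, b) (or b alone when p0 is fixed) by nested grids.

    objective_grid(p_arr, b_arr) -> matrix of objective values (higher is
    better).  Ties break to the first (lowest-index) grid point, making
    the whole search deterministic.  seed_points are extra (p, b)
    candidates whose neighbourhoods are also refined, guaranteeing the
    result is at least as good as every seed.
    """
    base = np.linspace(GRID_LO, GRID_HI, 100)

    def local_max(pc, bc, step):
        for _ in range(REFINE_ROUNDS):
            p_arr = (np.array([pc]) if p0 is not None
                     else np.clip(np.linspace(pc - step, pc + step, 21),
                                  BOUND_LO, BOUND_HI))
            b_arr = np.clip(np.linspace(bc - step, bc + step, 21),
                            BOUND_LO, BOUND_HI)
            vals = objective_grid(p_arr, b_arr)
            ip, ib = np.unravel_index(np.argmax(vals), vals.shape)
            pc, bc = float(p_arr[ip]), float(b_arr[ib])
            step /= 10.0
        return pc, bc

    p_arr = np.array([p0]) if p0 is not None else base
    vals = objective_grid(p_arr, base)
    ip, ib = np.unravel_index(np.argmax(vals), vals.shape)
    starts = [(float(p_arr[ip]), float(base[ib]))]
    starts += [(min(max(p, BOUND_LO), BOUND_HI), min(max(b, BOUND_LO), BOUND_HI))
               for p, b in seed_points]

    best = None
    for pc, bc in starts:
        cand = local_max(pc, bc, GRID_STEP)
        val = float(objective_grid(np.array([cand[0]]), np.array([cand[1]]))[0, 0])
        if best is None or val > best[0] + 1e-12:
            best = (val, cand)
    (_, (phat, bhat)) = best
    return phat, bhat, best[0]


def fit_ml(sample, fixed_p: float | None = None) -> FitResult:
    """Maximum-likelihood fit of (p, b), optionally with p held fixed."""
    s = as_sample(sample)
    values = s.values
    if fixed_p is not None and not (0.0 <= fixed_p <= 1.0):
        raise ValueError("fixed_p must be in [0, 1]")

    if np.all(values == values[0]):
        # all-identical sample: likelihood is maximized at the degenerate
        # point mass (b -> 1, p = the common value), or at the p boundary
        # for all-0 / all-1 data
        v = float(values[0])
        p = fixed_p if fixed_p is not None else v
        b = 1.0 if not (v in (0.0, 1.0) and fixed_p is None) else 0.0
        if v in (0.0, 1.0) and fixed_p is None:
            p, b = v, 1.0
        params = KimuraParams(p, b)
        return FitResult(
            params=params, method="mle", loglik=kimura_loglik(params, s),
            fixed_p=fixed_p, degenerate=True,
        )

    def obj(p_arr, b_arr):
        return _loglik_grid(values, p_arr, b_arr)

    seeds = []
    try:
        mom = fit_mom(s)
        seeds.append((mom.params.p if fixed_p is None else fixed_p, mom.params.b))
    except ValueError:
        pass
    phat, bhat, ll = _zoom_maximize(obj, fixed_p, seed_points=seeds)
    params = KimuraParams(phat if fixed_p is None else fixed_p, bhat)
    return FitResult(
        params=params, method="mle", loglik=float(ll), fixed_p=fixed_p,
        converged=True, degenerate=bhat >= BOUND_HI,
    )


def fit_min_ks(sample, fixed_p: float | None = None) -> FitResult:
    """Parameterization minimizing the one-sample KS distance to the data."""
    s = as_sample(sample)

    def obj(p_arr, b_arr):
        return -_ks_grid(s.values, p_arr, b_arr)

    seeds = []
    try:
        mom = fit_mom(s)
        seeds.append((mom.params.p if fixed_p is None else fixed_p, mom.params.b))
    except ValueError:
        pass
    ml = fit_ml(s, fixed_p=fixed_p)
    if not ml.degenerate:
        seeds.append((ml.params.p, ml.params.b))
    phat, bhat, negd = _zoom_maximize(obj, fixed_p, seed_points=seeds)
    params = KimuraParams(phat if fixed_p is None else fixed_p, bhat)
    return FitResult(
        params=params, method="min_ks", ks_distance=float(-negd),
        loglik=kimura_loglik(params, s), fixed_p=fixed_p,
    )


# -- confidence intervals ------------------------------------------------

def _profile_loglik_b(values: np.ndarray, b: float, fixed_p: float | None) -> float:
    """Log-likelihood at b with p either fixed or profiled out."""
    if fixed_p is not None:
        return float(_loglik_grid(values, np.array([fixed_p]), np.array([b]))[0, 0])
    grid = np.linspace(GRID_LO, GRID_HI, 100)
    vals = _loglik_grid(values, grid, np.array([b]))[:, 0]
    pc = float(grid[int(np.argmax(vals))])
    step = GRID_STEP
    for _ in range(REFINE_ROUNDS):
        local = np.clip(np.linspace(pc - step, pc + step, 21), BOUND_LO, BOUND_HI)
        vals = _loglik_grid(values, local, np.array([b]))[:, 0]
        pc = float(local[int(np.argmax(vals))])
        step /= 10.0
    return float(_loglik_grid(values, np.array([pc]), np.array([b]))[0, 0])


def confint_b(
    sample,
    fit: FitResult,
    method: str = "profile",
    level: float = 0.95,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Confidence interval for b from the likelihood or a bootstrap.

    "profile" (default) inverts the likelihood-ratio statistic on the
    profile log-likelihood in b — asymmetric, respects the [0, 1]
    boundary, and is the construction used for the worked examples.
    "fisher" uses the numerical curvature of the profile log-likelihood
    at the MLE and a normal interval (falls back to bootstrap when the
    curvature is non-positive, e.g. at boundary fits).  "bootstrap"
    refits the same model on B resamples and takes percentile endpoints.
    """
    if fit.method != "mle":
        raise ValueError("confidence intervals are defined for ML fits")
    s = as_sample(sample)
    bhat = fit.params.b

    if method == "profile":
        from scipy.stats import chi2

        cut = (fit.loglik if fit.loglik is not None
               else _profile_loglik_b(s.values, bhat, fit.fixed_p))
        cut -= chi2.ppf(level, 1) / 2.0
        grid = np.linspace(BOUND_LO, BOUND_HI, 400)
        lls = np.array([_profile_loglik_b(s.values, float(b), fit.fixed_p)
                        for b in grid])
        inside = lls >= cut
        if not inside.any():
            lo = hi = bhat
        else:
            def bisect(a, c):
                # bracket [a, c] with exactly one crossing of the cutoff
                for _ in range(30):
                    m = 0.5 * (a + c)
                    if _profile_loglik_b(s.values, m, fit.fixed_p) >= cut:
                        c = m
                    else:
                        a = m
                return 0.5 * (a + c)

            first = int(np.argmax(inside))
            last = len(grid) - 1 - int(np.argmax(inside[::-1]))
            lo = grid[0] if first == 0 else bisect(grid[first - 1], grid[first])
            hi = (grid[-1] if last == len(grid) - 1
                  else bisect(grid[last + 1], grid[last]))
            lo, hi = min(lo, hi), max(lo, hi)
    elif method == "fisher":
        eps = 1e-3
        pts = np.clip([bhat - eps, bhat, bhat + eps], BOUND_LO, BOUND_HI)
        ll = [_profile_loglik_b(s.values, float(b), fit.fixed_p) for b in pts]
        d2 = (ll[0] - 2 * ll[1] + ll[2]) / eps**2
        if not math.isfinite(d2) or d2 >= -1e-8:
            import warnings

            warnings.warn(
                "non-positive observed information at the fit; "
                "falling back to bootstrap interval"
            )
            return confint_b(s, fit, method="bootstrap", level=level, B=B, seed=seed)
        se = 1.0 / math.sqrt(-d2)
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        lo, hi = bhat - z * se, bhat + z * se
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(B)
        for k in range(B):
            idx = rng.integers(0, s.n, s.n)
            res = HeteroplasmySample(s.values[idx])
            boots[k] = fit_ml(res, fixed_p=fit.fixed_p).params.b
        alpha = 1.0 - level
        lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    else:
        raise ValueError(f"unknown CI method {method!r}")

    lo, hi = max(float(lo), 0.0), min(float(hi), 1.0)
    fit.ci_b = (lo, hi)
    fit.ci_method = method
    fit.ci_level = level
    return lo, hi


# -- the classical moment estimator --------------------------------------

def bottleneck_classic(
    sample,
    p_source: str = "sample_mean",
    variance_kind: str = "sample",
) -> ClassicBottleneck:
    """The textbook bottleneck estimate n_b = p(1-p)/V.

    Provided for comparison; estimates below one segregating unit are
    flagged as sub-unit (a bottleneck cannot transmit less than one unit
    of information), which is precisely the pathology the likelihood
    route avoids.
    """
    s = as_sample(sample)
    if p_source == "sample_mean":
        p = s.mean
    elif p_source == "reference_h":
        if s.reference_h is None:
            raise ValueError("sample carries no reference heteroplasmy")
        p = s.reference_h
    else:
        raise ValueError(f"unknown p_source {p_source!r}")
    if variance_kind == "sample":
        V = s.s2
    elif variance_kind == "population":
        V = float(np.var(s.values, ddof=0))
    else:
        raise ValueError(f"unknown variance_kind {variance_kind!r}")
    if V <= 0.0:
        raise ValueError("variance is zero; classic estimator undefined")
    nb = p * (1.0 - p) / V
    return ClassicBottleneck(
        n_b=nb, p_used=p, variance_used=V,
        p_source=p_source, variance_kind=variance_kind,
        sub_unit=nb < 1.0,
    )
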