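"""Kimura distribution of allele frequency under pure neutral drift.

The distribution describes the heteroplasmy fraction ``h`` of a mutant
mtDNA allele after random drift has acted on an initial frequency ``p``.
It is of mixed type: point masses at ``h = 0`` (loss) and ``h = 1``
(fixation) plus a continuous density on ``(0, 1)``.  The amount of drift
is summarised by a retention parameter ``b`` in ``[0, 1]``: ``b = 1``
means no drift (a point mass at ``p``); smaller ``b`` means more
variance, with population moments

    mean     = p
    variance = p (1 - p) (1 - b)

``b`` maps onto the effective germline bottleneck size via
``n_b = 1 / (1 - b)``.

Numerically the density is the classical eigenfunction expansion

    phi(h) = sum_i i(i+1)(2i+1) p q F_i(p) F_i(h) b^{i(i+1)/2}

with ``q = 1 - p`` and ``F_i(x) = 2F1(1 - i, i + 2; 2; x)``, a finite
polynomial evaluated here through the Gegenbauer identity
``F_i(x) = 2/(i(i+1)) C_{i-1}^{3/2}(1 - 2x)``, which is stable at high
degree.  The CDF integrates the series term-wise through the Legendre
antiderivative ``C_{n}^{3/2}(z) = P'_{n+1}(z)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import eval_gegenbauer, eval_legendre

__all__ = [
    "KimuraParams",
    "HeteroplasmySample",
    "kimura_point_masses",
    "kimura_density",
    "kimura_cdf",
    "kimura_moments",
    "kimura_sample",
    "kimura_loglik",
    "bottleneck_from_b",
    "b_from_bottleneck",
]

# -- numerical policy ---------------------------------------------------
TERM_TOL = 1e-12        # truncate series when the term bound drops below this
MAX_TERMS = 1000        # hard cap on series length
B_DEGENERATE = 1e-6     # 1 - b below this: treat as point mass at p
ATOM_TOL = 1e-12        # |h| or |1-h| below this counts as an atom observation
LOGLIK_FLOOR = -1e10    # sentinel for zero-probability observations
_INV_CDF_GRID = 4097    # grid size for inverse-CDF sampling


class KimuraNumericalError(RuntimeError):
    """Raised when the series or an integration step fails to converge."""


@dataclass(frozen=True)
class KimuraParams:
    """Parameter pair (p, b) of the neutral-drift distribution.

    p : initial heteroplasmy fraction in [0, 1]
    b : drift/retention parameter in [0, 1]; b = 1 means no drift
    """

    p: float
    b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0) or not math.isfinite(self.p):
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not (0.0 <= self.b <= 1.0) or not math.isfinite(self.b):
            raise ValueError(f"b must be in [0, 1], got {self.b}")

    @property
    def n_b(self) -> float:
        """Effective bottleneck size 1/(1-b); +inf at b = 1."""
        return bottleneck_from_b(self.b)

    @property
    def degenerate(self) -> bool:
        """True when the distribution collapses to a point mass at p."""
        return 1.0 - self.b < B_DEGENERATE


@dataclass
class HeteroplasmySample:
    """An ordered set of heteroplasmy fractions, each in [0, 1].

    reference_h is an optional maternal/initial heteroplasmy measurement
    attached to the sample (itself a sample, not a population value).
    """

    values: np.ndarray
    reference_h: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("sample must be a non-empty 1-D collection")
        if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v > 1):
            raise ValueError("heteroplasmy values must be finite and in [0, 1]")
        if self.reference_h is not None and not (0.0 <= self.reference_h <= 1.0):
            raise ValueError("reference_h must be in [0, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def s2(self) -> float:
        """Sample variance with the (n-1) denominator."""
        if self.n < 2:
            raise ValueError("sample variance requires n >= 2")
        return float(np.var(self.values, ddof=1))


def as_sample(x) -> HeteroplasmySample:
    """Coerce an array-like (or pass through a sample) to HeteroplasmySample."""
    if isinstance(x, HeteroplasmySample):
        return x
    return HeteroplasmySample(np.asarray(x, dtype=float))


# -- series plumbing ----------------------------------------------------

def _n_terms(b: float) -> int:
    """Series length so the bound (2i+1) * i(i+1)/2 * b^{i(i+1)/2} < TERM_TOL."""
    if b <= 0.0:
        return 1
    logb = math.log(b)
    for i in range(1, MAX_TERMS + 1):
        bound = math.log(2 * i + 1) + math.log(i * (i + 1) / 2) + i * (i + 1) / 2 * logb
        if bound < math.log(TERM_TOL):
            return i
    raise KimuraNumericalError(
        f"Kimura series did not converge within {MAX_TERMS} terms at b={b}"
    )


def _shape_fn(i: np.ndarray, x: np.ndarray) -> np.ndarray:
    """F_i(x) = 2F1(1-i, i+2; 2; x), shape (len(i), len(x))."""
    i = np.asarray(i)[:, None]
    x = np.asarray(x, dtype=float)[None, :]
    return 2.0 / (i * (i + 1.0)) * eval_gegenbauer(i - 1, 1.5, 1.0 - 2.0 * x)


def _series_weights(b: float, i: np.ndarray) -> np.ndarray:
    return b ** (i * (i + 1) / 2.0)


# -- distribution functions ---------------------------------------------

def kimura_point_masses(params: KimuraParams) -> tuple[float, float]:
    """Probabilities of loss (h = 0) and fixation (h = 1)."""
    p, b = params.p, params.b
    q = 1.0 - p
    if params.degenerate:
        return (1.0 if p == 0.0 else 0.0), (1.0 if p == 1.0 else 0.0)
    if p == 0.0:
        return 1.0, 0.0
    if p == 1.0:
        return 0.0, 1.0
    i = np.arange(1, _n_terms(b) + 1)
    c = (2 * i + 1) * p * q * _series_weights(b, i)
    fp = _shape_fn(i, np.array([p]))[:, 0]
    m0 = q - float(np.sum(c * fp))
    m1 = p + float(np.sum(c * ((-1.0) ** i) * fp))
    # tiny negative round-off is clipped; real mass errors fail the
    # normalization invariant tests instead
    return min(max(m0, 0.0), 1.0), min(max(m1, 0.0), 1.0)


def kimura_density(params: KimuraParams, h) -> np.ndarray | float:
    """Continuous density on (0, 1); raises on h outside the open interval."""
    harr = np.atleast_1d(np.asarray(h, dtype=float))
    if np.any(harr <= 0.0) or np.any(harr >= 1.0):
        raise ValueError("density is defined on the open interval (0, 1)")
    p, b = params.p, params.b
    q = 1.0 - p
    if params.degenerate or p == 0.0 or p == 1.0:
        out = np.zeros_like(harr)
        return out if np.ndim(h) else float(out[0])
    i = np.arange(1, _n_terms(b) + 1)
    c = i * (i + 1) * (2 * i + 1) * p * q * _series_weights(b, i)
    fp = _shape_fn(i, np.array([p]))[:, 0]
    fx = _shape_fn(i, harr)
    out = (c * fp) @ fx
    # the true density is strictly positive on (0,1) for interior p;
    # deep-tail values below the series' cancellation noise are floored
    # at that noise level instead of returning a sign-flipped ~0
    noise = 1e-16 * (np.abs(c * fp) @ np.abs(fx))
    out = np.maximum(out, noise)
    return out if np.ndim(h) else float(out[0])


def _cdf_arr(params: KimuraParams, harr: np.ndarray) -> np.ndarray:
    """Right-continuous CDF on [0, 1], vectorized (atoms included)."""
    p, b = params.p, params.b
    q = 1.0 - p
    if params.degenerate:
        return np.where(harr >= p, 1.0, 0.0)
    m0, m1 = kimura_point_masses(params)
    out = np.full(harr.shape, m0)
    inner = (harr > 0.0) & (harr < 1.0)
    if np.any(inner) and p not in (0.0, 1.0):
        i = np.arange(1, _n_terms(b) + 1)
        c = (2 * i + 1) * p * q * _series_weights(b, i)
        fp = _shape_fn(i, np.array([p]))[:, 0]
        leg = eval_legendre(i[:, None], 1.0 - 2.0 * harr[inner][None, :])
        out[inner] = m0 + (c * fp) @ (1.0 - leg)
    elif np.any(inner):
        out[inner] = m0
    out[harr >= 1.0] = 1.0
    return np.clip(out, 0.0, 1.0)


def kimura_cdf(params: KimuraParams, h) -> np.ndarray | float:
    """P(H <= h) including the point masses at 0 and 1."""
    harr = np.atleast_1d(np.asarray(h, dtype=float))
    if np.any(harr < 0.0) or np.any(harr > 1.0):
        raise ValueError("cdf argument must lie in [0, 1]")
    out = _cdf_arr(params, harr)
    return out if np.ndim(h) else float(out[0])


def kimura_moments(params: KimuraParams) -> tuple[float, float, float]:
    """(mean, variance, fourth central moment), all in closed form.

    The raw moments follow from the Wright-Fisher pure-drift moment
    recursion, whose eigenvalues give powers b, b^3, b^6 for the second,
    third and fourth moments respectively.
    """
    p, b = params.p, params.b
    q = 1.0 - p
    pq = p * q
    mean = p
    var = pq * (1.0 - b)
    m2 = p - pq * b
    m3 = p - 1.5 * pq * b + pq * (0.5 - p) * b**3
    m4 = p - 1.8 * pq * b + pq * (1.0 - 2.0 * p) * b**3 + pq * (pq - 0.2) * b**6
    mu4 = m4 - 4.0 * p * m3 + 6.0 * p**2 * m2 - 3.0 * p**4
    return mean, var, max(mu4, 0.0)


# -- sampling -----------------------------------------------------------

def _continuous_inverse_table(params: KimuraParams) -> tuple[np.ndarray, np.ndarray]:
    """Monotone (cdf, h) table of the continuous part for inverse sampling."""
    h = np.linspace(0.0, 1.0, _INV_CDF_GRID)
    cdf = _cdf_arr(params, h)
    m0, m1 = kimura_point_masses(params)
    cont = cdf.copy()
    cont[-1] = 1.0 - m1   # left limit at 1: strip the fixation atom
    cont = np.maximum.accumulate(cont)
    return cont, h


def _sample_values(
    params: KimuraParams,
    shape,
    rng: np.random.Generator,
    table: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Inverse-CDF draws of the given shape; table is reusable across calls."""
    p = params.p
    if params.degenerate:
        return np.full(shape, p)
    m0, m1 = kimura_point_masses(params)
    u = rng.random(shape)
    out = np.empty(np.shape(u))
    lo = u < m0
    hi = u > 1.0 - m1
    mid = ~(lo | hi)
    out[lo] = 0.0
    out[hi] = 1.0
    if np.any(mid):
        if table is None:
            table = _continuous_inverse_table(params)
        cont, h = table
        out[mid] = np.interp(u[mid], cont, h)
    return np.clip(out, 0.0, 1.0)


def kimura_sample(
    params: KimuraParams, n: int, seed: int | np.random.Generator
) -> HeteroplasmySample:
    """Draw n values by inverse-CDF with explicit point-mass handling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return HeteroplasmySample(_sample_values(params, n, rng), reference_h=params.p)


# -- likelihood ---------------------------------------------------------

def _split_atoms(values: np.ndarray) -> tuple[int, int, np.ndarray]:
    """Counts of observations at the atoms 0 and 1, plus interior values."""
    at0 = np.abs(values) < ATOM_TOL
    at1 = np.abs(1.0 - values) < ATOM_TOL
    return int(at0.sum()), int(at1.sum()), values[~(at0 | at1)]


def kimura_loglik(params: KimuraParams, sample) -> float:
    """Mixed log-likelihood: log point masses at the atoms, log density inside.

    Zero-probability observations contribute the LOGLIK_FLOOR sentinel
    instead of -inf so optimizers stay finite.
    """
    values = as_sample(sample).values
    n0, n1, inner = _split_atoms(values)
    p, b = params.p, params.b
    if params.degenerate:
        ok_atoms = (n0 == 0 or p == 0.0) and (n1 == 0 or p == 1.0)
        ok_inner = np.all(np.abs(inner - p) < ATOM_TOL)
        return 0.0 if (ok_atoms and ok_inner) else LOGLIK_FLOOR
    return float(_loglik_grid(values, np.array([p]), np.array([b]))[0, 0])


def _loglik_grid(values: np.ndarray, p_arr: np.ndarray, b_arr: np.ndarray) -> np.ndarray:
    """Log-likelihood on a (p, b) grid, shape (len(p_arr), len(b_arr)).

    Shared Gegenbauer/series factors are computed once per dataset; this
    is what makes the grid-seeded fits cheap.
    """
    values = np.asarray(values, dtype=float)
    p_arr = np.asarray(p_arr, dtype=float)
    b_arr = np.asarray(b_arr, dtype=float)
    n0, n1, inner = _split_atoms(values)
    xs, xcounts = np.unique(inner, return_counts=True)

    kmax = max(_n_terms(b) for b in b_arr if 1.0 - b >= B_DEGENERATE) if np.any(
        1.0 - b_arr >= B_DEGENERATE) else 1
    i = np.arange(1, kmax + 1)
    fp = _shape_fn(i, p_arr)                      # (K, P)
    fx = _shape_fn(i, xs) if xs.size else np.zeros((kmax, 0))
    sign = (-1.0) ** i
    q_arr = 1.0 - p_arr
    pq = p_arr * q_arr

    out = np.empty((p_arr.size, b_arr.size))
    for jb, b in enumerate(b_arr):
        if 1.0 - b < B_DEGENERATE:
            col = np.full(p_arr.size, LOGLIK_FLOOR)
            if n0 == 0 and n1 == 0 and xs.size == 1:
                col[np.abs(p_arr - xs[0]) < ATOM_TOL] = 0.0
            out[:, jb] = col
            continue
        kb = _n_terms(b)                          # same truncation as the
        ib = i[:kb]                               # scalar evaluators
        w = _series_weights(b, ib)
        c_mass = (2 * ib + 1) * w                 # (kb,)
        c_dens = ib * (ib + 1) * c_mass
        s_mass = fp[:kb].T @ c_mass               # sum_i (2i+1) w_i F_i(p)
        s_mass_alt = fp[:kb].T @ (sign[:kb] * c_mass)
        m0 = np.clip(q_arr - pq * s_mass, 0.0, 1.0)
        m1 = np.clip(p_arr + pq * s_mass_alt, 0.0, 1.0)
        col = np.zeros(p_arr.size)
        if n0:
            col += n0 * np.where(m0 > 0, np.log(np.maximum(m0, 1e-300)), LOGLIK_FLOOR)
        if n1:
            col += n1 * np.where(m1 > 0, np.log(np.maximum(m1, 1e-300)), LOGLIK_FLOOR)
        if xs.size:
            dens = pq[:, None] * ((fp[:kb] * c_dens[:, None]).T @ fx[:kb])  # (P, m)
            noise = 1e-16 * np.abs(pq)[:, None] * (
                (np.abs(fp[:kb]) * c_dens[:, None]).T @ np.abs(fx[:kb])
            )
            dens = np.maximum(dens, noise)
            logd = np.where(dens > 0, np.log(np.maximum(dens, 1e-300)), LOGLIK_FLOOR)
            col += logd @ xcounts
        out[:, jb] = np.maximum(col, LOGLIK_FLOOR)
    return out


# -- bottleneck transform ------------------------------------------------

def bottleneck_from_b(b: float) -> float:
    """Effective bottleneck size n_b = 1/(1-b); b = 1 maps to +inf."""
    if not (0.0 <= b <= 1.0):
        raise ValueError(f"b must be in [0, 1], got {b}")
    if b == 1.0:
        return math.inf
    return 1.0 / (1.0 - b)


def b_from_bottleneck(n_b: float) -> float:
    """Inverse transform b = 1 - 1/n_b for n_b >= 1 (inf maps to 1)."""
    if n_b < 1.0:
        raise ValueError(f"bottleneck size must be >= 1, got {n_b}")
    if math.isinf(n_b):
        return 1.0
    return 1.0 - 1.0 / n_b
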