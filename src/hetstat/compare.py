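"""Comparing germline bottleneck sizes between groups of heteroplasmy sets.

A bottleneck size is the reciprocal of a variance-like quantity and is
far from normally distributed, so t-tests on bottleneck estimates are
invalid.  Instead, two nested Kimura models are compared by a
likelihood-ratio test:

* full model:  every set has its own initial heteroplasmy p_i, every
  group has its own drift parameter b_j;
* null model:  every set has its own p_i, one common b for all groups.

With maximized log-likelihoods l1 (full) and l2 (null), the statistic
Lambda = -2 (l2 - l1) is referred to a chi-squared distribution with
(number of groups - 1) degrees of freedom.

Because the per-set p's separate conditionally on b, the joint
maximization reduces to nested one-dimensional searches: profile each
set's p at a trial b, then maximize the summed profile over b.  Group
bottleneck intervals come from the chi-squared(1) profile-likelihood
cutoff on the same profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, ttest_ind

from .fitting import BOUND_HI, BOUND_LO, GRID_HI, GRID_LO, GRID_STEP, REFINE_ROUNDS
from .kimura import HeteroplasmySample, _loglik_grid, as_sample, bottleneck_from_b

__all__ = [
    "GroupedSamples",
    "GroupFit",
    "LRTResult",
    "loglik_grouped",
    "bottleneck_lrt",
    "two_sample_location_test",
]


@dataclass
class GroupedSamples:
    """Groups of heteroplasmy sets: groups[j][i] is set i of group j."""

    groups: list[list[HeteroplasmySample]]
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.groups = [[as_sample(s) for s in g] for g in self.groups]
        if any(len(g) == 0 for g in self.groups) or len(self.groups) == 0:
            raise ValueError("every group must contain at least one set")
        if self.group_labels is None:
            self.group_labels = [f"group{j + 1}" for j in range(len(self.groups))]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_sets(self) -> int:
        return sum(len(g) for g in self.groups)


@dataclass
class GroupFit:
    """Per-group result of a shared-b fit."""

    b: float
    loglik: float
    p_per_set: list[float]
    ci_b: tuple[float, float] | None = None

    @property
    def n_b(self) -> float:
        return bottleneck_from_b(self.b)

    @property
    def ci_n_b(self) -> tuple[float, float] | None:
        if self.ci_b is None:
            return None
        return bottleneck_from_b(self.ci_b[0]), bottleneck_from_b(self.ci_b[1])


@dataclass
class LRTResult:
    """Likelihood-ratio test of equal bottleneck size across groups."""

    lam: float
    df: int
    p_value: float
    fit_full: list[GroupFit]         # one per group (group-specific b)
    fit_null: GroupFit               # shared b across all sets
    loglik_full: float
    loglik_null: float


# -- profile machinery ---------------------------------------------------

_P_GRID = np.linspace(GRID_LO, GRID_HI, 100)


def _set_profile(values: np.ndarray, b: float) -> tuple[float, float]:
    """(max_p loglik, argmax p) for one set at a fixed b."""
    barr = np.array([b])
    vals = _loglik_grid(values, _P_GRID, barr)[:, 0]
    pc = float(_P_GRID[int(np.argmax(vals))])
    step = GRID_STEP
    for _ in range(REFINE_ROUNDS):
        local = np.clip(np.linspace(pc - step, pc + step, 21), BOUND_LO, BOUND_HI)
        vals = _loglik_grid(values, local, barr)[:, 0]
        pc = float(local[int(np.argmax(vals))])
        step /= 10.0
    ll = float(_loglik_grid(values, np.array([pc]), barr)[0, 0])
    return ll, pc


def _sets_profile(sets: list[HeteroplasmySample], b: float) -> tuple[float, list[float]]:
    lls, ps = zip(*(_set_profile(s.values, b) for s in sets))
    return float(sum(lls)), list(ps)


def _profile_curve(sets: list[HeteroplasmySample], b_arr: np.ndarray) -> np.ndarray:
    """Summed p-profiled log-likelihood over a whole b grid in one pass.

    The p maximization is over the coarse grid only (no local
    refinement) — accurate to O(step^2) in the profile value, which is
    ample for locating maxima and cutoff crossings; refined values are
    recomputed at the points that matter.
    """
    total = np.zeros(b_arr.size)
    for s in sets:
        total += _loglik_grid(s.values, _P_GRID, b_arr).max(axis=0)
    return total


def _maximize_over_b(sets: list[HeteroplasmySample]) -> GroupFit:
    """Shared-b fit for a collection of sets, p profiled per set."""
    b_grid = np.linspace(GRID_LO, GRID_HI, 100)
    lls = _profile_curve(sets, b_grid)
    bc = float(b_grid[int(np.argmax(lls))])
    step = GRID_STEP
    for _ in range(REFINE_ROUNDS):
        local = np.clip(np.linspace(bc - step, bc + step, 21), BOUND_LO, BOUND_HI)
        vals = _profile_curve(sets, local)
        bc = float(local[int(np.argmax(vals))])
        step /= 10.0
    ll, ps = _sets_profile(sets, bc)
    return GroupFit(b=bc, loglik=ll, p_per_set=ps)


def _profile_ci_b(sets: list[HeteroplasmySample], fit: GroupFit,
                  level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood interval: {b : l(b) >= l(bhat) - chi2_1(level)/2}."""
    cut = fit.loglik - chi2.ppf(level, 1) / 2.0
    grid = np.linspace(BOUND_LO, BOUND_HI, 400)
    lls = _profile_curve(sets, grid)
    inside = lls >= cut
    if not inside.any():
        return fit.b, fit.b

    def bisect(lo, hi):
        # lo outside, hi inside the confidence region
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if _sets_profile(sets, mid)[0] >= cut:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    first, last = int(np.argmax(inside)), len(grid) - 1 - int(np.argmax(inside[::-1]))
    lo = grid[first] if first == 0 else bisect(grid[first - 1], grid[first])
    hi = (grid[last] if last == len(grid) - 1
          else bisect(grid[last + 1], grid[last]))
    return float(min(lo, hi)), float(max(lo, hi))


# -- public API ----------------------------------------------------------

def loglik_grouped(data: GroupedSamples, shared_b: bool):
    """Maximized log-likelihood of the grouped model.

    shared_b=False: one b per group (full model); returns
    (loglik, [GroupFit per group]).  shared_b=True: a single b across
    all sets (null model); returns (loglik, GroupFit over all sets).
    """
    if shared_b:
        fit = _maximize_over_b([s for g in data.groups for s in g])
        return fit.loglik, fit
    fits = [_maximize_over_b(g) for g in data.groups]
    return float(sum(f.loglik for f in fits)), fits


def bottleneck_lrt(
    data: GroupedSamples, ci_level: float = 0.95, compute_ci: bool = True
) -> LRTResult:
    """LRT of equal drift parameter (hence bottleneck size) across groups.

    compute_ci=False skips the per-group profile-likelihood intervals
    (useful in calibration loops where only the p-value matters).
    """
    if data.n_groups < 2:
        raise ValueError("need at least 2 groups to compare")
    l1, fits_full = loglik_grouped(data, shared_b=False)
    l2, fit_null = loglik_grouped(data, shared_b=True)
    lam = -2.0 * (l2 - l1)
    if lam < -1e-6:
        raise RuntimeError(
            f"null model out-scored the full model (Lambda={lam}); "
            "grouped optimization failed"
        )
    lam = max(lam, 0.0)
    df = data.n_groups - 1
    if compute_ci:
        for g, fit in zip(data.groups, fits_full):
            fit.ci_b = _profile_ci_b(g, fit, level=ci_level)
    return LRTResult(
        lam=lam,
        df=df,
        p_value=float(chi2.sf(lam, df)),
        fit_full=fits_full,
        fit_null=fit_null,
        loglik_full=l1,
        loglik_null=l2,
    )


def two_sample_location_test(a, b) -> float:
    """Equal-variance two-sample t-test p-value on the heteroplasmy *means*.

    Provided as the classical contrast for location questions only.  Do
    not apply it to variances or bottleneck sizes: a sample variance is
    not normally distributed and its reciprocal even less so — that is
    what :func:`bottleneck_lrt` is for.
    """
    av, bv = as_sample(a).values, as_sample(b).values
    if av.size < 2 or bv.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(av, ddof=1) == 0.0 and np.var(bv, ddof=1) == 0.0:
        # degenerate pooled variance: identical constants are indistinguishable,
        # different constants are infinitely separated
        return 1.0 if av.mean() == bv.mean() else 0.0
    return float(ttest_ind(av, bv, equal_var=True).pvalue)
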