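"""Data ingestion, synthetic-data generation, and the analysis roadmap.

Input files are CSV/TSV with columns (set_id, group_id, heteroplasmy,
reference_h) — only ``heteroplasmy`` is required — or a bare single
column of values.  Heteroplasmy columns reported in percent are
auto-detected (any value above 1 but within [0, 100]) and divided by
100, loudly, since all downstream code works on the [0, 1] scale.

Also here: uniform-within-bin resampling for histogram-only datasets,
a noise-perturbation utility for sensitivity analyses, the grouped
Kimura sampler used throughout the test simulations, and the
decision-tree recommender for which statistical route to take.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare import GroupedSamples
from .kimura import HeteroplasmySample, KimuraParams, kimura_sample

__all__ = [
    "BinnedData",
    "AnalysisConfig",
    "read_samples",
    "write_samples",
    "resample_binned",
    "perturb",
    "simulate_grouped",
    "recommend_method",
]

log = logging.getLogger("hetstat")


@dataclass
class AnalysisConfig:
    """Run-level knobs shared by the CLI subcommands."""

    seed: int = 0
    B_bootstrap: int = 1000
    B_ks: int = 5000
    grid_resolution: float = 0.01
    ci_level: float = 0.95
    ci_method: str = "profile"
    percent_autodetect: bool = True

    def __post_init__(self) -> None:
        if self.B_bootstrap < 100 or self.B_ks < 100:
            raise ValueError("resample counts must be >= 100")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class BinnedData:
    """Histogram representation: edges spanning part of [0, 1] plus counts."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        c = np.asarray(self.counts, dtype=int)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(e < 0) or np.any(e > 1):
            raise ValueError("bin edges must lie in [0, 1]")
        if c.size != e.size - 1 or np.any(c < 0):
            raise ValueError("need one nonnegative count per bin")
        self.bin_edges, self.counts = e, c


def _normalize_column(values: np.ndarray, autodetect: bool, label: str) -> np.ndarray:
    if np.any(values < 0) or np.any(values > 100):
        bad = values[(values < 0) | (values > 100)]
        raise ValueError(f"{label}: heteroplasmy values outside [0, 100]: {bad[:5]}")
    if autodetect and np.any(values > 1.0):
        log.warning(
            "%s: values above 1 detected; interpreting the column as "
            "percentages and dividing by 100", label,
        )
        values = values / 100.0
    return values


def read_samples(
    path,
    format: str = "csv",
    percent_autodetect: bool = True,
) -> GroupedSamples:
    """Read grouped heteroplasmy samples from disk.

    format "csv"/"tsv": a header with at least a ``heteroplasmy``
    column; optional ``set_id``, ``group_id`` and per-set
    ``reference_h``.  format "single_column": one bare value per line,
    read as a single set in a single group.
    """
    if format == "single_column":
        vals = np.loadtxt(path, dtype=float, ndmin=1)
        vals = _normalize_column(vals, percent_autodetect, str(path))
        return GroupedSamples([[HeteroplasmySample(vals, label="set1")]])
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if "heteroplasmy" not in df.columns:
        raise ValueError(f"{path}: missing required column 'heteroplasmy'")
    if df["heteroplasmy"].isna().any():
        row = int(df.index[df["heteroplasmy"].isna()][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: malformed heteroplasmy value at line {row}")
    df = df.copy()
    df["heteroplasmy"] = _normalize_column(
        df["heteroplasmy"].to_numpy(dtype=float), percent_autodetect, str(path)
    )
    if "set_id" not in df.columns:
        df["set_id"] = "set1"
    if "group_id" not in df.columns:
        df["group_id"] = "group1"
    groups, labels = [], []
    for gid, gdf in df.groupby("group_id", sort=False):
        sets = []
        for sid, sdf in gdf.groupby("set_id", sort=False):
            ref = None
            if "reference_h" in sdf.columns and sdf["reference_h"].notna().any():
                ref = float(sdf["reference_h"].dropna().iloc[0])
                if ref > 1.0:
                    ref = ref / 100.0
            sets.append(
                HeteroplasmySample(
                    sdf["heteroplasmy"].to_numpy(), reference_h=ref, label=str(sid)
                )
            )
        groups.append(sets)
        labels.append(str(gid))
    return GroupedSamples(groups, group_labels=labels)


def write_samples(data: GroupedSamples, path) -> None:
    """Write grouped samples back to CSV (full float precision)."""
    rows = []
    for gid, sets in zip(data.group_labels, data.groups):
        for s in sets:
            for v in s.values:
                rows.append(
                    {
                        "set_id": s.label or "set1",
                        "group_id": gid,
                        "heteroplasmy": repr(float(v)),
                        "reference_h": "" if s.reference_h is None
                        else repr(float(s.reference_h)),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def input_digest(path) -> str:
    """SHA-256 of the raw input bytes, for replayable run logs."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def resample_binned(binned: BinnedData, seed: int = 0) -> HeteroplasmySample:
    """Un-bin a histogram by drawing each count uniformly within its bin.

    This is the un-binning rule that most faithfully reproduces analyses
    of histogram-only datasets; repeated draws with different seeds give
    the p-value *ranges* such data honestly support.
    """
    if binned.counts.sum() < 1:
        raise ValueError("binned data contain no observations")
    rng = np.random.default_rng(seed)
    parts = [
        rng.uniform(lo, hi, size=int(c))
        for lo, hi, c in zip(binned.bin_edges[:-1], binned.bin_edges[1:], binned.counts)
        if c > 0
    ]
    return HeteroplasmySample(np.concatenate(parts))


def perturb(sample, noise_level: float, seed: int = 0) -> HeteroplasmySample:
    """Add uniform noise in [-noise_level, +noise_level], clipped to [0, 1]."""
    from .kimura import as_sample

    if not (0.0 <= noise_level < 1.0):
        raise ValueError("noise_level must be in [0, 1)")
    s = as_sample(sample)
    if noise_level == 0.0:
        return HeteroplasmySample(s.values.copy(), reference_h=s.reference_h,
                                  label=s.label)
    rng = np.random.default_rng(seed)
    noisy = s.values + rng.uniform(-noise_level, noise_level, s.n)
    return HeteroplasmySample(np.clip(noisy, 0.0, 1.0),
                              reference_h=s.reference_h, label=s.label)


def simulate_grouped(
    params_per_set: list[KimuraParams],
    n_per_set: list[int],
    seed: int = 0,
    group_of_set: list[int] | None = None,
) -> GroupedSamples:
    """Seeded synthetic grouped dataset from per-set Kimura parameters.

    group_of_set assigns each set to a group index (default: one group).
    This wraps the exact inverse-CDF sampler and is the generator behind
    all calibration and power simulations.
    """
    if len(params_per_set) != len(n_per_set):
        raise ValueError("params_per_set and n_per_set must have equal length")
    if group_of_set is None:
        group_of_set = [0] * len(params_per_set)
    if len(group_of_set) != len(params_per_set):
        raise ValueError("group_of_set must have one entry per set")
    rng = np.random.default_rng(seed)
    n_groups = max(group_of_set) + 1
    groups: list[list[HeteroplasmySample]] = [[] for _ in range(n_groups)]
    for k, (params, n, g) in enumerate(zip(params_per_set, n_per_set, group_of_set)):
        s = kimura_sample(params, n, rng)
        s.label = f"set{k + 1}"
        groups[g].append(s)
    return GroupedSamples(groups)


_ROADMAP = {
    "h_statistic": (
        "No individual measurements: estimate V(s^2) from summary "
        "statistics via the h-statistic h4. Caveat: interpreting the "
        "result as a confidence interval requires a parametric choice "
        "(e.g. +/-1.96 s.e. assumes normality)."
    ),
    "maximum_likelihood": (
        "Individual measurements and the Kimura model accepted: fit "
        "(p, b) by maximum likelihood, read bottleneck size as "
        "n_b = 1/(1-b), and get confidence intervals from the likelihood "
        "(Fisher information) or a bootstrap. Caveat: conclusions are "
        "conditional on the Kimura model."
    ),
    "bootstrap": (
        "Individual measurements but no trusted parametric model: "
        "bootstrap (or jackknife) the sample variance, with the n/(n-1) "
        "bias correction. Caveat: spreads are standard-error-like; "
        "turning them into confidence intervals again needs a "
        "parametric choice."
    ),
}


def recommend_method(
    have_individual_measurements: bool,
    accept_kimura_model: bool = True,
    accept_parametric_ci: bool = True,
) -> tuple[str, str]:
    """Decision-tree recommendation for analyzing a heteroplasmy dataset.

    Returns (method_tag, rationale).  Without individual measurements
    only the h-statistic route is open; with them, the choice is between
    a Kimura maximum-likelihood analysis and model-free resampling.
    """
    if not have_individual_measurements:
        tag = "h_statistic"
    elif accept_kimura_model:
        tag = "maximum_likelihood"
    else:
        tag = "bootstrap"
    return tag, _ROADMAP[tag]
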