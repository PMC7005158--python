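"""Generative per-interval coverage model and reproducibility statistics.

The model summarizes a technology by, for every interval i, the mean M_i
and standard deviation s_i (across samples) of its normalized mean
coverage, together with a within-interval relative-coverage shape of mean
1. A simulated sample then draws a normalized level C_i ~ Normal(M_i,
s_i^2) (truncated at 0), spreads it along the interval with the shape, and
scales by a nominal mean depth D; counting bases with predicted depth below
a threshold (default 10 reads) yields the expected poorly covered
territory at any sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet

__all__ = [
    "IntervalCoverageModel",
    "LowCoveragePrediction",
    "ReproducibilityReport",
    "stretch_profile",
    "fit_model",
    "predict_low_coverage",
    "systematically_low_intervals",
    "coverage_correlation",
    "intersection_union_ratio",
]


@dataclass
class IntervalCoverageModel:
    """Per-interval (M_i, s_i) plus a mean-1 within-interval shape."""

    M: np.ndarray
    s: np.ndarray
    lengths: np.ndarray
    shapes: list[np.ndarray] = field(repr=False)
    n_samples: int = 0

    def __post_init__(self) -> None:
        if not (len(self.M) == len(self.s) == len(self.lengths) == len(self.shapes)):
            raise ValueError("model arrays must be parallel")
        if np.any(self.s < 0):
            raise ValueError("s_i must be non-negative")
        for L, shape in zip(self.lengths, self.shapes):
            if len(shape) != L:
                raise ValueError("shape length mismatch")
            if abs(float(shape.mean()) - 1.0) > 1e-6:
                raise ValueError("interval shape must have mean 1")

    @property
    def n_intervals(self) -> int:
        return len(self.M)

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())


@dataclass
class LowCoveragePrediction:
    """Expected bp below the depth threshold along a mean-depth grid."""

    mean_depth_grid: np.ndarray
    bases_below: np.ndarray
    se: np.ndarray
    threshold: float
    n_rep: int
    seed: int | None


@dataclass
class ReproducibilityReport:
    mean_pairwise_r: float
    r_ratio: float
    cutoff: float
    n_samples: int


def stretch_profile(profile: np.ndarray, length: int) -> np.ndarray:
    """Stretch an n-bin shape profile to ``length`` bases and renormalize to
    mean 1. Base j takes the value of bin floor(n_bins*j/length)."""
    profile = np.asarray(profile, dtype=float)
    n_bins = len(profile)
    idx = (n_bins * np.arange(length)) // length
    out = profile[idx]
    m = out.mean()
    if m <= 0:
        raise ValueError("profile mean must be positive")
    return out / m


def fit_model(
    norm_matrix: pd.DataFrame | np.ndarray,
    lengths: Sequence[int],
    shape_profile: np.ndarray | None = None,
) -> IntervalCoverageModel:
    """Fit (M_i, s_i, shape_i) from an intervals x samples matrix of
    normalized mean coverages.

    ``shape_profile`` is the technology-average 100-bin within-interval
    profile; it is stretched to each interval's length and renormalized to
    mean 1 (flat when omitted). The matrix must be complete; s_i uses the
    n-1 denominator.
    """
    mat = np.asarray(norm_matrix, dtype=float)
    if mat.ndim != 2:
        raise ValueError("norm_matrix must be intervals x samples")
    n_int, n_samples = mat.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples to estimate s_i")
    if np.any(~np.isfinite(mat)):
        raise ValueError("norm_matrix contains missing values; matrix must be complete")
    lengths = np.asarray(lengths, dtype=np.int64)
    if len(lengths) != n_int:
        raise ValueError("lengths must match matrix rows")
    if shape_profile is None:
        shape_profile = np.ones(100)
    shapes = [stretch_profile(shape_profile, int(L)) for L in lengths]
    return IntervalCoverageModel(
        M=mat.mean(axis=1),
        s=mat.std(axis=1, ddof=1),
        lengths=lengths,
        shapes=shapes,
        n_samples=n_samples,
    )


def predict_low_coverage(
    model: IntervalCoverageModel,
    depth_grid: Sequence[float],
    threshold: float = 10.0,
    n_rep: int = 100,
    seed: int | None = None,
) -> LowCoveragePrediction:
    """Monte-Carlo expected bp covered below ``threshold`` reads at each
    nominal mean depth D.

    Per replicate, draw C_i ~ Normal(M_i, s_i^2) truncated at 0, form
    per-base depth D_ij = C_i * shape_ij * D, and count bases with
    D_ij < threshold; the reported curve is the mean over ``n_rep``
    replicates, with its Monte-Carlo standard error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    depth_grid = np.asarray(depth_grid, dtype=float)
    if np.any(depth_grid <= 0):
        raise ValueError("mean depths must be positive")
    rng = np.random.default_rng(seed)
    # For each base j the count condition C_i * shape_ij * D < t is
    # equivalent to C_i < t / (shape_ij * D): precompute, per interval, the
    # sorted per-base values of 1/shape so each replicate is a searchsorted.
    inv_shape_sorted = [np.sort(1.0 / np.maximum(s, 1e-12)) for s in model.shapes]
    counts = np.zeros((n_rep, len(depth_grid)))
    for r in range(n_rep):
        C = rng.normal(model.M, model.s)
        np.clip(C, 0.0, None, out=C)
        for i in range(model.n_intervals):
            inv = inv_shape_sorted[i]
            for g, D in enumerate(depth_grid):
                # bases with shape_ij < t/(C_i D)  <=>  1/shape_ij > C_i D / t
                if C[i] <= 0:
                    counts[r, g] += len(inv)
                else:
                    x = C[i] * D / threshold
                    counts[r, g] += len(inv) - np.searchsorted(inv, x, side="right")
    mean = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(n_rep) if n_rep > 1 else np.zeros_like(mean)
    return LowCoveragePrediction(
        mean_depth_grid=depth_grid,
        bases_below=mean,
        se=se,
        threshold=threshold,
        n_rep=n_rep,
        seed=seed,
    )


def low_coverage_pvalues(
    M: np.ndarray, s: np.ndarray, n_samples: int, cutoff: float
) -> np.ndarray:
    """One-sided one-sample t-test p-values for mean normalized coverage
    below ``cutoff`` (n-1 df). Zero-spread intervals degenerate to p = 0 if
    M < cutoff else p = 1."""
    M = np.asarray(M, dtype=float)
    s = np.asarray(s, dtype=float)
    p = np.ones_like(M)
    deg = s == 0
    p[deg] = np.where(M[deg] < cutoff, 0.0, 1.0)
    ok = ~deg
    t = (M[ok] - cutoff) / (s[ok] / np.sqrt(n_samples))
    p[ok] = stats.t.cdf(t, df=n_samples - 1)
    return p


def systematically_low_intervals(
    model: IntervalCoverageModel,
    intervals: IntervalSet | None = None,
    design: IntervalSet | None = None,
    cutoff: float = 0.1,
    alpha: float = 0.05,
    method: str = "holm",
) -> pd.DataFrame:
    """Intervals whose normalized coverage is systematically below ``cutoff``.

    Runs a one-sided one-sample t-test per interval (H1: mean < cutoff) and
    applies step-down Holm correction (``method='fdr_bh'`` switches to
    Benjamini-Hochberg) at family level ``alpha``. Returns the full table
    with p, adjusted p, significance flag, and — when ``intervals``/
    ``design`` are supplied — the targeted flag of each interval.
    """
    p = low_coverage_pvalues(model.M, model.s, model.n_samples, cutoff)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)
    df = pd.DataFrame(
        {
            "M": model.M,
            "s": model.s,
            "length": model.lengths,
            "p": p,
            "p_adj": p_adj,
            "significant": reject,
        }
    )
    if intervals is not None:
        if len(intervals) != model.n_intervals:
            raise ValueError("intervals must align with model rows")
        df["chrom"] = [iv.chrom for iv in intervals]
        df["start"] = [iv.start for iv in intervals]
        df["end"] = [iv.end for iv in intervals]
        if design is not None:
            merged = design.merge()
            df["targeted"] = [
                IntervalSet([iv]).intersect(merged).total_length > 0 for iv in intervals
            ]
    return df


def coverage_correlation(
    norm_matrix: pd.DataFrame | np.ndarray, method: str = "pearson"
) -> tuple[np.ndarray, float]:
    """Pairwise correlation of per-interval normalized coverage vectors.

    Returns the samples x samples correlation matrix and the mean over
    off-diagonal pairs. Zero-variance samples make their pairs undefined;
    those pairs are excluded from the mean (NaN in the matrix).
    """
    mat = np.asarray(norm_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need an intervals x samples matrix with >= 2 samples")
    if np.any(~np.isfinite(mat)):
        raise ValueError("matrix must be complete")
    df = pd.DataFrame(mat)
    corr = df.corr(method=method).to_numpy()
    n = mat.shape[1]
    iu = np.triu_indices(n, k=1)
    vals = corr[iu]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("all sample pairs undefined (zero-variance vectors)")
    return corr, float(vals[finite].mean())


def intersection_union_ratio(low_sets: Sequence[IntervalSet]) -> tuple[float, int, int]:
    """Intersection-to-union ratio R = L_intersection / L_union of
    per-sample low-coverage interval sets.

    Returns (R, L_intersection, L_union); raises when the union is empty.
    """
    if len(low_sets) < 2:
        raise ValueError("need >= 2 sample sets")
    union = low_sets[0].merge()
    inter = low_sets[0].merge()
    for s in low_sets[1:]:
        union = union.union(s)
        inter = inter.intersect(s)
    if union.total_length == 0:
        raise ValueError("union of low-coverage sets is empty; R undefined")
    return inter.total_length / union.total_length, inter.total_length, union.total_length


def reproducibility_report(
    norm_matrix: pd.DataFrame | np.ndarray,
    intervals: IntervalSet,
    cutoff: float = 0.1,
    method: str = "pearson",
) -> ReproducibilityReport:
    """Combined reproducibility summary: mean pairwise correlation of
    normalized coverage plus the intersection-to-union ratio of the
    per-sample sets of intervals with normalized coverage < ``cutoff``."""
    mat = np.asarray(norm_matrix, dtype=float)
    _, mean_r = coverage_correlation(mat, method=method)
    sets = []
    for k in range(mat.shape[1]):
        low = [iv for iv, v in zip(intervals, mat[:, k]) if v < cutoff]
        sets.append(IntervalSet(low).merge())
    r_ratio, _, _ = intersection_union_ratio(sets)
    return ReproducibilityReport(
        mean_pairwise_r=mean_r,
        r_ratio=r_ratio,
        cutoff=cutoff,
        n_samples=mat.shape[1],
    )
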