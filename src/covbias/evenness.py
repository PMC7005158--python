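"""Coverage evenness statistics.

Three complementary scores, all on [0, 1] with 1 = perfectly uniform:

* **OE** (overall evenness): area under the curve F(N) = fraction of bases
  whose normalized coverage (depth / sample mean CDS depth) is at least N,
  integrated over N in (0, 1] on a 0.01 grid.
* **BIE** (between-interval evenness): the same functional applied to the
  normalized *mean* coverages of individual intervals, each interval
  weighted equally.
* **WIE** (within-interval evenness, or smoothness): intervals are divided
  into 100 equal-length bins; per-bin coverage is normalized by the interval
  mean and averaged across intervals, giving a shape profile x_1..x_100;
  WIE = sum_b 0.01 * min(x_b, 1), the area under the capped shape curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import CoverageTrack
from .intervals import IntervalSet

__all__ = [
    "NormalizedCoverageProfile",
    "WithinIntervalProfile",
    "EvennessScores",
    "base_profile",
    "oe_score",
    "interval_profile",
    "bie_score",
    "within_interval_profile",
    "wie_score",
    "bin_map",
]

#: normalized-coverage grid N = 0.00, 0.01, ..., 3.00
GRID = np.round(np.arange(0, 301) * 0.01, 2)


@dataclass
class NormalizedCoverageProfile:
    """F(N) = fraction of units with normalized coverage >= N on ``GRID``."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.values):
            raise ValueError("grid/values length mismatch")
        if self.values[0] != 1.0:
            raise ValueError("F(0) must be 1")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("F must be non-increasing")


@dataclass
class WithinIntervalProfile:
    """Average relative-coverage shape across intervals (100 bins)."""

    x: np.ndarray
    n_intervals: int


@dataclass
class EvennessScores:
    oe: float
    bie: float
    wie: float


def _exceedance_profile(values: np.ndarray) -> NormalizedCoverageProfile:
    """F(N) over the grid for an array of normalized coverage values."""
    if len(values) == 0:
        raise ValueError("no units to profile")
    values = np.asarray(values, dtype=float)
    srt = np.sort(values)
    # count of values >= N, via left-bisection on the sorted array
    counts = len(srt) - np.searchsorted(srt, GRID, side="left")
    return NormalizedCoverageProfile(grid=GRID.copy(), values=counts / len(srt))


def base_profile(track: CoverageTrack, mean_depth: float | None = None) -> NormalizedCoverageProfile:
    """Per-base normalized-coverage exceedance profile over the track universe.

    Zero-depth bases are included. ``mean_depth`` defaults to the track's own
    mean over its universe.
    """
    if mean_depth is None:
        mean_depth = track.mean_depth()
    if mean_depth <= 0:
        raise ValueError("normalization denominator must be positive")
    return _exceedance_profile(track.all_depths() / mean_depth)


def oe_score(profile: NormalizedCoverageProfile) -> float:
    """Area under F(N) for N in (0, 1]: sum of 0.01 * F(0.01 k), k = 1..100.

    Computed as the mean of F over those 100 grid points (identical sum,
    exact at the flat-coverage baseline).
    """
    idx = np.flatnonzero((profile.grid > 0) & (profile.grid <= 1.0 + 1e-9))
    return float(profile.values[idx[:100]].mean())


def interval_profile(norm_means: np.ndarray) -> NormalizedCoverageProfile:
    """Exceedance profile of per-interval normalized mean coverages
    (each interval one unit, regardless of its length)."""
    return _exceedance_profile(np.asarray(norm_means, dtype=float))


def bie_score(profile: NormalizedCoverageProfile) -> float:
    """Between-interval evenness: same functional as :func:`oe_score`."""
    return oe_score(profile)


def bin_map(length: int, n_bins: int = 100) -> np.ndarray:
    """Bin index of each base: base j of an L-bp interval goes to
    floor(n_bins * j / L)."""
    return (n_bins * np.arange(length)) // length


def within_interval_profile(
    track: CoverageTrack,
    intervals: IntervalSet,
    min_mean_depth: float = 10.0,
    n_bins: int = 100,
    flank: int = 0,
    min_length: int | None = None,
    max_length: int | None = None,
) -> WithinIntervalProfile:
    """Average relative-coverage shape over qualifying intervals.

    Intervals with mean depth strictly greater than ``min_mean_depth``
    qualify. Per interval, base j maps to bin ``floor(n_bins*j/L)``; the bin
    value is (mean depth in bin) / (interval mean depth). Intervals shorter
    than ``n_bins`` leave some bins empty; those are filled from the nearest
    populated bin before averaging so every interval contributes a full
    n_bins-point shape. ``flank`` extends each interval symmetrically before
    binning (the extension must still lie inside the track universe).
    """
    from .intervals import GenomicInterval

    shapes = []
    for iv in intervals:
        if min_length is not None and iv.length < min_length:
            continue
        if max_length is not None and iv.length > max_length:
            continue
        if flank > 0:
            iv = GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank, iv.name)
        d = track.depth_over(iv).astype(float)
        mean = d.mean()
        if mean <= min_mean_depth:
            continue
        bins = bin_map(len(d), n_bins)
        sums = np.bincount(bins, weights=d, minlength=n_bins)
        counts = np.bincount(bins, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            shape = (sums / counts) / mean
        if np.any(counts == 0):
            shape = _fill_empty_bins(shape, counts)
        shapes.append(shape)
    if not shapes:
        raise ValueError(
            f"no interval qualifies (mean depth > {min_mean_depth} required)"
        )
    return WithinIntervalProfile(x=np.mean(shapes, axis=0), n_intervals=len(shapes))


def _fill_empty_bins(shape: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Replace empty-bin values with the nearest populated bin's value
    (ties broken toward the left neighbour)."""
    filled = shape.copy()
    populated = np.flatnonzero(counts > 0)
    empty = np.flatnonzero(counts == 0)
    pos = np.searchsorted(populated, empty)
    left = populated[np.clip(pos - 1, 0, len(populated) - 1)]
    right = populated[np.clip(pos, 0, len(populated) - 1)]
    use_left = (empty - left) <= (right - empty)
    filled[empty] = np.where(use_left, shape[left], shape[right])
    return filled


def wie_score(profile: WithinIntervalProfile) -> float:
    """Area under the capped shape curve: sum_b 0.01 * min(x_b, 1).

    Computed as the mean of the capped bin values (identical sum for the
    100-bin grid), so a perfectly flat shape scores exactly 1.0.
    """
    return float(np.minimum(profile.x, 1.0).mean())
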