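"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive per-base / per-element computations so
they share no code path with the library implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from covbias import synthetic
from covbias.intervals import GenomicInterval, IntervalSet


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_fixture():
    """A modest seeded synthetic dataset shared by read-only tests."""
    cfg = synthetic.SyntheticConfig(seed=11, n_intervals=60, mean_depth=100)
    intervals, genome, truth = synthetic.generate_intervals(cfg)
    return cfg, intervals, genome, truth


def make_universe(*spans: tuple[str, int, int]) -> IntervalSet:
    return IntervalSet([GenomicInterval(c, s, e) for c, s, e in spans], merged=True)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def random_interval_set(
    rng: np.random.Generator, n: int, genome_size: int = 10_000, chroms: tuple[str, ...] = ("c1", "c2")
) -> IntervalSet:
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, genome_size - 2))
        end = int(rng.integers(start + 1, min(genome_size, start + 60) + 1))
        ivs.append(GenomicInterval(str(rng.choice(chroms)), start, end))
    return IntervalSet(ivs)


def membership_mask(iset: IntervalSet, chroms: tuple[str, ...], genome_size: int) -> dict[str, np.ndarray]:
    """Per-base boolean membership, one array per chromosome."""
    masks = {c: np.zeros(genome_size, dtype=bool) for c in chroms}
    for iv in iset:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def holm_oracle(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Literal step-down Holm procedure."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Pearson r."""
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def exceedance_oracle(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Direct counting of F(N) at every grid point."""
    return np.array([(values >= n).mean() for n in grid])
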