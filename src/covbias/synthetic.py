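"""Synthetic fixtures with known ground truth.

Generates everything the toolkit consumes — intervals with controlled GC,
paired filtered/unfiltered coverage tracks, and variant calls — from a
single seeded configuration, so every statistic can be checked against the
parameters that produced the data.

The coverage generator mirrors the per-interval model: each interval gets a
long-run mean level (lognormal across intervals, normalized to mean 1), a
per-sample level drawn around it (truncated Normal), a within-interval
shape (flat, dome, or edge-falloff), a GC-dependent depth multiplier, a
multimapping component, and optional exclusion from the capture design.
Observed depths are Poisson around the expected value; the filtered track
is a binomial thinning of the unfiltered one with retention 1 - MF, so
filtered depth never exceeds unfiltered depth at any base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SyntheticConfig",
    "generate_intervals",
    "generate_coverage",
    "generate_variant_calls",
    "write_fasta",
    "simulate_cohort",
    "latent_low_bases",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """All knobs of the generator. Regenerating with the same config is
    byte-identical."""

    seed: int = 0
    chrom: str = "chr1"
    n_intervals: int = 200
    min_length: int = 120
    max_length: int = 400
    gap: int = 50
    # genome GC model: per-interval target GC ~ Beta(a, b)
    gc_beta: tuple[float, float] = (5.0, 5.0)
    # coverage model
    mean_depth: float = 80.0
    between_sigma: float = 0.5       # lognormal sigma of long-run interval means
    sample_cv: float = 0.15          # per-sample spread: s_i = sample_cv * M_i
    shape: str = "flat"              # flat | dome | edge
    shape_param: float = 0.5         # dome amplitude a, or edge-falloff fraction
    gc_slope: float = 0.0            # depth multiplier 1 - b*(GC - 0.5)
    # multimapping: MF = 0 with prob mf_zero_prob, else Uniform(*mf_range);
    # a slice of the nonzero draws is forced to exactly 1
    mf_zero_prob: float = 0.9
    mf_range: tuple[float, float] = (0.3, 1.0)
    mf_one_prob: float = 0.02
    # capture design: an interval is dropped from the design with prob q and
    # then sequenced at background_factor of its expected depth
    inclusion_drop_prob: float = 0.0
    background_factor: float = 0.02
    noise: str = "poisson"           # poisson | none (latent expected depths)
    # variant fixtures
    het_density: float = 0.005       # het sites per interval bp
    allele_p: float = 0.5            # P(read supports reference)
    variant_depth: float = 60.0
    lowgq_fraction: float = 0.0
    indel_fraction: float = 0.1

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


# ---------------------------------------------------------------------------
# Intervals + genome
# ---------------------------------------------------------------------------

def generate_intervals(config: SyntheticConfig) -> tuple[IntervalSet, dict[str, str], pd.DataFrame]:
    """Disjoint intervals on one synthetic chromosome plus a matching genome.

    Per-interval target GC is Beta-distributed; the realized sequence places
    exactly ``round(GC * L)`` G/C bases, so the realized GC matches the
    target within rounding (<= 0.5/L). Returns (intervals, genome, truth)
    where truth has one row per interval: coordinates, GC, long-run mean,
    MF, targeted flag.
    """
    rng = config.rng(0)
    n = config.n_intervals
    lengths = rng.integers(config.min_length, config.max_length + 1, size=n)
    gaps = np.full(n, config.gap, dtype=np.int64)
    starts = np.cumsum(gaps + np.concatenate(([0], lengths[:-1])))
    ends = starts + lengths
    chrom_len = int(ends[-1] + config.gap)

    gc_target = rng.beta(*config.gc_beta, size=n)
    # long-run interval means, lognormal with unit mean
    sigma = config.between_sigma
    M = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    # multimapping fractions
    mf = np.zeros(n)
    nonzero = rng.random(n) >= config.mf_zero_prob
    mf[nonzero] = rng.uniform(*config.mf_range, size=int(nonzero.sum()))
    force_one = rng.random(n) < config.mf_one_prob
    mf[force_one] = 1.0
    targeted = rng.random(n) >= config.inclusion_drop_prob

    # realize the genome: random background, interval sequence with exact GC count
    seq = rng.choice(_BASES, size=chrom_len)
    for s, e, g in zip(starts, ends, gc_target):
        L = int(e - s)
        n_gc = int(round(g * L))
        flags = np.zeros(L, dtype=bool)
        flags[:n_gc] = True
        rng.shuffle(flags)
        letters = np.where(
            flags, rng.choice(np.array(list("GC")), size=L), rng.choice(np.array(list("AT")), size=L)
        )
        seq[s:e] = letters
    genome = {config.chrom: "".join(seq)}

    intervals = IntervalSet(
        [
            GenomicInterval(config.chrom, int(s), int(e), f"iv{k}")
            for k, (s, e) in enumerate(zip(starts, ends))
        ],
        merged=True,
    )
    gc_real = np.array(
        [
            _gc_of(genome[config.chrom][iv.start : iv.end])
            for iv in intervals
        ]
    )
    if np.nanmax(np.abs(gc_real - gc_target)) > 0.02:
        raise AssertionError("realized GC drifted from target beyond 0.02")
    truth = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "name": [iv.name for iv in intervals],
            "length": lengths,
            "gc_target": gc_target,
            "gc": gc_real,
            "mean": M,
            "mf": mf,
            "targeted": targeted,
        }
    )
    return intervals, genome, truth


def _gc_of(seq: str) -> float:
    gc = seq.count("G") + seq.count("C")
    return gc / len(seq) if seq else float("nan")


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

def shape_vector(kind: str, length: int, param: float) -> np.ndarray:
    """Within-interval relative-coverage shape of mean exactly 1."""
    t = (np.arange(length) + 0.5) / length
    if kind == "flat":
        x = np.ones(length)
    elif kind == "dome":
        x = 1.0 + param * np.cos(2 * np.pi * t - np.pi)
    elif kind == "edge":
        f = max(param, 1e-9)
        x = np.minimum(1.0, np.minimum(t / f, (1 - t) / f))
    else:
        raise ValueError(f"unknown shape {kind!r}")
    x = np.clip(x, 0.0, None)
    m = x.mean()
    if m <= 0:
        raise ValueError("degenerate shape")
    return x / m


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def _expected_unfiltered(
    config: SyntheticConfig, truth: pd.DataFrame, C: np.ndarray
) -> list[np.ndarray]:
    """Latent expected unfiltered depth per base for one sample with
    per-sample interval levels ``C``."""
    out = []
    for k, row in enumerate(truth.itertuples()):
        L = int(row.length)
        shape = shape_vector(config.shape, L, config.shape_param)
        gc_mult = max(0.0, 1.0 - config.gc_slope * (row.gc - 0.5))
        factor = 1.0 if row.targeted else config.background_factor
        out.append(config.mean_depth * C[k] * shape * gc_mult * factor)
    return out


def draw_sample_levels(
    config: SyntheticConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample interval levels C_i ~ Normal(M_i, (cv*M_i)^2), >= 0."""
    M = truth["mean"].to_numpy()
    C = rng.normal(M, config.sample_cv * M)
    return np.clip(C, 0.0, None)


def generate_coverage(
    config: SyntheticConfig,
    intervals: IntervalSet,
    truth: pd.DataFrame,
    sample: int = 0,
    mean_depth: float | None = None,
) -> tuple[CoverageTrack, CoverageTrack, np.ndarray]:
    """One sample's (filtered, unfiltered) tracks over ``intervals``.

    ``sample`` indexes an independent random stream, so a cohort is
    reproducible sample-by-sample. Unfiltered depth is Poisson around the
    latent expectation; the filtered track is a per-base Binomial thinning
    with retention 1 - MF_i. With ``noise='none'`` the latent expectations
    themselves are stored (float depths; useful for noise-free checks).
    Returns the two tracks and the sample's interval levels C_i.
    """
    rng = config.rng(1, sample)
    if mean_depth is not None:
        config = SyntheticConfig(**{**asdict(config), "mean_depth": mean_depth})
    C = draw_sample_levels(config, truth, rng)
    lam = _expected_unfiltered(config, truth, C)
    mf = truth["mf"].to_numpy()
    unfiltered_depths = []
    filtered_depths = []
    for k, lam_k in enumerate(lam):
        if config.noise == "poisson":
            u = rng.poisson(lam_k)
            f = rng.binomial(u, 1.0 - mf[k])
        elif config.noise == "none":
            u = lam_k
            f = lam_k * (1.0 - mf[k])
        else:
            raise ValueError(f"unknown noise model {config.noise!r}")
        unfiltered_depths.append(u)
        filtered_depths.append(f)
    sid = f"sim{sample}"
    return (
        CoverageTrack(intervals, filtered_depths, sample_id=sid),
        CoverageTrack(intervals, unfiltered_depths, sample_id=sid),
        C,
    )


def simulate_cohort(
    config: SyntheticConfig,
    intervals: IntervalSet,
    truth: pd.DataFrame,
    n_samples: int,
    first_sample: int = 0,
) -> list[tuple[CoverageTrack, CoverageTrack]]:
    """Convenience: ``n_samples`` independent (filtered, unfiltered) pairs."""
    return [
        generate_coverage(config, intervals, truth, sample=first_sample + k)[:2]
        for k in range(n_samples)
    ]


def latent_low_bases(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    depth: float,
    threshold: float = 10.0,
    n_samples: int = 50,
    first_sample: int = 10_000,
) -> np.ndarray:
    """Generator-side truth for the low-coverage curve: for ``n_samples``
    fresh samples whose *realized* mean CDS depth is ``depth``, count bases
    whose latent (noise-free) depth falls below ``threshold``.

    Each sample's interval levels are rescaled by their length-weighted mean
    so the per-base depth is ``depth`` times the sample's normalized
    coverage — the same units the fitted model predicts in. Counted
    directly per base, independently of the model module's prediction path.
    """
    counts = np.empty(n_samples)
    lengths = truth["length"].to_numpy()
    shapes = [shape_vector(config.shape, int(L), config.shape_param) for L in lengths]
    for s in range(n_samples):
        rng = config.rng(2, first_sample + s)
        C = draw_sample_levels(config, truth, rng)
        sample_mean = float((C * lengths).sum() / lengths.sum())
        total = 0
        for k, shape in enumerate(shapes):
            total += int((depth * (C[k] / sample_mean) * shape < threshold).sum())
        counts[s] = total
    return counts


# ---------------------------------------------------------------------------
# Predictor-importance study table
# ---------------------------------------------------------------------------

def generate_importance_table(
    n_intervals: int = 1000,
    seed: int = 0,
    gc_effect: float = 0.8,
    mf_collapse: float = 0.9,
    collapse_range: tuple[float, float] = (0.02, 0.18),
    drop_prob: float = 0.002,
    noise_sigma: float = 0.12,
) -> pd.DataFrame:
    """Per-interval feature table for the predictor-importance analysis.

    Emulates the regime where *continuous* normalized coverage drifts
    mildly with GC (multiplier ``1 - gc_effect*(GC-0.5)``) while *low
    coverage* (the classifier label) is driven by a mappability threshold
    rule: intervals with MF above ``mf_collapse`` keep only a random
    Uniform(*collapse_range*) multiple of their coverage (imperfect
    penetrance, so the label is not perfectly separable), as do the rare
    intervals dropped from the capture design. MF itself is a 90/10 mixture
    of ~0 and Uniform(0.3, 1), so MF carries almost no linear signal below
    the collapse point.

    Columns: gc, length, mf, targeted, norm_mean.
    """
    rng = np.random.default_rng([seed, 4])
    gc = rng.beta(5, 5, n_intervals)
    length = rng.integers(120, 401, n_intervals)
    mf = np.where(
        rng.random(n_intervals) < 0.9,
        rng.uniform(0, 0.05, n_intervals),
        rng.uniform(0.3, 1.0, n_intervals),
    )
    targeted = rng.random(n_intervals) >= drop_prob
    norm = (1.0 - gc_effect * (gc - 0.5)) * rng.lognormal(0, noise_sigma, n_intervals)
    collapse_mult = rng.uniform(*collapse_range, n_intervals)
    norm = np.where(mf > mf_collapse, norm * collapse_mult, norm)
    norm = np.where(targeted, norm, norm * collapse_mult)
    return pd.DataFrame(
        {"gc": gc, "length": length, "mf": mf, "targeted": targeted, "norm_mean": norm}
    )


# ---------------------------------------------------------------------------
# Variant calls
# ---------------------------------------------------------------------------

def generate_variant_calls(
    config: SyntheticConfig,
    intervals: IntervalSet,
    genome: dict[str, str],
    path: str,
    sample_name: str = "S1",
) -> pd.DataFrame:
    """Write a single-sample VCF of heterozygous sites inside the intervals.

    Sites are placed at ``het_density`` per bp; allele depths are
    Binomial(DP, allele_p) for the reference allele with DP ~
    Poisson(variant_depth); GQ is 99 except a ``lowgq_fraction`` slice drawn
    from [0, 20); an ``indel_fraction`` slice becomes 1-bp insertions.
    Returns the truth table (one row per emitted site). An empty site list
    still yields a valid VCF.
    """
    rng = config.rng(3)
    complement = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}
    rows = []
    for iv in intervals:
        n_sites = rng.binomial(iv.length, config.het_density)
        if n_sites == 0:
            continue
        offsets = np.sort(rng.choice(iv.length, size=n_sites, replace=False))
        for off in offsets:
            pos = iv.start + int(off)
            ref = genome[iv.chrom][pos].upper()
            if ref == "N":
                ref = "A"
            dp = max(1, int(rng.poisson(config.variant_depth)))
            ref_reads = int(rng.binomial(dp, config.allele_p))
            alt_reads = dp - ref_reads
            is_indel = rng.random() < config.indel_fraction
            alt = ref + "A" if is_indel else complement[ref]
            gq = int(rng.integers(0, 20)) if rng.random() < config.lowgq_fraction else 99
            rows.append(
                {
                    "chrom": iv.chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "is_indel": is_indel,
                    "ref_reads": ref_reads,
                    "alt_reads": alt_reads,
                    "gq": gq,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "is_indel", "ref_reads", "alt_reads", "gq"],
    )
    _write_vcf(truth, genome, path, sample_name)
    return truth


def _write_vcf(truth: pd.DataFrame, genome: dict[str, str], path: str, sample_name: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}\n")
        for row in truth.itertuples():
            dp = row.ref_reads + row.alt_reads
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t100\tPASS\t.\t"
                f"GT:AD:DP:GQ\t0/1:{row.ref_reads},{row.alt_reads}:{dp}:{row.gq}\n"
            )
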