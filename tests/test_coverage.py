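"""Coverage tracks: BAM ingestion, bedgraph round trips, summaries, MF."""

import numpy as np
import pysam
import pytest

from covbias import coverage as cov
from covbias.intervals import BedParseError, GenomicInterval, IntervalSet

from conftest import make_universe


# ---------------------------------------------------------------------------
# BAM ingestion
# ---------------------------------------------------------------------------

def _write_bam(path, reads, ref_len=2000, ref="chr1"):
    """reads: list of (start, length, mq, is_dup)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": ref, "LN": ref_len}]}
    reads = sorted(reads, key=lambda r: r[0])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for k, (start, length, mq, dup) in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"r{k}"
            a.query_sequence = "A" * length
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = mq
            a.cigarstring = f"{length}M"
            a.flag = 1024 if dup else 0
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            bam.write(a)
    pysam.index(str(path))


def test_mq_filter_and_duplicates(tmp_path):
    bam = tmp_path / "t.bam"
    universe = make_universe(("chr1", 100, 200))
    _write_bam(bam, [(110, 50, 0, False), (120, 50, 60, True)])
    filt, unfilt = cov.coverage_from_alignments(str(bam), universe)
    # MQ=0 read counts only in the unfiltered track
    assert unfilt.depth_over(GenomicInterval("chr1", 110, 160)).min() == 1
    assert filt.total_depth == 0
    # duplicate-flagged read counts in neither
    assert unfilt.depth_over(GenomicInterval("chr1", 160, 170)).max() == 0


def test_bam_depth_matches_overlap_oracle(tmp_path):
    rng = np.random.default_rng(5)
    reads = [
        (int(rng.integers(0, 1900)), int(rng.integers(30, 100)), int(rng.choice([0, 5, 30, 60])), False)
        for _ in range(50)
    ]
    bam = tmp_path / "t.bam"
    _write_bam(bam, reads)
    universe = make_universe(("chr1", 0, 2000))
    filt, unfilt = cov.coverage_from_alignments(str(bam), universe)
    exp_u = np.zeros(2000, dtype=int)
    exp_f = np.zeros(2000, dtype=int)
    for start, length, mq, _ in reads:
        end = min(2000, start + length)
        exp_u[start:end] += 1
        if mq >= 10:
            exp_f[start:end] += 1
    assert np.array_equal(unfilt.depths[0], exp_u)
    assert np.array_equal(filt.depths[0], exp_f)


def test_missing_index_and_chrom_mismatch(tmp_path):
    bam = tmp_path / "t.bam"
    _write_bam(bam, [(10, 20, 60, False)])
    (tmp_path / "t.bam.bai").unlink()
    with pytest.raises(IOError, match="index"):
        cov.coverage_from_alignments(str(bam), make_universe(("chr1", 0, 100)))
    _write_bam(bam, [(10, 20, 60, False)])
    with pytest.raises(ValueError, match="chrX"):
        cov.coverage_from_alignments(str(bam), make_universe(("chrX", 0, 100)))


# ---------------------------------------------------------------------------
# bedgraph I/O
# ---------------------------------------------------------------------------

def test_bedgraph_round_trip_random(tmp_path):
    rng = np.random.default_rng(2)
    universe = make_universe(("c", 0, 500), ("c", 700, 900))
    track = cov.CoverageTrack(
        universe, [rng.integers(0, 6, iv.length) for iv in universe], sample_id="x"
    )
    p = tmp_path / "t.bg"
    cov.write_bedgraph(track, str(p))
    back = cov.read_bedgraph(str(p), universe)
    assert all(np.array_equal(a, b) for a, b in zip(back.depths, track.depths))


def test_bedgraph_zero_fill_and_coalescing(tmp_path):
    universe = make_universe(("c", 0, 10))
    p = tmp_path / "t.bg"
    # omitted region materializes as depth 0
    p.write_text("c\t0\t4\t7\n")
    track = cov.read_bedgraph(str(p), universe)
    assert list(track.depths[0]) == [7] * 4 + [0] * 6
    # equal-depth adjacent segments are coalesced on write
    p.write_text("c\t0\t5\t3\nc\t5\t10\t3\n")
    track = cov.read_bedgraph(str(p), universe)
    cov.write_bedgraph(track, str(p))
    assert p.read_text() == "c\t0\t10\t3\n"


def test_bedgraph_overlap_rejected(tmp_path):
    p = tmp_path / "t.bg"
    p.write_text("c\t0\t5\t3\nc\t3\t8\t2\n")
    with pytest.raises(BedParseError, match="overlap"):
        cov.read_bedgraph(str(p), make_universe(("c", 0, 10)))


# ---------------------------------------------------------------------------
# Summaries and MF
# ---------------------------------------------------------------------------

def _const_tracks(universe, f_depth, u_depth):
    filt = cov.CoverageTrack(universe, [np.full(iv.length, f_depth) for iv in universe])
    unfilt = cov.CoverageTrack(universe, [np.full(iv.length, u_depth) for iv in universe])
    return filt, unfilt


def test_mf_arithmetic():
    universe = make_universe(("c", 0, 100))
    intervals = IntervalSet([GenomicInterval("c", 0, 100)])
    filt, unfilt = _const_tracks(universe, 60, 100)
    summary = cov.summarize_intervals(filt, unfilt, intervals)
    assert summary.loc[0, "mf"] == pytest.approx(0.4)
    # identical tracks -> mf 0 everywhere
    filt, unfilt = _const_tracks(universe, 80, 80)
    assert cov.summarize_intervals(filt, unfilt, intervals)["mf"].eq(0).all()


def test_normalization_error_on_zero_depth():
    universe = make_universe(("c", 0, 100))
    filt, unfilt = _const_tracks(universe, 0, 0)
    with pytest.raises(ValueError, match="mean CDS depth"):
        cov.summarize_intervals(filt, unfilt, IntervalSet([GenomicInterval("c", 0, 100)]))


def test_mf_invariant_to_depth_scaling():
    universe = make_universe(("c", 0, 50))
    intervals = IntervalSet([GenomicInterval("c", 0, 50)])
    f1, u1 = _const_tracks(universe, 30, 90)
    f2, u2 = _const_tracks(universe, 300, 900)
    mf1 = cov.summarize_intervals(f1, u1, intervals).loc[0, "mf"]
    mf2 = cov.summarize_intervals(f2, u2, intervals).loc[0, "mf"]
    assert mf1 == pytest.approx(mf2)


def test_length_weighted_sum_identity():
    """Σ_i length_i * mean_depth_i equals the total per-base depth (exact)."""
    rng = np.random.default_rng(7)
    universe = make_universe(("c", 0, 300), ("c", 400, 650))
    depths = [rng.integers(0, 50, iv.length) for iv in universe]
    filt = cov.CoverageTrack(universe, depths)
    summary = cov.summarize_intervals(filt, filt, universe)
    lhs = (summary["length"] * summary["mean_depth"]).sum()
    assert lhs == pytest.approx(sum(int(d.sum()) for d in depths))


def test_per_base_mf_examples_and_oracle():
    rng = np.random.default_rng(9)
    universe = make_universe(("c", 0, 1000))
    u = rng.integers(0, 6, 1000)
    f = np.minimum(rng.integers(0, 6, 1000), u)
    filt = cov.CoverageTrack(universe, [f])
    unfilt = cov.CoverageTrack(universe, [u])
    mf = cov.per_base_mf(filt, unfilt)[0]
    # convention: mf = 0 where unfiltered depth is 0
    if (u == 0).any():
        assert mf[u == 0].max() == 0
    # mf=1 exactly at bases with coverage entirely from filtered-out reads
    oracle_ones = int(((f == 0) & (u > 0)).sum())
    assert cov.mf_threshold_report([mf], [1.0])[1.0] == oracle_ones
    expected = np.where(u > 0, (u - f) / np.where(u > 0, u, 1), 0.0)
    assert np.allclose(mf, expected)


def test_filtered_never_exceeds_unfiltered_from_generator(small_fixture):
    from covbias import synthetic

    cfg, intervals, genome, truth = small_fixture
    filt, unfilt, _ = synthetic.generate_coverage(cfg, intervals, truth, sample=3)
    for df, du in zip(filt.depths, unfilt.depths):
        assert (df <= du).all()


# ---------------------------------------------------------------------------
# Enrichment efficiency
# ---------------------------------------------------------------------------

def test_enrichment_limits_and_oracle():
    universe = make_universe(("c", 0, 1000))
    target = IntervalSet([GenomicInterval("c", 100, 300)]).merge()
    depths = np.zeros(1000, dtype=int)
    depths[100:300] = 10
    track = cov.CoverageTrack(universe, [depths])
    frac, fold = cov.enrichment_efficiency(track, target, genome_length=1000)
    assert frac == 1.0
    # uniform depth genome-wide -> fold enrichment 1
    track = cov.CoverageTrack(universe, [np.full(1000, 5)])
    frac, fold = cov.enrichment_efficiency(track, target, genome_length=1000)
    assert fold == pytest.approx(1.0)
    assert frac == pytest.approx(0.2)

    rng = np.random.default_rng(1)
    depths = rng.integers(0, 20, 1000)
    track = cov.CoverageTrack(universe, [depths])
    frac, fold = cov.enrichment_efficiency(track, target, genome_length=5000)
    on = depths[100:300].sum()
    assert frac == pytest.approx(on / depths.sum())
    assert fold == pytest.approx((on / 200) / (depths.sum() / 5000))

    with pytest.raises(ValueError, match="zero total depth"):
        cov.enrichment_efficiency(
            cov.CoverageTrack(universe, [np.zeros(1000, dtype=int)]), target, 1000
        )
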