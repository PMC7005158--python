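"""Per-base coverage tracks and interval-level coverage summaries.

A :class:`CoverageTrack` stores the read depth of every base of a fixed
*universe* (a merged :class:`~covbias.intervals.IntervalSet`, typically the
CDS annotation) as one integer array per universe interval. Zero depth is
explicit, so every universe base has exactly one value.

Coverage is meant to be computed the way variant callers see the data:
duplicate reads are dropped and the *filtered* track additionally drops
reads below a mapping-quality floor (default MQ < 10). The gap between the
unfiltered and filtered track is the multimapping fraction (MF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .intervals import BedParseError, GenomicInterval, IntervalSet

__all__ = [
    "CoverageTrack",
    "SampleCoverage",
    "coverage_from_alignments",
    "read_bedgraph",
    "write_bedgraph",
    "summarize_intervals",
    "per_base_mf",
    "mf_threshold_report",
    "enrichment_efficiency",
]


class CoverageTrack:
    """Read depth for every base of a universe interval set.

    Parameters
    ----------
    universe:
        Merged interval set defining which bases carry a depth value.
    depths:
        One ``int64`` array per universe interval, aligned by index.
    sample_id:
        Free-form label of the originating sample.
    """

    def __init__(
        self,
        universe: IntervalSet,
        depths: Iterable[np.ndarray] | None = None,
        sample_id: str = "",
    ):
        self.universe = universe.merge()
        if depths is None:
            self.depths = [np.zeros(iv.length, dtype=np.int64) for iv in self.universe]
        else:
            self.depths = [np.asarray(d) for d in depths]
            for iv, d in zip(self.universe, self.depths):
                if len(d) != iv.length:
                    raise ValueError(
                        f"depth array length {len(d)} != interval length {iv.length} "
                        f"({iv.chrom}:{iv.start}-{iv.end})"
                    )
                if np.any(d < 0):
                    raise ValueError("negative depth")
        self.sample_id = sample_id
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    # -- indexing -----------------------------------------------------------
    def _chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        if self._index is None:
            idx: dict[str, list[list[int]]] = {}
            for k, iv in enumerate(self.universe):
                idx.setdefault(iv.chrom, [[], [], []])
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
                idx[iv.chrom][2].append(k)
            self._index = {
                c: (np.asarray(v[0]), np.asarray(v[1]), np.asarray(v[2]))
                for c, v in idx.items()
            }
        return self._index

    def depth_over(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base depth over ``interval``, which must lie inside one
        universe interval (universe intervals are merged, so any region
        contained in the universe satisfies this)."""
        chrom_idx = self._chrom_index()
        if interval.chrom not in chrom_idx:
            raise KeyError(f"chromosome {interval.chrom!r} not in track universe")
        starts, ends, ks = chrom_idx[interval.chrom]
        j = int(np.searchsorted(starts, interval.start, side="right")) - 1
        if j < 0 or interval.end > ends[j]:
            raise KeyError(
                f"{interval.chrom}:{interval.start}-{interval.end} not contained in universe"
            )
        k = int(ks[j])
        off = interval.start - int(starts[j])
        return self.depths[k][off : off + interval.length]

    def mean_over(self, interval: GenomicInterval) -> float:
        return float(self.depth_over(interval).mean())

    # -- aggregates ---------------------------------------------------------
    @property
    def total_bases(self) -> int:
        return self.universe.total_length

    @property
    def total_depth(self) -> int:
        return int(sum(int(d.sum()) for d in self.depths))

    def mean_depth(self) -> float:
        if self.total_bases == 0:
            raise ValueError("empty universe")
        return self.total_depth / self.total_bases

    def all_depths(self) -> np.ndarray:
        """All per-base depths concatenated in universe order."""
        if not self.depths:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(self.depths)

    def segments(self) -> Iterator[tuple[str, int, int, int]]:
        """Run-length encoded (chrom, start, end, depth) in canonical form
        (adjacent equal-depth runs coalesced within each universe interval)."""
        for iv, d in zip(self.universe, self.depths):
            if len(d) == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                yield iv.chrom, iv.start + int(s), iv.start + int(e), int(d[s])


@dataclass
class SampleCoverage:
    """A sample's filtered/unfiltered coverage plus its CDS normalization."""

    sample_id: str
    platform: str
    filtered: CoverageTrack
    unfiltered: CoverageTrack

    @property
    def mean_cds_depth(self) -> float:
        return self.filtered.mean_depth()


# ---------------------------------------------------------------------------
# BAM ingestion
# ---------------------------------------------------------------------------

def coverage_from_alignments(
    bam_path: str,
    universe: IntervalSet,
    mq_min: int = 10,
    drop_duplicates: bool = True,
    sample_id: str = "",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Build (filtered, unfiltered) tracks from a coordinate-sorted BAM.

    The filtered track counts reads with ``MQ >= mq_min``; the unfiltered
    track counts all reads regardless of MQ. Duplicate-flagged reads (when
    ``drop_duplicates``) and secondary/supplementary alignments are excluded
    from both. Depth at a position is the number of aligned read bases
    overlapping it (insertions/soft-clips do not contribute).
    """
    import pysam

    universe = universe.merge()
    try:
        bam = pysam.AlignmentFile(bam_path, "rb")
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot open alignment file {bam_path}: {exc}") from exc
    if not bam.has_index():
        raise IOError(f"{bam_path} has no index (.bai); coordinate-sort and index it first")

    refs = set(bam.references)
    missing = [c for c in universe.chroms if c not in refs]
    if missing:
        raise ValueError(
            f"universe chromosomes absent from {bam_path}: {missing[:5]} "
            f"(BAM references look like {sorted(refs)[:5]})"
        )

    filt = CoverageTrack(universe, sample_id=sample_id)
    unfilt = CoverageTrack(universe, sample_id=sample_id)
    for k, iv in enumerate(universe):
        df = filt.depths[k]
        du = unfilt.depths[k]
        for read in bam.fetch(iv.chrom, iv.start, iv.end):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            keep = read.mapping_quality >= mq_min
            for bs, be in read.get_blocks():
                s = max(bs, iv.start) - iv.start
                e = min(be, iv.end) - iv.start
                if e > s:
                    du[s:e] += 1
                    if keep:
                        df[s:e] += 1
    bam.close()
    return filt, unfilt


# ---------------------------------------------------------------------------
# bedgraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path: str, universe: IntervalSet, sample_id: str = "") -> CoverageTrack:
    """Read a 4-column bedgraph into a track over ``universe``.

    Universe bases absent from the file get depth 0. Segments overlapping
    each other raise; segments outside the universe are ignored (bedgraphs
    may cover more than the region of interest).
    """
    track = CoverageTrack(universe.merge(), sample_id=sample_id)
    written = [np.zeros(iv.length, dtype=bool) for iv in track.universe]
    chrom_idx = track._chrom_index()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            try:
                start, end, depth = int(fields[1]), int(fields[2]), int(float(fields[3]))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed segment") from exc
            if end <= start or depth < 0:
                raise BedParseError(f"{path}:{lineno}: invalid segment {start}-{end}:{depth}")
            if chrom not in chrom_idx:
                continue
            starts, ends, ks = chrom_idx[chrom]
            first = int(np.searchsorted(ends, start, side="right"))
            for j in range(first, len(starts)):
                if starts[j] >= end:
                    break
                s = max(start, int(starts[j])) - int(starts[j])
                e = min(end, int(ends[j])) - int(starts[j])
                if e <= s:
                    continue
                k = int(ks[j])
                if written[k][s:e].any():
                    raise BedParseError(f"{path}:{lineno}: overlapping bedgraph segments")
                written[k][s:e] = True
                track.depths[k][s:e] = depth
    return track


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a track in canonical bedgraph form (equal-depth runs coalesced,
    zero-depth runs included so the round trip is exact)."""
    with open(path, "w") as fh:
        for chrom, start, end, depth in track.segments():
            fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_intervals(
    filtered: CoverageTrack,
    unfiltered: CoverageTrack,
    intervals: IntervalSet,
    gc: np.ndarray | None = None,
    design: IntervalSet | None = None,
    mean_cds_depth: float | None = None,
) -> pd.DataFrame:
    """Per-interval coverage summary table.

    Columns: ``chrom, start, end, name, length, gc, mean_depth, norm_mean,
    mf, targeted``. ``mf = (unfiltered - filtered) / unfiltered`` mean depth,
    0 when the interval has no unfiltered coverage, clamped to [0, 1].
    ``norm_mean`` divides by the sample's mean filtered depth over the track
    universe (the CDS) unless an explicit denominator is given. ``targeted``
    means >=1 bp overlap with ``design``.
    """
    if mean_cds_depth is None:
        mean_cds_depth = filtered.mean_depth()
    if mean_cds_depth <= 0:
        raise ValueError("sample mean CDS depth is 0; normalized coverage undefined")
    design_merged = design.merge() if design is not None else None

    rows = []
    for k, iv in enumerate(intervals):
        mean_f = filtered.mean_over(iv)
        mean_u = unfiltered.mean_over(iv)
        if mean_u > 0:
            mf = float(np.clip((mean_u - mean_f) / mean_u, 0.0, 1.0))
        else:
            mf = 0.0
        if design_merged is None:
            targeted = True
        else:
            hit = IntervalSet([iv]).intersect(design_merged)
            targeted = hit.total_length > 0
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "name": iv.name,
                "length": iv.length,
                "gc": float(gc[k]) if gc is not None else np.nan,
                "mean_depth": mean_f,
                "norm_mean": mean_f / mean_cds_depth,
                "mf": mf,
                "targeted": targeted,
            }
        )
    return pd.DataFrame(rows)


def per_base_mf(filtered: CoverageTrack, unfiltered: CoverageTrack) -> list[np.ndarray]:
    """Per-base multimapping fraction, one float array per universe interval.

    ``mf = (u - f)/u`` with the convention mf = 0 where unfiltered depth is
    0; clamped to [0, 1] (filtered > unfiltered cannot occur when both
    tracks come from the same read set).
    """
    if filtered.universe != unfiltered.universe:
        raise ValueError("filtered and unfiltered tracks have different universes")
    out = []
    for df, du in zip(filtered.depths, unfiltered.depths):
        with np.errstate(divide="ignore", invalid="ignore"):
            mf = np.where(du > 0, (du - df) / np.maximum(du, 1), 0.0)
        out.append(np.clip(mf, 0.0, 1.0))
    return out


def mf_threshold_report(
    mf_track: list[np.ndarray], thresholds: Iterable[float] = (0.4, 1.0)
) -> dict[float, int]:
    """Total bp with per-base MF >= each threshold."""
    flat = np.concatenate(mf_track) if mf_track else np.zeros(0)
    return {float(t): int((flat >= t).sum()) for t in thresholds}


def enrichment_efficiency(
    track: CoverageTrack, target: IntervalSet, genome_length: int
) -> tuple[float, float]:
    """On-target fraction and fold enrichment of a capture experiment.

    ``on_target_fraction`` is the share of all sequenced bases (depth summed
    over the track universe) falling inside ``target``; ``fold_enrichment``
    compares mean on-target depth with the genome-wide mean depth
    (total depth / genome_length).
    """
    total = track.total_depth
    if total == 0:
        raise ValueError("track has zero total depth")
    target = target.merge()
    on_target = 0
    target_bases = 0
    for iv in target:
        d = track.depth_over(iv)
        on_target += int(d.sum())
        target_bases += iv.length
    on_target_fraction = on_target / total
    if target_bases == 0:
        raise ValueError("empty target set")
    fold = (on_target / target_bases) / (total / genome_length)
    return float(on_target_fraction), float(fold)
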