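"""Genomic interval containers, I/O and algebra.

All coordinates are 0-based half-open (BED convention). Interval algebra
(union, intersection, difference) is delegated to :mod:`pyranges`; this
module wraps it behind a small, sorted, optionally merged ``IntervalSet``
container so downstream statistics never deal with raw DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "DesignComparison",
    "read_bed",
    "read_gencode_cds",
    "merge",
    "intersect",
    "subtract",
    "annotate_gc",
    "design_coverage_stats",
    "DEFAULT_CHROMOSOMES",
]

# Primary human chromosomes, accepted with and without the "chr" prefix.
_BASE_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y", "MT", "M"]
DEFAULT_CHROMOSOMES = frozenset(_BASE_CHROMS) | frozenset("chr" + c for c in _BASE_CHROMS)


class BedParseError(ValueError):
    """Raised when a BED/bedgraph line cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic region ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Sorted collection of :class:`GenomicInterval`.

    ``merged`` records whether overlapping intervals were coalesced; algebra
    results are always merged, raw file reads are not.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], merged: bool = False):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.merged = bool(merged)
        if self.merged:
            prev: GenomicInterval | None = None
            for iv in self.intervals:
                if prev is not None and iv.chrom == prev.chrom and iv.start < prev.end:
                    raise ValueError("merged IntervalSet contains overlapping intervals")
                prev = iv

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [(i.chrom, i.start, i.end) for i in self] == [
            (i.chrom, i.start, i.end) for i in other
        ]

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bp={self.total_length}, merged={self.merged})"

    # -- properties ---------------------------------------------------------
    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    # -- conversions --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Chromosome": [iv.chrom for iv in self.intervals],
                "Start": np.asarray([iv.start for iv in self.intervals], dtype=np.int64),
                "End": np.asarray([iv.end for iv in self.intervals], dtype=np.int64),
                "Name": [iv.name for iv in self.intervals],
            }
        )

    def _to_pyranges(self) -> pr.PyRanges:
        return pr.PyRanges(self.to_frame()[["Chromosome", "Start", "End"]])

    @classmethod
    def _from_pyranges(cls, ranges: pr.PyRanges, merged: bool) -> "IntervalSet":
        if len(ranges) == 0:
            return cls([], merged=merged)
        df = ranges.df
        ivs = [
            GenomicInterval(str(c), int(s), int(e))
            for c, s, e in zip(df["Chromosome"], df["Start"], df["End"])
        ]
        return cls(ivs, merged=merged)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                name = iv.name if iv.name is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")

    # -- algebra ------------------------------------------------------------
    def merge(self) -> "IntervalSet":
        if self.merged:
            return self
        if len(self) == 0:
            return IntervalSet([], merged=True)
        return IntervalSet._from_pyranges(self._to_pyranges().merge(), merged=True)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        if len(self) == 0 or len(other) == 0:
            return IntervalSet([], merged=True)
        a = self.merge()._to_pyranges()
        b = other.merge()._to_pyranges()
        return IntervalSet._from_pyranges(a.intersect(b), merged=True)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        a = self.merge()
        if len(a) == 0 or len(other) == 0:
            return IntervalSet(a.intervals, merged=True)
        res = a._to_pyranges().subtract(other.merge()._to_pyranges())
        return IntervalSet._from_pyranges(res, merged=True)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self.intervals) + list(other.intervals)).merge()

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership test for a single position (0-based)."""
        ivs = [iv for iv in self.intervals if iv.chrom == chrom]
        if not ivs:
            return False
        starts = np.asarray([iv.start for iv in ivs])
        ends = np.asarray([iv.end for iv in ivs])
        k = int(np.searchsorted(starts, pos, side="right")) - 1
        return k >= 0 and pos < ends[k]

    def membership(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership of ``positions`` on ``chrom`` (merged sets)."""
        ivs = [iv for iv in self.merge().intervals if iv.chrom == chrom]
        out = np.zeros(len(positions), dtype=bool)
        if not ivs:
            return out
        starts = np.asarray([iv.start for iv in ivs])
        ends = np.asarray([iv.end for iv in ivs])
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out[ok] = positions[ok] < ends[idx[ok]]
        return out


@dataclass
class DesignComparison:
    """How well a capture design covers CDS/UTR annotation and variant sites."""

    design_total_length: int
    cds_bases_targeted: int
    cds_fraction_targeted: float
    utr_fraction_targeted: float | None
    variant_sites_targeted: int
    variant_sites_total: int


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str) -> IntervalSet:
    """Read a 3+ column BED file into a sorted, unmerged :class:`IntervalSet`.

    Raises :class:`BedParseError` naming the offending line for malformed
    coordinates.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise BedParseError(f"{path}:{lineno}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            intervals.append(GenomicInterval(chrom, start, end, name))
    return IntervalSet(intervals, merged=False)


def read_gencode_cds(
    path: str,
    chromosomes: frozenset[str] | set[str] = DEFAULT_CHROMOSOMES,
    biotypes: Sequence[str] = ("protein_coding",),
) -> IntervalSet:
    """Extract the merged union of protein-coding CDS regions from a GTF.

    Only features on whitelisted (primary) chromosomes are kept; scaffolds
    and non-coding biotypes are dropped. Uses :mod:`gffutils` with an
    in-memory database, so arbitrary GENCODE-dialect attribute layouts work.

    Emits a ``UserWarning`` and returns an empty set when no CDS feature
    survives the filters.
    """
    import warnings

    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    intervals: list[GenomicInterval] = []
    for feat in db.features_of_type("CDS"):
        if feat.seqid not in chromosomes:
            continue
        biotype = feat.attributes.get("gene_type") or feat.attributes.get("gene_biotype") or []
        if not any(b in biotypes for b in biotype):
            continue
        gene = (feat.attributes.get("gene_id") or [None])[0]
        # GTF is 1-based inclusive; convert to 0-based half-open.
        intervals.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, gene))
    if not intervals:
        warnings.warn(f"no protein-coding CDS features found in {path}", stacklevel=2)
        return IntervalSet([], merged=True)
    return IntervalSet(intervals).merge()


# ---------------------------------------------------------------------------
# Algebra (functional spellings)
# ---------------------------------------------------------------------------

def merge(a: IntervalSet) -> IntervalSet:
    return a.merge()


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


# ---------------------------------------------------------------------------
# GC annotation
# ---------------------------------------------------------------------------

def annotate_gc(intervals: IntervalSet, genome) -> np.ndarray:
    """Per-interval GC fraction ``(G+C)/(A+C+G+T)``.

    ``genome`` is a FASTA path, an open :class:`pyfaidx.Fasta`, or a plain
    ``{chrom: sequence}`` mapping. Ambiguous bases are excluded from the
    denominator; an interval made entirely of N returns ``nan``. Missing
    chromosomes raise ``KeyError`` naming the chromosome.
    """
    fasta = Fasta(genome) if isinstance(genome, str) else genome
    out = np.empty(len(intervals), dtype=float)
    for k, iv in enumerate(intervals):
        if iv.chrom not in fasta:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome FASTA")
        seq = str(fasta[iv.chrom][iv.start : iv.end]).upper()
        out[k] = gc_fraction(seq)
    return out


def gc_fraction(seq: str) -> float:
    """GC fraction of one sequence string, N-aware (nan when no ACGT base)."""
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    denom = gc + at
    return gc / denom if denom else float("nan")


# ---------------------------------------------------------------------------
# Design comparison
# ---------------------------------------------------------------------------

def design_coverage_stats(
    design: IntervalSet,
    cds: IntervalSet,
    utr: IntervalSet | None = None,
    variant_sites: Sequence[tuple[str, int]] = (),
) -> DesignComparison:
    """Fractions of CDS/UTR annotation and variant sites a design declares.

    All sets are merged before intersection; fractions are bp-based
    (``|design ∩ cds| / |cds|``). Variant sites are (chrom, 0-based pos)
    pairs counted as targeted when inside the design.
    """
    design = design.merge()
    cds = cds.merge()
    if cds.total_length == 0:
        raise ValueError("CDS set is empty; targeted fraction undefined")
    cds_hit = design.intersect(cds).total_length
    utr_frac: float | None = None
    if utr is not None:
        utr = utr.merge()
        if utr.total_length == 0:
            raise ValueError("UTR set is empty; targeted fraction undefined")
        utr_frac = design.intersect(utr).total_length / utr.total_length

    n_hit = 0
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in variant_sites:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom, positions in by_chrom.items():
        n_hit += int(design.membership(chrom, np.asarray(positions, dtype=np.int64)).sum())

    return DesignComparison(
        design_total_length=design.total_length,
        cds_bases_targeted=cds_hit,
        cds_fraction_targeted=cds_hit / cds.total_length,
        utr_fraction_targeted=utr_frac,
        variant_sites_targeted=n_hit,
        variant_sites_total=len(variant_sites),
    )
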