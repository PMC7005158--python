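"""Variant-call quality summaries from a VCF.

Counts variants per region set and type (SNV vs indel), counts low
genotype-quality calls (GQ below a working threshold, default 20 as in the
GATK genotype-refinement convention), and summarizes reference-allele
ratios at heterozygous sites — the allele-bias (AB) statistic is the
median fraction of reference-supporting reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .intervals import IntervalSet

__all__ = [
    "VariantCall",
    "AlleleRatioSummary",
    "read_calls",
    "count_variants",
    "lowgq_counts",
    "allele_ratios",
]


@dataclass
class VariantCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    is_indel: bool
    is_het: bool
    gq: int | None
    allele_depths: tuple[int, int] | None  # (ref_reads, alt_reads)


@dataclass
class AlleleRatioSummary:
    ratios: np.ndarray
    ab: float
    n_sites: int
    n_excluded_zero_depth: int = 0

    @property
    def empty(self) -> bool:
        return self.n_sites == 0


def _classify_indel(ref: str, alts: tuple[str, ...]) -> bool:
    """A record is indel-class iff any alt differs from the ref in length;
    MNPs therefore count as SNV-class."""
    return any(len(a) != len(ref) for a in alts)


def read_calls(vcf_path: str, sample: str | None = None) -> list[VariantCall]:
    """Load the variant (non hom-ref, non-missing) genotypes of one sample.

    With ``sample=None`` a single-sample VCF is required. Positions are
    converted to 0-based. Multi-allelic records yield one call.
    """
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    if sample is None:
        if len(samples) != 1:
            raise ValueError(f"VCF has {len(samples)} samples; specify one of {samples}")
        sidx = 0
    else:
        if sample not in samples:
            raise ValueError(f"sample {sample!r} not in VCF (has {samples})")
        sidx = samples.index(sample)

    calls: list[VariantCall] = []
    for rec in vcf:
        gt = rec.genotypes[sidx]
        alleles = [a for a in gt[:-1] if a is not None and a >= 0]
        if not alleles or all(a == 0 for a in alleles):
            continue  # missing or hom-ref
        alts = tuple(rec.ALT)
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        is_het = gts[sidx] == 1
        gq = None
        try:
            gq_arr = rec.gt_quals
            if gq_arr is not None and gq_arr[sidx] >= 0:
                gq = int(gq_arr[sidx])
        except Exception:
            gq = None
        ad = None
        try:
            ad_arr = rec.format("AD")
            if ad_arr is not None:
                ref_d = int(ad_arr[sidx][0])
                alt_d = int(ad_arr[sidx][1:].sum())
                if ref_d >= 0 and alt_d >= 0:
                    ad = (ref_d, alt_d)
        except Exception:
            ad = None
        calls.append(
            VariantCall(
                chrom=rec.CHROM,
                pos=rec.POS - 1,
                ref=rec.REF,
                alts=alts,
                is_indel=_classify_indel(rec.REF, alts),
                is_het=is_het,
                gq=gq,
                allele_depths=ad,
            )
        )
    return calls


def _in_set(call: VariantCall, region_set: IntervalSet) -> bool:
    return region_set.contains(call.chrom, call.pos)


def count_variants(
    calls: list[VariantCall] | str,
    region_sets: dict[str, IntervalSet],
    sample: str | None = None,
    split_by_type: bool = True,
) -> pd.DataFrame:
    """Variant counts per region set (rows) and type (columns).

    ``calls`` may be a VCF path (then ``sample`` selects the genotype
    column) or a pre-loaded call list. A record counts once per set when its
    position lies inside the set.
    """
    if isinstance(calls, str):
        calls = read_calls(calls, sample=sample)
    rows = []
    for name, rset in region_sets.items():
        inside = [c for c in calls if _in_set(c, rset)]
        row = {"set": name, "total": len(inside)}
        if split_by_type:
            row["snv"] = sum(not c.is_indel for c in inside)
            row["indel"] = sum(c.is_indel for c in inside)
        rows.append(row)
    return pd.DataFrame(rows)


def lowgq_counts(
    calls: list[VariantCall] | str,
    region_sets: dict[str, IntervalSet],
    gq_threshold: int = 20,
    sample: str | None = None,
    split_by_type: bool = True,
) -> pd.DataFrame:
    """Counts of low genotype-quality calls (GQ < threshold) per set x type.

    Calls with missing GQ are treated as lowGQ and also reported separately
    in the ``missing_gq`` column.
    """
    if isinstance(calls, str):
        calls = read_calls(calls, sample=sample)
    rows = []
    for name, rset in region_sets.items():
        inside = [c for c in calls if _in_set(c, rset)]
        low = [c for c in inside if c.gq is None or c.gq < gq_threshold]
        row = {
            "set": name,
            "lowgq": len(low),
            "missing_gq": sum(c.gq is None for c in inside),
        }
        if split_by_type:
            row["lowgq_snv"] = sum(not c.is_indel for c in low)
            row["lowgq_indel"] = sum(c.is_indel for c in low)
        rows.append(row)
    return pd.DataFrame(rows)


def allele_ratios(
    calls: list[VariantCall] | str,
    min_depth: int = 0,
    sample: str | None = None,
) -> AlleleRatioSummary:
    """Reference-allele ratios at heterozygous biallelic sites.

    ratio = ref_reads / (ref_reads + alt_reads), restricted to sites with
    total allele depth > ``min_depth``; AB is the median ratio. Zero-depth
    sites are excluded and counted.
    """
    if isinstance(calls, str):
        calls = read_calls(calls, sample=sample)
    ratios = []
    n_zero = 0
    for c in calls:
        if not c.is_het or len(c.alts) != 1 or c.allele_depths is None:
            continue
        ref_d, alt_d = c.allele_depths
        total = ref_d + alt_d
        if total == 0:
            n_zero += 1
            continue
        if total > min_depth:
            ratios.append(ref_d / total)
    arr = np.asarray(ratios, dtype=float)
    return AlleleRatioSummary(
        ratios=arr,
        ab=float(np.median(arr)) if len(arr) else float("nan"),
        n_sites=len(arr),
        n_excluded_zero_depth=n_zero,
    )
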