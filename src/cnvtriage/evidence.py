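"""Per-CNV alignment evidence from BAM/CRAM.

A real deletion or duplication leaves three footprints in paired-end WGS
alignments: a read-depth shift inside the event (about 0.5x for a
heterozygous deletion, 1.5x for a heterozygous duplication), anomalous
read pairs whose insert size or orientation reflects the rearranged
allele, and split reads whose alignment is divided across a breakpoint.
This module extracts all three for one CNV and a window that includes
flanks of 50% of the variant size (minimum 100 kb) on each side, and
condenses them into a depth ratio, a median mapping quality, a
supporting-read count and a [0, 1] guidance quality score.

Depth semantics: unmapped, secondary, duplicate-marked and QC-fail reads
are excluded; supplementary alignments are used only for split-read
detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .core import CnvCall, CnvType, GenomicInterval

__all__ = [
    "MIN_FLANK_BP",
    "AnomalousRead",
    "BinStat",
    "EvidenceProfile",
    "compute_flanks",
    "binned_depth_mq",
    "depth_metrics",
    "estimate_insert_bounds",
    "classify_anomalous_reads",
    "count_supporting_reads",
    "quality_score",
    "compare_reference_sample",
    "extract_evidence",
]

MIN_FLANK_BP = 100_000
DEFAULT_N_BINS = 200
DEFAULT_LOWER_PCT = 0.5
DEFAULT_UPPER_PCT = 99.5
DEFAULT_BREAKPOINT_TOLERANCE = 1_000
DEFAULT_SUPPORT_SATURATION = 5
MQ_SATURATION = 40.0

CATEGORIES = ("inward_insert_outlier", "outward", "same_direction", "split")


@dataclass(frozen=True)
class AnomalousRead:
    read_name: str
    category: str
    chrom: str
    start: int
    end: int
    mate_start: int | None
    insert_size: int | None
    junction: int | None = None  # clip-side coordinate for split reads
    supports_cnv: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown anomalous category {self.category!r}")


@dataclass(frozen=True)
class BinStat:
    interval: GenomicInterval
    mean_depth: float
    mean_mq: float | None


@dataclass
class EvidenceProfile:
    cnv: CnvCall
    flank_bp: int
    bins: list[BinStat]
    depth_ratio: float | None
    median_mq_inside: float | None
    insert_bounds: tuple[float, float, float, float]  # lower, upper, lower_pct, upper_pct
    anomalous_reads: list[AnomalousRead]
    supporting_read_count: int
    quality_score: float
    reference_flagged_bins: list[int] = field(default_factory=list)


class EvidenceError(Exception):
    pass


def _read_passes(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.is_qcfail
    )


def compute_flanks(cnv: CnvCall, min_flank_bp: int = MIN_FLANK_BP) -> int:
    """Per-side flank width: half the variant size, but at least 100 kb."""
    return max(int(math.ceil(0.5 * cnv.length())), min_flank_bp)


def window_for(cnv: CnvCall, flank_bp: int, chrom_length: int | None = None) -> GenomicInterval:
    """Flanked window around the CNV, clamped to chromosome bounds."""
    start = max(0, cnv.start - flank_bp)
    end = cnv.end + flank_bp
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(cnv.chrom, start, end)


def _chrom_length(af: pysam.AlignmentFile, chrom: str) -> int | None:
    try:
        return af.get_reference_length(chrom)
    except (KeyError, ValueError):
        return None


def _per_base_depth(af: pysam.AlignmentFile, iv: GenomicInterval) -> np.ndarray:
    acgt = af.count_coverage(
        iv.chrom, iv.start, iv.end, quality_threshold=0, read_callback=_read_passes
    )
    return np.asarray(acgt, dtype=np.int64).sum(axis=0)


def binned_depth_mq(
    alignments: pysam.AlignmentFile,
    window: GenomicInterval,
    n_bins: int = DEFAULT_N_BINS,
) -> list[BinStat]:
    """Split *window* into near-equal bins; per-bin mean per-base depth and
    mean mapping quality of overlapping reads.  Empty bins report depth 0
    and MQ absent."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    depth = _per_base_depth(alignments, window)
    edges = np.linspace(window.start, window.end, n_bins + 1).astype(int)
    mq_sum = np.zeros(n_bins)
    mq_n = np.zeros(n_bins, dtype=np.int64)
    for read in alignments.fetch(window.chrom, window.start, window.end):
        if not _read_passes(read):
            continue
        lo = np.searchsorted(edges, read.reference_start, side="right") - 1
        hi = np.searchsorted(edges, read.reference_end - 1, side="right") - 1
        lo = max(lo, 0)
        hi = min(hi, n_bins - 1)
        for b in range(lo, hi + 1):
            mq_sum[b] += read.mapping_quality
            mq_n[b] += 1
    bins = []
    for b in range(n_bins):
        s, e = int(edges[b]), int(edges[b + 1])
        if e <= s:
            continue
        seg = depth[s - window.start : e - window.start]
        bins.append(
            BinStat(
                GenomicInterval(window.chrom, s, e),
                float(seg.mean()) if seg.size else 0.0,
                float(mq_sum[b] / mq_n[b]) if mq_n[b] else None,
            )
        )
    return bins


def depth_metrics(
    alignments: pysam.AlignmentFile, cnv: CnvCall, flank_bp: int
) -> tuple[float | None, float | None]:
    """(depth_ratio, median_mq_inside).

    depth_ratio = median per-base depth inside the CNV divided by the
    median over both flanks pooled; absent when the flank median is zero.
    """
    chrom_len = _chrom_length(alignments, cnv.chrom)
    inside = _per_base_depth(alignments, cnv.interval)
    left_start = max(0, cnv.start - flank_bp)
    flank_parts = []
    if left_start < cnv.start:
        flank_parts.append(
            _per_base_depth(alignments, GenomicInterval(cnv.chrom, left_start, cnv.start))
        )
    right_end = cnv.end + flank_bp
    if chrom_len is not None:
        right_end = min(right_end, chrom_len)
    if right_end > cnv.end:
        flank_parts.append(
            _per_base_depth(alignments, GenomicInterval(cnv.chrom, cnv.end, right_end))
        )
    flank = np.concatenate(flank_parts) if flank_parts else np.array([])
    flank_median = float(np.median(flank)) if flank.size else 0.0
    ratio = float(np.median(inside)) / flank_median if flank_median > 0 else None

    mqs = [
        read.mapping_quality
        for read in alignments.fetch(cnv.chrom, cnv.start, cnv.end)
        if _read_passes(read)
    ]
    median_mq = float(np.median(mqs)) if mqs else None
    return ratio, median_mq


def _is_inward(read: pysam.AlignedSegment) -> bool:
    """Inward (FR) orientation: leftmost mate forward, rightmost reverse."""
    if read.is_reverse == read.mate_is_reverse:
        return False
    left_is_self = read.reference_start <= read.next_reference_start
    left_reverse = read.is_reverse if left_is_self else read.mate_is_reverse
    return not left_reverse


def _pair_usable(read: pysam.AlignedSegment) -> bool:
    return (
        _read_passes(read)
        and read.is_paired
        and not read.mate_is_unmapped
        and read.reference_id == read.next_reference_id
    )


def estimate_insert_bounds(
    alignments: pysam.AlignmentFile,
    window: GenomicInterval | None,
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
    min_pairs: int = 1_000,
    fallback_sample: int = 100_000,
) -> tuple[float, float, float, float]:
    """Empirical insert-size outlier bounds.

    Percentiles (default 0.5 / 99.5) of the absolute template length of
    inward-oriented pairs in *window*; if fewer than *min_pairs* are found
    the sample falls back to up to *fallback_sample* pairs genome-wide.
    """

    def collect(fetch_iter, limit=None):
        out = []
        for read in fetch_iter:
            if not _pair_usable(read) or read.template_length <= 0:
                continue  # use the positive-tlen mate once per pair
            if not _is_inward(read):
                continue
            out.append(read.template_length)
            if limit and len(out) >= limit:
                break
        return out

    inserts: list[int] = []
    if window is not None:
        inserts = collect(alignments.fetch(window.chrom, window.start, window.end))
    if len(inserts) < min_pairs:
        inserts = collect(alignments.fetch(), limit=fallback_sample)
    if not inserts:
        raise EvidenceError(
            "no inward proper pairs found to estimate insert-size bounds; "
            "check that the alignment file is paired-end and indexed"
        )
    arr = np.asarray(inserts)
    lower = float(np.percentile(arr, lower_pct))
    upper = float(np.percentile(arr, upper_pct))
    return lower, upper, lower_pct, upper_pct


def classify_anomalous_reads(
    alignments: pysam.AlignmentFile,
    window: GenomicInterval,
    insert_bounds: tuple[float, float, float, float],
) -> list[AnomalousRead]:
    """Four-way anomalous-read taxonomy over primary alignments in *window*.

    Precedence per pair: split (supplementary-alignment evidence, SA tag)
    > same_direction (mates on the same strand) > outward (pair faces
    away) > inward_insert_outlier (normal orientation, template length
    outside the bounds).  Normally-sized inward pairs are not anomalous.
    One record is emitted per read name.
    """
    lower, upper = insert_bounds[0], insert_bounds[1]
    seen: dict[str, AnomalousRead] = {}
    for read in alignments.fetch(window.chrom, window.start, window.end):
        if not _pair_usable(read):
            continue
        name = read.query_name
        insert = abs(read.template_length) or None
        category = None
        junction = None
        if read.has_tag("SA"):
            category = "split"
            # junction side = the soft-clipped end of the primary alignment
            cigar = read.cigartuples or []
            if cigar and cigar[0][0] in (4, 5):
                junction = read.reference_start
            else:
                junction = read.reference_end
        elif read.is_reverse == read.mate_is_reverse:
            category = "same_direction"
        elif not _is_inward(read):
            category = "outward"
        elif insert is not None and (insert < lower or insert > upper):
            category = "inward_insert_outlier"
        if category is None:
            continue
        record = AnomalousRead(
            name,
            category,
            read.reference_name,
            read.reference_start,
            read.reference_end,
            read.next_reference_start,
            insert,
            junction,
        )
        prev = seen.get(name)
        # split evidence wins if the two mates classify differently
        if prev is None or (category == "split" and prev.category != "split"):
            seen[name] = record
    return sorted(seen.values(), key=lambda r: (r.start, r.read_name))


def _pair_span(read: AnomalousRead, read_length: int | None = None) -> tuple[int, int]:
    length = read.end - read.start if read_length is None else read_length
    left = min(read.start, read.mate_start if read.mate_start is not None else read.start)
    right = max(read.end, (read.mate_start + length) if read.mate_start is not None else read.end)
    return left, right


def count_supporting_reads(
    anomalous: Sequence[AnomalousRead],
    cnv: CnvCall,
    tolerance_bp: int = DEFAULT_BREAKPOINT_TOLERANCE,
) -> tuple[int, list[AnomalousRead]]:
    """Count anomalous reads whose geometry supports this CNV.

    Deletion support: inward large-insert pairs whose outer span straddles
    both breakpoints (leftmost alignment ending within *tolerance_bp* of
    the start, rightmost starting within tolerance of the end), plus split
    reads whose junction lies within tolerance of either breakpoint.
    Duplication support: outward pairs bracketing the event (leftmost
    alignment starting near the start, rightmost ending near the end),
    plus split reads at either breakpoint.  Returns the count and the
    records with ``supports_cnv`` set.
    """
    flagged: list[AnomalousRead] = []
    count = 0
    for read in anomalous:
        supports = False
        if read.category == "split" and read.junction is not None:
            supports = (
                abs(read.junction - cnv.start) <= tolerance_bp
                or abs(read.junction - cnv.end) <= tolerance_bp
            )
        elif cnv.cnv_type is CnvType.DELETION and read.category == "inward_insert_outlier":
            left, right = _pair_span(read)
            supports = (
                abs(left + (read.end - read.start) - cnv.start) <= tolerance_bp
                and abs(right - (read.end - read.start) - cnv.end) <= tolerance_bp
            )
        elif cnv.cnv_type is CnvType.DUPLICATION and read.category == "outward":
            left, right = _pair_span(read)
            supports = (
                abs(left - cnv.start) <= tolerance_bp and abs(right - cnv.end) <= tolerance_bp
            )
        if supports:
            count += 1
            read = AnomalousRead(
                read.read_name,
                read.category,
                read.chrom,
                read.start,
                read.end,
                read.mate_start,
                read.insert_size,
                read.junction,
                True,
            )
        flagged.append(read)
    return count, flagged


def quality_score(
    depth_ratio: float | None,
    median_mq_inside: float | None,
    supporting_read_count: int,
    cnv_type: CnvType,
    support_saturation: int = DEFAULT_SUPPORT_SATURATION,
) -> float:
    """Composite [0, 1] guidance score: product of three terms.

    depth term — how far the ratio has moved from 1.0 toward the
    heterozygous expectation (0.5 for deletions, 1.5 for duplications),
    clamped to [0, 1]; zero at ratio 1.0, saturating at the expectation.
    MQ term — median MQ / 40, capped at 1.  Support term — supporting
    reads / saturation count (default 5), capped at 1.  Guidance only;
    each term is monotone in its input.
    """
    if depth_ratio is None:
        depth_term = 0.0
    elif cnv_type is CnvType.DELETION:
        depth_term = min(max((1.0 - depth_ratio) / 0.5, 0.0), 1.0)
    else:
        depth_term = min(max((depth_ratio - 1.0) / 0.5, 0.0), 1.0)
    mq_term = 0.0 if median_mq_inside is None else min(median_mq_inside / MQ_SATURATION, 1.0)
    support_term = min(supporting_read_count / support_saturation, 1.0)
    return depth_term * mq_term * support_term


def compare_reference_sample(
    sample_bins: Sequence[BinStat],
    reference_bins: Sequence[BinStat],
    deviation_threshold: float = 0.3,
) -> list[int]:
    """Flag bins where the REFERENCE sample deviates from its own baseline.

    The reference sample does not carry the proband's CNV, so any depth
    excursion it shows marks a locus with systematic mapping issues; a
    co-located excursion in the proband is then suspect.  Baseline =
    median reference bin depth; a bin is flagged when its relative
    deviation exceeds *deviation_threshold*.  Both samples must share the
    binning grid.
    """
    if len(sample_bins) != len(reference_bins) or any(
        s.interval != r.interval for s, r in zip(sample_bins, reference_bins)
    ):
        raise EvidenceError("sample and reference bin grids differ")
    depths = np.array([b.mean_depth for b in reference_bins])
    baseline = float(np.median(depths))
    if baseline == 0:
        return []
    return [
        i for i, d in enumerate(depths) if abs(d - baseline) / baseline > deviation_threshold
    ]


def extract_evidence(
    bam_path: str,
    cnv: CnvCall,
    reference_bam_path: str | None = None,
    n_bins: int = DEFAULT_N_BINS,
    tolerance_bp: int = DEFAULT_BREAKPOINT_TOLERANCE,
    lower_pct: float = DEFAULT_LOWER_PCT,
    upper_pct: float = DEFAULT_UPPER_PCT,
    reference_fasta: str | None = None,
    flank_bp: int | None = None,
) -> EvidenceProfile:
    """Full evidence profile for one CNV from an indexed BAM/CRAM."""
    mode_kwargs = {}
    if reference_fasta:
        mode_kwargs["reference_filename"] = reference_fasta
    with pysam.AlignmentFile(bam_path, **mode_kwargs) as af:
        if not af.has_index():
            raise EvidenceError(
                f"{bam_path} has no index; run `samtools index` (or pysam.index) first"
            )
        flank = compute_flanks(cnv) if flank_bp is None else flank_bp
        window = window_for(cnv, flank, _chrom_length(af, cnv.chrom))
        bins = binned_depth_mq(af, window, n_bins)
        ratio, median_mq = depth_metrics(af, cnv, flank)
        bounds = estimate_insert_bounds(af, window, lower_pct, upper_pct)
        anomalous = classify_anomalous_reads(af, window, bounds)
        support, anomalous = count_supporting_reads(anomalous, cnv, tolerance_bp)
        q = quality_score(ratio, median_mq, support, cnv.cnv_type)
    flagged: list[int] = []
    if reference_bam_path:
        with pysam.AlignmentFile(reference_bam_path, **mode_kwargs) as ref:
            ref_bins = binned_depth_mq(ref, window, n_bins)
        flagged = compare_reference_sample(bins, ref_bins)
    return EvidenceProfile(
        cnv=cnv,
        flank_bp=flank,
        bins=bins,
        depth_ratio=ratio,
        median_mq_inside=median_mq,
        insert_bounds=bounds,
        anomalous_reads=anomalous,
        supporting_read_count=support,
        quality_score=q,
        reference_flagged_bins=flagged,
    )
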