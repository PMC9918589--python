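"""Three-step variant filtration.

Raw WGS CNV call lists run to thousands of calls per genome, almost all of
them artefacts of problematic reference regions or common polymorphisms.
Filtration removes, in order:

1. calls fully contained in problem regions (assembly gaps, centromeres,
   repeats) or locally recurrent artefact regions;
2. calls that touch no coding sequence, unless they overlap a gene on the
   non-coding exception list (genes with clinically relevant non-coding
   variation);
3. calls fully contained in a same-type population variant whose allele
   frequency exceeds 1% in any surveyed population.

Each removal records the step and a human-readable reason, so the funnel
is auditable call by call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotations import AnnotationSet
from .core import CnvCall, GenomicInterval, containment_fraction, normalize_chrom, overlap_bp

__all__ = [
    "FiltrationResult",
    "filter_problem_regions",
    "filter_coding_overlap",
    "filter_population_contained",
    "run_filtration",
    "recurrence_regions",
]

DEFAULT_AF_THRESHOLD = 0.01  # "> 1% frequency" rule; strictly greater
DEFAULT_RECURRENCE_FRACTION = 0.03


@dataclass
class FiltrationResult:
    survivors: list[CnvCall]
    removed: list[tuple[CnvCall, int, str]]
    per_step_counts: dict[int, int] = field(default_factory=dict)

    @property
    def input_count(self) -> int:
        return len(self.survivors) + len(self.removed)


def _contained_in_union(call: CnvCall, regions: Sequence[GenomicInterval]) -> bool:
    """True iff every base of *call* is covered by the region union.

    Regions must be the pre-merged union (sorted, non-overlapping per
    chromosome); coverage is then a single sweep.
    """
    covered = 0
    for region in regions:
        covered += overlap_bp(call.interval, region)
    return covered >= call.length()


def filter_problem_regions(
    calls: Sequence[CnvCall],
    annotation: AnnotationSet,
    use_union: bool = True,
) -> tuple[list[CnvCall], list[tuple[CnvCall, str]]]:
    """Step 1: drop calls fully contained in problem/recurrence regions.

    With *use_union* (default) containment is judged against the merged
    union of all problem regions, so a call straddling two abutting repeat
    records still counts as contained; otherwise each record is tested
    individually.
    """
    if not annotation.problem_regions:
        return list(calls), []
    union = annotation.merged_problem_regions() if use_union else None
    retained, removed = [], []
    for call in calls:
        if use_union:
            contained = _contained_in_union(call, union)
        else:
            contained = any(
                containment_fraction(call.interval, r) == 1.0
                for r in annotation.problem_overlaps(call.interval)
            )
        if contained:
            removed.append((call, "problem-region containment"))
        else:
            retained.append(call)
    return retained, removed


def _overlaps_cds(call: CnvCall, annotation: AnnotationSet) -> bool:
    for gene in annotation.genes_overlapping(call.interval):
        for tx in gene.transcripts:
            for cds in tx.cds:
                if overlap_bp(call.interval, cds) > 0:
                    return True
    return False


def _overlaps_exception_gene(call: CnvCall, annotation: AnnotationSet) -> bool:
    for gene in annotation.genes_overlapping(call.interval):
        if gene.symbol in annotation.noncoding_exception_genes:
            if overlap_bp(call.interval, gene.span()) > 0:
                return True
    return False


def filter_coding_overlap(
    calls: Sequence[CnvCall], annotation: AnnotationSet
) -> tuple[list[CnvCall], list[tuple[CnvCall, str]]]:
    """Step 2: retain calls touching >=1 bp of CDS (any transcript), or
    overlapping any part of a non-coding-exception gene; drop the rest."""
    retained, removed = [], []
    for call in calls:
        if _overlaps_cds(call, annotation) or _overlaps_exception_gene(call, annotation):
            retained.append(call)
        else:
            removed.append((call, "non-coding"))
    return retained, removed


def filter_population_contained(
    calls: Sequence[CnvCall],
    annotation: AnnotationSet,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
) -> tuple[list[CnvCall], list[tuple[CnvCall, str]]]:
    """Step 3: drop calls fully contained in a same-type population SV seen
    at a frequency strictly greater than *af_threshold* in any population."""
    retained, removed = [], []
    for call in calls:
        reason = None
        for sv in annotation.population_overlaps(call.interval):
            if sv.sv_type is not call.cnv_type:
                continue
            if not any(af > af_threshold for af in sv.af_by_population.values()):
                continue
            if containment_fraction(call.interval, sv.interval) == 1.0:
                reason = f"contained in population SV {sv.id} (popmax AF {sv.popmax_af:g})"
                break
        if reason is None:
            retained.append(call)
        else:
            removed.append((call, reason))
    return retained, removed


def run_filtration(
    calls: Sequence[CnvCall],
    annotation: AnnotationSet,
    af_threshold: float = DEFAULT_AF_THRESHOLD,
    skip_filtration: bool = False,
    problem_region_union: bool = True,
) -> FiltrationResult:
    """Apply the three filtration steps in order, recording the funnel.

    With *skip_filtration* the input passes through untouched (analysts who
    pre-filter upstream go straight to prioritization).
    """
    calls = list(calls)
    if skip_filtration:
        return FiltrationResult(calls, [], {1: len(calls), 2: len(calls), 3: len(calls)})
    removed_all: list[tuple[CnvCall, int, str]] = []
    counts: dict[int, int] = {}

    survivors, removed = filter_problem_regions(calls, annotation, problem_region_union)
    removed_all += [(c, 1, r) for c, r in removed]
    counts[1] = len(survivors)

    survivors, removed = filter_coding_overlap(survivors, annotation)
    removed_all += [(c, 2, r) for c, r in removed]
    counts[2] = len(survivors)

    survivors, removed = filter_population_contained(survivors, annotation, af_threshold)
    removed_all += [(c, 3, r) for c, r in removed]
    counts[3] = len(survivors)

    return FiltrationResult(survivors, removed_all, counts)


def recurrence_regions(
    annotation: AnnotationSet,
    n_samples: int,
    min_carrier_fraction: float = DEFAULT_RECURRENCE_FRACTION,
) -> list[GenomicInterval]:
    """Derive recurrence regions from the internal cohort.

    A recurrence region is a maximal interval where the fraction of cohort
    samples carrying a same-type CNV exceeds *min_carrier_fraction* — a
    proxy for locally recurrent artefacts / common CNV hotspots.  The
    result can be appended to the problem-region table for step 1.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    events: dict[str, list[tuple[int, int, str]]] = {}
    for entry in annotation.internal_cohort:
        iv = entry.call.interval
        events.setdefault(normalize_chrom(iv.chrom), []).append(
            (iv.start, iv.end, entry.sample_id)
        )
    out: list[GenomicInterval] = []
    for chrom, items in events.items():
        breaks = sorted({p for s, e, _ in items for p in (s, e)})
        dialect_chrom = next(
            e.call.chrom
            for e in annotation.internal_cohort
            if normalize_chrom(e.call.chrom) == chrom
        )
        run_start = None
        prev_end = None
        for lo, hi in zip(breaks, breaks[1:]):
            carriers = {sid for s, e, sid in items if s <= lo and e >= hi}
            hot = len(carriers) / n_samples > min_carrier_fraction
            if hot:
                if run_start is None:
                    run_start = lo
                prev_end = hi
            elif run_start is not None:
                out.append(GenomicInterval(dialect_chrom, run_start, prev_end))
                run_start = None
        if run_start is not None:
            out.append(GenomicInterval(dialect_chrom, run_start, prev_end))
    out.sort(key=lambda r: (normalize_chrom(r.chrom), r.start))
    return out
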