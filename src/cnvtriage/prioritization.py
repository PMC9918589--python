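"""Annotation and priority scoring of CNV calls.

Every surviving CNV is annotated against five categories — population
SVs, known pathogenic SVs, the internal cohort, dosage-sensitivity
curations, and gene models — and receives a priority score:

    priority = clinical_relevance + adverse_information

Lower is better.  Clinical relevance is a ladder over dosage curation,
loss-of-function constraint and disease association: deletions score in
{1..5, 99}, duplications in {1..7, 99}, with 99 meaning "no known clinical
relevance".  Adverse information is binary {0, 100}: 100 whenever any
evidence against the call being real or pathogenic fires (substantial
population overlap, depth signal inconsistent with the call type, poor
mapping quality, heavy problem-region overlap).  The tier cutpoints follow
from the sum: < 99 high priority (needs review), == 99 moderate, > 99 low.

The ladder itself is data (a rules table of (score, finding-code) pairs),
so a site can reorder or extend it without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .annotations import AnnotationSet, DosageRegion, GeneModel, TranscriptModel
from .core import (
    CnvCall,
    CnvType,
    GenomicInterval,
    containment_fraction,
    overlap_bp,
    reciprocal_overlap,
)

__all__ = [
    "ScoreConfig",
    "TranscriptImpact",
    "GeneImpact",
    "AnnotationBundle",
    "PriorityResult",
    "annotate_cnv",
    "clinical_relevance_score",
    "adverse_information_score",
    "priority_score",
    "rank_cnvs",
    "summarize_findings",
    "DEFAULT_DELETION_LADDER",
    "DEFAULT_DUPLICATION_LADDER",
]

NO_RELEVANCE = 99
ADVERSE = 100


@dataclass(frozen=True)
class ScoreConfig:
    """Tunable thresholds of the scoring scheme (defaults documented in
    docs/methods.md)."""

    pli_cutoff: float = 0.9
    curated_levels: frozenset[str] = frozenset({"2", "3"})
    adverse_reciprocal_overlap: float = 0.7
    adverse_popmax_af: float = 0.01
    deletion_ratio_max: float = 0.85   # a real deletion should dip below this
    duplication_ratio_min: float = 1.15  # a real duplication should rise above
    min_median_mq: float = 20.0
    problem_fraction_max: float = 0.7
    deletion_ladder: tuple[tuple[int, str], ...] | None = None
    duplication_ladder: tuple[tuple[int, str], ...] | None = None


@dataclass(frozen=True)
class TranscriptImpact:
    transcript_id: str
    is_canonical: bool
    affected_exon_numbers: tuple[int, ...]
    affected_cds_bp: int
    pext_min: float | None = None
    pext_max: float | None = None


@dataclass(frozen=True)
class GeneImpact:
    symbol: str
    overlap_kind: str  # "full" | "partial"
    strand: str
    pli: float | None
    disease_associations: tuple[tuple[str, str], ...]
    affected_transcripts: tuple[TranscriptImpact, ...]

    @property
    def affected_cds_bp(self) -> int:
        return max((t.affected_cds_bp for t in self.affected_transcripts), default=0)

    @property
    def has_disease_association(self) -> bool:
        return len(self.disease_associations) > 0


@dataclass
class AnnotationBundle:
    cnv: CnvCall
    population_hits: list[tuple] = field(default_factory=list)  # (sv, ro, containment)
    known_sv_hits: list[tuple] = field(default_factory=list)    # (sv, ro, containment)
    internal_hits: list[tuple] = field(default_factory=list)    # (entry, ro)
    dosage_hits: list[tuple] = field(default_factory=list)      # (entry, region_in_cnv, overlap_bp)
    gene_impacts: list[GeneImpact] = field(default_factory=list)
    problem_fraction: float = 0.0


@dataclass(frozen=True)
class PriorityResult:
    clinical_relevance: int
    adverse: int
    triggered_rules: tuple[str, ...] = ()
    adverse_reasons: tuple[str, ...] = ()

    def __post_init__(self):
        if self.adverse not in (0, ADVERSE):
            raise ValueError(f"adverse must be 0 or {ADVERSE}")
        if not (1 <= self.clinical_relevance < NO_RELEVANCE or self.clinical_relevance == NO_RELEVANCE):
            raise ValueError(f"illegal clinical relevance {self.clinical_relevance}")

    @property
    def priority(self) -> int:
        return self.clinical_relevance + self.adverse

    @property
    def tier(self) -> str:
        if self.priority < NO_RELEVANCE:
            return "high"
        if self.priority == NO_RELEVANCE:
            return "moderate"
        return "low"


# ---------------------------------------------------------------------------
# Annotation


def _impact_for_gene(cnv: CnvCall, gene: GeneModel) -> GeneImpact | None:
    span = gene.span()
    if overlap_bp(cnv.interval, span) == 0:
        return None
    kind = "full" if containment_fraction(span, cnv.interval) == 1.0 else "partial"
    tx_impacts = []
    for tx in gene.transcripts:
        exon_numbers = []
        pexts = []
        for i, exon in enumerate(tx.exons):
            if overlap_bp(cnv.interval, exon) > 0:
                exon_numbers.append(tx.exon_number(i, gene.strand))
                if tx.exon_pext is not None:
                    pexts.append(tx.exon_pext[i])
        cds_bp = sum(overlap_bp(cnv.interval, c) for c in tx.cds)
        if exon_numbers or cds_bp:
            tx_impacts.append(
                TranscriptImpact(
                    tx.transcript_id,
                    tx.is_canonical,
                    tuple(sorted(exon_numbers)),
                    cds_bp,
                    min(pexts) if pexts else None,
                    max(pexts) if pexts else None,
                )
            )
    return GeneImpact(
        gene.symbol,
        kind,
        gene.strand,
        gene.pli,
        gene.disease_associations,
        tuple(tx_impacts),
    )


def annotate_cnv(cnv: CnvCall, annotation: AnnotationSet) -> AnnotationBundle:
    """Attach all five annotation categories to one CNV.

    Hit lists are deterministic: sorted by position then identifier.
    ``problem_fraction`` (fraction of the CNV covered by the merged
    problem-region union) is carried for the adverse-information score.
    """
    iv = cnv.interval
    bundle = AnnotationBundle(cnv)

    for sv in annotation.population_overlaps(iv):
        bundle.population_hits.append(
            (sv, reciprocal_overlap(iv, sv.interval), containment_fraction(iv, sv.interval))
        )
    bundle.population_hits.sort(key=lambda h: (h[0].interval, h[0].id))

    for sv in annotation.known_sv_overlaps(iv):
        bundle.known_sv_hits.append(
            (sv, reciprocal_overlap(iv, sv.interval), containment_fraction(iv, sv.interval))
        )
    bundle.known_sv_hits.sort(key=lambda h: (h[0].interval, h[0].id))

    for entry in annotation.cohort_overlaps(iv):
        bundle.internal_hits.append((entry, reciprocal_overlap(iv, entry.call.interval)))
    bundle.internal_hits.sort(key=lambda h: (h[0].call.interval, h[0].sample_id))

    for entry in annotation.dosage_overlaps(iv):
        bundle.dosage_hits.append(
            (
                entry,
                containment_fraction(entry.interval, iv),
                overlap_bp(iv, entry.interval),
            )
        )
    bundle.dosage_hits.sort(key=lambda h: (h[0].interval, h[0].symbol_or_id))

    impacts = []
    for gene in annotation.genes_overlapping(iv):
        impact = _impact_for_gene(cnv, gene)
        if impact is not None:
            impacts.append(impact)
    impacts.sort(key=lambda g: g.symbol)
    bundle.gene_impacts = impacts

    covered = sum(overlap_bp(iv, r) for r in annotation.merged_problem_regions())
    bundle.problem_fraction = covered / iv.length()
    return bundle


# ---------------------------------------------------------------------------
# Clinical relevance ladder (rules are data; predicates live in a registry)


def _hi_curated(entry: DosageRegion, cfg: ScoreConfig) -> bool:
    return entry.hi_score is not None and entry.hi_score in cfg.curated_levels


def _ts_curated(entry: DosageRegion, cfg: ScoreConfig) -> bool:
    return entry.ts_score is not None and entry.ts_score in cfg.curated_levels


def _impact_by_symbol(bundle: AnnotationBundle, symbol: str) -> GeneImpact | None:
    for impact in bundle.gene_impacts:
        if impact.symbol == symbol:
            return impact
    return None


def _del_contains_hi(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(_hi_curated(e, cfg) and cont == 1.0 for e, cont, _ in b.dosage_hits)


def _del_breaks_hi(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    for entry, cont, _bp in b.dosage_hits:
        if not _hi_curated(entry, cfg):
            continue
        if entry.kind == "region" and cont < 1.0:
            return True
        if entry.kind == "gene":
            impact = _impact_by_symbol(b, entry.symbol_or_id)
            if impact is not None and impact.affected_cds_bp >= 1:
                return True
    return False


def _del_cds_of_constrained(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(
        g.pli is not None and g.pli >= cfg.pli_cutoff and g.affected_cds_bp >= 1
        for g in b.gene_impacts
    )


def _del_cds_of_disease(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(g.has_disease_association and g.affected_cds_bp >= 1 for g in b.gene_impacts)


def _overlaps_disease(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(g.has_disease_association for g in b.gene_impacts)


def _dup_contains_ts(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(_ts_curated(e, cfg) and cont == 1.0 for e, cont, _ in b.dosage_hits)


def _dup_breaks_ts_region(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(
        _ts_curated(e, cfg) and e.kind == "region" and cont < 1.0
        for e, cont, _ in b.dosage_hits
    )


def _dup_contains_hi_gene(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(
        _hi_curated(e, cfg) and e.kind == "gene" and cont == 1.0
        for e, cont, _ in b.dosage_hits
    )


def _hi_gene_symbols(b: AnnotationBundle, cfg: ScoreConfig) -> set[str]:
    return {
        e.symbol_or_id for e, _, _ in b.dosage_hits if e.kind == "gene" and _hi_curated(e, cfg)
    }


def _dup_breaks_constrained(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    hi_symbols = _hi_gene_symbols(b, cfg)
    return any(
        g.overlap_kind == "partial"
        and (g.symbol in hi_symbols or (g.pli is not None and g.pli >= cfg.pli_cutoff))
        for g in b.gene_impacts
    )


def _dup_contains_constrained(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(
        g.overlap_kind == "full" and g.pli is not None and g.pli >= cfg.pli_cutoff
        for g in b.gene_impacts
    )


def _dup_contains_disease(b: AnnotationBundle, cfg: ScoreConfig) -> bool:
    return any(g.overlap_kind == "full" and g.has_disease_association for g in b.gene_impacts)


PREDICATES: dict[str, Callable[[AnnotationBundle, ScoreConfig], bool]] = {
    "FULLY_CONTAINS_HI": _del_contains_hi,
    "BREAKS_HI": _del_breaks_hi,
    "DELETES_CDS_OF_CONSTRAINED_GENE": _del_cds_of_constrained,
    "DELETES_CDS_OF_DISEASE_GENE": _del_cds_of_disease,
    "OVERLAPS_DISEASE_GENE": _overlaps_disease,
    "FULLY_CONTAINS_TS": _dup_contains_ts,
    "BREAKS_TS_REGION": _dup_breaks_ts_region,
    "FULLY_CONTAINS_HI_GENE_DUP": _dup_contains_hi_gene,
    "BREAKS_CONSTRAINED_GENE": _dup_breaks_constrained,
    "FULLY_CONTAINS_CONSTRAINED_GENE": _dup_contains_constrained,
    "FULLY_CONTAINS_DISEASE_GENE": _dup_contains_disease,
}

DEFAULT_DELETION_LADDER: tuple[tuple[int, str], ...] = (
    (1, "FULLY_CONTAINS_HI"),
    (2, "BREAKS_HI"),
    (3, "DELETES_CDS_OF_CONSTRAINED_GENE"),
    (4, "DELETES_CDS_OF_DISEASE_GENE"),
    (5, "OVERLAPS_DISEASE_GENE"),
)

DEFAULT_DUPLICATION_LADDER: tuple[tuple[int, str], ...] = (
    (1, "FULLY_CONTAINS_TS"),
    (2, "BREAKS_TS_REGION"),
    (3, "FULLY_CONTAINS_HI_GENE_DUP"),
    (4, "BREAKS_CONSTRAINED_GENE"),
    (5, "FULLY_CONTAINS_CONSTRAINED_GENE"),
    (6, "FULLY_CONTAINS_DISEASE_GENE"),
    (7, "OVERLAPS_DISEASE_GENE"),
)


def clinical_relevance_score(
    bundle: AnnotationBundle, config: ScoreConfig | None = None
) -> tuple[int, list[str]]:
    """Best (lowest) matching tier of the rules ladder; 99 if none fires.

    All firing rules are reported (for the findings summary); the returned
    score is the minimum.
    """
    cfg = config or ScoreConfig()
    if bundle.cnv.cnv_type is CnvType.DELETION:
        ladder = cfg.deletion_ladder or DEFAULT_DELETION_LADDER
    elif bundle.cnv.cnv_type is CnvType.DUPLICATION:
        ladder = cfg.duplication_ladder or DEFAULT_DUPLICATION_LADDER
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown CNV type {bundle.cnv.cnv_type}")
    triggered = [(score, code) for score, code in ladder if PREDICATES[code](bundle, cfg)]
    if not triggered:
        return NO_RELEVANCE, []
    triggered.sort()
    return triggered[0][0], [code for _, code in triggered]


def adverse_information_score(
    bundle: AnnotationBundle,
    evidence: Optional[object] = None,
    config: ScoreConfig | None = None,
) -> tuple[int, list[str]]:
    """100 if any evidence against the CNV being real/pathogenic fires,
    else 0.

    *evidence* is an :class:`~cnvtriage.evidence.EvidenceProfile` (or any
    object with ``depth_ratio`` and ``median_mq_inside``); alignment-based
    criteria never fire when it is absent, so annotation-only runs work.
    """
    cfg = config or ScoreConfig()
    reasons: list[str] = []

    for sv, ro, _cont in bundle.population_hits:
        if (
            sv.sv_type is bundle.cnv.cnv_type
            and ro >= cfg.adverse_reciprocal_overlap
            and sv.popmax_af > cfg.adverse_popmax_af
        ):
            reasons.append("SUBSTANTIAL_POPULATION_OVERLAP")
            break

    if evidence is not None:
        ratio = getattr(evidence, "depth_ratio", None)
        if ratio is not None:
            if bundle.cnv.cnv_type is CnvType.DELETION and ratio > cfg.deletion_ratio_max:
                reasons.append("DEPTH_INCONSISTENT")
            elif (
                bundle.cnv.cnv_type is CnvType.DUPLICATION
                and ratio < cfg.duplication_ratio_min
            ):
                reasons.append("DEPTH_INCONSISTENT")
        mq = getattr(evidence, "median_mq_inside", None)
        if mq is not None and mq < cfg.min_median_mq:
            reasons.append("LOW_MAPPING_QUALITY")

    if bundle.problem_fraction > cfg.problem_fraction_max:
        reasons.append("PROBLEM_REGION_OVERLAP")

    return (ADVERSE if reasons else 0), reasons


def priority_score(clinical: int, adverse: int) -> PriorityResult:
    """Combine the two components (validates the legal value sets)."""
    return PriorityResult(clinical, adverse)


def score_cnv(
    bundle: AnnotationBundle,
    evidence: Optional[object] = None,
    config: ScoreConfig | None = None,
) -> PriorityResult:
    clinical, rules = clinical_relevance_score(bundle, config)
    adverse, reasons = adverse_information_score(bundle, evidence, config)
    return PriorityResult(clinical, adverse, tuple(rules), tuple(reasons))


def rank_cnvs(
    results: Sequence[tuple[CnvCall, PriorityResult]]
) -> list[tuple[CnvCall, PriorityResult]]:
    """Review order: ascending priority, then descending size; stable for
    full ties."""
    return sorted(results, key=lambda item: (item[1].priority, -item[0].length()))


# ---------------------------------------------------------------------------
# Findings summary

_POSITIVE_SENTENCES = {
    "FULLY_CONTAINS_HI": "Fully contains a curated haploinsufficient region/gene",
    "BREAKS_HI": "Disrupts a curated haploinsufficient region/gene",
    "DELETES_CDS_OF_CONSTRAINED_GENE": "Deletes coding sequence of a loss-of-function constrained gene",
    "DELETES_CDS_OF_DISEASE_GENE": "Deletes coding sequence of a disease-associated gene",
    "OVERLAPS_DISEASE_GENE": "Overlaps a disease-associated gene",
    "FULLY_CONTAINS_TS": "Fully contains a curated triplosensitive region/gene",
    "BREAKS_TS_REGION": "Disrupts a curated triplosensitive region",
    "FULLY_CONTAINS_HI_GENE_DUP": "Whole-gene duplication of a curated haploinsufficient gene",
    "BREAKS_CONSTRAINED_GENE": "Breakpoint falls inside a constrained gene",
    "FULLY_CONTAINS_CONSTRAINED_GENE": "Fully contains a loss-of-function constrained gene",
    "FULLY_CONTAINS_DISEASE_GENE": "Fully contains a disease-associated gene",
}

_NEGATIVE_SENTENCES = {
    "SUBSTANTIAL_POPULATION_OVERLAP": "Substantial overlap with common population variants",
    "DEPTH_INCONSISTENT": "Read-depth signal inconsistent with the called CNV type",
    "LOW_MAPPING_QUALITY": "Low median mapping quality inside the variant",
    "PROBLEM_REGION_OVERLAP": "Mostly covered by known problem regions",
}


def summarize_findings(
    bundle: AnnotationBundle,
    priority: PriorityResult,
    evidence: Optional[object] = None,
) -> dict:
    """Machine-readable finding codes plus human-readable sentences for the
    variant-summary panel; evidence metrics included when available."""
    positive = [
        {"code": code, "sentence": _POSITIVE_SENTENCES.get(code, code)}
        for code in priority.triggered_rules
    ]
    negative = [
        {"code": code, "sentence": _NEGATIVE_SENTENCES.get(code, code)}
        for code in priority.adverse_reasons
    ]
    summary = {
        "cnv": bundle.cnv.name(),
        "type": bundle.cnv.cnv_type.value,
        "size_bp": bundle.cnv.length(),
        "priority": priority.priority,
        "clinical_relevance": priority.clinical_relevance,
        "adverse": priority.adverse,
        "tier": priority.tier,
        "positive_findings": positive,
        "negative_findings": negative,
        "genes": [g.symbol for g in bundle.gene_impacts],
    }
    if evidence is not None:
        summary["depth_ratio"] = getattr(evidence, "depth_ratio", None)
        summary["median_mq_inside"] = getattr(evidence, "median_mq_inside", None)
        summary["quality_score"] = getattr(evidence, "quality_score", None)
        summary["supporting_read_count"] = getattr(evidence, "supporting_read_count", None)
    return summary
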