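"""End-to-end orchestration: merge -> filter -> annotate/score -> evidence
-> inheritance -> ranked report.

Stages degrade gracefully: with no BAM the alignment-evidence stage (and
its adverse criteria) is skipped; with no family data inheritance is
skipped.  The run is deterministic — identical config and inputs produce
byte-identical reports — and per-stage counts are logged so the
filtration funnel is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .annotations import AnnotationSet, load_annotation_set, _load_cohort
from .config import RunConfig
from .core import CnvCall, merge_nearby_cnvs, parse_cnv_calls
from .evidence import EvidenceProfile, extract_evidence
from .filtration import FiltrationResult, run_filtration
from .inheritance import label_inheritance
from .prioritization import (
    AnnotationBundle,
    annotate_cnv,
    rank_cnvs,
    score_cnv,
    summarize_findings,
)
from .report import InterpretationStore, SampleReport, write_report

logger = logging.getLogger("cnvtriage")

__all__ = ["run_pipeline", "build_rows"]


class PipelineError(Exception):
    pass


def _load_inputs(config: RunConfig) -> tuple[list[CnvCall], AnnotationSet]:
    if not config.cnv_path:
        raise PipelineError("config.cnv_path is required")
    if not config.annodir:
        raise PipelineError("config.annodir is required")
    if not Path(config.cnv_path).exists():
        raise PipelineError(f"CNV list not found: {config.cnv_path}")
    if not Path(config.annodir).is_dir():
        raise PipelineError(f"annotation directory not found: {config.annodir}")
    calls = parse_cnv_calls(config.cnv_path, config.cnv_dialect, config.sample_id)
    annotation = load_annotation_set(config.annodir)
    if config.family_tsv:
        annotation.internal_cohort.extend(_load_cohort(Path(config.family_tsv)))
        annotation._reindex()
    return calls, annotation


def _hit_summary(bundle: AnnotationBundle) -> dict:
    return {
        "population_hits": [
            {"id": sv.id, "popmax_af": sv.popmax_af, "reciprocal_overlap": round(ro, 4),
             "containment": round(cont, 4)}
            for sv, ro, cont in bundle.population_hits
        ],
        "known_sv_hits": [
            {"id": sv.id, "interpretation": sv.interpretation, "condition": sv.condition,
             "allele_origin": sv.allele_origin, "genes": list(sv.gene_content),
             "reciprocal_overlap": round(ro, 4)}
            for sv, ro, _ in bundle.known_sv_hits
        ],
        "internal_hits": [
            {"sample_id": e.sample_id, "family_id": e.family_id, "relation": e.relation,
             "reciprocal_overlap": round(ro, 4)}
            for e, ro in bundle.internal_hits
        ],
        "dosage_hits": [
            {"symbol": d.symbol_or_id, "kind": d.kind, "hi_score": d.hi_score,
             "ts_score": d.ts_score, "containment_in_cnv": round(cont, 4)}
            for d, cont, _ in bundle.dosage_hits
        ],
        "gene_impacts": [
            {"symbol": g.symbol, "overlap": g.overlap_kind, "strand": g.strand,
             "pli": g.pli,
             "disease_associations": [f"{s}|{c}" for s, c in g.disease_associations],
             "transcripts": [
                 {"transcript_id": t.transcript_id, "canonical": t.is_canonical,
                  "affected_exons": list(t.affected_exon_numbers),
                  "affected_cds_bp": t.affected_cds_bp,
                  "pext_min": t.pext_min, "pext_max": t.pext_max}
                 for t in g.affected_transcripts
             ]}
            for g in bundle.gene_impacts
        ],
    }


def build_rows(
    survivors,
    annotation: AnnotationSet,
    config: RunConfig,
    interpretations: InterpretationStore | None = None,
) -> list[dict]:
    """Annotate, score, extract evidence and label inheritance for each
    surviving call; return ranked report rows."""
    score_cfg = config.score_config()
    scored = []
    extras = {}
    for cnv in survivors:
        bundle = annotate_cnv(cnv, annotation)
        evidence: EvidenceProfile | None = None
        if config.bam:
            evidence = extract_evidence(
                config.bam,
                cnv,
                reference_bam_path=config.reference_bam or None,
                n_bins=config.n_bins,
                tolerance_bp=config.breakpoint_tolerance,
                lower_pct=config.insert_lower_pct,
                upper_pct=config.insert_upper_pct,
                reference_fasta=config.reference_fasta or None,
            )
        priority = score_cnv(bundle, evidence, score_cfg)
        scored.append((cnv, priority))
        extras[id(cnv)] = (bundle, evidence)

    rows = []
    for rank, (cnv, priority) in enumerate(rank_cnvs(scored), start=1):
        bundle, evidence = extras[id(cnv)]
        summary = summarize_findings(bundle, priority, evidence)
        row = {
            "sample_id": cnv.sample_id or config.sample_id,
            "rank": rank,
            "chrom": cnv.chrom,
            "start": cnv.start,
            "end": cnv.end,
            "type": cnv.cnv_type.value,
            "size_bp": cnv.length(),
            "priority": priority.priority,
            "clinical_relevance": priority.clinical_relevance,
            "adverse": priority.adverse,
            "tier": priority.tier,
            "triggered_rules": list(priority.triggered_rules),
            "adverse_reasons": list(priority.adverse_reasons),
            "genes": [g.symbol for g in bundle.gene_impacts],
            "positive_findings": summary["positive_findings"],
            "negative_findings": summary["negative_findings"],
        }
        row.update(_hit_summary(bundle))
        if evidence is not None:
            row.update(
                depth_ratio=evidence.depth_ratio,
                median_mq_inside=evidence.median_mq_inside,
                supporting_read_count=evidence.supporting_read_count,
                quality_score=round(evidence.quality_score, 4),
                insert_bounds=list(evidence.insert_bounds),
                reference_flagged_bins=evidence.reference_flagged_bins,
            )
        else:
            row.update(depth_ratio=None, median_mq_inside=None,
                       supporting_read_count=None, quality_score=None)
        if config.family_id and annotation.internal_cohort:
            inh = label_inheritance(
                cnv, annotation.internal_cohort, config.family_id,
                config.min_reciprocal_inheritance,
            )
            row["inheritance"] = inh.label
            row["inheritance_flags"] = inh.flags
            row["inheritance_matches"] = [
                {"relation": m.relation, "interval": str(m.call.interval),
                 "reciprocal_overlap": round(m.reciprocal, 4),
                 "size_discordant": m.size_discordant}
                for m in inh.matching_calls
            ]
        else:
            row["inheritance"] = ""
        name = f"{cnv.sample_id or config.sample_id}:{cnv.name()}"
        row["cnv_name"] = name
        row["interpretation"] = interpretations.get(name) if interpretations else ""
        rows.append(row)
    return rows


def run_pipeline(config: RunConfig) -> SampleReport:
    """Run every stage and return the ranked per-sample report."""
    calls, annotation = _load_inputs(config)
    logger.info("input: %d CNV calls", len(calls))
    if config.premerge:
        calls = merge_nearby_cnvs(calls, config.merge_max_gap)
        logger.info("after merge: %d calls", len(calls))
    filtration: FiltrationResult = run_filtration(
        calls,
        annotation,
        af_threshold=config.af_threshold,
        skip_filtration=config.skip_filtration,
        problem_region_union=config.problem_region_union,
    )
    for step in sorted(filtration.per_step_counts):
        logger.info("filtration step %d: %d remaining", step, filtration.per_step_counts[step])
    interpretations = (
        InterpretationStore(config.interpretations_file)
        if config.interpretations_file
        else None
    )
    rows = build_rows(filtration.survivors, annotation, config, interpretations)
    version_file = Path(config.annodir) / "VERSION"
    annotation_version = (
        version_file.read_text().strip() if version_file.exists() else "unversioned"
    )
    report = SampleReport(
        sample_id=config.sample_id,
        rows=rows,
        per_step_counts=filtration.per_step_counts,
        input_count=len(calls),
        metadata={
            "cnvtriage_version": __version__,
            "annotation_version": annotation_version,
            "config_hash": config.config_hash(),
            "genome_build": config.genome_build,
            "config": asdict(config),
            "removed": [
                {"cnv": c.name(), "step": step, "reason": reason}
                for c, step, reason in filtration.removed
            ],
        },
    )
    return report


def run_and_write(config: RunConfig) -> dict[str, Path]:
    """Run the pipeline and write reports (static evidence plots are
    emitted by ``cnvtriage evidence --plot``, not here)."""
    report = run_pipeline(config)
    return write_report(report, config.out_dir, tuple(config.output_formats))
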