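"""Annotation bundles, the clinical-relevance ladder, adverse information,
priority/tier arithmetic, ranking and findings summaries."""

import pytest

from cnvtriage.annotations import (
    AnnotationSet,
    CohortEntry,
    DosageRegion,
    GeneModel,
    KnownPathogenicSv,
    PopulationSv,
    TranscriptModel,
)
from cnvtriage.core import CnvCall, CnvType, GenomicInterval
from cnvtriage.prioritization import (
    DEFAULT_DELETION_LADDER,
    DEFAULT_DUPLICATION_LADDER,
    NO_RELEVANCE,
    PriorityResult,
    ScoreConfig,
    adverse_information_score,
    annotate_cnv,
    clinical_relevance_score,
    priority_score,
    rank_cnvs,
    score_cnv,
    summarize_findings,
)

CHROM = "chrT"


def _iv(start, end):
    return GenomicInterval(CHROM, start, end)


def _cnv(start, end, cnv_type=CnvType.DELETION):
    return CnvCall(_iv(start, end), cnv_type, "S1")


def _gene(symbol, start, n_exons=5, exon_len=200, intron_len=800, pli=None,
          assoc=(), coding=True, strand="+", pext=None):
    exons, pos = [], start
    for _ in range(n_exons):
        exons.append(_iv(pos, pos + exon_len))
        pos += exon_len + intron_len
    tx = TranscriptModel(
        f"{symbol}-201", True, tuple(exons), tuple(exons) if coding else (),
        tuple(pext) if pext else None,
    )
    return GeneModel(symbol, strand, (tx,), pli, tuple(assoc))


# span of _gene(start=10_000, n_exons=5): [10_000, 14_200)
GENE_SPAN = (10_000, 14_200)


def ladder_grid_deletion():
    """(fixture name, annotation, cnv, expected clinical score)."""
    omim = (("OMIM", "toy condition"),)
    grid = []
    hi_region = DosageRegion(_iv(10_000, 20_000), "region", "ISCA-1", hi_score="3")
    grid.append((
        "contains HI region -> 1",
        AnnotationSet(dosage_entries=[hi_region]),
        _cnv(5_000, 25_000), 1,
    ))
    grid.append((
        "partially overlaps HI region -> 2",
        AnnotationSet(dosage_entries=[hi_region]),
        _cnv(5_000, 15_000), 2,
    ))
    hi_gene = _gene("HIG", 10_000, pli=0.5)
    grid.append((
        "deletes CDS of curated HI gene -> 2",
        AnnotationSet(
            dosage_entries=[DosageRegion(hi_gene.span(), "gene", "HIG", hi_score="3")],
            genes=[hi_gene],
        ),
        _cnv(9_900, 10_100), 2,  # removes exon 1 only
    ))
    grid.append((
        "deletes CDS of pLI>=0.9 gene -> 3",
        AnnotationSet(genes=[_gene("CONSTR", 10_000, pli=0.99)]),
        _cnv(9_900, 10_100), 3,
    ))
    grid.append((
        "deletes CDS of disease gene -> 4",
        AnnotationSet(genes=[_gene("DIS", 10_000, pli=0.1, assoc=omim)]),
        _cnv(9_900, 10_100), 4,
    ))
    grid.append((
        "intronic overlap of disease gene -> 5",
        AnnotationSet(genes=[_gene("DIS", 10_000, pli=0.1, assoc=omim)]),
        _cnv(10_300, 10_900), 5,  # inside intron 1
    ))
    grid.append((
        "plain gene only -> 99",
        AnnotationSet(genes=[_gene("PLAIN", 10_000, pli=0.01)]),
        _cnv(9_900, 10_100), NO_RELEVANCE,
    ))
    grid.append((
        "no overlap at all -> 99",
        AnnotationSet(),
        _cnv(1_000, 2_000), NO_RELEVANCE,
    ))
    return grid


def ladder_grid_duplication():
    omim = (("OMIM", "toy condition"),)
    grid = []
    ts_region = DosageRegion(_iv(10_000, 20_000), "region", "ISCA-2", ts_score="3")
    grid.append((
        "contains TS region -> 1",
        AnnotationSet(dosage_entries=[ts_region]),
        _cnv(5_000, 25_000, CnvType.DUPLICATION), 1,
    ))
    grid.append((
        "partially overlaps TS region -> 2",
        AnnotationSet(dosage_entries=[ts_region]),
        _cnv(5_000, 15_000, CnvType.DUPLICATION), 2,
    ))
    hi_gene = _gene("HIG", 10_000, pli=0.5)
    grid.append((
        "whole-gene duplication of HI gene -> 3",
        AnnotationSet(
            dosage_entries=[DosageRegion(hi_gene.span(), "gene", "HIG", hi_score="3")],
            genes=[hi_gene],
        ),
        _cnv(9_000, 15_000, CnvType.DUPLICATION), 3,
    ))
    grid.append((
        "breaks HI gene -> 4",
        AnnotationSet(
            dosage_entries=[DosageRegion(hi_gene.span(), "gene", "HIG", hi_score="3")],
            genes=[hi_gene],
        ),
        _cnv(9_000, 12_000, CnvType.DUPLICATION), 4,
    ))
    grid.append((
        "breaks pLI>=0.9 gene -> 4",
        AnnotationSet(genes=[_gene("CONSTR", 10_000, pli=0.99)]),
        _cnv(9_000, 12_000, CnvType.DUPLICATION), 4,
    ))
    grid.append((
        "fully contains pLI>=0.9 gene -> 5",
        AnnotationSet(genes=[_gene("CONSTR", 10_000, pli=0.99)]),
        _cnv(9_000, 15_000, CnvType.DUPLICATION), 5,
    ))
    grid.append((
        "fully contains disease gene -> 6",
        AnnotationSet(genes=[_gene("DIS", 10_000, pli=0.1, assoc=omim)]),
        _cnv(9_000, 15_000, CnvType.DUPLICATION), 6,
    ))
    grid.append((
        "partial overlap of disease gene -> 7",
        AnnotationSet(genes=[_gene("DIS", 10_000, pli=0.1, assoc=omim)]),
        _cnv(9_000, 12_000, CnvType.DUPLICATION), 7,
    ))
    grid.append((
        "plain gene only -> 99",
        AnnotationSet(genes=[_gene("PLAIN", 10_000, pli=0.01)]),
        _cnv(9_000, 12_000, CnvType.DUPLICATION), NO_RELEVANCE,
    ))
    return grid


class TestAnnotateCnv:
    def test_empty_bundle_when_nothing_overlaps(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000), AnnotationSet())
        assert bundle.population_hits == []
        assert bundle.gene_impacts == []
        assert bundle.problem_fraction == 0.0

    def test_full_gene_overlap_kind(self):
        annotation = AnnotationSet(genes=[_gene("G1", 10_000)])
        bundle = annotate_cnv(_cnv(9_000, 20_000), annotation)
        (impact,) = bundle.gene_impacts
        assert impact.overlap_kind == "full"

    def test_affected_exons_1_to_7_of_ten_exon_transcript(self):
        """A deletion removing the first seven exons of a 10-exon canonical
        transcript reports affected exon numbers 1..7."""
        gene = _gene("CHD2_LIKE", 10_000, n_exons=10, pext=[0.9] * 10)
        annotation = AnnotationSet(genes=[gene])
        # exon k spans [10_000 + (k-1)*1000, +200); exon 7 ends at 16_200
        bundle = annotate_cnv(_cnv(9_000, 16_500), annotation)
        (impact,) = bundle.gene_impacts
        (tx,) = impact.affected_transcripts
        assert tx.affected_exon_numbers == tuple(range(1, 8))
        assert impact.overlap_kind == "partial"
        assert tx.pext_min == tx.pext_max == 0.9

    def test_minus_strand_exon_numbering_reversed(self):
        gene = _gene("MINUS", 10_000, n_exons=10, strand="-")
        bundle = annotate_cnv(_cnv(9_000, 16_500), AnnotationSet(genes=[gene]))
        (tx,) = bundle.gene_impacts[0].affected_transcripts
        # genomic-leftmost 7 exons are exons 10..4 in transcription order
        assert tx.affected_exon_numbers == tuple(range(4, 11))

    def test_deterministic_hit_ordering(self):
        svs = [
            PopulationSv(_iv(1_000, 3_000), CnvType.DELETION, "b", {"eur": 0.1}),
            PopulationSv(_iv(1_000, 3_000), CnvType.DELETION, "a", {"eur": 0.1}),
            PopulationSv(_iv(500, 2_000), CnvType.DELETION, "c", {"eur": 0.1}),
        ]
        bundle = annotate_cnv(_cnv(1_000, 2_500), AnnotationSet(population_svs=svs))
        assert [sv.id for sv, _, _ in bundle.population_hits] == ["c", "a", "b"]


class TestClinicalRelevanceLadder:
    @pytest.mark.parametrize(
        "name,annotation,cnv,expected",
        [pytest.param(*row, id=row[0]) for row in ladder_grid_deletion()],
    )
    def test_deletion_ladder(self, name, annotation, cnv, expected):
        bundle = annotate_cnv(cnv, annotation)
        score, rules = clinical_relevance_score(bundle)
        assert score == expected
        assert (score == NO_RELEVANCE) == (rules == [])

    @pytest.mark.parametrize(
        "name,annotation,cnv,expected",
        [pytest.param(*row, id=row[0]) for row in ladder_grid_duplication()],
    )
    def test_duplication_ladder(self, name, annotation, cnv, expected):
        bundle = annotate_cnv(cnv, annotation)
        score, rules = clinical_relevance_score(bundle)
        assert score == expected

    def test_scores_confined_to_legal_sets(self):
        del_scores = {row[3] for row in ladder_grid_deletion()}
        dup_scores = {row[3] for row in ladder_grid_duplication()}
        assert del_scores <= set(range(1, 6)) | {NO_RELEVANCE}
        assert dup_scores <= set(range(1, 8)) | {NO_RELEVANCE}
        # the grid exercises every tier of both default ladders
        assert del_scores >= {s for s, _ in DEFAULT_DELETION_LADDER}
        assert dup_scores >= {s for s, _ in DEFAULT_DUPLICATION_LADDER}

    def test_custom_ladder_override(self):
        annotation = AnnotationSet(
            dosage_entries=[DosageRegion(_iv(10_000, 20_000), "region", "R", hi_score="3")]
        )
        bundle = annotate_cnv(_cnv(5_000, 25_000), annotation)
        cfg = ScoreConfig(deletion_ladder=((7, "FULLY_CONTAINS_HI"),))
        score, _ = clinical_relevance_score(bundle, cfg)
        assert score == 7

    def test_purity_identical_inputs_identical_outputs(self):
        annotation = AnnotationSet(genes=[_gene("CONSTR", 10_000, pli=0.99)])
        bundle = annotate_cnv(_cnv(9_900, 10_100), annotation)
        results = {clinical_relevance_score(bundle)[0] for _ in range(5)}
        assert results == {3}


class _FakeEvidence:
    def __init__(self, depth_ratio=None, median_mq_inside=None, quality_score=None):
        self.depth_ratio = depth_ratio
        self.median_mq_inside = median_mq_inside
        self.quality_score = quality_score
        self.supporting_read_count = 0


class TestAdverseInformation:
    def _pop_bundle(self, ro_sv_af=0.05):
        sv = PopulationSv(_iv(10_000, 20_000), CnvType.DELETION, "sv", {"eur": ro_sv_af})
        annotation = AnnotationSet(population_svs=[sv])
        return annotate_cnv(_cnv(11_000, 19_000), annotation)  # RO = 0.8

    def test_population_overlap_fires_100(self):
        score, reasons = adverse_information_score(self._pop_bundle())
        assert score == 100 and reasons == ["SUBSTANTIAL_POPULATION_OVERLAP"]

    def test_low_af_population_overlap_clean(self):
        score, reasons = adverse_information_score(self._pop_bundle(ro_sv_af=0.001))
        assert score == 0 and reasons == []

    def test_clean_cnv_with_consistent_evidence_zero(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000), AnnotationSet())
        score, reasons = adverse_information_score(
            bundle, _FakeEvidence(depth_ratio=0.5, median_mq_inside=60.0)
        )
        assert score == 0 and reasons == []

    def test_flat_depth_deletion_fires(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000), AnnotationSet())
        score, reasons = adverse_information_score(bundle, _FakeEvidence(depth_ratio=1.0))
        assert score == 100 and "DEPTH_INCONSISTENT" in reasons

    def test_flat_depth_duplication_fires(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000, CnvType.DUPLICATION), AnnotationSet())
        score, _ = adverse_information_score(
            bundle, _FakeEvidence(depth_ratio=1.0, median_mq_inside=60.0)
        )
        assert score == 100

    def test_low_mq_fires(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000), AnnotationSet())
        _, reasons = adverse_information_score(
            bundle, _FakeEvidence(depth_ratio=0.5, median_mq_inside=10.0)
        )
        assert "LOW_MAPPING_QUALITY" in reasons

    def test_no_evidence_skips_alignment_criteria(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000), AnnotationSet())
        score, reasons = adverse_information_score(bundle, None)
        assert score == 0 and reasons == []

    def test_problem_region_fraction_fires(self):
        annotation = AnnotationSet(problem_regions=[_iv(0, 5_000)])
        bundle = annotate_cnv(_cnv(1_000, 2_000), annotation)
        score, reasons = adverse_information_score(bundle)
        assert score == 100 and "PROBLEM_REGION_OVERLAP" in reasons


class TestPriorityAndRank:
    @pytest.mark.parametrize(
        "clinical,adverse,priority,tier",
        [
            (1, 0, 1, "high"),
            (5, 0, 5, "high"),
            (99, 0, 99, "moderate"),
            (1, 100, 101, "low"),
            (99, 100, 199, "low"),
        ],
    )
    def test_sum_and_tier(self, clinical, adverse, priority, tier):
        result = priority_score(clinical, adverse)
        assert result.priority == priority and result.tier == tier

    def test_illegal_components_fatal(self):
        with pytest.raises(ValueError):
            priority_score(1, 50)
        with pytest.raises(ValueError):
            priority_score(0, 0)

    def test_tier_consistency_invariant(self):
        for clinical in list(range(1, 8)) + [99]:
            for adverse in (0, 100):
                r = priority_score(clinical, adverse)
                assert (r.tier == "high") == (r.priority < 99)
                assert (r.tier == "high") == (clinical < 99 and adverse == 0)

    def test_rank_by_priority_then_size(self):
        rows = [
            (_cnv(0, 10_000), priority_score(99, 0)),
            (_cnv(20_000, 21_000), priority_score(1, 0)),
            (_cnv(30_000, 31_000), priority_score(1, 100)),
            (_cnv(40_000, 1_040_000), priority_score(99, 0)),
        ]
        ranked = rank_cnvs(rows)
        assert [r[1].priority for r in ranked] == [1, 99, 99, 101]
        # among the two 99s, the 1-Mb call outranks the 10-kb call
        assert ranked[1][0].length() == 1_000_000

    def test_rank_empty(self):
        assert rank_cnvs([]) == []


class TestSummarizeFindings:
    def test_hi_deletion_summary_has_positive_code(self):
        annotation = AnnotationSet(
            dosage_entries=[DosageRegion(_iv(10_000, 20_000), "region", "R", hi_score="3")]
        )
        cnv = _cnv(5_000, 25_000)
        bundle = annotate_cnv(cnv, annotation)
        result = score_cnv(bundle)
        summary = summarize_findings(bundle, result)
        assert "FULLY_CONTAINS_HI" in [f["code"] for f in summary["positive_findings"]]
        assert summary["tier"] == "high"

    def test_population_overlap_summary_has_negative_code(self):
        sv = PopulationSv(_iv(10_000, 20_000), CnvType.DELETION, "sv", {"eur": 0.05})
        bundle = annotate_cnv(_cnv(11_000, 19_000), AnnotationSet(population_svs=[sv]))
        result = score_cnv(bundle)
        codes = [f["code"] for f in summarize_findings(bundle, result)["negative_findings"]]
        assert codes == ["SUBSTANTIAL_POPULATION_OVERLAP"]

    def test_no_findings_yields_empty_lists(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000), AnnotationSet())
        result = score_cnv(bundle)
        summary = summarize_findings(bundle, result)
        assert summary["positive_findings"] == [] and summary["negative_findings"] == []

    def test_evidence_metrics_included_when_present(self):
        bundle = annotate_cnv(_cnv(1_000, 2_000), AnnotationSet())
        result = score_cnv(bundle)
        ev = _FakeEvidence(depth_ratio=0.5, median_mq_inside=60.0, quality_score=0.9)
        summary = summarize_findings(bundle, result, ev)
        assert summary["depth_ratio"] == 0.5 and summary["quality_score"] == 0.9
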