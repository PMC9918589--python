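"""Alignment-evidence extraction: flanks, binned depth/MQ, depth ratio,
insert-size bounds, anomalous-read classification, support counting and
the guidance quality score."""

import numpy as np
import pysam
import pytest

from cnvtriage.core import CnvCall, CnvType, GenomicInterval
from cnvtriage.evidence import (
    BinStat,
    EvidenceError,
    binned_depth_mq,
    classify_anomalous_reads,
    compare_reference_sample,
    compute_flanks,
    count_supporting_reads,
    depth_metrics,
    estimate_insert_bounds,
    extract_evidence,
    quality_score,
    window_for,
)
from cnvtriage.fixtures import (
    CnvSignal,
    FixtureSpec,
    make_reference_fasta,
    simulate_alignments_with_cnv,
    write_custom_bam,
)

CHROM = "chrT"


def _cnv(start, end, cnv_type=CnvType.DELETION):
    return CnvCall(GenomicInterval(CHROM, start, end), cnv_type, "S1")


def _sim(tmpdir, seed, cnvs, length=120_000, depth=25.0):
    spec = FixtureSpec(
        seed=seed, chrom_lengths={CHROM: length}, mean_depth=depth,
        read_length=100, cnvs=cnvs,
    )
    fasta = make_reference_fasta(spec, tmpdir / f"ref{seed}.fa")
    return simulate_alignments_with_cnv(spec, fasta, tmpdir / f"s{seed}.bam")


@pytest.fixture(scope="module")
def het_del_bam(tmp_path_factory):
    d = tmp_path_factory.mktemp("ev")
    return _sim(d, 101, [CnvSignal(GenomicInterval(CHROM, 50_000, 80_000),
                                   CnvType.DELETION, "het",
                                   n_discordant_pairs=12, n_split_reads=4)])


@pytest.fixture(scope="module")
def het_dup_bam(tmp_path_factory):
    d = tmp_path_factory.mktemp("ev2")
    return _sim(d, 102, [CnvSignal(GenomicInterval(CHROM, 50_000, 80_000),
                                   CnvType.DUPLICATION, "het",
                                   n_discordant_pairs=10, n_split_reads=0)])


class TestFlanks:
    def test_small_cnv_gets_minimum_flank(self):
        assert compute_flanks(_cnv(0, 40_000)) == 100_000

    def test_large_cnv_gets_half_size(self):
        assert compute_flanks(_cnv(0, 1_000_000)) == 500_000

    def test_boundary_case_rules_agree(self):
        assert compute_flanks(_cnv(0, 200_000)) == 100_000

    def test_window_clamped_at_chromosome_bounds(self):
        w = window_for(_cnv(10_000, 50_000), 100_000, chrom_length=120_000)
        assert (w.start, w.end) == (0, 120_000)


class TestBinnedDepthMq:
    def test_uniform_coverage_region(self, het_del_bam):
        with pysam.AlignmentFile(str(het_del_bam)) as af:
            bins = binned_depth_mq(af, GenomicInterval(CHROM, 5_000, 45_000), 20)
        depths = [b.mean_depth for b in bins]
        assert np.mean(depths) == pytest.approx(25.0, rel=0.1)
        assert all(b.mean_mq == pytest.approx(60.0) for b in bins)

    def test_hom_deletion_bins_are_zero(self, tmp_path):
        bam = _sim(tmp_path, 103, [CnvSignal(GenomicInterval(CHROM, 50_000, 80_000),
                                             CnvType.DELETION, "hom")])
        with pysam.AlignmentFile(str(bam)) as af:
            bins = binned_depth_mq(af, GenomicInterval(CHROM, 55_000, 75_000), 10)
        assert all(b.mean_depth == 0.0 for b in bins)
        assert all(b.mean_mq is None for b in bins)

    def test_single_bin_equals_whole_window_mean(self, het_del_bam):
        window = GenomicInterval(CHROM, 5_000, 45_000)
        with pysam.AlignmentFile(str(het_del_bam)) as af:
            many = binned_depth_mq(af, window, 40)
            (one,) = binned_depth_mq(af, window, 1)
        assert one.mean_depth == pytest.approx(np.mean([b.mean_depth for b in many]), rel=1e-6)


class TestDepthMetrics:
    def test_het_deletion_ratio_near_half(self, het_del_bam):
        with pysam.AlignmentFile(str(het_del_bam)) as af:
            ratio, mq = depth_metrics(af, _cnv(50_000, 80_000), 20_000)
        assert ratio == pytest.approx(0.5, abs=0.1)
        assert mq == pytest.approx(60.0)

    def test_het_duplication_ratio_near_1p5(self, het_dup_bam):
        with pysam.AlignmentFile(str(het_dup_bam)) as af:
            ratio, _ = depth_metrics(
                af, _cnv(50_000, 80_000, CnvType.DUPLICATION), 20_000
            )
        assert ratio == pytest.approx(1.5, abs=0.1)

    def test_no_cnv_region_ratio_near_one(self, het_del_bam):
        with pysam.AlignmentFile(str(het_del_bam)) as af:
            ratio, _ = depth_metrics(af, _cnv(10_000, 20_000), 10_000)
        assert ratio == pytest.approx(1.0, abs=0.1)


class TestInsertBounds:
    def test_constant_insert_degenerate_bounds(self, tmp_path):
        spec = FixtureSpec(seed=104, chrom_lengths={CHROM: 100_000},
                           mean_depth=10, read_length=100, insert_sd=0.0)
        fasta = make_reference_fasta(spec, tmp_path / "r.fa")
        bam = simulate_alignments_with_cnv(spec, fasta, tmp_path / "s.bam")
        with pysam.AlignmentFile(str(bam)) as af:
            lower, upper, *_ = estimate_insert_bounds(af, None)
        assert (lower, upper) == (400.0, 400.0)

    def test_upper_pct_100_returns_max(self, het_del_bam):
        with pysam.AlignmentFile(str(het_del_bam)) as af:
            inserts = [r.template_length for r in af.fetch()
                       if r.is_paired and r.template_length > 0 and not r.is_supplementary
                       and not r.is_reverse and r.mate_is_reverse]
            _, upper, *_ = estimate_insert_bounds(af, None, upper_pct=100.0)
        assert upper == max(inserts)

    def test_default_bounds_bracket_insert_distribution(self, het_del_bam):
        with pysam.AlignmentFile(str(het_del_bam)) as af:
            lower, upper, lp, up = estimate_insert_bounds(
                af, GenomicInterval(CHROM, 0, 120_000)
            )
        assert (lp, up) == (0.5, 99.5)
        # Normal(400, 50): 0.5/99.5 percentiles ~ 400 +/- 2.576*50 = 271/529
        assert lower == pytest.approx(271, abs=15)
        assert upper == pytest.approx(529, abs=15)

    def test_no_pairs_is_fatal_with_hint(self, tmp_path):
        bam = write_custom_bam(
            {CHROM: 10_000},
            [{"name": "r1", "chrom": CHROM, "pos": 100, "paired": False}],
            tmp_path / "single.bam",
        )
        with pysam.AlignmentFile(str(bam)) as af:
            with pytest.raises(EvidenceError, match="paired-end"):
                estimate_insert_bounds(af, None)


def _classify(tmp_path, reads, window=(0, 50_000), bounds=(300.0, 600.0, 0.5, 99.5)):
    bam = write_custom_bam({CHROM: 100_000}, reads, tmp_path / "c.bam")
    with pysam.AlignmentFile(str(bam)) as af:
        return classify_anomalous_reads(
            af, GenomicInterval(CHROM, *window), bounds
        )


class TestClassification:
    def test_large_insert_inward_pair(self, tmp_path):
        reads = [
            {"name": "p1", "chrom": CHROM, "pos": 1_000, "mate_pos": 6_000,
             "mate_reverse": True, "tlen": 5_150},
            {"name": "p1", "chrom": CHROM, "pos": 6_000, "reverse": True,
             "read1": False, "mate_pos": 1_000, "tlen": -5_150},
        ]
        (rec,) = _classify(tmp_path, reads)
        assert rec.category == "inward_insert_outlier"
        assert rec.insert_size == 5_150

    def test_normal_inward_pair_not_anomalous(self, tmp_path):
        reads = [
            {"name": "p1", "chrom": CHROM, "pos": 1_000, "mate_pos": 1_250,
             "mate_reverse": True, "tlen": 400, "proper": True},
            {"name": "p1", "chrom": CHROM, "pos": 1_250, "reverse": True,
             "read1": False, "mate_pos": 1_000, "tlen": -400, "proper": True},
        ]
        assert _classify(tmp_path, reads) == []

    def test_same_direction_pair(self, tmp_path):
        reads = [
            {"name": "p1", "chrom": CHROM, "pos": 1_000, "mate_pos": 2_000, "tlen": 1_150},
            {"name": "p1", "chrom": CHROM, "pos": 2_000, "read1": False,
             "mate_pos": 1_000, "tlen": -1_150},
        ]
        (rec,) = _classify(tmp_path, reads)
        assert rec.category == "same_direction"

    def test_outward_pair(self, tmp_path):
        reads = [
            {"name": "p1", "chrom": CHROM, "pos": 1_000, "reverse": True,
             "mate_pos": 2_000, "tlen": 1_150},
            {"name": "p1", "chrom": CHROM, "pos": 2_000, "read1": False,
             "mate_pos": 1_000, "mate_reverse": True, "tlen": -1_150},
        ]
        (rec,) = _classify(tmp_path, reads)
        assert rec.category == "outward"

    def test_split_read_has_precedence(self, tmp_path):
        reads = [
            {"name": "s1", "chrom": CHROM, "pos": 1_000,
             "cigar": [(0, 75), (4, 75)], "sa_tag": f"{CHROM},9001,+,75S75M,60,0;",
             "mate_pos": 9_200, "mate_reverse": True, "tlen": 8_350},
            {"name": "s1", "chrom": CHROM, "pos": 9_200, "reverse": True,
             "read1": False, "mate_pos": 1_000, "tlen": -8_350},
        ]
        (rec,) = _classify(tmp_path, reads)
        assert rec.category == "split"
        assert rec.junction == 1_075  # end of the aligned prefix

    def test_exactly_one_category_per_read_name(self, tmp_path, het_del_bam):
        with pysam.AlignmentFile(str(het_del_bam)) as af:
            bounds = estimate_insert_bounds(af, None)
            records = classify_anomalous_reads(
                af, GenomicInterval(CHROM, 0, 120_000), bounds
            )
        names = [r.read_name for r in records]
        assert len(names) == len(set(names))
        assert all(r.category in
                   ("inward_insert_outlier", "outward", "same_direction", "split")
                   for r in records)


class TestSupportCounting:
    def _anomalous(self, bam):
        with pysam.AlignmentFile(str(bam)) as af:
            bounds = estimate_insert_bounds(af, None)
            return classify_anomalous_reads(
                af, GenomicInterval(CHROM, 0, 120_000), bounds
            )

    def test_seeded_deletion_support_recovered_exactly(self, het_del_bam):
        records = self._anomalous(het_del_bam)
        cnv = _cnv(50_000, 80_000)
        count, flagged = count_supporting_reads(records, cnv, tolerance_bp=0)
        # 12 discordant pairs + 4 split reads, planted at exact breakpoints
        assert count == 16
        discordant = [r for r in flagged
                      if r.supports_cnv and r.category == "inward_insert_outlier"]
        splits = [r for r in flagged if r.supports_cnv and r.category == "split"]
        assert len(discordant) == 12 and len(splits) == 4

    def test_type_inconsistent_evidence_not_counted(self, het_dup_bam):
        """Outward pairs support a duplication, not a deletion."""
        records = self._anomalous(het_dup_bam)
        as_deletion = _cnv(50_000, 80_000, CnvType.DELETION)
        count, _ = count_supporting_reads(
            [r for r in records if r.category == "outward"], as_deletion, 1_000
        )
        assert count == 0

    def test_duplication_outward_support(self, het_dup_bam):
        records = self._anomalous(het_dup_bam)
        cnv = _cnv(50_000, 80_000, CnvType.DUPLICATION)
        count, _ = count_supporting_reads(records, cnv, tolerance_bp=0)
        assert count == 10

    def test_support_non_increasing_as_tolerance_shrinks(self, het_del_bam):
        records = self._anomalous(het_del_bam)
        cnv = _cnv(50_000, 80_000)
        counts = [count_supporting_reads(records, cnv, tol)[0]
                  for tol in (5_000, 1_000, 100, 0)]
        assert counts == sorted(counts, reverse=True)


class TestQualityScore:
    def test_ideal_het_deletion_saturates_to_one(self):
        assert quality_score(0.5, 60.0, 10, CnvType.DELETION) == 1.0

    def test_flat_ratio_deletion_scores_zero(self):
        assert quality_score(1.0, 60.0, 10, CnvType.DELETION) == 0.0

    def test_mid_grade_matches_hand_computed_product(self):
        # depth term (1-0.75)/0.5 = 0.5; MQ 20/40 = 0.5; support 2/5 = 0.4
        assert quality_score(0.75, 20.0, 2, CnvType.DELETION) == pytest.approx(0.1)
        # duplication: (1.25-1)/0.5 = 0.5
        assert quality_score(1.25, 40.0, 5, CnvType.DUPLICATION) == pytest.approx(0.5)

    def test_bounded_and_monotone_in_support(self):
        prev = -1.0
        for n in range(0, 12):
            q = quality_score(0.6, 35.0, n, CnvType.DELETION)
            assert 0.0 <= q <= 1.0 and q >= prev
            prev = q


class TestReferenceComparison:
    def _bins(self, depths, start=0, width=1_000):
        return [
            BinStat(GenomicInterval(CHROM, start + i * width, start + (i + 1) * width),
                    d, 60.0)
            for i, d in enumerate(depths)
        ]

    def test_reference_dip_flagged(self):
        sample = self._bins([30, 30, 15, 30, 30])
        reference = self._bins([30, 30, 12, 30, 30])
        assert compare_reference_sample(sample, reference, 0.3) == [2]

    def test_flat_reference_no_flags(self):
        sample = self._bins([30, 15, 15, 30])
        reference = self._bins([30, 30, 30, 30])
        assert compare_reference_sample(sample, reference, 0.3) == []

    def test_reference_only_artifact_still_flagged(self):
        sample = self._bins([30, 30, 30, 30])
        reference = self._bins([30, 5, 30, 30])
        assert compare_reference_sample(sample, reference, 0.3) == [1]

    def test_grid_mismatch_fatal(self):
        with pytest.raises(EvidenceError):
            compare_reference_sample(
                self._bins([30, 30]), self._bins([30, 30], start=500), 0.3
            )


class TestExtractEvidence:
    def test_full_profile_on_seeded_deletion(self, sim_bundle):
        profile = extract_evidence(str(sim_bundle.bam), sim_bundle.pathogenic_cnv)
        assert profile.flank_bp == 100_000
        assert profile.depth_ratio == pytest.approx(0.5, abs=0.1)
        assert profile.median_mq_inside == pytest.approx(60.0)
        assert profile.supporting_read_count == 18  # 12 discordant + 6 split
        assert profile.quality_score == 1.0
        # bins tile the flanked window without overlap
        for a, b in zip(profile.bins, profile.bins[1:]):
            assert a.interval.end == b.interval.start

    def test_missing_index_fatal_with_hint(self, tmp_path, sim_bundle):
        import shutil

        orphan = tmp_path / "noindex.bam"
        shutil.copy(sim_bundle.bam, orphan)
        with pytest.raises(EvidenceError, match="index"):
            extract_evidence(str(orphan), sim_bundle.pathogenic_cnv)
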