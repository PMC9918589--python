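"""Deterministic synthetic genomes, alignments and annotation databases.

Real WGS alignments and the population/clinical annotation releases they
are interpreted against are controlled-access or huge; every consumer of
this package is therefore testable against synthetic data generated here.
The simulator writes aligned records directly (no read-mapper round
trip), which gives exact control over the engineered signal:

* background inward proper pairs at a target mean depth, template length
  Normal(insert_mean, insert_sd);
* a heterozygous deletion halves depth inside the event (homozygous:
  zero) and adds inward pairs whose insert approximates the deletion
  length, straddling both breakpoints exactly, plus split reads with
  supplementary alignments across the junction;
* a duplication raises depth 1.5x (het) and adds outward pairs
  bracketing the breakpoints.

Base qualities are constant and no sequencing-error model is applied —
depth and pair geometry, not base identity, carry CNV evidence.  A given
seed reproduces output byte-identically under fixed library versions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml

from .annotations import (
    AnnotationSet,
    CohortEntry,
    DosageRegion,
    GeneModel,
    KnownPathogenicSv,
    PopulationSv,
    TranscriptModel,
    write_annotation_set,
)
from .core import CnvCall, CnvType, GenomicInterval

__all__ = [
    "CnvSignal",
    "FixtureSpec",
    "make_reference_fasta",
    "simulate_alignments_with_cnv",
    "make_toy_annotations",
    "default_fixture_spec",
    "default_annotation_set",
    "load_fixture_spec",
]


@dataclass(frozen=True)
class CnvSignal:
    """One engineered CNV: its interval, type, zygosity and the exact
    number of discordant pairs / split reads to plant at its breakpoints."""

    interval: GenomicInterval
    cnv_type: CnvType
    zygosity: str = "het"  # het | hom
    n_discordant_pairs: int = 0
    n_split_reads: int = 0

    def __post_init__(self):
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het/hom, got {self.zygosity!r}")


@dataclass
class FixtureSpec:
    seed: int = 1
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chrT": 600_000})
    mean_depth: float = 30.0
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    mapping_quality: int = 60
    cnvs: list[CnvSignal] = field(default_factory=list)
    sample_id: str = "SAMPLE1"

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        for cnv in self.cnvs:
            length = self.chrom_lengths.get(cnv.interval.chrom)
            if length is None or cnv.interval.end > length:
                raise ValueError(f"engineered CNV {cnv.interval} outside reference bounds")


def make_reference_fasta(spec: FixtureSpec, path: str | Path) -> Path:
    """Seeded random reference sequence, one record per chromosome in
    declared order; faidx-indexed on write."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    path = Path(path)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for chrom, length in spec.chrom_lengths.items():
            fh.write(f">{chrom}\n")
            seq = rng.integers(0, 4, size=length)
            text = bases[seq].tobytes().decode()
            for i in range(0, length, 60):
                fh.write(text[i : i + 60] + "\n")
    pysam.faidx(str(path))
    return path


def _seg(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    pos: int,
    read_length: int,
    mq: int,
    *,
    reverse: bool = False,
    paired: bool = True,
    proper: bool = False,
    read1: bool = True,
    mate_pos: int | None = None,
    mate_reverse: bool = False,
    tlen: int = 0,
    cigar=None,
    supplementary: bool = False,
    sa_tag: str | None = None,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = header.get_tid(chrom)
    a.reference_start = pos
    a.mapping_quality = mq
    a.cigartuples = cigar or [(0, read_length)]
    n_query = sum(ln for op, ln in a.cigartuples if op in (0, 1, 4))
    a.query_sequence = "A" * n_query
    a.query_qualities = pysam.qualitystring_to_array("I" * n_query)
    a.is_paired = paired
    a.is_read1 = paired and read1
    a.is_read2 = paired and not read1
    a.is_reverse = reverse
    a.is_proper_pair = proper
    a.is_supplementary = supplementary
    if paired:
        a.next_reference_id = a.reference_id
        a.next_reference_start = mate_pos if mate_pos is not None else pos
        a.mate_is_reverse = mate_reverse
        a.template_length = tlen
    if sa_tag:
        a.set_tag("SA", sa_tag)
    return a


def _background_fragments(spec: FixtureSpec, rng: np.random.Generator, chrom: str, length: int):
    rl = spec.read_length
    n_frags = int(length * spec.mean_depth / (2 * rl))
    min_insert = 2 * rl + 10
    inserts = np.clip(
        rng.normal(spec.insert_mean, spec.insert_sd, n_frags), min_insert, None
    ).astype(int)
    starts = rng.integers(0, np.maximum(1, length - inserts))
    return starts, inserts


def simulate_alignments_with_cnv(
    spec: FixtureSpec, reference_fasta: str | Path, out_bam: str | Path
) -> Path:
    """Write a coordinate-sorted, indexed BAM carrying the engineered CNV
    signal described by *spec*."""
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    rl = spec.read_length
    mq = spec.mapping_quality
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in spec.chrom_lengths.items()],
        }
    )
    segments: list[pysam.AlignedSegment] = []

    for chrom, length in spec.chrom_lengths.items():
        chrom_cnvs = [c for c in spec.cnvs if c.interval.chrom == chrom]
        starts, inserts = _background_fragments(spec, rng, chrom, length)
        drop = np.zeros(len(starts), dtype=bool)
        for cnv in [c for c in chrom_cnvs if c.cnv_type is CnvType.DELETION]:
            p_drop = 0.5 if cnv.zygosity == "het" else 1.0
            r1_hit = (starts < cnv.interval.end) & (starts + rl > cnv.interval.start)
            r2_start = starts + inserts - rl
            r2_hit = (r2_start < cnv.interval.end) & (r2_start + rl > cnv.interval.start)
            hit = r1_hit | r2_hit
            drop |= hit & (rng.random(len(starts)) < p_drop)
        for i, (s, ins) in enumerate(zip(starts, inserts)):
            if drop[i]:
                continue
            name = f"{chrom}.frag{i}"
            segments.append(
                _seg(header, name, chrom, int(s), rl, mq, proper=True,
                     mate_pos=int(s + ins - rl), mate_reverse=True, tlen=int(ins))
            )
            segments.append(
                _seg(header, name, chrom, int(s + ins - rl), rl, mq, reverse=True,
                     proper=True, read1=False, mate_pos=int(s), tlen=-int(ins))
            )

        for k, cnv in enumerate(c for c in chrom_cnvs if c.cnv_type is CnvType.DUPLICATION):
            gain = 0.5 if cnv.zygosity == "het" else 1.0
            iv = cnv.interval
            extra = int(iv.length() * spec.mean_depth * gain / (2 * rl))
            min_insert = 2 * rl + 10
            ins2 = np.clip(
                rng.normal(spec.insert_mean, spec.insert_sd, extra), min_insert, None
            ).astype(int)
            ins2 = np.minimum(ins2, iv.length() - 1)
            s2 = iv.start + rng.integers(0, np.maximum(1, iv.length() - ins2))
            for i, (s, ins) in enumerate(zip(s2, ins2)):
                name = f"{chrom}.dup{k}.extra{i}"
                segments.append(
                    _seg(header, name, chrom, int(s), rl, mq, proper=True,
                         mate_pos=int(s + ins - rl), mate_reverse=True, tlen=int(ins))
                )
                segments.append(
                    _seg(header, name, chrom, int(s + ins - rl), rl, mq, reverse=True,
                         proper=True, read1=False, mate_pos=int(s), tlen=-int(ins))
                )

        for k, cnv in enumerate(chrom_cnvs):
            iv = cnv.interval
            if cnv.cnv_type is CnvType.DELETION:
                # inward pairs straddling the deletion: left read ends at the
                # start breakpoint, right read begins at the end breakpoint
                left, right = iv.start - rl, iv.end
                tlen = right + rl - left
                for i in range(cnv.n_discordant_pairs):
                    name = f"{chrom}.cnv{k}.disc{i}"
                    segments.append(
                        _seg(header, name, chrom, left, rl, mq,
                             mate_pos=right, mate_reverse=True, tlen=tlen)
                    )
                    segments.append(
                        _seg(header, name, chrom, right, rl, mq, reverse=True,
                             read1=False, mate_pos=left, tlen=-tlen)
                    )
            else:
                # outward pairs bracketing a tandem duplication: reverse read
                # at the start breakpoint, forward read ending at the end
                left, right = iv.start, iv.end - rl
                tlen = iv.length()
                for i in range(cnv.n_discordant_pairs):
                    name = f"{chrom}.cnv{k}.disc{i}"
                    segments.append(
                        _seg(header, name, chrom, left, rl, mq, reverse=True,
                             mate_pos=right, tlen=tlen)
                    )
                    segments.append(
                        _seg(header, name, chrom, right, rl, mq, read1=False,
                             mate_pos=left, mate_reverse=True, tlen=-tlen)
                    )

            half = rl // 2
            bp1, bp2 = (iv.start, iv.end)
            for i in range(cnv.n_split_reads):
                name = f"{chrom}.cnv{k}.split{i}"
                sa_primary = f"{chrom},{bp2 + 1},+,{half}S{rl - half}M,{mq},0;"
                sa_suppl = f"{chrom},{bp1 - half + 1},+,{half}M{rl - half}S,{mq},0;"
                mate_pos = bp2 + 200
                segments.append(
                    _seg(header, name, chrom, bp1 - half, rl, mq,
                         cigar=[(0, half), (4, rl - half)], sa_tag=sa_primary,
                         mate_pos=mate_pos, mate_reverse=True, tlen=mate_pos + rl - (bp1 - half))
                )
                segments.append(
                    _seg(header, name, chrom, bp2, rl, mq, supplementary=True,
                         cigar=[(4, half), (0, rl - half)], sa_tag=sa_suppl,
                         mate_pos=mate_pos, mate_reverse=True, tlen=0)
                )
                segments.append(
                    _seg(header, name, chrom, mate_pos, rl, mq, reverse=True,
                         read1=False, mate_pos=bp1 - half, tlen=-(mate_pos + rl - (bp1 - half)))
                )

    segments.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name, a.flag))
    out_bam = Path(out_bam)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for seg in segments:
            bam.write(seg)
    pysam.index(str(out_bam))
    return out_bam


def write_custom_bam(
    chrom_lengths: dict[str, int],
    reads: Sequence[dict],
    out_bam: str | Path,
    read_length: int = 150,
    mapping_quality: int = 60,
) -> Path:
    """Write a hand-specified coordinate-sorted indexed BAM.

    Each entry of *reads* is a kwargs dict for one aligned record:
    ``{"name", "chrom", "pos"}`` plus any of ``reverse, paired, proper,
    read1, mate_pos, mate_reverse, tlen, cigar, supplementary, sa_tag``.
    Intended for constructing minimal edge-case alignments in tests.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
        }
    )
    segments = []
    for spec in reads:
        spec = dict(spec)
        name = spec.pop("name")
        chrom = spec.pop("chrom")
        pos = spec.pop("pos")
        rl = spec.pop("read_length", read_length)
        mq = spec.pop("mapping_quality", mapping_quality)
        segments.append(_seg(header, name, chrom, pos, rl, mq, **spec))
    segments.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name, a.flag))
    out_bam = Path(out_bam)
    with pysam.AlignmentFile(str(out_bam), "wb", header=header) as bam:
        for seg in segments:
            bam.write(seg)
    pysam.index(str(out_bam))
    return out_bam


# ---------------------------------------------------------------------------
# Toy annotation databases


def _toy_gene(
    symbol: str,
    chrom: str,
    start: int,
    n_exons: int,
    exon_len: int = 200,
    intron_len: int = 800,
    strand: str = "+",
    pli: float | None = None,
    associations: tuple[tuple[str, str], ...] = (),
    coding: bool = True,
    pext: Sequence[float] | None = None,
    canonical_id: str | None = None,
) -> GeneModel:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len))
        pos += exon_len + intron_len
    cds = tuple(exons) if coding else ()
    tx = TranscriptModel(
        canonical_id or f"{symbol}-201",
        True,
        tuple(exons),
        cds,
        tuple(pext) if pext is not None else None,
    )
    return GeneModel(symbol, strand, (tx,), pli, associations)


def default_annotation_set(
    chrom: str = "chrT", family_cnvs: Sequence[CohortEntry] = ()
) -> AnnotationSet:
    """Toy annotation database covering every scoring ingredient: an HI
    region enclosing a constrained disease gene, a TS region, common
    population SVs of both types, a known pathogenic deletion, a problem
    region and a non-coding exception gene."""
    hi_gene = _toy_gene(
        "GENE_HI", chrom, 308_000, n_exons=10, pli=0.99,
        associations=(("OMIM", "Toy dominant disorder"),),
        pext=[1.0, 0.98, 0.95, 0.9, 0.92, 0.97, 0.99, 0.4, 0.35, 0.3],
    )
    benign_gene = _toy_gene("GENE_B", chrom, 150_000, n_exons=4, pli=0.01)
    pop_gene = _toy_gene("GENE_POP", chrom, 52_000, n_exons=3, pli=0.0)
    noncoding_gene = _toy_gene("NCG_X", chrom, 450_000, n_exons=3, coding=False)
    ts_gene = _toy_gene(
        "GENE_TS", chrom, 402_000, n_exons=5, pli=0.35,
        associations=(("GenCC", "Toy duplication syndrome"),),
    )
    return AnnotationSet(
        population_svs=[
            PopulationSv(
                GenomicInterval(chrom, 50_000, 60_000), CnvType.DELETION,
                "gnomad_DEL_toy1", {"afr": 0.05, "eur": 0.02},
            ),
            PopulationSv(
                GenomicInterval(chrom, 70_000, 80_000), CnvType.DUPLICATION,
                "gnomad_DUP_toy1", {"afr": 0.12, "eur": 0.08},
            ),
        ],
        known_svs=[
            KnownPathogenicSv(
                GenomicInterval(chrom, 300_000, 340_000), CnvType.DELETION,
                "clinvar_toy1", "pathogenic", "Toy dominant disorder",
                "de novo", ("GENE_HI",),
            ),
        ],
        dosage_entries=[
            DosageRegion(GenomicInterval(chrom, 305_000, 335_000), "region", "ISCA-TOY1", hi_score="3"),
            DosageRegion(hi_gene.span(), "gene", "GENE_HI", hi_score="3"),
            DosageRegion(GenomicInterval(chrom, 400_000, 420_000), "region", "ISCA-TOY2", ts_score="3"),
        ],
        genes=[hi_gene, benign_gene, pop_gene, noncoding_gene, ts_gene],
        internal_cohort=list(family_cnvs),
        problem_regions=[GenomicInterval(chrom, 10_000, 20_000)],
        noncoding_exception_genes={"NCG_X"},
    )


def _check_contradictions(annotation: AnnotationSet) -> None:
    def dupes(pairs):
        seen, bad = {}, []
        for key, iv in pairs:
            if key in seen and seen[key] != iv:
                bad.append(key)
            seen[key] = iv
        return bad

    problems = []
    problems += dupes((sv.id, sv.interval) for sv in annotation.population_svs)
    problems += dupes((sv.id, sv.interval) for sv in annotation.known_svs)
    problems += dupes(((d.kind, d.symbol_or_id), d.interval) for d in annotation.dosage_entries)
    problems += dupes((g.symbol, g.span()) for g in annotation.genes)
    if problems:
        raise ValueError(f"contradictory annotation recipe entries: {problems}")


def make_toy_annotations(annotation: AnnotationSet, outdir: str | Path) -> Path:
    """Validate and write a toy annotation set in the documented dialects
    (round-trips through the loaders)."""
    _check_contradictions(annotation)
    outdir = Path(outdir)
    write_annotation_set(annotation, outdir)
    return outdir


def default_fixture_spec(seed: int = 1) -> FixtureSpec:
    """Study-condition defaults: 30x 150-bp paired-end background with
    template length Normal(400, 50) on a 600-kb toy contig, carrying one
    heterozygous 40-kb pathogenic-like deletion with 12 discordant pairs
    and 6 split reads at its breakpoints."""
    return FixtureSpec(
        seed=seed,
        chrom_lengths={"chrT": 600_000},
        mean_depth=30.0,
        read_length=150,
        insert_mean=400.0,
        insert_sd=50.0,
        cnvs=[
            CnvSignal(
                GenomicInterval("chrT", 300_000, 340_000),
                CnvType.DELETION,
                "het",
                n_discordant_pairs=12,
                n_split_reads=6,
            )
        ],
    )


def load_fixture_spec(path: str | Path) -> FixtureSpec:
    """Read a fixture spec from YAML (see `cnvtriage simulate --template`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cnvs = [
        CnvSignal(
            GenomicInterval(c["chrom"], int(c["start"]), int(c["end"])),
            CnvType.from_token(c["type"]),
            c.get("zygosity", "het"),
            int(c.get("n_discordant_pairs", 0)),
            int(c.get("n_split_reads", 0)),
        )
        for c in raw.get("cnvs", [])
    ]
    known = {f.name for f in FixtureSpec.__dataclass_fields__.values()}
    extra = set(raw) - known - {"cnvs"}
    if extra:
        raise ValueError(f"unknown fixture spec keys: {sorted(extra)}")
    kwargs = {k: v for k, v in raw.items() if k in known and k != "cnvs"}
    return FixtureSpec(cnvs=cnvs, **kwargs)


FIXTURE_TEMPLATE = """\
# cnvtriage fixture spec
# Synthetic reference + alignments + engineered CNV signal.
seed: 1
chrom_lengths:
  chrT: 600000
mean_depth: 30.0        # haploid-genome mean coverage
read_length: 150        # bp
insert_mean: 400.0      # template length, bp
insert_sd: 50.0
mapping_quality: 60
sample_id: SAMPLE1
cnvs:
  - chrom: chrT
    start: 300000
    end: 340000
    type: DEL           # DEL or DUP
    zygosity: het       # het halves depth (DEL) / x1.5 (DUP); hom doubles the effect
    n_discordant_pairs: 12
    n_split_reads: 6
"""
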