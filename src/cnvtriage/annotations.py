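"""Annotation databases: population SVs, known pathogenic SVs, dosage
curations, gene models, constraint/pext scores, problem regions and the
internal cohort.

Each category lives in one tab-separated file inside an annotation
directory; :func:`load_annotation_set` assembles them into an
:class:`AnnotationSet` whose tables are independently queryable by
interval (interval trees, one per chromosome).

File dialects (all TSV with a header line unless noted):

``population_svs.tsv``   chrom start end type id af_<pop> [af_<pop> ...]
``known_svs.tsv``        chrom start end type id interpretation condition
                         allele_origin genes (comma-separated symbols)
``dosage.tsv``           chrom start end kind symbol hi_score ts_score
                         (kind in {region, gene}; "." = not curated)
``gene_models.tsv``      feature symbol transcript_id chrom start end strand
                         canonical associations — one row per gene /
                         transcript / exon / cds feature
``constraint.tsv``       symbol pli
``pext.tsv``             transcript_id exon_number pext
``problem_regions.bed``  chrom start end label (headerless BED)
``noncoding_exceptions.txt``  one gene symbol per line
``internal_cohort.tsv``  sample_id family_id relation chrom start end type
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .core import CnvCall, CnvType, GenomicInterval, normalize_chrom

__all__ = [
    "PopulationSv",
    "KnownPathogenicSv",
    "DosageRegion",
    "TranscriptModel",
    "GeneModel",
    "CohortEntry",
    "AnnotationSet",
    "load_annotation_set",
    "write_annotation_set",
]

INTERPRETATIONS = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")


@dataclass(frozen=True)
class PopulationSv:
    interval: GenomicInterval
    sv_type: CnvType
    id: str
    af_by_population: dict[str, float]

    def __post_init__(self):
        for pop, af in self.af_by_population.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"{self.id}: AF {af} for {pop} outside [0,1]")

    @property
    def popmax_af(self) -> float:
        return max(self.af_by_population.values(), default=0.0)


@dataclass(frozen=True)
class KnownPathogenicSv:
    interval: GenomicInterval
    sv_type: CnvType
    id: str
    interpretation: str
    condition: str = ""
    allele_origin: str = ""
    gene_content: tuple[str, ...] = ()

    def __post_init__(self):
        if self.interpretation not in INTERPRETATIONS:
            raise ValueError(f"{self.id}: bad interpretation {self.interpretation!r}")


@dataclass(frozen=True)
class DosageRegion:
    """A ClinGen-style dosage-sensitivity curation for a region or gene."""

    interval: GenomicInterval
    kind: str  # "region" | "gene"
    symbol_or_id: str
    hi_score: str | None = None
    ts_score: str | None = None

    def __post_init__(self):
        if self.kind not in ("region", "gene"):
            raise ValueError(f"dosage kind must be region/gene, got {self.kind!r}")
        if self.hi_score is None and self.ts_score is None:
            raise ValueError(f"{self.symbol_or_id}: needs hi_score or ts_score")


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    is_canonical: bool
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    exon_pext: tuple[float, ...] | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
        if self.exon_pext is not None and len(self.exon_pext) != len(self.exons):
            raise ValueError(f"{self.transcript_id}: pext/exon length mismatch")

    def exon_number(self, index: int, strand: str) -> int:
        """1-based exon number in transcription order for the exon at
        genomic index *index* (exons are stored in genomic order)."""
        return index + 1 if strand == "+" else len(self.exons) - index


@dataclass(frozen=True)
class GeneModel:
    symbol: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]
    pli: float | None = None
    disease_associations: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.symbol}: strand must be +/-")
        if not self.transcripts:
            raise ValueError(f"{self.symbol}: gene without transcripts")
        if self.pli is not None and not 0.0 <= self.pli <= 1.0:
            raise ValueError(f"{self.symbol}: pLI {self.pli} outside [0,1]")

    def span(self) -> GenomicInterval:
        chrom = self.transcripts[0].exons[0].chrom
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(chrom, start, end)


@dataclass(frozen=True)
class CohortEntry:
    sample_id: str
    family_id: str
    relation: str  # proband | mother | father | sibling | unrelated
    call: CnvCall


def _build_tree(items, get_interval) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for item in items:
        iv = get_interval(item)
        trees.setdefault(normalize_chrom(iv.chrom), IntervalTree()).addi(
            iv.start, iv.end, item
        )
    return trees


def _query(trees: dict[str, IntervalTree], iv: GenomicInterval) -> list:
    tree = trees.get(normalize_chrom(iv.chrom))
    if tree is None:
        return []
    return [hit.data for hit in tree.overlap(iv.start, iv.end)]


@dataclass
class AnnotationSet:
    """All annotation tables, each queryable by genomic interval."""

    population_svs: list[PopulationSv] = field(default_factory=list)
    known_svs: list[KnownPathogenicSv] = field(default_factory=list)
    dosage_entries: list[DosageRegion] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    internal_cohort: list[CohortEntry] = field(default_factory=list)
    problem_regions: list[GenomicInterval] = field(default_factory=list)
    noncoding_exception_genes: set[str] = field(default_factory=set)

    def __post_init__(self):
        self._reindex()

    def _reindex(self) -> None:
        self._pop_trees = _build_tree(self.population_svs, lambda s: s.interval)
        self._known_trees = _build_tree(self.known_svs, lambda s: s.interval)
        self._dosage_trees = _build_tree(self.dosage_entries, lambda d: d.interval)
        self._gene_trees = _build_tree(self.genes, lambda g: g.span())
        self._cohort_trees = _build_tree(self.internal_cohort, lambda e: e.call.interval)
        self._problem_trees = _build_tree(self.problem_regions, lambda r: r)

    def population_overlaps(self, iv: GenomicInterval) -> list[PopulationSv]:
        return _query(self._pop_trees, iv)

    def known_sv_overlaps(self, iv: GenomicInterval) -> list[KnownPathogenicSv]:
        return _query(self._known_trees, iv)

    def dosage_overlaps(self, iv: GenomicInterval) -> list[DosageRegion]:
        return _query(self._dosage_trees, iv)

    def genes_overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        return _query(self._gene_trees, iv)

    def cohort_overlaps(self, iv: GenomicInterval) -> list[CohortEntry]:
        return _query(self._cohort_trees, iv)

    def problem_overlaps(self, iv: GenomicInterval) -> list[GenomicInterval]:
        return _query(self._problem_trees, iv)

    def merged_problem_regions(self) -> list[GenomicInterval]:
        """Union of problem regions (abutting/overlapping records merged)."""
        out: list[GenomicInterval] = []
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for r in self.problem_regions:
            by_chrom.setdefault(normalize_chrom(r.chrom), []).append(r)
        for regions in by_chrom.values():
            regions.sort(key=lambda r: (r.start, r.end))
            cur = regions[0]
            for r in regions[1:]:
                if r.start <= cur.end:
                    if r.end > cur.end:
                        cur = GenomicInterval(cur.chrom, cur.start, r.end)
                else:
                    out.append(cur)
                    cur = r
            out.append(cur)
        out.sort(key=lambda r: (normalize_chrom(r.chrom), r.start))
        return out


# ---------------------------------------------------------------------------
# Readers


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def _opt(value: str) -> str | None:
    return None if value in (".", "", "NA") else value


def _load_population(path: Path) -> list[PopulationSv]:
    out = []
    for row in _read_tsv(path):
        afs = {
            k[3:]: float(v)
            for k, v in row.items()
            if k.startswith("af_") and v not in (".", "")
        }
        out.append(
            PopulationSv(
                GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                CnvType.from_token(row["type"]),
                row["id"],
                afs,
            )
        )
    return out


def _load_known(path: Path) -> list[KnownPathogenicSv]:
    return [
        KnownPathogenicSv(
            GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            CnvType.from_token(row["type"]),
            row["id"],
            row["interpretation"],
            row.get("condition", ""),
            row.get("allele_origin", ""),
            tuple(g for g in row.get("genes", "").split(",") if g),
        )
        for row in _read_tsv(path)
    ]


def _load_dosage(path: Path) -> list[DosageRegion]:
    return [
        DosageRegion(
            GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            row["kind"],
            row["symbol"],
            _opt(row["hi_score"]),
            _opt(row["ts_score"]),
        )
        for row in _read_tsv(path)
    ]


def _parse_associations(packed: str) -> tuple[tuple[str, str], ...]:
    out = []
    for item in packed.split(";"):
        if not item or item == ".":
            continue
        source, _, condition = item.partition("|")
        out.append((source, condition))
    return tuple(out)


def _load_genes(
    path: Path, constraint: dict[str, float], pext: dict[tuple[str, int], float]
) -> list[GeneModel]:
    gene_rows: dict[str, dict] = {}
    tx_rows: dict[str, dict] = {}
    tx_order: dict[str, list[str]] = {}
    for row in _read_tsv(path):
        feat = row["feature"]
        if feat == "gene":
            gene_rows[row["symbol"]] = {
                "strand": row["strand"],
                "associations": _parse_associations(row.get("associations", "")),
            }
            tx_order.setdefault(row["symbol"], [])
        elif feat == "transcript":
            tx_rows[row["transcript_id"]] = {
                "symbol": row["symbol"],
                "canonical": row["canonical"] in ("1", "true", "True"),
                "exons": [],
                "cds": [],
            }
            tx_order.setdefault(row["symbol"], []).append(row["transcript_id"])
        elif feat in ("exon", "cds"):
            iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]))
            tx_rows[row["transcript_id"]]["exons" if feat == "exon" else "cds"].append(iv)
        else:
            raise ValueError(f"{path}: unknown feature {feat!r}")
    genes = []
    for symbol, meta in gene_rows.items():
        transcripts = []
        for tid in tx_order.get(symbol, []):
            t = tx_rows[tid]
            exons = tuple(sorted(t["exons"]))
            pext_vals = [pext.get((tid, i + 1)) for i in range(len(exons))]
            has_pext = any(v is not None for v in pext_vals)
            transcripts.append(
                TranscriptModel(
                    tid,
                    t["canonical"],
                    exons,
                    tuple(sorted(t["cds"])),
                    tuple(v if v is not None else 0.0 for v in pext_vals)
                    if has_pext
                    else None,
                )
            )
        genes.append(
            GeneModel(
                symbol,
                meta["strand"],
                tuple(transcripts),
                constraint.get(symbol),
                meta["associations"],
            )
        )
    return genes


def _load_cohort(path: Path) -> list[CohortEntry]:
    return [
        CohortEntry(
            row["sample_id"],
            row["family_id"],
            row["relation"],
            CnvCall(
                GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                CnvType.from_token(row["type"]),
                row["sample_id"],
            ),
        )
        for row in _read_tsv(path)
    ]


def _load_bed(path: Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


FILENAMES = {
    "population_svs": "population_svs.tsv",
    "known_svs": "known_svs.tsv",
    "dosage": "dosage.tsv",
    "gene_models": "gene_models.tsv",
    "constraint": "constraint.tsv",
    "pext": "pext.tsv",
    "problem_regions": "problem_regions.bed",
    "noncoding_exceptions": "noncoding_exceptions.txt",
    "internal_cohort": "internal_cohort.tsv",
}


def load_annotation_set(annodir: str | Path) -> AnnotationSet:
    """Load every annotation table present in *annodir*; missing optional
    tables load as empty."""
    annodir = Path(annodir)

    def maybe(name: str):
        p = annodir / FILENAMES[name]
        return p if p.exists() else None

    constraint: dict[str, float] = {}
    if (p := maybe("constraint")) is not None:
        constraint = {row["symbol"]: float(row["pli"]) for row in _read_tsv(p)}
    pext: dict[tuple[str, int], float] = {}
    if (p := maybe("pext")) is not None:
        pext = {
            (row["transcript_id"], int(row["exon_number"])): float(row["pext"])
            for row in _read_tsv(p)
        }
    genes: list[GeneModel] = []
    if (p := maybe("gene_models")) is not None:
        genes = _load_genes(p, constraint, pext)
    exceptions: set[str] = set()
    if (p := maybe("noncoding_exceptions")) is not None:
        exceptions = {
            line.strip() for line in open(p) if line.strip() and not line.startswith("#")
        }
    return AnnotationSet(
        population_svs=_load_population(p) if (p := maybe("population_svs")) else [],
        known_svs=_load_known(p) if (p := maybe("known_svs")) else [],
        dosage_entries=_load_dosage(p) if (p := maybe("dosage")) else [],
        genes=genes,
        internal_cohort=_load_cohort(p) if (p := maybe("internal_cohort")) else [],
        problem_regions=_load_bed(p) if (p := maybe("problem_regions")) else [],
        noncoding_exception_genes=exceptions,
    )


# ---------------------------------------------------------------------------
# Writers (used by the synthetic fixture generator; round-trip with loaders)


def write_annotation_set(annotation: AnnotationSet, annodir: str | Path) -> None:
    annodir = Path(annodir)
    annodir.mkdir(parents=True, exist_ok=True)

    pops = sorted({p for sv in annotation.population_svs for p in sv.af_by_population})
    with open(annodir / FILENAMES["population_svs"], "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tid" + "".join(f"\taf_{p}" for p in pops) + "\n")
        for sv in annotation.population_svs:
            afs = "".join(
                f"\t{sv.af_by_population[p]}" if p in sv.af_by_population else "\t."
                for p in pops
            )
            fh.write(
                f"{sv.interval.chrom}\t{sv.interval.start}\t{sv.interval.end}\t"
                f"{'DEL' if sv.sv_type is CnvType.DELETION else 'DUP'}\t{sv.id}{afs}\n"
            )

    with open(annodir / FILENAMES["known_svs"], "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tid\tinterpretation\tcondition\tallele_origin\tgenes\n")
        for sv in annotation.known_svs:
            fh.write(
                f"{sv.interval.chrom}\t{sv.interval.start}\t{sv.interval.end}\t"
                f"{'DEL' if sv.sv_type is CnvType.DELETION else 'DUP'}\t{sv.id}\t"
                f"{sv.interpretation}\t{sv.condition}\t{sv.allele_origin}\t"
                f"{','.join(sv.gene_content)}\n"
            )

    with open(annodir / FILENAMES["dosage"], "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tsymbol\thi_score\tts_score\n")
        for d in annotation.dosage_entries:
            fh.write(
                f"{d.interval.chrom}\t{d.interval.start}\t{d.interval.end}\t{d.kind}\t"
                f"{d.symbol_or_id}\t{d.hi_score or '.'}\t{d.ts_score or '.'}\n"
            )

    with open(annodir / FILENAMES["gene_models"], "w") as fh, open(
        annodir / FILENAMES["constraint"], "w"
    ) as cfh, open(annodir / FILENAMES["pext"], "w") as pfh:
        fh.write("feature\tsymbol\ttranscript_id\tchrom\tstart\tend\tstrand\tcanonical\tassociations\n")
        cfh.write("symbol\tpli\n")
        pfh.write("transcript_id\texon_number\tpext\n")
        for gene in annotation.genes:
            span = gene.span()
            assoc = ";".join(f"{s}|{c}" for s, c in gene.disease_associations) or "."
            fh.write(
                f"gene\t{gene.symbol}\t.\t{span.chrom}\t{span.start}\t{span.end}\t"
                f"{gene.strand}\t.\t{assoc}\n"
            )
            if gene.pli is not None:
                cfh.write(f"{gene.symbol}\t{gene.pli}\n")
            for tx in gene.transcripts:
                fh.write(
                    f"transcript\t{gene.symbol}\t{tx.transcript_id}\t{span.chrom}\t"
                    f"{tx.exons[0].start}\t{tx.exons[-1].end}\t{gene.strand}\t"
                    f"{1 if tx.is_canonical else 0}\t.\n"
                )
                for i, exon in enumerate(tx.exons):
                    fh.write(
                        f"exon\t{gene.symbol}\t{tx.transcript_id}\t{exon.chrom}\t"
                        f"{exon.start}\t{exon.end}\t{gene.strand}\t.\t.\n"
                    )
                    if tx.exon_pext is not None:
                        pfh.write(f"{tx.transcript_id}\t{i + 1}\t{tx.exon_pext[i]}\n")
                for c in tx.cds:
                    fh.write(
                        f"cds\t{gene.symbol}\t{tx.transcript_id}\t{c.chrom}\t"
                        f"{c.start}\t{c.end}\t{gene.strand}\t.\t.\n"
                    )

    with open(annodir / FILENAMES["problem_regions"], "w") as fh:
        for r in annotation.problem_regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tproblem\n")

    with open(annodir / FILENAMES["noncoding_exceptions"], "w") as fh:
        for symbol in sorted(annotation.noncoding_exception_genes):
            fh.write(symbol + "\n")

    with open(annodir / FILENAMES["internal_cohort"], "w") as fh:
        fh.write("sample_id\tfamily_id\trelation\tchrom\tstart\tend\ttype\n")
        for e in annotation.internal_cohort:
            c = e.call
            fh.write(
                f"{e.sample_id}\t{e.family_id}\t{e.relation}\t{c.chrom}\t{c.start}\t"
                f"{c.end}\t{'DEL' if c.cnv_type is CnvType.DELETION else 'DUP'}\n"
            )
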