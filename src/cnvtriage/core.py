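"""Core domain types, interval arithmetic and CNV list I/O.

All genomic coordinates are 0-based half-open (BED convention) internally.
VCF input (1-based inclusive POS/END) is converted on ingest.  Chromosome
names keep their input dialect ("chr1" vs "1") for output, but every
comparison goes through :func:`normalize_chrom` so that mixed-dialect
inputs interoperate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

__all__ = [
    "GenomicInterval",
    "CnvType",
    "CnvCall",
    "ParseIssue",
    "CnvParseError",
    "normalize_chrom",
    "same_chrom",
    "overlap_bp",
    "reciprocal_overlap",
    "containment_fraction",
    "parse_cnv_calls",
    "write_cnv_calls",
    "merge_nearby_cnvs",
]


def normalize_chrom(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map a chromosome name to its canonical comparison key.

    Default policy strips a leading ``chr`` prefix and upper-cases the
    mitochondrial aliases, so ``chr1``/``1`` and ``chrM``/``MT`` compare
    equal.  A custom alias map (applied after the default) may be given.
    """
    key = name[3:] if name.lower().startswith("chr") else name
    if key.upper() in ("M", "MT"):
        key = "MT"
    if aliases:
        key = aliases.get(key, key)
    return key


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # e.g. chr1:1000-5000
        return f"{self.chrom}:{self.start}-{self.end}"


def same_chrom(a: GenomicInterval, b: GenomicInterval) -> bool:
    return normalize_chrom(a.chrom) == normalize_chrom(b.chrom)


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if different chromosomes)."""
    if not same_chrom(a, b):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Symmetric overlap: ``min(shared/len(a), shared/len(b))`` in [0, 1].

    The standard concordance measure for structural variants; two calls are
    conventionally "the same variant" at reciprocal overlap >= 0.5.
    """
    shared = overlap_bp(a, b)
    if shared == 0:
        return 0.0
    return min(shared / a.length(), shared / b.length())


def containment_fraction(inner: GenomicInterval, outer: GenomicInterval) -> float:
    """Fraction of ``inner`` covered by ``outer``; 1.0 iff inner is contained."""
    return overlap_bp(inner, outer) / inner.length()


class CnvType(enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"

    @classmethod
    def from_token(cls, token: str) -> "CnvType":
        t = token.strip().upper()
        if t in ("DEL", "DELETION", "LOSS"):
            return cls.DELETION
        if t in ("DUP", "DUPLICATION", "GAIN"):
            return cls.DUPLICATION
        raise ValueError(f"unknown CNV type token {token!r}")


@dataclass(frozen=True)
class CnvCall:
    """One deletion/duplication call with provenance."""

    interval: GenomicInterval
    cnv_type: CnvType
    sample_id: str = ""
    caller: str = ""
    source_lines: tuple[int, ...] = ()

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def length(self) -> int:
        return self.interval.length()

    def name(self) -> str:
        return f"{self.interval}:{self.cnv_type.value[:3].upper()}"


@dataclass(frozen=True)
class ParseIssue:
    line: int
    message: str


class CnvParseError(Exception):
    """Raised when an input yields zero parseable CNV records."""


def _parse_bed_tsv(path: Path, sample_id: str, caller: str):
    calls: list[CnvCall] = []
    issues: list[ParseIssue] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                issues.append(ParseIssue(lineno, f"expected >=4 columns, got {len(fields)}"))
                continue
            # header sniffing: a non-integer start on line 1 is a header row
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                if lineno == 1:
                    continue
                issues.append(ParseIssue(lineno, f"non-integer coordinates {fields[1]!r}/{fields[2]!r}"))
                continue
            try:
                cnv_type = CnvType.from_token(fields[3])
            except ValueError as exc:
                issues.append(ParseIssue(lineno, str(exc)))
                continue
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                issues.append(ParseIssue(lineno, str(exc)))
                continue
            sid = fields[4] if len(fields) > 4 and fields[4] else sample_id
            calls.append(CnvCall(iv, cnv_type, sid, caller, (lineno,)))
    return calls, issues


def _parse_vcf(path: Path, sample_id: str, caller: str):
    calls: list[CnvCall] = []
    issues: list[ParseIssue] = []
    with pysam.VariantFile(str(path)) as vcf:
        for lineno, rec in enumerate(vcf, start=1):
            svtype = rec.info.get("SVTYPE")
            if svtype not in ("DEL", "DUP"):
                issues.append(ParseIssue(lineno, f"skipping non-CNV SVTYPE {svtype!r}"))
                continue
            # pysam exposes POS already 0-based (rec.start) and END as rec.stop,
            # which matches our half-open convention directly.
            try:
                iv = GenomicInterval(rec.chrom, rec.start, rec.stop)
            except ValueError as exc:
                issues.append(ParseIssue(lineno, str(exc)))
                continue
            calls.append(CnvCall(iv, CnvType.from_token(svtype), sample_id, caller, (lineno,)))
    return calls, issues


def parse_cnv_calls(
    path: str | Path,
    dialect: str = "bed_tsv",
    sample_id: str = "",
    caller: str = "",
    collect_issues: list[ParseIssue] | None = None,
) -> list[CnvCall]:
    """Read a CNV call list from a BED-like TSV or a VCF.

    bed_tsv columns: chrom, start (0-based), end (half-open), type
    [, sample_id].  VCF records need SVTYPE in {DEL, DUP} and END; other
    SV types are skipped with a record-level issue.  Malformed records are
    reported (with line numbers) through *collect_issues* and skipped; an
    input with zero parseable records raises :class:`CnvParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise CnvParseError(f"no such file: {path}")
    if dialect == "bed_tsv":
        calls, issues = _parse_bed_tsv(path, sample_id, caller)
    elif dialect == "vcf":
        calls, issues = _parse_vcf(path, sample_id, caller)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if collect_issues is not None:
        collect_issues.extend(issues)
    if not calls:
        raise CnvParseError(
            f"{path}: no parseable CNV records "
            f"({len(issues)} malformed/skipped lines)"
        )
    return calls


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    """Write calls in the bed_tsv dialect (round-trips with parse_cnv_calls)."""
    with open(path, "w") as fh:
        for call in calls:
            fh.write(
                f"{call.chrom}\t{call.start}\t{call.end}\t"
                f"{'DEL' if call.cnv_type is CnvType.DELETION else 'DUP'}\t"
                f"{call.sample_id}\n"
            )


def merge_nearby_cnvs(calls: Sequence[CnvCall], max_gap: int = 50_000) -> list[CnvCall]:
    """Merge fragmented calls of the same sample/type/chromosome.

    Read-depth callers frequently report one large CNV as several nearby
    fragments (broken by gaps or noisy windows); downstream containment
    tests then misjudge each fragment.  Calls whose gap is <= *max_gap*
    are merged into one spanning call that records all constituent source
    lines.  Output is sorted by (chrom, start).  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    groups: dict[tuple[str, str, CnvType], list[CnvCall]] = {}
    for call in calls:
        key = (call.sample_id, normalize_chrom(call.chrom), call.cnv_type)
        groups.setdefault(key, []).append(call)
    merged: list[CnvCall] = []
    for group in groups.values():
        group.sort(key=lambda c: (c.start, c.end))
        current = group[0]
        for nxt in group[1:]:
            if nxt.start - current.end <= max_gap:
                current = replace(
                    current,
                    interval=GenomicInterval(
                        current.chrom, current.start, max(current.end, nxt.end)
                    ),
                    source_lines=tuple(sorted(set(current.source_lines + nxt.source_lines))),
                )
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda c: (normalize_chrom(c.chrom), c.start, c.end))
    return merged
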