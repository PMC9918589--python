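"""Report writers and the central interpretation store.

The per-sample report is emitted as a flat TSV (one row per CNV, ranked),
a nested JSON document (full annotation bundles for downstream
rendering), and a human-readable text summary.  Analyst interpretations
live in one central tab-separated text file keyed by CNV name; re-running
the pipeline preserves and redisplays previous entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = [
    "SampleReport",
    "InterpretationStore",
    "write_report",
    "validate_report_json",
    "TSV_COLUMNS",
]

TSV_COLUMNS = [
    "sample_id", "rank", "chrom", "start", "end", "type", "size_bp",
    "priority", "clinical_relevance", "adverse", "tier",
    "triggered_rules", "adverse_reasons", "genes",
    "depth_ratio", "median_mq_inside", "supporting_read_count", "quality_score",
    "inheritance", "population_hits", "known_sv_hits", "internal_hits",
    "dosage_hits", "interpretation",
]

# external resource URL templates surfaced as plain strings in the JSON report
URL_TEMPLATES = {
    "gnomad_region": "https://gnomad.broadinstitute.org/region/{chrom}-{start}-{end}",
    "omim_search": "https://omim.org/search?search={gene}",
    "genecards": "https://www.genecards.org/cgi-bin/carddisp.pl?gene={gene}",
    "google_gene_phenotype": "https://www.google.com/search?q={gene}+{phenotype}",
}


@dataclass
class SampleReport:
    sample_id: str
    rows: list[dict] = field(default_factory=list)  # ordered by rank
    per_step_counts: dict[int, int] = field(default_factory=dict)
    input_count: int = 0
    metadata: dict = field(default_factory=dict)


class InterpretationStore:
    """Tab-separated ``cnv_name<TAB>interpretation`` text file; read-modify-
    write preserves entries for CNVs not touched in the current session."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._entries: dict[str, str] = {}
        if self.path.exists():
            for line in self.path.read_text().splitlines():
                if "\t" in line:
                    name, text = line.split("\t", 1)
                    self._entries[name] = text

    def get(self, cnv_name: str) -> str:
        return self._entries.get(cnv_name, "")

    def set(self, cnv_name: str, text: str) -> None:
        self._entries[cnv_name] = text
        self.save()

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            for name in sorted(self._entries):
                fh.write(f"{name}\t{self._entries[name]}\n")


def _fmt(value: Any) -> Any:
    if isinstance(value, float):
        return round(value, 6)
    if isinstance(value, (list, tuple)):
        return ";".join(str(v) for v in value)
    return value


def write_report(report: SampleReport, out_dir: str | Path, formats=("tsv", "json", "txt")) -> dict[str, Path]:
    """Write the report in the requested formats; returns paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "tsv" in formats:
        path = out_dir / f"{report.sample_id}.report.tsv"
        flat = [
            {col: _fmt(row.get(col, "")) for col in TSV_COLUMNS} for row in report.rows
        ]
        df = pd.DataFrame(flat, columns=TSV_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
        written["tsv"] = path

    if "json" in formats:
        path = out_dir / f"{report.sample_id}.report.json"
        doc = {
            "sample_id": report.sample_id,
            "metadata": report.metadata,
            "input_count": report.input_count,
            "per_step_counts": {str(k): v for k, v in report.per_step_counts.items()},
            "url_templates": URL_TEMPLATES,
            "cnvs": report.rows,
        }
        path.write_text(json.dumps(doc, indent=2, default=str) + "\n")
        written["json"] = path

    if "txt" in formats:
        path = out_dir / f"{report.sample_id}.summary.txt"
        lines = [
            f"Sample {report.sample_id}: {report.input_count} input CNVs, "
            f"filtration funnel {_funnel(report)}, "
            f"{sum(1 for r in report.rows if r.get('tier') == 'high')} high-priority",
            "",
        ]
        for row in report.rows:
            lines.append(
                f"#{row['rank']} {row['chrom']}:{row['start']}-{row['end']} "
                f"{row['type']} priority={row['priority']} tier={row['tier']}"
            )
            for finding in row.get("positive_findings", []):
                lines.append(f"    + {finding['sentence']}")
            for finding in row.get("negative_findings", []):
                lines.append(f"    - {finding['sentence']}")
            if row.get("interpretation"):
                lines.append(f"    interpretation: {row['interpretation']}")
        path.write_text("\n".join(lines) + "\n")
        written["txt"] = path

    return written


def _funnel(report: SampleReport) -> str:
    counts = [str(report.input_count)] + [
        str(report.per_step_counts[k]) for k in sorted(report.per_step_counts)
    ]
    return " -> ".join(counts)


_REQUIRED_TOP = {"sample_id": str, "metadata": dict, "input_count": int,
                 "per_step_counts": dict, "cnvs": list}
_REQUIRED_ROW = {"chrom": str, "start": int, "end": int, "type": str,
                 "priority": int, "clinical_relevance": int, "adverse": int,
                 "tier": str, "rank": int}


def validate_report_json(doc: dict) -> None:
    """Structural validation of the JSON report (schema documented in
    docs/report_schema.md); raises ValueError on the first violation."""
    for key, typ in _REQUIRED_TOP.items():
        if key not in doc:
            raise ValueError(f"report JSON missing key {key!r}")
        if not isinstance(doc[key], typ):
            raise ValueError(f"report JSON key {key!r} has type {type(doc[key]).__name__}, expected {typ.__name__}")
    for i, row in enumerate(doc["cnvs"]):
        for key, typ in _REQUIRED_ROW.items():
            if key not in row:
                raise ValueError(f"cnv row {i} missing key {key!r}")
            if not isinstance(row[key], typ):
                raise ValueError(f"cnv row {i} key {key!r} has wrong type")
        if row["tier"] not in ("high", "moderate", "low"):
            raise ValueError(f"cnv row {i}: bad tier {row['tier']!r}")
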