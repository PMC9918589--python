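# Report JSON structure

`<sample>.report.json` is a single object:

| key | type | meaning |
| --- | --- | --- |
| `sample_id` | string | sample the report describes |
| `metadata` | object | `cnvtriage_version`, `annotation_version`, `config_hash`, `genome_build`, full `config`, and the `removed` audit list (`cnv`, `step`, `reason`) |
| `input_count` | int | calls entering filtration (after pre-merge) |
| `per_step_counts` | object | calls remaining after each filtration step ("1", "2", "3") |
| `url_templates` | object | plain-string URL templates for external resources (gnomAD region, OMIM, GeneCards, gene+phenotype web search) |
| `cnvs` | array | one object per surviving CNV, ordered by rank |

Each `cnvs[]` row carries:

- identity: `cnv_name`, `sample_id`, `chrom`, `start`, `end` (0-based
  half-open), `type` (`deletion`/`duplication`), `size_bp`, `rank`
- scores: `priority`, `clinical_relevance`, `adverse`, `tier`
  (`high` | `moderate` | `low`), `triggered_rules`, `adverse_reasons`,
  `positive_findings` / `negative_findings` (lists of
  `{code, sentence}`)
- annotation bundle: `population_hits`, `known_sv_hits`, `internal_hits`,
  `dosage_hits`, `gene_impacts` (per gene: overlap kind, strand, pLI,
  disease associations, per-transcript affected exon numbers, affected
  CDS bp, pext min/max), `genes`
- evidence (null/absent without a BAM): `depth_ratio`,
  `median_mq_inside`, `supporting_read_count`, `quality_score`,
  `insert_bounds` (lower bp, upper bp, lower pct, upper pct),
  `reference_flagged_bins`
- inheritance (when family data given): `inheritance`,
  `inheritance_flags`, `inheritance_matches`
- `interpretation`: the analyst's stored interpretation, if any

`cnvtriage.report.validate_report_json` enforces the required keys and
types; the TSV column order is `cnvtriage.report.TSV_COLUMNS`.
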