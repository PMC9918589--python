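# cnvtriage

Filtration, prioritization and alignment-evidence extraction for germline
copy number variants (CNVs) called from whole-genome sequencing.

A 30x human genome yields thousands of deletion/duplication calls, nearly
all of them reference artefacts or common polymorphisms; a clinical
analyst can review perhaps a dozen. `cnvtriage` is the programmatic
backend for that triage: it reduces a raw call list to reviewable
candidates, scores each candidate's clinical relevance, measures how well
the alignments actually support the call, labels inheritance from family
call sets, and emits ranked structured reports (TSV / JSON / text).

## What it computes

**Filtration** removes, in three steps: (1) calls fully contained in
problem regions (assembly gaps, centromeres, repeats, recurrent-artefact
regions); (2) calls touching no coding sequence, unless they overlap a
gene with clinically relevant non-coding variation; (3) calls fully
contained in a same-type population structural variant with allele
frequency > 1% in any surveyed population.

**Prioritization** annotates each survivor against five categories —
population SVs, known pathogenic SVs, the internal cohort, ClinGen-style
dosage-sensitivity curations (HI = haploinsufficient, TS =
triplosensitive), and gene models with constraint (pLI) and per-exon
expression (pext) scores — and computes

```
priority = clinical_relevance + adverse_information
```

where clinical relevance is a ladder over dosage curation, constraint and
disease association (deletions score 1–5, duplications 1–7, 99 = no known
relevance; e.g. a deletion fully containing a curated HI region scores 1)
and adverse information is binary (100 whenever evidence argues against
the call being real or pathogenic — substantial overlap with a common
population SV, a read-depth ratio inconsistent with the call type, poor
mapping quality, heavy problem-region coverage; 0 otherwise). Lower is
better: priority < 99 is high (review), 99 moderate, > 99 low. Calls are
ranked by priority, then size.

**Evidence** extracts, from an indexed BAM/CRAM, per-CNV binned read
depth and mapping quality over the event plus flanks (50% of the variant
size per side, minimum 100 kb), the ratio of median depth inside vs.
flanking, insert-size outlier bounds (0.5/99.5 percentiles of the
empirical template-length distribution), a four-way anomalous-read
classification (inward pairs with outlier insert, outward pairs,
same-direction pairs, split reads), a type-consistent supporting-read
count, and a composite [0, 1] guidance quality score. An optional
reference control sample (e.g. NA12878) flags bins with systematic depth
artefacts.

**Inheritance** matches proband CNVs against family members' calls at
≥ 50% reciprocal overlap: no parental match in a complete trio → de novo;
single-parent match → maternal/paternal.

A deterministic synthetic-data module (`cnvtriage.fixtures`) generates
seeded references, alignments with engineered CNV signal (depth shifts,
discordant pairs, split reads) and toy annotation databases, so the whole
pipeline is testable without access-controlled data.

## Worked example

Simulate a study (600-kb contig, 30x paired-end background, one
heterozygous 40-kb deletion at chrT:300000-340000 that fully contains a
curated HI region, with 12 discordant pairs and 6 split reads planted at
its breakpoints), then triage three called CNVs:

```bash
cnvtriage simulate --outdir fixture
printf 'chrT\t300000\t340000\tDEL\nchrT\t150100\t150300\tDEL\nchrT\t52000\t58000\tDEL\n' > calls.tsv
cnvtriage config --init run.yaml   # edit: cnv_path, annodir, bam, out_dir
cnvtriage run --config run.yaml
cat out/DEMO.summary.txt
```

```
Sample DEMO: 3 input CNVs, filtration funnel 3 -> 3 -> 3 -> 2, 1 high-priority

#1 chrT:300000-340000 deletion priority=1 tier=high
    + Fully contains a curated haploinsufficient region/gene
    + Disrupts a curated haploinsufficient region/gene
    + Deletes coding sequence of a loss-of-function constrained gene
    + Deletes coding sequence of a disease-associated gene
    + Overlaps a disease-associated gene
#2 chrT:150100-150300 deletion priority=199 tier=low
    - Read-depth signal inconsistent with the called CNV type
```

Reading the result: the call at chrT:52000-58000 was removed by
filtration step 3 (fully contained in a deletion-type population SV at 5%
allele frequency, hence the funnel ends at 2). The engineered pathogenic
deletion ranks first with priority 1 — its measured depth ratio is 0.50
(the heterozygous expectation), median mapping quality 60, 18 supporting
anomalous reads, quality score 1.0. The 200-bp call at chrT:150100 hits
coding sequence so it survives filtration, but its depth ratio is ~1.0 —
no deletion signal — so the adverse-information criterion fires and it
drops to priority 199 (low): almost certainly a false positive.

The same stages are available piecewise (`cnvtriage filter`,
`prioritize`, `evidence` — the latter with `--plot` for static
depth/MQ/anomalous-read panels) and as a Python library
(`run_pipeline(RunConfig(...))`).

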