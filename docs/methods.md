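# Methods

## Scope and model

`cnvtriage` implements the backend of a clinical CNV-interpretation
workflow for germline deletions and duplications detected by short-read
whole-genome sequencing. It assumes: calls come from read-depth or
anomalous-read callers and may be fragmented (hence the pre-merge step);
the genome build of the calls, alignments and annotation tables is
consistent (the build tag is metadata only — there is no liftover); and
paired-end alignments are coordinate-sorted and indexed. Copy-neutral SV
types (inversions, translocations) are tolerated on parsing (skipped with
a record-level warning) but not analyzed, and full-chromosome aneuploidy
is out of scope.

All coordinates are handled 0-based half-open internally (BED
convention); VCF input (1-based POS, INFO/END) is converted on ingest.
Chromosome-name dialects ("chr1" vs "1") are reconciled through a
normalization map at comparison time while the input spelling is
preserved for output. Zero-length intervals are rejected at parse: a CNV
has positive extent by definition.

## Filtration

Step 1 removes calls *fully contained* in problem regions. Containment is
judged against the merged union of problem-region records by default, so
a call straddling two abutting repeat annotations still counts as
contained; per-record containment is available
(`problem_region_union: false`) for sites that prefer the laxer reading.
"Recurrence regions" — loci where the internal cohort carries same-type
CNVs at high frequency, a signature of recurrent artefacts — can be
derived with `filtration.recurrence_regions` (carrier fraction
> 0.03 by default) and appended to the problem-region table, or supplied
directly as BED.

Step 2 retains calls that touch ≥ 1 bp of coding sequence of *any*
transcript (not only the canonical one): the retention step is meant to
be maximally sensitive, and prioritization narrows later. Calls
overlapping any part (exon or intron) of a gene on the non-coding
exception list — genes with established clinically relevant non-coding
variation — are also retained.

Step 3 removes calls fully contained in a same-type population SV whose
allele frequency is *strictly greater than* 1% (`af_threshold: 0.01`) in
any surveyed population. The strict inequality matters: a variant at
exactly 1% is kept.

## Priority scoring

Clinical relevance is the lowest (best) matching tier of a rules ladder,
evaluated on the annotation bundle. The ladder is data — a table of
(score, finding-code) pairs resolvable against a predicate registry — so
a site can reorder, drop or extend tiers in configuration without code
changes. Defaults:

Deletions: 1 fully contains a curated HI region/gene; 2 partially
overlaps a curated HI region or deletes ≥ 1 CDS bp of a curated HI gene;
3 deletes ≥ 1 CDS bp of a gene with pLI ≥ 0.9; 4 deletes ≥ 1 CDS bp of an
OMIM/GenCC disease gene; 5 any other overlap of a disease gene.

Duplications: 1 fully contains a curated TS region/gene; 2 partially
overlaps a TS region; 3 fully contains an HI-curated gene (whole-gene
duplication, a dosage-gain of a dosage-sensitive gene); 4 breakpoint
inside an HI-curated or pLI ≥ 0.9 gene (possible gene disruption); 5
fully contains a pLI ≥ 0.9 gene; 6 fully contains a disease gene; 7 any
other overlap of a disease gene.

"Curated" means the dosage table's HI/TS level is in the configured
curated set (default levels 2 and 3, i.e. emerging/sufficient evidence).
The pLI cutoff 0.9 is the conventional loss-of-function-constraint
threshold. 99 means no rule fired. Known-pathogenic-SV and
internal-cohort overlaps are reported in the bundle and findings summary
but do not move the score: recurrence of a pathogenic variant is
something the reviewing analyst weighs, not an automatic promotion.

Adverse information is binary. Criteria (all configurable): (a)
reciprocal overlap ≥ 0.7 with a same-type population SV at popmax AF
> 1%; (b) depth ratio > 0.85 for a deletion / < 1.15 for a duplication
(the heterozygous expectations are 0.5 and 1.5; these cutoffs sit roughly
two-thirds of the way back toward 1.0, loose enough to tolerate noisy
coverage); (c) median mapping quality inside the CNV < 20; (d) > 70% of
the CNV covered by problem regions. Criteria (b) and (c) need alignment
evidence and never fire in annotation-only runs, so the backend degrades
gracefully without a BAM.

Ranking is ascending priority with descending size as tie-break (larger
events are more likely reportable), stable for full ties.

## Alignment evidence

Flanks are 50% of the variant size per side with a 100-kb minimum,
clamped at chromosome ends. The depth ratio uses medians of per-base
depth (inside vs. both flanks pooled) for robustness to coverage spikes;
if the flank median is zero the ratio is reported absent rather than
infinite. Depth excludes unmapped, secondary, duplicate and QC-fail
reads; supplementary alignments are used only for split-read detection.
The binned series defaults to 200 bins across the flanked window.

Insert-size outlier bounds are the 0.5/99.5 empirical percentiles of the
absolute template length of inward-oriented pairs in the window; if fewer
than 1,000 such pairs are present the sample falls back to up to 100,000
pairs file-wide.

Anomalous-read classification is exhaustive and mutually exclusive per
read pair, with precedence: split (supplementary-alignment/SA evidence)
> same-direction > outward > inward insert outlier; normally-sized inward
pairs are not anomalous. Split detection uses recorded supplementary
alignments only — soft-clipped reads are not re-aligned — which slightly
undercounts junction reads relative to what a breakpoint-refining caller
would report; this is the accepted trade-off for working from what the
BAM already contains.

Supporting-read counting is type-specific, with a 1,000-bp breakpoint
tolerance by default (read-depth callers with ~500-bp windows give
imprecise edges): a deletion is supported by large-insert inward pairs
whose flanking alignments end/begin within tolerance of the two
breakpoints and by split reads whose clip junction falls within tolerance
of either breakpoint; a duplication by outward pairs bracketing the event
and by split reads. The geometry check assumes both mates have the same
read length when reconstructing the mate's end from its start.

The quality score is this package's own composite (guidance only, never a
classification): the product of a depth-consistency term (0 at ratio 1.0,
saturating at the heterozygous expectation 0.5 or 1.5), an MQ term
(median MQ / 40, capped), and a support term (supporting reads / 5,
capped). It is monotone in each input and lives in [0, 1]; 0 means at
least one evidence channel is absent, 1 means all three saturate.

Reference-sample comparison flags bins where the *reference* (a control
genome without the proband's CNV) deviates from its own median bin depth
by more than 30% — such bins mark loci with systematic mapping artefacts,
and a co-located excursion in the proband is suspect.

## Inheritance

Family matching uses same-type calls at reciprocal overlap ≥ 0.5, the
conventional "same variant" criterion for CNV concordance. De novo is
asserted only when both parents are in the cohort table and neither
matches. A parental call that overlaps but fails the reciprocal threshold
while one interval is ≥ 90% contained in the other is flagged "possible
inherited, size-discordant" and blocks a de novo label — parental
under-calling would otherwise manufacture de novo findings.

## Synthetic data: what it does and does not show

The generator writes aligned records directly (no read mapper): inward
proper pairs at a target mean depth with template length
Normal(insert_mean, insert_sd), default 30x / 150 bp / 400 ± 50 bp — a
standard short-read WGS operating point. A heterozygous deletion drops
each fragment touching the event with probability 0.5 (homozygous: 1.0);
a duplication adds fragments inside at half (het) or full (hom) the
background rate; the requested numbers of discordant pairs and split
reads are planted at exact breakpoints. Base qualities are constant and
there is no sequencing-error or GC-bias model — depth and pair geometry,
not base identity, carry the evidence this package consumes. Output is
byte-deterministic per seed under fixed library versions.

Consequences for interpretation: tests passing on these fixtures show the
*logic* is right — coordinate arithmetic, the scoring ladder, the
classifier's decision rules, the depth estimator's calibration under
binomial sampling noise. They do not show robustness to multi-mapping in
segmental duplications, GC-coverage waves, batch-variable insert-size
distributions, or imprecise real-world breakpoints; on real data the
breakpoint tolerance and the adverse depth cutoffs do the absorbing, and
the quality score remains guidance.

Default test/acceptance problem sizes: a 600-kb contig at 30x for the
end-to-end study; 120-kb contigs at 25x with explicit 20-kb flank windows
for the 20-replicate depth-recovery suite; a 1-Mb contig at 30x
(~100,000 pairs) for the insert-percentile measurement.

## Numerical and degenerate-input choices

Interval operations are closed-form on half-open bounds and are
property-tested against a per-base set-intersection oracle. Merging is
idempotent and records constituent source lines. Empty bins report depth
0 and absent MQ; an empty flank makes the depth ratio absent; an
alignment file with no inward pairs makes insert-bound estimation fail
loudly with a remediation hint. Percentiles use numpy's default linear
interpolation. The report writers round floats (6 decimals in TSV, 4 for
scores) so reruns are byte-identical.

## Known limitations

No liftover; no phenotype-aware prioritization; no ACMG/ClinGen point
classification (the output tier selects what a human reviews, it does not
classify); no compound-heterozygous CNV+SNV analysis; split-read
detection bounded by what the aligner recorded; single-process execution
(the stages are composable but not parallelized).
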