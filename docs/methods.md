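# Methods

## Scope and data model

`strainvar` operates downstream of read alignment, variant calling, and
consequence annotation: its input is a single-sample VCF whose records
carry per-transcript consequence annotations in a pipe-delimited `CSQ`
INFO field (sub-field layout read from the header's `Format:` clause, with
a configurable fallback). It does not realign reads, call genotypes, or
re-derive SO terms or predictor scores.

The unit of analysis is a biallelic, decomposed variant. Multiallelic
sites are split into one record per alternate allele present in the
genotype; zygosity is derived from GT only (`1/1` homozygous-alt, any
mixed genotype heterozygous). QUAL and DP are carried through but not
re-thresholded — call-stage filtering belongs to the upstream pipeline.
Coordinates are 1-based throughout; named intervals are inclusive at both
ends; sliding windows are half-open `[s, s + W)`.

Indel alleles are trimmed to a canonical minimal representation (shared
suffix, then shared prefix, keeping one anchor base) at parse time, so
that the position-identity tests used by the private-indel rule are
well defined. Full left-alignment requires reference sequence, which the
pipeline does not otherwise consume; `left_align(pos, ref, alt, chrom_seq)`
is provided for callers that have it. This is the one place where
representation differences between callers could still leak through: two
call sets normalized by different tools should be passed through the same
normalization before comparison.

## Consequence prioritization

The priority ordering is a fixed 19-term list from `stop_gained` down to
`intergenic_variant`. Reduction happens in two steps: each distinct
per-transcript SO term *set* is summarized by its highest-priority member
(the representative term), and a variant carrying two or more distinct
sets — a "multiple classification sets" variant — takes the
highest-priority representative. Because the minimum of per-set minima is
the global minimum, the final term is equivalently the highest-priority
term across all transcript annotations; the representative structure is
kept because the per-set table is itself a deliverable.

Terms outside the 19-term list rank after every listed term, with ties
broken lexicographically, so classification is total and deterministic for
any annotator vocabulary. Annotation-free variants classify as
`intergenic_variant`. In the set table each variant is counted exactly
once: multi-set variants are pooled into a single row rather than being
re-counted under each of their sets. The potentially-pathogenic flag uses
any-transcript semantics — the ten-term set is tested against the union of
a variant's annotations, not against its final term — so an intronic-final
variant can still be flagged through a minor transcript.

## Private-variant rule

A site is *informative* for a panel strain when its call quality is at
least `min_qual` (default 20) and its depth at least `min_depth` (default
5), both inclusive. Privacy requires a quorum of informative strains
(default 21 of 28) plus the absence of a disqualifying call: for SNPs, a
panel strain carrying the identical (chrom, pos, ref, alt) allele
(heterozygous or homozygous); for indels, any panel variant at the same
normalized position. The indel rule is deliberately stricter because
equivalent indels frequently surface with different allele
representations across callers.

Two readings of the rule differ on whether a disqualifying call must
itself pass the quality thresholds. The default applies the quorum to the
site and lets any allele match disqualify regardless of its own
confidence; `PanelConfig(strict_disqualifiers=True)` implements the other
reading. Under the default, tightening `min_qual`/`min_depth` can only
shrink the informative set, so it never converts a non-private variant to
private — a property the suite checks.

## Deleteriousness consensus

SIFT and PROVEAN cutoffs are strict: deleterious iff SIFT < 0.05, iff
PROVEAN < −2.5. Strictness matters at the boundary — a score printed
exactly at the cutoff (0.05, −2.5) is tolerated — and is what makes the
packaged tabw2 missense table yield 5 both-deleterious SNPs in *tabw2a*
and 2 in *tabw2b*. Both thresholds are exposed (`--sift-max`,
`--provean-max`) for sensitivity analyses with ≤-style inclusion. A
missing score is a no-call: the predictor abstains, `either` can still be
reached through the other predictor, `both` cannot. When a variant is
missense in several transcripts, the minimum SIFT and minimum PROVEAN
across transcripts are used (most-deleterious transcript), with
per-transcript detail retained.

Codon-change verification translates the ref/alt codon pair with the
standard genetic code (Biopython); the residue index is
`ceil(cds_position / 3)`. The packaged table
(`strainvar/data/tabw2_missense_snps.tsv`) is a curated transcription of
the chromosome-6 tabw2 missense SNPs with their predictor scores; `NA`
marks scores the predictors did not produce.

## Trait gene sets and candidate reports

Trait matching on the GWAS-catalog `DISEASE/TRAIT` column is
case-insensitive substring by default (regex optional); the three gene-ID
columns are pooled as a set union, and upstream/downstream genes are not
deduplicated against mapped genes beyond that union. Ortholog projection
consumes a two-column human→mouse mapping file (many-to-many); IDs with no
ortholog are dropped and counted in the log, never fatal. In a candidate
report a variant counts once per class (SNP/indel) however many candidate
genes it hits, while `total_genes` counts distinct genes with at least one
qualifying variant.

## Sliding-window density

Window counts use sorted positions and binary search; a window starting at
`s` counts positions in `[s, s + W)`. All windows with start ≤ chromosome
length are emitted, including partial terminal windows; the convention is
recorded in the track header. The library default is the figure-grade
1 Mb window sliding in 1 kb steps; the pipeline's density *report* defaults
to tiling 1 Mb windows (step = window) to keep report files compact, with
the step exposed as `--density-step`.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline consumes,
starting at called, annotated variants (no reads, no BAMs):

* zygosity mix: 1.37 % heterozygous SNPs, 12.24 % heterozygous indels;
* consequence-set composition drawn from a weighted library of SNP and
  indel term-set combinations (≈50 % intergenic, ≈27 % intronic, small
  genic classes, multi-transcript combinations), with codon changes that
  genuinely translate to the planted amino-acid effect;
* SIFT/PROVEAN scores from a mixture with planted both-deleterious,
  SIFT-only, tolerated, and score-missing components;
* privacy planted at 2.29 % of SNPs and 15.4 % of indels, with panel
  calls constructed so the planted flag is exactly recoverable: private
  variants get no disqualifying call and a satisfied quorum (private SNPs
  may see other alleles in the panel, which must not disqualify them);
  non-private variants get either a disqualifying call or a planted
  quorum failure;
* candidate gene sets drawn from genes the cohort actually annotates,
  with configurable ortholog coverage and decoy catalog rows.

Each generator draws from an independent, named substream of the seed
(stream keys via CRC-32, which is stable across processes), so outputs are
byte-identical under a fixed seed and adding a generator does not perturb
the others. Default problem size is 1,000 variants against a 28-strain
panel — large enough that every consequence class, privacy mode, and
score-mixture component is populated, while the full suite runs in
seconds.

What passing on synthetic data does **not** show: the generator plants
annotations directly, so it cannot detect disagreements with a real
annotator's term assignment, VEP's allele-trimming conventions in `CSQ`
records, or reference-dependent indel left-alignment differences; and its
uniform position model has none of the linkage structure or density
heterogeneity of a real genome.

## Numerical and degenerate-input conventions

Heterozygous-fraction reporting on an empty class is absent (`None`), not
zero. An empty SO term set is an argument error; an empty panel call list
is an error rather than vacuous privacy. SIFT scores outside [0, 1] are
rejected. Pipeline stages fail with a stage-named error and a distinct
nonzero exit code per stage; the run manifest records input checksums,
the effective configuration, and per-stage record counts, and reruns are
byte-identical given identical inputs.
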