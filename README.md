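# strainvar

Variant prioritization for inbred mouse strains.

When a disease-model strain such as TALLYHO/Jng is whole-genome sequenced
against the C57BL/6 reference, the result is millions of SNPs and small
indels, almost all of them irrelevant to the phenotype. `strainvar`
implements the triage that turns that catalog into a short candidate-gene
list:

1. **Consequence classification.** Each variant carries, per overlapping
   transcript, a set of Sequence Ontology (SO) terms assigned by a
   consequence annotator (VEP-style `CSQ` records). Each distinct term set
   is summarized by a *representative term* — its highest-priority member
   under a fixed 19-term ordering from `stop_gained` down to
   `intergenic_variant` — and a variant with several distinct sets takes
   the *most pathogenic* representative. Independently, a variant is
   *potentially pathogenic* if any transcript's terms intersect a ten-term
   set (frameshift, in-frame indels, missense, stop gained/lost, initiator
   codon, splice region/acceptor/donor).
2. **Strain-private detection.** A variant is *private* if it is absent from
   every strain of a reference panel (modelled on the 28 Mouse Genomes
   Project strains), with a quorum rule: at least 21 of 28 strains must be
   confidently genotyped at the site (QUAL ≥ 20, DP ≥ 5). A SNP is
   disqualified only by the *same* allele in a panel strain; an indel by
   *any* panel variant at the same (normalized) position.
3. **Deleteriousness consensus.** Missense variants are deleterious by SIFT
   iff score < 0.05 and by PROVEAN iff score < −2.5 (both strict); the
   *both* consensus is the high-confidence filter.
4. **QTL and trait intersection.** Variants are filtered to QTL intervals
   (the obesity loci *tabw2a* 6:80,217,217–125,356,646 and *tabw2b*
   6:133,853,029–144,639,629 ship as defaults) and intersected with mouse
   gene sets built from a GWAS-catalog TSV (trait keyword → human genes →
   mouse orthologs) and a monogenic obesity gene list.

A synthetic-data module generates annotated cohorts, strain panels, and
gene-set files with recorded ground truth, so the full pipeline is testable
without any sequencing data.

## Worked example

Simulate a cohort and run every stage:

```sh
strainvar simulate --out sim --seed 2 --n-variants 200
strainvar run-all --vcf sim/cohort.vcf --panel sim/panel.tsv \
    --catalog sim/gwas_catalog.tsv --orthologs sim/orthologs.tsv \
    --mendelian sim/mendelian_genes.tsv --out reports
```

which prints the per-stage record counts, e.g.

```
parse: {"n_homozygous": 195, "n_input": 200}
classify: {"n_distinct_sets": 10}
private: {"n_private_indels": 7, "n_private_snps": 5}
deleterious: {"n_missense": 8}
intervals: {"n_intervals": 2}
candidates: {"n_reports": 6}
density: {"n_chromosomes": 2}
```

195 of 200 simulated variants are homozygous (heterozygous calls are
excluded from all downstream stages); 5 SNPs and 7 indels are private to
the target strain under the 21-of-28 quorum rule; and the candidate stage
writes one report row per trait keyword and Mendelian obesity category.
`reports/` then contains the classification tables, private flags and
summary, the missense deleteriousness table, the per-interval QTL summary,
per-chromosome density tracks, and a manifest with input checksums.

The packaged table of tabw2 missense SNPs can be screened directly:

```sh
$ strainvar tabw2-report
tabw2a: 5 SNPs in 5 genes (A2m, Chchd6, Cidec, Gcfc2, Ret)
tabw2b: 2 SNPs in 2 genes (BC049715, Pik3c2g)
```

Five SNPs in the *tabw2a* interval and two in *tabw2b* pass the strict
both-deleterious consensus; among them is the *Cidec* R46S substitution
(CDS 136 C>A, codon CGT→AGT):

```python
>>> from strainvar import CodonChange, translate_codon_change
>>> str(translate_codon_change(CodonChange(136, "CGT", "AGT")))
'R46S'
```

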