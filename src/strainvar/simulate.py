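"""Synthetic annotated-variant cohorts with recorded ground truth.

The generator emulates the statistical structure of an inbred-strain variant
catalog after calling and consequence annotation: a single-sample VCF with
CSQ-style per-transcript annotations, a multi-strain panel call table for
private-variant detection, and GWAS-catalog / ortholog / Mendelian gene-list
files for candidate-gene intersection.  Every planted property (zygosity,
consequence sets, deleteriousness, privacy, interval membership, candidate
genes) is recorded in a :class:`GroundTruth` sidecar so each pipeline stage
can be checked for exact recovery.

Defaults mirror the observed composition of a laboratory mouse genome
relative to the reference strain: mostly intergenic/intronic consequences,
~1.4 % heterozygous SNPs and ~12 % heterozygous indels, ~2.3 % private SNPs
and ~15 % private indels.  Simulation starts at called, annotated variants;
no read-level data is modelled.

All generators are deterministic given the seed (independent substreams per
output file, so adding one generator does not perturb the others).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import so_terms
from .private import CallStatus, PanelConfig, StrainSiteCall, write_panel_tsv
from .so_terms import DEFAULT_PRIORITY, SOPriority
from .variants import DEFAULT_INTERVALS, GenomicInterval

# (term sets per transcript, weight); an empty tuple of sets = intergenic.
SetSpec = tuple[tuple[frozenset[str], ...], float]


def _s(*terms: str) -> frozenset[str]:
    return frozenset(terms)


#: Consequence-set library for SNPs, loosely matching the observed genome-wide
#: mix (about half intergenic, a third intronic, the rest genic classes).
DEFAULT_SNP_SETS: tuple[SetSpec, ...] = (
    ((), 0.50),
    ((_s("intron_variant"),), 0.26),
    ((_s("upstream_gene_variant"),), 0.08),
    ((_s("downstream_gene_variant"),), 0.06),
    ((_s("3_prime_UTR_variant"),), 0.01),
    ((_s("5_prime_UTR_variant"),), 0.01),
    ((_s("synonymous_variant"),), 0.02),
    ((_s("missense_variant"),), 0.02),
    ((_s("missense_variant", "splice_region_variant"),), 0.005),
    ((_s("intron_variant", "splice_region_variant"),), 0.005),
    ((_s("stop_gained"),), 0.002),
    ((_s("missense_variant"), _s("intron_variant")), 0.015),
    ((_s("upstream_gene_variant"), _s("downstream_gene_variant")), 0.01),
    ((_s("synonymous_variant"), _s("3_prime_UTR_variant")), 0.003),
)

DEFAULT_INDEL_SETS: tuple[SetSpec, ...] = (
    ((), 0.49),
    ((_s("intron_variant"),), 0.27),
    ((_s("upstream_gene_variant"),), 0.08),
    ((_s("downstream_gene_variant"),), 0.07),
    ((_s("5_prime_UTR_variant"),), 0.01),
    ((_s("non_coding_transcript_variant"),), 0.02),
    ((_s("frameshift_variant"),), 0.02),
    ((_s("inframe_insertion"),), 0.01),
    ((_s("inframe_deletion"),), 0.01),
    ((_s("frameshift_variant"), _s("intron_variant")), 0.01),
    ((_s("intron_variant", "splice_region_variant"),), 0.01),
)

# Non-synonymous codon pairs by within-codon offset of the changed base,
# and synonymous pairs (third-position wobble).
_MISSENSE_CODONS = {
    0: (("CGT", "AGT"), ("GAC", "AAC"), ("ACC", "GCC")),
    1: (("GAC", "GGC"), ("ACC", "ATC"), ("AAT", "AGT")),
    2: (("ATG", "ATA"), ("AAA", "AAT"), ("TGC", "TGG")),
}
_SYNONYMOUS_CODONS = (("AAA", "AAG"), ("CTG", "CTA"), ("GGT", "GGC"))

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Knobs for the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_variants: int = 1000
    snp_fraction: float = 0.8
    het_fraction: dict[str, float] = field(
        default_factory=lambda: {"SNP": 0.0137, "INDEL": 0.1224}
    )
    private_fraction: dict[str, float] = field(
        default_factory=lambda: {"SNP": 0.0229, "INDEL": 0.154}
    )
    snp_sets: tuple[SetSpec, ...] = DEFAULT_SNP_SETS
    indel_sets: tuple[SetSpec, ...] = DEFAULT_INDEL_SETS
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"6": 149_736_546, "7": 145_441_459}
    )
    intervals: tuple[GenomicInterval, ...] = DEFAULT_INTERVALS
    n_genes: int = 120
    n_candidate_genes: int = 12
    ortholog_coverage: float = 0.9
    # deleteriousness mixture over missense variants
    p_both_deleterious: float = 0.15
    p_sift_only: float = 0.10
    p_score_missing: float = 0.08
    # panel call-quality model
    panel: PanelConfig = field(default_factory=PanelConfig)
    panel_qual_range: tuple[float, float] = (30.0, 90.0)
    panel_depth_range: tuple[int, int] = (8, 40)
    nonprivate_quorum_fail: float = 0.25  # fraction of non-private planted via quorum failure
    sample_name: str = "TARGET"

    def __post_init__(self) -> None:
        for name, val in [("snp_fraction", self.snp_fraction), ("ortholog_coverage", self.ortholog_coverage)]:
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for d in (self.het_fraction, self.private_fraction):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("fractions must be in [0, 1]")
        if any(f > 0 for f in self.private_fraction.values()) and self.panel.n_strains < 1:
            raise ValueError("private_fraction > 0 requires a non-empty panel")


@dataclass
class GroundTruth:
    """Planted per-variant truth plus expected candidate-gene reports."""

    variants: pd.DataFrame  # one row per variant with all planted properties
    candidate_reports: pd.DataFrame | None = None
    trait_gene_sets: dict[str, set[str]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.variants.to_csv(path, sep="\t", index=False)
        if self.candidate_reports is not None:
            self.candidate_reports.to_csv(
                path.with_suffix(".candidates.tsv"), sep="\t", index=False
            )


def _rng_for(config: SimConfig, stream: str) -> np.random.Generator:
    # independent substream per output file; crc32 is stable across processes
    key = zlib.crc32(stream.encode()) % (2**31)
    ss = np.random.SeedSequence(config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def _choose_weighted(rng: np.random.Generator, specs: tuple[SetSpec, ...]) -> int:
    weights = np.array([w for _, w in specs], dtype=float)
    return int(rng.choice(len(specs), p=weights / weights.sum()))


def _interval_names(intervals, chrom: str, pos: int) -> str:
    return ",".join(iv.name for iv in intervals if iv.contains(chrom, pos))


def gen_cohort(config: SimConfig, out_dir: str | Path) -> tuple[Path, GroundTruth]:
    """Write an annotated single-sample VCF and its ground truth.

    Returns the VCF path and the in-memory :class:`GroundTruth`; a TSV
    sidecar ``truth.tsv`` is written next to the VCF.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng_for(config, "cohort")
    priority = DEFAULT_PRIORITY

    chroms = sorted(config.chrom_lengths)
    genes = [f"ENSMUSG{i:011d}" for i in range(1, config.n_genes + 1)]

    # unique positions per chromosome
    chrom_of = rng.choice(chroms, size=config.n_variants)
    rows = []
    used: dict[str, set[int]] = {c: set() for c in chroms}
    for i in range(config.n_variants):
        chrom = str(chrom_of[i])
        length = config.chrom_lengths[chrom]
        while True:
            pos = int(rng.integers(1, length + 1))
            if pos not in used[chrom]:
                used[chrom].add(pos)
                break
        is_snp = rng.random() < config.snp_fraction
        vclass = "SNP" if is_snp else "INDEL"
        if is_snp:
            ref, alt = rng.choice(4, size=2, replace=False)
            ref, alt = _BASES[ref], _BASES[alt]
        else:
            anchor = _BASES[rng.integers(4)]
            tail = "".join(_BASES[rng.integers(4, size=int(rng.integers(1, 4)))])
            if rng.random() < 0.5:
                ref, alt = anchor, anchor + tail  # insertion
            else:
                ref, alt = anchor + tail, anchor  # deletion
        het = rng.random() < config.het_fraction[vclass]
        specs = config.snp_sets if is_snp else config.indel_sets
        set_idx = _choose_weighted(rng, specs)
        term_sets = specs[set_idx][0]
        gene = genes[int(rng.integers(config.n_genes))] if term_sets else ""
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": str(ref),
                "alt": str(alt),
                "variant_class": vclass,
                "zygosity": "HET" if het else "HOM_ALT",
                "set_idx": set_idx,
                "gene": gene,
                "qual": round(float(rng.uniform(50, 220)), 1),
                "depth": int(rng.poisson(60)) + 1,
            }
        )
    truth = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    # plant consequence detail, deleteriousness, privacy, intervals
    finals, multi, pathogenic, sifts, proveans = [], [], [], [], []
    both_fl, either_fl, private_fl, iv_names, n_tx = [], [], [], [], []
    for row in truth.itertuples(index=False):
        specs = config.snp_sets if row.variant_class == "SNP" else config.indel_sets
        term_sets = specs[row.set_idx][0]
        n_tx.append(len(term_sets))
        if not term_sets:
            finals.append(so_terms.INTERGENIC)
            multi.append(False)
            pathogenic.append(False)
        else:
            reps = [so_terms.representative_term(ts, priority) for ts in term_sets]
            finals.append(min(reps, key=priority.rank_key))
            multi.append(len(set(term_sets)) >= 2)
            pathogenic.append(
                any(ts & priority.pathogenic_terms for ts in term_sets)
            )
        is_missense = any("missense_variant" in ts for ts in term_sets)
        sift = provean = np.nan
        both = either = False
        if is_missense:
            u = rng.random()
            if rng.random() < config.p_score_missing:
                provean = float(np.round(rng.uniform(-8, 4), 2))
                either = provean < -2.5
            elif u < config.p_both_deleterious:
                sift = float(np.round(rng.uniform(0.0, 0.049), 3))
                provean = float(np.round(rng.uniform(-8.0, -2.6), 2))
                both = either = True
            elif u < config.p_both_deleterious + config.p_sift_only:
                sift = float(np.round(rng.uniform(0.0, 0.049), 3))
                provean = float(np.round(rng.uniform(-2.4, 4.0), 2))
                either = True
            else:
                sift = float(np.round(rng.uniform(0.06, 1.0), 3))
                provean = float(np.round(rng.uniform(-2.4, 4.0), 2))
        sifts.append(sift)
        proveans.append(provean)
        both_fl.append(both)
        either_fl.append(either)
        private_fl.append(
            row.zygosity == "HOM_ALT"
            and rng.random() < config.private_fraction[row.variant_class]
        )
        iv_names.append(_interval_names(config.intervals, row.chrom, row.pos))
    truth["n_transcripts"] = n_tx
    truth["final_term"] = finals
    truth["multi_set"] = multi
    truth["pathogenic"] = pathogenic
    truth["sift"] = sifts
    truth["provean"] = proveans
    truth["deleterious_both"] = both_fl
    truth["deleterious_either"] = either_fl
    truth["private"] = private_fl
    truth["intervals"] = iv_names

    vcf_path = out_dir / "cohort.vcf"
    _write_cohort_vcf(truth, config, vcf_path, rng)
    gt = GroundTruth(variants=truth)
    gt.save(out_dir / "truth.tsv")
    return vcf_path, gt


def _csq_entries(row, config: SimConfig, rng: np.random.Generator) -> list[str]:
    specs = config.snp_sets if row.variant_class == "SNP" else config.indel_sets
    term_sets = specs[row.set_idx][0]
    entries = []
    for t, terms in enumerate(term_sets, start=1):
        tx = f"{row.gene}.T{t}"
        codons = aa = cds = prot = ""
        sift = provean = ""
        if "missense_variant" in terms:
            offset = int(rng.integers(3))
            ref_c, alt_c = _MISSENSE_CODONS[offset][int(rng.integers(3))]
            codon_idx = int(rng.integers(1, 400))
            cds = str((codon_idx - 1) * 3 + offset + 1)
            prot = str(codon_idx)
            codons = f"{ref_c}/{alt_c}"
            from Bio.Seq import Seq

            aa = f"{Seq(ref_c).translate()}/{Seq(alt_c).translate()}"
            if not np.isnan(row.sift):
                sift = f"{row.sift:.3f}"
            if not np.isnan(row.provean):
                provean = f"{row.provean:.2f}"
        elif "synonymous_variant" in terms:
            ref_c, alt_c = _SYNONYMOUS_CODONS[int(rng.integers(3))]
            codon_idx = int(rng.integers(1, 400))
            cds = str(codon_idx * 3)
            prot = str(codon_idx)
            codons = f"{ref_c}/{alt_c}"
        entries.append(
            "|".join(
                [
                    row.alt,
                    "&".join(sorted(terms)),
                    row.gene,
                    tx,
                    cds,
                    prot,
                    codons,
                    aa,
                    sift,
                    provean,
                ]
            )
        )
    return entries


def _write_cohort_vcf(truth: pd.DataFrame, config: SimConfig, path: Path, rng) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        "Format: Allele|Consequence|Gene|Feature|CDS_position|Protein_position|"
        'Codons|Amino_acids|SIFT|PROVEAN">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom in sorted(config.chrom_lengths):
        lines.append(f"##contig=<ID={chrom},length={config.chrom_lengths[chrom]}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + config.sample_name
    )
    for row in truth.itertuples(index=False):
        info = f"DP={row.depth}"
        entries = _csq_entries(row, config, rng)
        if entries:
            info += ";CSQ=" + ",".join(entries)
        gt = "1/1" if row.zygosity == "HOM_ALT" else "0/1"
        lines.append(
            f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{row.qual}\t.\t"
            f"{info}\tGT:DP\t{gt}:{row.depth}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Panel generation


def gen_panel(
    truth: GroundTruth, config: SimConfig, out_path: str | Path
) -> dict[tuple[str, int, str, str], list[StrainSiteCall]]:
    """Generate 28-strain panel calls consistent with planted privacy flags.

    Private variants get no disqualifying panel call and a satisfied quorum;
    non-private variants get either a disqualifying call (same allele for
    SNPs; any variant for indels) or a planted quorum failure.  Only
    homozygous variants are genotyped (heterozygous records are excluded
    from the private analysis upstream).
    """
    if config.panel.n_strains < 1:
        raise ValueError("panel must have at least one strain")
    rng = _rng_for(config, "panel")
    pc = config.panel
    strains = [f"STRAIN{i:02d}" for i in range(1, pc.n_strains + 1)]
    qlo, qhi = config.panel_qual_range
    dlo, dhi = config.panel_depth_range

    def good_call(strain: str, status: CallStatus) -> StrainSiteCall:
        return StrainSiteCall(
            strain,
            status,
            qual=round(float(rng.uniform(max(qlo, pc.min_qual), qhi)), 1),
            depth=int(rng.integers(max(dlo, pc.min_depth), dhi + 1)),
        )

    def bad_call(strain: str, status: CallStatus) -> StrainSiteCall:
        mode = rng.integers(3)  # fail qual, depth, or both
        qual = round(float(rng.uniform(0, pc.min_qual - 0.1)), 1) if mode != 1 else round(
            float(rng.uniform(pc.min_qual, qhi)), 1
        )
        depth = int(rng.integers(0, pc.min_depth)) if mode != 0 else int(
            rng.integers(pc.min_depth, dhi + 1)
        )
        return StrainSiteCall(strain, status, qual=qual, depth=depth)

    panel: dict[tuple[str, int, str, str], list[StrainSiteCall]] = {}
    hom = truth.variants[truth.variants["zygosity"] == "HOM_ALT"]
    for row in hom.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        is_snp = row.variant_class == "SNP"
        calls: list[StrainSiteCall] = []
        if row.private:
            n_fail = int(rng.integers(0, pc.n_strains - pc.quorum + 1))
            statuses = []
            for _ in range(pc.n_strains):
                # private SNPs tolerate other variants at the site
                if is_snp and rng.random() < 0.1:
                    statuses.append(CallStatus.OTHER_VARIANT)
                else:
                    statuses.append(CallStatus.NO_VARIANT)
            fail_idx = set(rng.choice(pc.n_strains, size=n_fail, replace=False).tolist())
            for i, strain in enumerate(strains):
                maker = bad_call if i in fail_idx else good_call
                calls.append(maker(strain, statuses[i]))
        else:
            if rng.random() < config.nonprivate_quorum_fail:
                # quorum failure: no disqualifying allele, too few informative
                n_inf = int(rng.integers(0, pc.quorum))
                inf_idx = set(rng.choice(pc.n_strains, size=n_inf, replace=False).tolist())
                for i, strain in enumerate(strains):
                    maker = good_call if i in inf_idx else bad_call
                    calls.append(maker(strain, CallStatus.NO_VARIANT))
            else:
                n_same = int(rng.integers(1, 4))
                same_idx = set(rng.choice(pc.n_strains, size=n_same, replace=False).tolist())
                for i, strain in enumerate(strains):
                    if i in same_idx:
                        status = (
                            CallStatus.SAME_ALLELE
                            if is_snp or rng.random() < 0.5
                            else CallStatus.OTHER_VARIANT
                        )
                        calls.append(good_call(strain, status))
                    else:
                        calls.append(good_call(strain, CallStatus.NO_VARIANT))
        panel[key] = calls
    write_panel_tsv(panel, str(out_path))
    return panel


# ---------------------------------------------------------------------------
# Catalog / ortholog / Mendelian list generation

TRAIT_KEYWORDS = ("obesity", "diabetes", "metabolic")
_TRAIT_TEMPLATES = {
    "obesity": ("Obesity (adult)", "Childhood obesity severity"),
    "diabetes": ("Type 2 diabetes", "Gestational diabetes"),
    "metabolic": ("Metabolic syndrome", "Metabolic traits composite"),
}
_DECOY_TRAITS = ("Height", "Eye color", "Freckling")


def gen_catalog_and_orthologs(
    truth: GroundTruth, config: SimConfig, out_dir: str | Path
) -> tuple[Path, Path, Path, GroundTruth]:
    """Write catalog, ortholog-map and Mendelian-list TSVs with planted truth.

    Candidate genes for each trait are drawn from genes the cohort actually
    annotates; the expected candidate report per trait (computed from the
    per-variant truth and the planted ortholog coverage) is recorded on the
    returned :class:`GroundTruth`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng_for(config, "catalog")
    tv = truth.variants
    annotated_genes = sorted(set(tv.loc[tv["gene"] != "", "gene"]))
    n_cand = min(config.n_candidate_genes, len(annotated_genes))

    mouse_to_human = {g: f"ENSG{i:011d}" for i, g in enumerate(annotated_genes, start=1)}
    # ortholog map covers a configured fraction of genes
    covered = {
        g
        for g in annotated_genes
        if rng.random() < config.ortholog_coverage
    }
    ortholog_rows = [(mouse_to_human[g], g) for g in sorted(covered)]
    ortholog_path = out_dir / "orthologs.tsv"
    pd.DataFrame(ortholog_rows, columns=["human_gene_id", "mouse_gene_id"]).to_csv(
        ortholog_path, sep="\t", index=False
    )

    catalog_rows = []
    trait_mouse_sets: dict[str, set[str]] = {}
    for kw in TRAIT_KEYWORDS:
        picked = (
            list(rng.choice(annotated_genes, size=n_cand, replace=False))
            if n_cand
            else []
        )
        trait_mouse_sets[kw] = {g for g in picked if g in covered}
        templates = _TRAIT_TEMPLATES[kw]
        for j, gene in enumerate(picked):
            catalog_rows.append(
                {
                    "DISEASE/TRAIT": templates[j % len(templates)],
                    "MAPPED GENE(S)": mouse_to_human[gene],
                    "UPSTREAM_GENE_ID": "",
                    "DOWNSTREAM_GENE_ID": "",
                }
            )
    for trait in _DECOY_TRAITS:
        catalog_rows.append(
            {
                "DISEASE/TRAIT": trait,
                "MAPPED GENE(S)": "ENSG99999999999",
                "UPSTREAM_GENE_ID": "",
                "DOWNSTREAM_GENE_ID": "",
            }
        )
    catalog_path = out_dir / "gwas_catalog.tsv"
    pd.DataFrame(catalog_rows).to_csv(catalog_path, sep="\t", index=False)

    mendelian_categories = (
        "syndromic obesity",
        "non-syndromic obesity",
        "non-syndromic lipodystrophy",
    )
    n_mend = min(6, len(annotated_genes))
    mend_genes = list(rng.choice(annotated_genes, size=n_mend, replace=False))
    mend_rows = [
        {"gene": mouse_to_human[g], "category": mendelian_categories[i % 3]}
        for i, g in enumerate(mend_genes)
    ]
    mendelian_path = out_dir / "mendelian_genes.tsv"
    pd.DataFrame(mend_rows).to_csv(mendelian_path, sep="\t", index=False)
    for i, g in enumerate(mend_genes):
        cat = mendelian_categories[i % 3]
        trait_mouse_sets.setdefault(cat, set())
        if g in covered:
            trait_mouse_sets[cat].add(g)

    # expected candidate reports from per-variant truth (homozygous subset)
    hom = tv[tv["zygosity"] == "HOM_ALT"]
    report_rows = []
    for label, gene_set in trait_mouse_sets.items():
        qual = hom[hom["pathogenic"] & hom["gene"].isin(gene_set)]
        snps = qual[qual["variant_class"] == "SNP"]
        indels = qual[qual["variant_class"] == "INDEL"]
        report_rows.append(
            {
                "source": label,
                "total_genes": qual["gene"].nunique(),
                "snps": len(snps),
                "indels": len(indels),
                "private_snps": int(snps["private"].sum()),
                "private_indels": int(indels["private"].sum()),
            }
        )
    truth.candidate_reports = pd.DataFrame(report_rows)
    truth.trait_gene_sets = trait_mouse_sets
    return catalog_path, ortholog_path, mendelian_path, truth
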