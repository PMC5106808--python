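"""SIFT/PROVEAN deleteriousness consensus, codon translation, and QTL summaries.

Missense substitutions are scored upstream by two predictors: SIFT (a score
in [0, 1]; low means the substitution is predicted to damage protein
function) and PROVEAN (an alignment-based delta score; strongly negative
means damaging).  This module applies the conventional cutoffs — deleterious
iff SIFT < 0.05 or PROVEAN < -2.5, both strict — and combines them into an
either/both consensus.  A missing score is a *no call*: the predictor simply
does not vote, and the variant can never reach "both" without two present
scores.

The module also verifies codon-change annotations by translating the
ref/alt codon pair with the standard genetic code, and aggregates variant
counts per gene and per QTL interval for candidate-gene triage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .so_terms import SOPriority, DEFAULT_PRIORITY, is_potentially_pathogenic
from .variants import GenomicInterval, VariantClass, VariantRecord

SIFT_DELETERIOUS_MAX = 0.05  # deleterious iff score strictly below
PROVEAN_DELETERIOUS_MAX = -2.5

_MISSENSE = "missense_variant"


def sift_call(score: float | None, threshold: float = SIFT_DELETERIOUS_MAX) -> bool | None:
    """Deleterious iff ``score < threshold`` (strict); ``None`` score -> no call."""
    if score is None:
        return None
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"SIFT score must be in [0, 1], got {score}")
    return score < threshold


def provean_call(score: float | None, threshold: float = PROVEAN_DELETERIOUS_MAX) -> bool | None:
    """Deleterious iff ``score < threshold`` (strict); ``None`` score -> no call."""
    if score is None:
        return None
    return score < threshold


@dataclass(frozen=True)
class DeleteriousnessCall:
    sift_deleterious: bool | None
    provean_deleterious: bool | None

    @property
    def either(self) -> bool:
        return bool(self.sift_deleterious) or bool(self.provean_deleterious)

    @property
    def both(self) -> bool:
        return bool(self.sift_deleterious) and bool(self.provean_deleterious)


def consensus(
    variant: VariantRecord,
    sift_threshold: float = SIFT_DELETERIOUS_MAX,
    provean_threshold: float = PROVEAN_DELETERIOUS_MAX,
) -> DeleteriousnessCall:
    """Either/both consensus over a missense variant's transcript scores.

    When a variant is missense in several transcripts, the minimum SIFT and
    minimum PROVEAN across transcripts are used (the most deleterious
    transcript wins).
    """
    missense = [a for a in variant.annotations if _MISSENSE in a.so_terms]
    if not missense:
        raise ValueError("consensus requires a variant with a missense annotation")
    sifts = [a.sift_score for a in missense if a.sift_score is not None]
    proveans = [a.provean_score for a in missense if a.provean_score is not None]
    return DeleteriousnessCall(
        sift_deleterious=sift_call(min(sifts), sift_threshold) if sifts else None,
        provean_deleterious=provean_call(min(proveans), provean_threshold) if proveans else None,
    )


def scores_call(
    sift: float | None,
    provean: float | None,
    sift_threshold: float = SIFT_DELETERIOUS_MAX,
    provean_threshold: float = PROVEAN_DELETERIOUS_MAX,
) -> DeleteriousnessCall:
    """Consensus directly from a (SIFT, PROVEAN) score pair."""
    return DeleteriousnessCall(
        sift_deleterious=sift_call(sift, sift_threshold),
        provean_deleterious=provean_call(provean, provean_threshold),
    )


# ---------------------------------------------------------------------------
# Codon-change translation


@dataclass(frozen=True)
class CodonChange:
    """A single-codon change at a 1-based CDS nucleotide position."""

    cds_position: int
    ref_codon: str
    alt_codon: str

    def __post_init__(self) -> None:
        for codon in (self.ref_codon, self.alt_codon):
            if len(codon) != 3 or any(b not in "ACGTacgt" for b in codon):
                raise ValueError(f"invalid codon {codon!r}")
        if self.cds_position < 1:
            raise ValueError("cds_position must be >= 1")
        if self.ref_codon.upper() == self.alt_codon.upper():
            raise ValueError("ref and alt codons are identical")


@dataclass(frozen=True)
class AminoAcidChange:
    ref_aa: str
    residue_index: int
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.residue_index}{self.alt_aa}"


def translate_codon_change(change: CodonChange) -> AminoAcidChange:
    """Translate a codon change into an amino-acid substitution.

    The affected residue is ``ceil(cds_position / 3)``; e.g. CDS position 136
    with CGT -> AGT yields R46S.
    """
    residue = math.ceil(change.cds_position / 3)
    ref_aa = str(Seq(change.ref_codon.upper()).translate())
    alt_aa = str(Seq(change.alt_codon.upper()).translate())
    return AminoAcidChange(ref_aa=ref_aa, residue_index=residue, alt_aa=alt_aa)


# ---------------------------------------------------------------------------
# Per-gene and per-interval aggregation

FilterSpec = Callable[[VariantRecord], bool]


def pathogenic_filter(priority: SOPriority = DEFAULT_PRIORITY) -> FilterSpec:
    return lambda v: is_potentially_pathogenic(v.annotations, priority)


def private_filter(private_flags: Mapping[tuple, bool]) -> FilterSpec:
    return lambda v: bool(private_flags.get(v.key, False))


def deleterious_filter(mode: str = "both") -> FilterSpec:
    """Filter missense variants by consensus; mode in {"sift", "provean", "either", "both"}."""

    def check(v: VariantRecord) -> bool:
        if not any(_MISSENSE in a.so_terms for a in v.annotations):
            return False
        call = consensus(v)
        return {
            "sift": bool(call.sift_deleterious),
            "provean": bool(call.provean_deleterious),
            "either": call.either,
            "both": call.both,
        }[mode]

    return check


def per_gene_counts(
    variants: Iterable[VariantRecord], filter_spec: FilterSpec
) -> dict[str, int]:
    """Count qualifying variants per annotated gene.

    A variant hitting several (overlapping) genes counts once in each; genes
    with no qualifying variant are omitted.
    """
    counts: dict[str, int] = {}
    for v in variants:
        if not filter_spec(v):
            continue
        for gene in sorted(v.gene_ids):
            counts[gene] = counts.get(gene, 0) + 1
    return counts


def interval_summary(
    variants: Sequence[VariantRecord],
    intervals: Sequence[GenomicInterval],
    priority: SOPriority = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Per-interval variant tallies (QTL triage table).

    For each interval: total SNPs and indels, counts inside annotated
    protein-coding genes, potentially pathogenic counts, and SIFT- /
    PROVEAN- / both-deleterious missense SNP counts.
    """
    rows = []
    for iv in intervals:
        inside = [v for v in variants if iv.contains(v.chrom, v.pos)]
        snps = [v for v in inside if v.variant_class is VariantClass.SNP]
        indels = [v for v in inside if v.variant_class is VariantClass.INDEL]
        rows.append(
            {
                "interval": iv.name,
                "total_snps": len(snps),
                "snps_in_genes": sum(1 for v in snps if v.gene_ids),
                "pathogenic_snps": sum(
                    1 for v in snps if is_potentially_pathogenic(v.annotations, priority)
                ),
                "sift_deleterious_snps": sum(1 for v in snps if deleterious_filter("sift")(v)),
                "provean_deleterious_snps": sum(
                    1 for v in snps if deleterious_filter("provean")(v)
                ),
                "both_deleterious_snps": sum(1 for v in snps if deleterious_filter("both")(v)),
                "total_indels": len(indels),
                "indels_in_genes": sum(1 for v in indels if v.gene_ids),
                "pathogenic_indels": sum(
                    1 for v in indels if is_potentially_pathogenic(v.annotations, priority)
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Curated tabw2 missense table


def tabw2_missense_table() -> pd.DataFrame:
    """Missense SNPs in the tabw2 obesity QTL with SIFT/PROVEAN scores.

    Curated table of the chromosome-6 missense substitutions in the tabw2
    candidate region of the TALLYHO/Jng genome (gene, position, ref/alt
    codon and amino acid, exon, predictor scores); missing scores are NaN.
    """
    path = resources.files("strainvar.data") / "tabw2_missense_snps.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    return df


def count_both_deleterious_in_interval(
    table: pd.DataFrame,
    interval: GenomicInterval,
    sift_threshold: float = SIFT_DELETERIOUS_MAX,
    provean_threshold: float = PROVEAN_DELETERIOUS_MAX,
) -> tuple[int, set[str]]:
    """Count table rows inside an interval deleterious by both predictors.

    Returns the qualifying SNP count and the set of genes they occur in.
    """
    n = 0
    genes: set[str] = set()
    for row in table.itertuples(index=False):
        if not interval.contains(str(row.chrom), int(row.pos)):
            continue
        sift = None if pd.isna(row.sift) else float(row.sift)
        provean = None if pd.isna(row.provean) else float(row.provean)
        call = scores_call(sift, provean, sift_threshold, provean_threshold)
        if call.both:
            n += 1
            genes.add(row.gene)
    return n, genes
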