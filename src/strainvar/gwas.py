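"""Trait gene sets from a GWAS catalog, ortholog projection, candidate reports.

Human genes associated with a trait are harvested from a GWAS-catalog-format
TSV by case-insensitive substring match on the DISEASE/TRAIT column, pooling
the mapped, upstream, and downstream gene ID columns.  Human IDs are then
projected onto mouse through a many-to-many ortholog mapping, and the
resulting mouse gene sets are intersected with the potentially pathogenic
variant catalog to produce per-trait candidate reports (gene, SNP, indel,
and private-variant counts).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .so_terms import SOPriority, DEFAULT_PRIORITY, is_potentially_pathogenic
from .variants import VariantClass, VariantRecord

logger = logging.getLogger(__name__)

# EBI GWAS catalog column headers, verbatim.
TRAIT_COLUMN = "DISEASE/TRAIT"
GENE_COLUMNS = ("MAPPED GENE(S)", "UPSTREAM_GENE_ID", "DOWNSTREAM_GENE_ID")

MENDELIAN_CATEGORIES = (
    "syndromic obesity",
    "non-syndromic obesity",
    "non-syndromic lipodystrophy",
)


def read_gwas_catalog(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if TRAIT_COLUMN not in df.columns:
        raise ValueError(f"catalog missing column {TRAIT_COLUMN!r}")
    return df


def _split_ids(cell: str) -> set[str]:
    return {tok for tok in re.split(r"[,;\s]+", cell.strip()) if tok and tok != "-"}


def trait_gene_ids(catalog: pd.DataFrame, keyword: str, regex: bool = False) -> set[str]:
    """Human gene IDs from catalog rows whose trait matches ``keyword``.

    Matching is a case-insensitive substring test (or regex search with
    ``regex=True``); the three gene-ID columns are pooled as a set union.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    traits = catalog[TRAIT_COLUMN].astype(str)
    if regex:
        mask = traits.str.contains(keyword, case=False, regex=True)
    else:
        mask = traits.str.contains(re.escape(keyword), case=False, regex=True)
    genes: set[str] = set()
    for col in GENE_COLUMNS:
        if col not in catalog.columns:
            continue
        for cell in catalog.loc[mask, col]:
            genes |= _split_ids(cell)
    return genes


def read_ortholog_map(path: str) -> set[tuple[str, str]]:
    """Two-column TSV (human gene ID, mouse gene ID); many-to-many allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns (human, mouse)")
    human, mouse = df.columns[0], df.columns[1]
    return {
        (h, m)
        for h, m in zip(df[human], df[mouse])
        if isinstance(h, str) and isinstance(m, str)
    }


def to_mouse_genes(
    human_ids: Iterable[str], ortholog_map: set[tuple[str, str]]
) -> set[str]:
    """Project human gene IDs to mouse orthologs (union over all pairs).

    Human IDs with no ortholog are dropped; the drop count is logged.
    """
    human_ids = set(human_ids)
    by_human: dict[str, set[str]] = {}
    for h, m in ortholog_map:
        by_human.setdefault(h, set()).add(m)
    mouse: set[str] = set()
    unmapped = 0
    for h in human_ids:
        if h in by_human:
            mouse |= by_human[h]
        else:
            unmapped += 1
    if unmapped:
        logger.info("%d of %d human gene IDs had no mouse ortholog", unmapped, len(human_ids))
    return mouse


def read_mendelian_list(path: str) -> dict[str, set[str]]:
    """Monogenic obesity gene list: TSV with columns (gene, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "category"} <= set(df.columns):
        raise ValueError("Mendelian list needs columns 'gene' and 'category'")
    sets: dict[str, set[str]] = {c: set() for c in MENDELIAN_CATEGORIES}
    for row in df.itertuples(index=False):
        if row.category not in sets:
            raise ValueError(f"unknown Mendelian category {row.category!r}")
        sets[row.category].add(row.gene)
    return sets


def mendelian_gene_sets(
    path: str, ortholog_map: set[tuple[str, str]]
) -> dict[str, set[str]]:
    """Per-category mouse gene sets for the monogenic obesity list."""
    return {
        category: to_mouse_genes(genes, ortholog_map)
        for category, genes in read_mendelian_list(path).items()
    }


@dataclass(frozen=True)
class CandidateReport:
    """One row of the trait-intersection report."""

    source: str
    n_genes: int
    n_snps: int
    n_indels: int
    n_private_snps: int
    n_private_indels: int


def candidate_report(
    variants: Sequence[VariantRecord],
    gene_set: set[str],
    private_flags: Mapping[tuple, bool] | None = None,
    priority: SOPriority = DEFAULT_PRIORITY,
    source_label: str = "",
) -> CandidateReport:
    """Intersect potentially pathogenic variants with a mouse gene set.

    A variant qualifies if any transcript's SO terms hit the pathogenic set
    and at least one annotated gene is in ``gene_set``.  A variant counts
    once in the SNP/indel tallies however many candidate genes it hits;
    ``n_genes`` is the number of distinct genes in the set with at least one
    qualifying variant.
    """
    private_flags = private_flags or {}
    hit_genes: set[str] = set()
    n = {VariantClass.SNP: 0, VariantClass.INDEL: 0}
    n_priv = {VariantClass.SNP: 0, VariantClass.INDEL: 0}
    for v in variants:
        if not is_potentially_pathogenic(v.annotations, priority):
            continue
        in_set = v.gene_ids & gene_set
        if not in_set:
            continue
        hit_genes |= in_set
        n[v.variant_class] += 1
        if private_flags.get(v.key, False):
            n_priv[v.variant_class] += 1
    return CandidateReport(
        source=source_label,
        n_genes=len(hit_genes),
        n_snps=n[VariantClass.SNP],
        n_indels=n[VariantClass.INDEL],
        n_private_snps=n_priv[VariantClass.SNP],
        n_private_indels=n_priv[VariantClass.INDEL],
    )


def reports_to_frame(reports: Iterable[CandidateReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source": r.source,
                "total_genes": r.n_genes,
                "snps": r.n_snps,
                "indels": r.n_indels,
                "private_snps": r.n_private_snps,
                "private_indels": r.n_private_indels,
            }
            for r in reports
        ]
    )
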