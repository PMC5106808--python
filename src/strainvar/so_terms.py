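"""Sequence Ontology consequence classification and prioritization.

A consequence annotator (e.g. VEP) assigns each variant, per transcript, a
*set* of SO terms.  This module reduces those sets to a single term per
variant in two steps:

1. each distinct term set is summarized by a *representative term* — the
   highest-priority member of the set under a fixed ordering;
2. a variant whose transcripts carry several distinct term sets (a
   "multiple classification sets" variant) takes the *most pathogenic* of
   its representative terms, again under the same ordering.

Independently, a variant is flagged *potentially pathogenic* if the SO terms
of any one of its transcripts intersect a fixed ten-term set of
protein-affecting consequences.  Note the any-transcript semantics: a variant
whose representative term is intronic can still be potentially pathogenic
through another transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .variants import ConsequenceAnnotation, VariantRecord

#: Priority ordering, most pathogenic first.  Terms not in this list rank
#: after every listed term (ties broken lexicographically).
DEFAULT_PRIORITY_ORDER: tuple[str, ...] = (
    "stop_gained",
    "stop_lost",
    "frameshift_variant",
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_region_variant",
    "initiator_codon_variant",
    "synonymous_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "mature_miRNA_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intron_variant",
    "non_coding_transcript_variant",
    "intergenic_variant",
)

#: The ten "potentially pathogenic" consequence terms.
DEFAULT_PATHOGENIC_TERMS: frozenset[str] = frozenset(
    {
        "frameshift_variant",
        "inframe_deletion",
        "inframe_insertion",
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "initiator_codon_variant",
        "splice_region_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

INTERGENIC = "intergenic_variant"
MULTI_SET_LABEL = "multiple classification sets"


@dataclass(frozen=True)
class SOPriority:
    """Priority ordering over SO terms plus the potentially-pathogenic set."""

    ordered_terms: tuple[str, ...] = DEFAULT_PRIORITY_ORDER
    pathogenic_terms: frozenset[str] = DEFAULT_PATHOGENIC_TERMS

    def __post_init__(self) -> None:
        if len(set(self.ordered_terms)) != len(self.ordered_terms):
            raise ValueError("ordered_terms contains duplicates")
        if not self.pathogenic_terms <= set(self.ordered_terms):
            raise ValueError("pathogenic_terms must be a subset of ordered_terms")

    def rank_key(self, term: str) -> tuple[int, str]:
        try:
            return (self.ordered_terms.index(term), "")
        except ValueError:
            return (len(self.ordered_terms), term)

    @classmethod
    def from_config(cls, ordered: Sequence[str], pathogenic: Iterable[str]) -> "SOPriority":
        return cls(tuple(ordered), frozenset(pathogenic))


DEFAULT_PRIORITY = SOPriority()


def representative_term(so_term_set: Iterable[str], priority: SOPriority = DEFAULT_PRIORITY) -> str:
    """The highest-priority member of one SO term set."""
    terms = set(so_term_set)
    if not terms:
        raise ValueError("so_term_set must be non-empty")
    return min(terms, key=priority.rank_key)


@dataclass
class ClassificationResult:
    per_transcript_reps: list[tuple[str, str]]  # (transcript_id, representative)
    final_term: str
    multi_set: bool
    pathogenic: bool


def _distinct_sets(annotations: Iterable[ConsequenceAnnotation]) -> set[frozenset[str]]:
    return {a.so_terms for a in annotations}


def final_classification(
    annotations: Sequence[ConsequenceAnnotation],
    priority: SOPriority = DEFAULT_PRIORITY,
) -> ClassificationResult:
    """Resolve a variant's transcript annotations to one final SO term.

    Annotation-free variants (no overlapping transcript) classify as
    intergenic.
    """
    if not annotations:
        return ClassificationResult([], INTERGENIC, False, False)
    reps = [
        (a.transcript_id, representative_term(a.so_terms, priority)) for a in annotations
    ]
    distinct = _distinct_sets(annotations)
    final = min((rep for _, rep in reps), key=priority.rank_key)
    return ClassificationResult(
        per_transcript_reps=reps,
        final_term=final,
        multi_set=len(distinct) >= 2,
        pathogenic=is_potentially_pathogenic(annotations, priority),
    )


def is_potentially_pathogenic(
    annotations: Iterable[ConsequenceAnnotation],
    priority: SOPriority = DEFAULT_PRIORITY,
) -> bool:
    """True iff any transcript's term set intersects the pathogenic set."""
    return any(a.so_terms & priority.pathogenic_terms for a in annotations)


def _set_label(terms: frozenset[str], priority: SOPriority) -> str:
    return "&".join(sorted(terms, key=priority.rank_key))


def tabulate_sets(
    variants: Sequence[VariantRecord],
    priority: SOPriority = DEFAULT_PRIORITY,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tabulate a cohort's classification sets.

    Returns three tables:

    * **set table** — one row per distinct SO term set observed on
      single-set variants, plus one pooled "multiple classification sets"
      row; each variant counted exactly once.
    * **final-term table** — counts of the final (most pathogenic
      representative) term over all variants; a partition of the cohort.
    * **multi-set pathogenic table** — for pooled multi-set variants only,
      how many carry each of the ten pathogenic terms in at least one
      transcript (a variant may count under several terms).
    """
    set_counts: dict[str, int] = {}
    final_counts: dict[str, int] = {}
    multi_pathogenic = {t: 0 for t in sorted(priority.pathogenic_terms, key=priority.rank_key)}

    for v in variants:
        result = final_classification(v.annotations, priority)
        final_counts[result.final_term] = final_counts.get(result.final_term, 0) + 1
        if result.multi_set:
            set_counts[MULTI_SET_LABEL] = set_counts.get(MULTI_SET_LABEL, 0) + 1
            all_terms = set().union(*(a.so_terms for a in v.annotations))
            for term in all_terms & priority.pathogenic_terms:
                multi_pathogenic[term] += 1
        else:
            terms = v.annotations[0].so_terms if v.annotations else frozenset({INTERGENIC})
            label = _set_label(terms, priority)
            set_counts[label] = set_counts.get(label, 0) + 1

    def _frame(counts: dict[str, int], key_col: str) -> pd.DataFrame:
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=[key_col, "count"])

    set_table = _frame(set_counts, "so_term_set")
    # attach the representative term for each single-set row
    reps = []
    for label in set_table["so_term_set"]:
        if label == MULTI_SET_LABEL:
            reps.append("")
        else:
            reps.append(representative_term(label.split("&"), priority))
    set_table["representative_term"] = reps
    final_table = _frame(final_counts, "final_term")
    multi_table = pd.DataFrame(
        sorted(multi_pathogenic.items(), key=lambda kv: priority.rank_key(kv[0])),
        columns=["pathogenic_term", "count"],
    )
    return set_table, final_table, multi_table
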