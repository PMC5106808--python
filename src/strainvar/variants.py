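"""Core variant domain model: VCF ingestion, zygosity filtering, intervals, density.

The unit of analysis throughout the package is a biallelic, decomposed
:class:`VariantRecord`.  Multiallelic VCF sites are split into one record per
alternate allele at parse time, and indel alleles are trimmed to a canonical
minimal representation so that position comparisons (interval membership,
strain-panel lookups) are well defined.

Coordinates are 1-based (VCF convention); named intervals are 1-based and
inclusive at both ends; sliding windows are half-open ``[start, start + size)``.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class VariantClass(enum.Enum):
    SNP = "SNP"
    INDEL = "INDEL"


class Zygosity(enum.Enum):
    HOM_ALT = "HOM_ALT"
    HET = "HET"


class VcfParseError(ValueError):
    """Raised when a VCF source cannot be parsed into variant records."""


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """One transcript-level consequence annotation for a variant.

    ``so_terms`` is the set of Sequence Ontology terms assigned to the variant
    in the context of a single transcript.  ``sift_score`` / ``provean_score``
    are only meaningful for missense annotations and are ``None`` otherwise.
    """

    transcript_id: str
    gene_id: str | None
    so_terms: frozenset[str]
    codon_change: tuple[str, str] | None = None  # (ref codon, alt codon)
    cds_position: int | None = None  # 1-based position in the CDS
    aa_change: tuple[str, str] | None = None  # (ref AA, alt AA)
    residue_index: int | None = None  # 1-based protein residue
    sift_score: float | None = None
    provean_score: float | None = None

    def __post_init__(self) -> None:
        if not self.so_terms:
            raise ValueError("so_terms must be non-empty")


@dataclass
class VariantRecord:
    """One biallelic variant (site already decomposed to a single ALT)."""

    chrom: str
    pos: int  # 1-based, first reference base of the event
    ref_allele: str
    alt_allele: str
    zygosity: Zygosity
    qual: float | None = None
    depth: int | None = None
    annotations: list[ConsequenceAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def variant_class(self) -> VariantClass:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return VariantClass.SNP
        return VariantClass.INDEL

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for allele matching against other call sets."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def gene_ids(self) -> set[str]:
        return {a.gene_id for a in self.annotations if a.gene_id}


@dataclass(frozen=True)
class GenomicInterval:
    """Named 1-based interval, inclusive at both endpoints."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.name}: start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# Obesity QTL sub-intervals on mouse chromosome 6 (GRCm38 coordinates),
# shipped as defaults for the tabw2 candidate-gene triage.
TABW2A = GenomicInterval("tabw2a", "6", 80_217_217, 125_356_646)
TABW2B = GenomicInterval("tabw2b", "6", 133_853_029, 144_639_629)
DEFAULT_INTERVALS = (TABW2A, TABW2B)


def in_interval(variant: VariantRecord, interval: GenomicInterval) -> bool:
    """True iff the variant's position lies inside the interval (inclusive)."""
    return interval.contains(variant.chrom, variant.pos)


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping at least one base each.

    This produces the canonical minimal representation used for position
    comparisons; callers that have reference sequence available may
    additionally left-shift with :func:`left_align`.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def left_align(pos: int, ref: str, alt: str, chrom_seq: str) -> tuple[int, str, str]:
    """Left-shift a trimmed indel against a reference sequence string.

    ``chrom_seq`` is the full chromosome sequence (1-based positions map to
    index ``pos - 1``).  SNPs are returned unchanged.
    """
    pos, ref, alt = trim_alleles(pos, ref, alt)
    if len(ref) == 1 and len(alt) == 1:
        return pos, ref, alt
    while pos > 1:
        if ref[-1] != alt[-1]:
            break
        prev = chrom_seq[pos - 2].upper()
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return trim_alleles(pos, ref, alt)


# ---------------------------------------------------------------------------
# VCF ingestion


#: Default layout of the pipe-delimited consequence (CSQ-style) INFO entries.
#: Overridable; when the VCF header's CSQ description carries a
#: ``Format: a|b|c`` clause, that declaration wins.
DEFAULT_CSQ_FIELDS = (
    "Allele",
    "Consequence",
    "Gene",
    "Feature",
    "CDS_position",
    "Protein_position",
    "Codons",
    "Amino_acids",
    "SIFT",
    "PROVEAN",
)

_MISSENSE_TERM = "missense_variant"


def _parse_optional_float(text: str) -> float | None:
    text = text.strip()
    if not text or text.upper() in {"N/A", "NA", "-", "."}:
        return None
    # VEP prints e.g. "deleterious(0.03)"; accept both bare and wrapped forms
    if "(" in text and text.endswith(")"):
        text = text[text.index("(") + 1 : -1]
    return float(text)


def _parse_pair(text: str) -> tuple[str, str] | None:
    if "/" not in text:
        return None
    a, b = text.split("/", 1)
    if not a or not b:
        return None
    return a, b


def parse_csq_entry(entry: str, fields: Sequence[str]) -> ConsequenceAnnotation | None:
    """Parse one pipe-delimited consequence entry into an annotation.

    Returns ``None`` for entries with an empty Consequence field.
    """
    values = entry.split("|")
    record = dict(zip(fields, values))
    terms = frozenset(t for t in record.get("Consequence", "").split("&") if t)
    if not terms:
        return None
    codons = _parse_pair(record.get("Codons", ""))
    aa = _parse_pair(record.get("Amino_acids", ""))
    cds_pos = record.get("CDS_position", "").strip()
    prot_pos = record.get("Protein_position", "").strip()
    sift = provean = None
    if _MISSENSE_TERM in terms:
        sift = _parse_optional_float(record.get("SIFT", ""))
        provean = _parse_optional_float(record.get("PROVEAN", ""))
    return ConsequenceAnnotation(
        transcript_id=record.get("Feature", ""),
        gene_id=record.get("Gene") or None,
        so_terms=terms,
        codon_change=(codons[0].upper(), codons[1].upper()) if codons else None,
        cds_position=int(cds_pos) if cds_pos.isdigit() else None,
        aa_change=aa,
        residue_index=int(prot_pos) if prot_pos.isdigit() else None,
        sift_score=sift,
        provean_score=provean,
    )


def _csq_fields_from_header(vcf) -> tuple[str, ...] | None:
    try:
        info = vcf.get_header_type("CSQ")
    except KeyError:
        return None
    desc = info.get("Description", "").strip('"')
    if "Format:" in desc:
        layout = desc.split("Format:", 1)[1].strip().strip('"')
        return tuple(f.strip() for f in layout.split("|"))
    return None


def _alt_zygosity(gt_indices: Sequence[int], alt_index: int) -> Zygosity | None:
    called = [g for g in gt_indices if g >= 0]
    if not called or alt_index not in called:
        return None
    if all(g == alt_index for g in called):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def parse_variants(
    vcf_source: str,
    csq_fields: Sequence[str] | None = None,
    normalize_indels: bool = True,
) -> list[VariantRecord]:
    """Read a single-sample annotated VCF into decomposed variant records.

    One record is emitted per (site, alternate allele) for every alternate
    allele present in the sample genotype; zygosity is derived from GT
    (``1/1`` homozygous-alt, anything mixed heterozygous).  Records lacking a
    usable genotype are skipped with a warning.  Consequence annotations are
    read from the CSQ INFO field when present; the sub-field layout is taken
    from the header's ``Format:`` clause, falling back to ``csq_fields`` or
    the package default.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(vcf_source)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad input
        raise VcfParseError(f"cannot open VCF {vcf_source!r}: {exc}") from exc

    fields = _csq_fields_from_header(vcf) or tuple(csq_fields or DEFAULT_CSQ_FIELDS)
    if len(vcf.samples) != 1:
        raise VcfParseError(
            f"expected a single-sample VCF, found {len(vcf.samples)} samples"
        )

    records: list[VariantRecord] = []
    for i, site in enumerate(vcf, start=1):
        try:
            gt = site.genotypes[0][:-1]  # last element is the phasing flag
        except (IndexError, TypeError):
            logger.warning("record %d (%s:%s): missing GT, skipped", i, site.CHROM, site.POS)
            continue
        if all(g < 0 for g in gt):
            logger.warning("record %d (%s:%s): uncalled GT, skipped", i, site.CHROM, site.POS)
            continue
        csq = site.INFO.get("CSQ")
        entries = csq.split(",") if csq else []
        depth = site.INFO.get("DP")
        if depth is None:
            try:
                depth = int(site.format("DP")[0][0])
            except (TypeError, ValueError):
                depth = None
        for alt_index, alt in enumerate(site.ALT, start=1):
            zyg = _alt_zygosity(gt, alt_index)
            if zyg is None:
                continue
            pos, ref, alt_a = site.POS, site.REF, alt
            if normalize_indels and (len(ref) > 1 or len(alt_a) > 1):
                pos, ref, alt_a = trim_alleles(pos, ref, alt_a)
            annotations = []
            for entry in entries:
                ann = parse_csq_entry(entry, fields)
                if ann is None:
                    continue
                allele = entry.split("|", 1)[0]
                # Annotation entries are allele-tagged; keep entries matching
                # this ALT, or untagged entries at biallelic sites.
                if allele and len(site.ALT) > 1 and allele != alt:
                    continue
                annotations.append(ann)
            records.append(
                VariantRecord(
                    chrom=site.CHROM,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt_a,
                    zygosity=zyg,
                    qual=site.QUAL,
                    depth=int(depth) if depth is not None else None,
                    annotations=annotations,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Homozygosity filter


def filter_homozygous(
    variants: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], dict[VariantClass, float | None]]:
    """Keep homozygous-alt records; report the heterozygous percentage per class.

    Heterozygous calls in an inbred genome reflect calling error, residual
    heterozygosity, or unfixed recent mutation, and are excluded from every
    downstream stage.  The returned fraction is a percentage per variant
    class, or ``None`` for a class with no records.
    """
    variants = list(variants)
    hom = [v for v in variants if v.zygosity is Zygosity.HOM_ALT]
    het_fraction: dict[VariantClass, float | None] = {}
    for vclass in VariantClass:
        in_class = [v for v in variants if v.variant_class is vclass]
        if not in_class:
            het_fraction[vclass] = None
        else:
            n_het = sum(1 for v in in_class if v.zygosity is Zygosity.HET)
            het_fraction[vclass] = 100.0 * n_het / len(in_class)
    return hom, het_fraction


# ---------------------------------------------------------------------------
# Sliding-window density


@dataclass
class DensityTrack:
    """Per-window variant counts along one chromosome.

    Windows are half-open ``[s, s + window_size)`` with starts
    ``1, 1 + step, ...`` up to and including ``chrom_length``; terminal
    windows extending past the chromosome end are emitted (partial windows
    are counted, noted in the output metadata).
    """

    chrom: str
    window_size: int
    step: int
    starts: np.ndarray
    counts: dict[str, np.ndarray]  # keys: "all", "SNP", "INDEL"

    def to_tsv(self, path: str) -> None:
        frames = [
            pd.DataFrame(
                {"window_start": self.starts, "class": label, "count": counts}
            )
            for label, counts in self.counts.items()
        ]
        out = pd.concat(frames, ignore_index=True)
        with open(path, "w") as fh:
            fh.write(
                f"# chrom={self.chrom} window_size={self.window_size} "
                f"step={self.step} terminal_windows=partial-counted\n"
            )
            out.to_csv(fh, sep="\t", index=False)


def window_density(
    variants: Iterable[VariantRecord],
    chrom: str,
    chrom_length: int,
    window_size: int = 1_000_000,
    step: int = 1_000,
) -> DensityTrack:
    """Count variants in a sliding window along a chromosome.

    A window starting at ``s`` counts variants with ``s <= pos < s + size``.
    """
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    starts = np.arange(1, chrom_length + 1, step, dtype=np.int64)
    on_chrom = [v for v in variants if v.chrom == chrom]
    counts: dict[str, np.ndarray] = {}
    groups = {
        "all": on_chrom,
        "SNP": [v for v in on_chrom if v.variant_class is VariantClass.SNP],
        "INDEL": [v for v in on_chrom if v.variant_class is VariantClass.INDEL],
    }
    for label, group in groups.items():
        pos = np.sort(np.asarray([v.pos for v in group], dtype=np.int64))
        # count pos in [s, s + window_size)
        hi = np.searchsorted(pos, starts + window_size, side="left")
        lo = np.searchsorted(pos, starts, side="left")
        counts[label] = (hi - lo).astype(np.int64)
    return DensityTrack(chrom, window_size, step, starts, counts)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed_intervals(path: str) -> list[GenomicInterval]:
    """Read BED (0-based half-open) intervals into 1-based inclusive form."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{i}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"interval_{i}"
            intervals.append(GenomicInterval(name, chrom, start + 1, end))
    return intervals


def write_bed_intervals(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}\n")


def write_positions_bed(variants: Iterable[VariantRecord], path: str) -> None:
    """Export target-variant positions as BED, for re-genotyping a panel."""
    with open(path, "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos - 1}\t{v.pos - 1 + len(v.ref_allele)}\n")
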