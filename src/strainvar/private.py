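"""Strain-private variant detection against a multi-strain reference panel.

A target-strain variant is *private* when it is absent from every strain of
a reference panel (here modelled on the 28 Mouse Genomes Project strains),
subject to a genotyping-confidence quorum: at least ``quorum`` of the panel
strains must have a call quality >= ``min_qual`` and read depth >=
``min_depth`` at the site before privacy may be declared.

The rule differs by variant class:

* a **SNP** is disqualified only by a panel strain carrying the *same*
  allele at the same position; a different variant at the position does not
  disqualify it;
* an **indel** is disqualified by *any* panel variant at the same
  (normalized) position — a stricter rule, because equivalent indels often
  have distinct allele representations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import VariantClass, VariantRecord


class CallStatus(enum.Enum):
    SAME_ALLELE = "SAME_ALLELE"
    OTHER_VARIANT = "OTHER_VARIANT"
    NO_VARIANT = "NO_VARIANT"


@dataclass(frozen=True)
class StrainSiteCall:
    """One panel strain's call at a target-variant site."""

    strain: str
    status: CallStatus
    qual: float
    depth: int

    def __post_init__(self) -> None:
        if self.qual < 0 or self.depth < 0:
            raise ValueError("qual and depth must be non-negative")


@dataclass(frozen=True)
class PanelConfig:
    """Panel size, informativeness thresholds, and quorum.

    ``strict_disqualifiers`` controls whether a disqualifying panel call must
    itself pass the quality/depth thresholds: by default it does not (the
    quorum applies to the site, any allele match disqualifies regardless of
    its own confidence).
    """

    n_strains: int = 28
    quorum: int = 21
    min_qual: float = 20.0
    min_depth: int = 5
    strict_disqualifiers: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.quorum <= self.n_strains):
            raise ValueError("require 0 < quorum <= n_strains")


DEFAULT_PANEL_CONFIG = PanelConfig()

#: Panel input type: one list of per-strain calls per target variant key.
PanelCalls = Mapping[tuple[str, int, str, str], Sequence[StrainSiteCall]]


def strain_informative(call: StrainSiteCall, config: PanelConfig = DEFAULT_PANEL_CONFIG) -> bool:
    """True iff the strain is confidently genotyped at the site (inclusive thresholds)."""
    return call.qual >= config.min_qual and call.depth >= config.min_depth


def _check_panel(calls: Sequence[StrainSiteCall], config: PanelConfig) -> None:
    if len(calls) != config.n_strains:
        raise ValueError(
            f"panel has {len(calls)} strain calls, expected {config.n_strains}"
        )


def _quorum_met(calls: Sequence[StrainSiteCall], config: PanelConfig) -> bool:
    return sum(strain_informative(c, config) for c in calls) >= config.quorum


def _disqualifies(call: StrainSiteCall, statuses: frozenset[CallStatus], config: PanelConfig) -> bool:
    if call.status not in statuses:
        return False
    if config.strict_disqualifiers and not strain_informative(call, config):
        return False
    return True


_SNP_DISQUALIFIERS = frozenset({CallStatus.SAME_ALLELE})
_INDEL_DISQUALIFIERS = frozenset({CallStatus.SAME_ALLELE, CallStatus.OTHER_VARIANT})


def is_private_snp(
    target_snp: VariantRecord,
    panel_calls: Sequence[StrainSiteCall],
    config: PanelConfig = DEFAULT_PANEL_CONFIG,
) -> bool:
    """Private iff no panel strain carries the same allele and quorum holds."""
    if target_snp.variant_class is not VariantClass.SNP:
        raise ValueError("is_private_snp requires a SNP record")
    _check_panel(panel_calls, config)
    if any(_disqualifies(c, _SNP_DISQUALIFIERS, config) for c in panel_calls):
        return False
    return _quorum_met(panel_calls, config)


def is_private_indel(
    target_indel: VariantRecord,
    panel_calls: Sequence[StrainSiteCall],
    config: PanelConfig = DEFAULT_PANEL_CONFIG,
) -> bool:
    """Private iff no panel strain has any variant at the location and quorum holds."""
    if target_indel.variant_class is not VariantClass.INDEL:
        raise ValueError("is_private_indel requires an indel record")
    _check_panel(panel_calls, config)
    if any(_disqualifies(c, _INDEL_DISQUALIFIERS, config) for c in panel_calls):
        return False
    return _quorum_met(panel_calls, config)


@dataclass
class PrivateSummary:
    n_private_snps: int
    n_private_indels: int
    n_snps: int
    n_indels: int

    @property
    def snp_fraction(self) -> float | None:
        return None if self.n_snps == 0 else self.n_private_snps / self.n_snps

    @property
    def indel_fraction(self) -> float | None:
        return None if self.n_indels == 0 else self.n_private_indels / self.n_indels


def call_private_set(
    target_variants: Sequence[VariantRecord],
    panel: PanelCalls,
    config: PanelConfig = DEFAULT_PANEL_CONFIG,
) -> tuple[dict[tuple[str, int, str, str], bool], PrivateSummary]:
    """Apply the private-variant rule across a cohort.

    ``panel`` maps each variant key ``(chrom, pos, ref, alt)`` to its panel
    strain calls; every target variant must have an entry.
    """
    flags: dict[tuple[str, int, str, str], bool] = {}
    n_priv = {VariantClass.SNP: 0, VariantClass.INDEL: 0}
    n_tot = {VariantClass.SNP: 0, VariantClass.INDEL: 0}
    for v in target_variants:
        calls = panel.get(v.key)
        if calls is None or len(calls) == 0:
            raise ValueError(f"no panel calls for variant {v.key}")
        if v.variant_class is VariantClass.SNP:
            flag = is_private_snp(v, calls, config)
        else:
            flag = is_private_indel(v, calls, config)
        flags[v.key] = flag
        n_tot[v.variant_class] += 1
        n_priv[v.variant_class] += flag
    summary = PrivateSummary(
        n_private_snps=n_priv[VariantClass.SNP],
        n_private_indels=n_priv[VariantClass.INDEL],
        n_snps=n_tot[VariantClass.SNP],
        n_indels=n_tot[VariantClass.INDEL],
    )
    return flags, summary


# ---------------------------------------------------------------------------
# Panel I/O — pre-joined TSV: chrom, pos, ref, alt, strain, status, qual, depth

PANEL_COLUMNS = ["chrom", "pos", "ref", "alt", "strain", "status", "qual", "depth"]


def read_panel_tsv(path: str) -> dict[tuple[str, int, str, str], list[StrainSiteCall]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel TSV missing columns: {sorted(missing)}")
    panel: dict[tuple[str, int, str, str], list[StrainSiteCall]] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        panel.setdefault(key, []).append(
            StrainSiteCall(row.strain, CallStatus[row.status], float(row.qual), int(row.depth))
        )
    return panel


def write_panel_tsv(panel: PanelCalls, path: str) -> None:
    rows = []
    for (chrom, pos, ref, alt), calls in panel.items():
        for c in calls:
            rows.append((chrom, pos, ref, alt, c.strain, c.status.name, c.qual, c.depth))
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep="\t", index=False)
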