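"""End-to-end orchestration: from an annotated VCF to candidate-gene reports.

Stages run in a fixed order, each writing a plot-ready TSV into the output
directory; a ``manifest.json`` records the package version, the effective
configuration, input checksums, and per-stage record counts.  Stage outputs
are pure functions of the inputs plus configuration, so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .deleterious import consensus, interval_summary
from .gwas import (
    candidate_report,
    mendelian_gene_sets,
    read_gwas_catalog,
    read_ortholog_map,
    reports_to_frame,
    to_mouse_genes,
    trait_gene_ids,
)
from .private import DEFAULT_PANEL_CONFIG, PanelConfig, call_private_set, read_panel_tsv
from .simulate import TRAIT_KEYWORDS
from .so_terms import DEFAULT_PRIORITY, SOPriority, final_classification, tabulate_sets
from .variants import (
    DEFAULT_INTERVALS,
    GenomicInterval,
    VariantClass,
    filter_homozygous,
    parse_variants,
    read_bed_intervals,
    window_density,
)

STAGES = (
    "parse",
    "classify",
    "private",
    "deleterious",
    "intervals",
    "candidates",
    "density",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for exit-code mapping."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class RunConfig:
    vcf: str
    out_dir: str
    panel: str | None = None  # pre-joined panel TSV
    intervals_bed: str | None = None  # default: tabw2a/tabw2b
    catalog: str | None = None
    orthologs: str | None = None
    mendelian: str | None = None
    trait_keywords: tuple[str, ...] = TRAIT_KEYWORDS
    panel_config: PanelConfig = field(default_factory=PanelConfig)
    priority: SOPriority = field(default_factory=SOPriority)
    sift_max: float = 0.05
    provean_max: float = -2.5
    density_window: int = 1_000_000
    density_step: int = 1_000_000  # tiling by default; set 1000 for figure-grade tracks


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _variants_frame(variants, priority) -> pd.DataFrame:
    rows = []
    for v in variants:
        res = final_classification(v.annotations, priority)
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "class": v.variant_class.value,
                "zygosity": v.zygosity.value,
                "genes": ",".join(sorted(v.gene_ids)),
                "final_term": res.final_term,
                "multi_set": res.multi_set,
                "pathogenic": res.pathogenic,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "inputs": {},
        "stages": {},
        "partial": False,
        "config": {
            "sift_max": config.sift_max,
            "provean_max": config.provean_max,
            "panel": vars(config.panel_config),
            "density_window": config.density_window,
            "density_step": config.density_step,
            "trait_keywords": list(config.trait_keywords),
        },
    }
    for label, path in [
        ("vcf", config.vcf),
        ("panel", config.panel),
        ("catalog", config.catalog),
        ("orthologs", config.orthologs),
        ("mendelian", config.mendelian),
        ("intervals_bed", config.intervals_bed),
    ]:
        if path is not None:
            if not Path(path).exists():
                raise StageError("parse" if label == "vcf" else "candidates" if label in ("catalog", "orthologs", "mendelian") else "private" if label == "panel" else "intervals", f"input file missing: {path}")
            manifest["inputs"][label] = {"path": str(path), "sha256": _sha256(path)}

    priority = config.priority

    # parse + homozygosity filter -------------------------------------------
    try:
        all_variants = parse_variants(config.vcf)
        hom, het_fraction = filter_homozygous(all_variants)
        frame = _variants_frame(hom, priority)
        frame.to_csv(out / "variants_homozygous.tsv", sep="\t", index=False)
        (out / "het_fraction.json").write_text(
            json.dumps(
                {k.value: v for k, v in het_fraction.items()}, indent=2, sort_keys=True
            )
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("parse", str(exc)) from exc
    manifest["stages"]["parse"] = {
        "n_input": len(all_variants),
        "n_homozygous": len(hom),
    }

    # classification ---------------------------------------------------------
    try:
        set_table, final_table, multi_table = tabulate_sets(hom, priority)
        set_table.to_csv(out / "classification_sets.tsv", sep="\t", index=False)
        final_table.to_csv(out / "final_terms.tsv", sep="\t", index=False)
        multi_table.to_csv(out / "multiset_pathogenic.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    manifest["stages"]["classify"] = {"n_distinct_sets": len(set_table)}

    # private calls ----------------------------------------------------------
    private_flags: dict = {}
    if config.panel is not None:
        try:
            panel = read_panel_tsv(config.panel)
            private_flags, summary = call_private_set(hom, panel, config.panel_config)
            flag_rows = [
                {"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "private": flag}
                for k, flag in private_flags.items()
            ]
            pd.DataFrame(flag_rows).to_csv(out / "private_flags.tsv", sep="\t", index=False)
            (out / "private_summary.json").write_text(
                json.dumps(
                    {
                        "n_private_snps": summary.n_private_snps,
                        "n_private_indels": summary.n_private_indels,
                        "n_snps": summary.n_snps,
                        "n_indels": summary.n_indels,
                        "snp_fraction": summary.snp_fraction,
                        "indel_fraction": summary.indel_fraction,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            manifest["stages"]["private"] = {
                "n_private_snps": summary.n_private_snps,
                "n_private_indels": summary.n_private_indels,
            }
        except Exception as exc:
            raise StageError("private", str(exc)) from exc

    # deleteriousness table --------------------------------------------------
    try:
        rows = []
        for v in hom:
            missense = [a for a in v.annotations if "missense_variant" in a.so_terms]
            if not missense:
                continue
            call = consensus(v, config.sift_max, config.provean_max)
            first = missense[0]
            rows.append(
                {
                    "gene": first.gene_id or "",
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "codon_change": "/".join(first.codon_change) if first.codon_change else "",
                    "aa_change": "/".join(first.aa_change) if first.aa_change else "",
                    "sift": first.sift_score,
                    "provean": first.provean_score,
                    "sift_deleterious": call.sift_deleterious,
                    "provean_deleterious": call.provean_deleterious,
                    "both": call.both,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "gene",
                "chrom",
                "pos",
                "codon_change",
                "aa_change",
                "sift",
                "provean",
                "sift_deleterious",
                "provean_deleterious",
                "both",
            ],
        ).to_csv(out / "missense_deleteriousness.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("deleterious", str(exc)) from exc
    manifest["stages"]["deleterious"] = {"n_missense": len(rows)}

    # interval summary -------------------------------------------------------
    try:
        intervals: list[GenomicInterval] = (
            read_bed_intervals(config.intervals_bed)
            if config.intervals_bed
            else list(DEFAULT_INTERVALS)
        )
        summary_df = interval_summary(hom, intervals, priority)
        summary_df.to_csv(out / "interval_summary.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("intervals", str(exc)) from exc
    manifest["stages"]["intervals"] = {"n_intervals": len(intervals)}

    # candidate reports ------------------------------------------------------
    if config.catalog is not None:
        try:
            if config.orthologs is None:
                raise ValueError("candidate stage requires an ortholog map")
            catalog = read_gwas_catalog(config.catalog)
            omap = read_ortholog_map(config.orthologs)
            reports = []
            for kw in config.trait_keywords:
                mouse = to_mouse_genes(trait_gene_ids(catalog, kw), omap)
                reports.append(
                    candidate_report(hom, mouse, private_flags, priority, f"GWAS {kw}")
                )
            if config.mendelian is not None:
                for category, genes in mendelian_gene_sets(config.mendelian, omap).items():
                    reports.append(
                        candidate_report(hom, genes, private_flags, priority, category)
                    )
            reports_to_frame(reports).to_csv(
                out / "candidate_reports.tsv", sep="\t", index=False
            )
            manifest["stages"]["candidates"] = {"n_reports": len(reports)}
        except Exception as exc:
            raise StageError("candidates", str(exc)) from exc

    # density tracks ---------------------------------------------------------
    try:
        chrom_lengths: dict[str, int] = {}
        for v in hom:
            chrom_lengths[v.chrom] = max(chrom_lengths.get(v.chrom, 0), v.pos)
        for chrom, length in sorted(chrom_lengths.items()):
            track = window_density(
                hom, chrom, length, config.density_window, config.density_step
            )
            track.to_tsv(str(out / f"density_{chrom}.tsv"))
        manifest["stages"]["density"] = {"n_chromosomes": len(chrom_lengths)}
    except Exception as exc:
        raise StageError("density", str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
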