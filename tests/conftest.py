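from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from strainvar.simulate import (
    SimConfig,
    gen_catalog_and_orthologs,
    gen_cohort,
    gen_panel,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


CSQ_FORMAT = (
    "Allele|Consequence|Gene|Feature|CDS_position|Protein_position|"
    "Codons|Amino_acids|SIFT|PROVEAN"
)

VCF_HEADER = "\n".join(
    [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        f'Format: {CSQ_FORMAT}">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "##contig=<ID=1,length=195471971>",
        "##contig=<ID=6,length=149736546>",
        "##contig=<ID=7,length=145441459>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTARGET",
    ]
)


@pytest.fixture
def make_vcf(tmp_path):
    """Write a toy VCF from body lines and return its path."""

    def _make(*body_lines: str, name: str = "toy.vcf") -> str:
        path = tmp_path / name
        path.write_text(VCF_HEADER + "\n" + "\n".join(body_lines) + "\n")
        return str(path)

    return _make


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A full synthetic bundle (cohort, panel, gene-set files) with truth.

    Study-condition scale: 1,000 variants against a 28-strain panel.
    """
    out = tmp_path_factory.mktemp("bundle")
    config = SimConfig(seed=11, n_variants=1000)
    vcf_path, truth = gen_cohort(config, out)
    panel = gen_panel(truth, config, out / "panel.tsv")
    catalog, orthologs, mendelian, truth = gen_catalog_and_orthologs(truth, config, out)
    return {
        "dir": Path(out),
        "config": config,
        "vcf": vcf_path,
        "truth": truth,
        "panel": panel,
        "panel_tsv": out / "panel.tsv",
        "catalog": catalog,
        "orthologs": orthologs,
        "mendelian": mendelian,
    }
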