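import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainvar.variants import (
    GenomicInterval,
    TABW2A,
    VariantClass,
    VariantRecord,
    VcfParseError,
    Zygosity,
    filter_homozygous,
    in_interval,
    left_align,
    parse_variants,
    read_bed_intervals,
    trim_alleles,
    window_density,
)


def snp(chrom="1", pos=100, ref="A", alt="G", zyg=Zygosity.HOM_ALT):
    return VariantRecord(chrom, pos, ref, alt, zyg)


class TestParsing:
    def test_homozygous_readback(self, make_vcf):
        path = make_vcf(
            "1\t100\t.\tC\tA\t60.0\t.\tDP=30\tGT:DP\t1/1:30",
            "1\t200\t.\tCA\tC\t50.0\t.\tDP=25\tGT:DP\t1/1:25",
        )
        records = parse_variants(path)
        assert len(records) == 2
        assert all(r.zygosity is Zygosity.HOM_ALT for r in records)
        assert records[0].variant_class is VariantClass.SNP
        assert records[1].variant_class is VariantClass.INDEL
        assert records[0].qual == pytest.approx(60.0)
        assert records[0].depth == 30

    def test_multiallelic_decomposition(self, make_vcf):
        path = make_vcf("1\t500\t.\tC\tA,T\t99.0\t.\tDP=40\tGT:DP\t1/2:40")
        records = parse_variants(path)
        assert len(records) == 2
        assert {r.alt_allele for r in records} == {"A", "T"}
        assert all(r.pos == 500 for r in records)
        assert all(r.zygosity is Zygosity.HET for r in records)

    def test_decomposition_conserves_allele_count(self, make_vcf):
        path = make_vcf(
            "1\t100\t.\tC\tA\t60.0\t.\tDP=30\tGT:DP\t1/1:30",
            "1\t500\t.\tC\tA,T\t99.0\t.\tDP=40\tGT:DP\t1/2:40",
        )
        assert len(parse_variants(path)) == 3

    def test_missing_genotype_skipped(self, make_vcf, caplog):
        path = make_vcf(
            "1\t100\t.\tC\tA\t60.0\t.\tDP=30\tGT:DP\t./.:30",
            "1\t200\t.\tG\tT\t60.0\t.\tDP=30\tGT:DP\t1/1:30",
        )
        with caplog.at_level("WARNING"):
            records = parse_variants(path)
        assert len(records) == 1 and records[0].pos == 200
        assert any("skipped" in m for m in caplog.messages)

    def test_csq_annotations_parsed(self, make_vcf):
        csq = "A|missense_variant&splice_region_variant|GENE1|TX1|136|46|Cgt/Agt|R/S|0.030|-5.85"
        path = make_vcf(f"6\t113433131\t.\tC\tA\t60.0\t.\tDP=30;CSQ={csq}\tGT:DP\t1/1:30")
        (rec,) = parse_variants(path)
        (ann,) = rec.annotations
        assert ann.so_terms == {"missense_variant", "splice_region_variant"}
        assert ann.gene_id == "GENE1"
        assert ann.codon_change == ("CGT", "AGT")
        assert ann.cds_position == 136
        assert ann.sift_score == pytest.approx(0.03)
        assert ann.provean_score == pytest.approx(-5.85)

    def test_malformed_vcf_raises(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("not a vcf at all\n")
        with pytest.raises(VcfParseError):
            parse_variants(str(bad))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VariantRecord("1", 0, "A", "G", Zygosity.HOM_ALT)
        with pytest.raises(ValueError):
            VariantRecord("1", 10, "A", "A", Zygosity.HOM_ALT)


class TestNormalization:
    @pytest.mark.parametrize(
        "pos,ref,alt,expected",
        [
            (100, "CA", "C", (100, "CA", "C")),  # already minimal
            (100, "CAG", "CG", (100, "CA", "C")),  # shared suffix
            (100, "GCA", "GA", (100, "GC", "G")),  # shared suffix, anchored left
            (100, "ATA", "AGA", (101, "T", "G")),  # embedded SNP
        ],
    )
    def test_trim(self, pos, ref, alt, expected):
        assert trim_alleles(pos, ref, alt) == expected

    def test_left_align_shifts_through_repeat(self):
        #    123456789
        seq = "GGCACACAT"
        # deleting "CA" anywhere in the CACACA repeat shifts left to pos 2
        pos, ref, alt = left_align(6, "ACA", "A", seq)
        assert (pos, ref, alt) == (2, "GCA", "G")


class TestHomozygousFilter:
    def test_all_homozygous(self):
        variants = [snp(pos=i) for i in range(1, 11)]
        hom, het = filter_homozygous(variants)
        assert len(hom) == 10
        assert het[VariantClass.SNP] == 0.0

    def test_het_fraction_percentage(self):
        variants = [snp(pos=i) for i in range(1, 9)] + [
            snp(pos=100, zyg=Zygosity.HET),
            snp(pos=101, zyg=Zygosity.HET),
        ]
        hom, het = filter_homozygous(variants)
        assert len(hom) == 8
        assert het[VariantClass.SNP] == pytest.approx(20.0)

    def test_empty_input_reports_absent(self):
        hom, het = filter_homozygous([])
        assert hom == []
        assert het[VariantClass.SNP] is None
        assert het[VariantClass.INDEL] is None

    def test_partition(self):
        variants = [
            snp(pos=i, zyg=Zygosity.HET if i % 3 == 0 else Zygosity.HOM_ALT)
            for i in range(1, 30)
        ]
        hom, _ = filter_homozygous(variants)
        n_het = sum(1 for v in variants if v.zygosity is Zygosity.HET)
        assert len(hom) + n_het == len(variants)


class TestIntervalMembership:
    def test_cidec_position_in_tabw2a(self):
        assert in_interval(snp(chrom="6", pos=113_433_131), TABW2A)

    def test_inclusive_boundaries(self):
        assert in_interval(snp(chrom="6", pos=80_217_217), TABW2A)
        assert in_interval(snp(chrom="6", pos=125_356_646), TABW2A)
        assert not in_interval(snp(chrom="6", pos=80_217_216), TABW2A)

    def test_chromosome_mismatch(self):
        assert not in_interval(snp(chrom="7", pos=80_300_000), TABW2A)

    @given(
        pos=st.integers(1, 2000),
        start=st.integers(1, 2000),
        length=st.integers(0, 500),
        same_chrom=st.booleans(),
    )
    def test_agrees_with_brute_force_scan(self, pos, start, length, same_chrom):
        interval = GenomicInterval("iv", "1", start, start + length)
        v = snp(chrom="1" if same_chrom else "2", pos=pos)
        expected = same_chrom and pos in range(start, start + length + 1)
        assert in_interval(v, interval) == expected


class TestWindowDensity:
    def brute_force(self, positions, chrom_length, window, step):
        starts = list(range(1, chrom_length + 1, step))
        return [sum(1 for p in positions if s <= p < s + window) for s in starts]

    def test_no_variants(self):
        track = window_density([], "1", 1_000_000)
        assert (track.counts["all"] == 0).all()

    def test_single_variant_covering_windows(self):
        v = [snp(pos=1_500_000)]
        track = window_density(v, "1", 3_000_000, window_size=1_000_000, step=1_000)
        expected = self.brute_force([1_500_000], 3_000_000, 1_000_000, 1_000)
        assert track.counts["all"].tolist() == expected
        covered = track.starts[track.counts["all"] > 0]
        # covering starts are those in (500000, 1500000]; on the 1 kb grid the
        # first is 500001 and the last is 1499001
        assert covered.min() == 500_001 and covered.max() == 1_499_001

    def test_two_variants_same_window(self):
        v = [snp(pos=1000), snp(pos=2000)]
        track = window_density(v, "1", 10_000, window_size=5_000, step=5_000)
        assert track.counts["all"][0] == 2

    @given(
        positions=st.lists(st.integers(1, 5000), max_size=30),
        window=st.integers(1, 2000),
        step=st.integers(1, 2000),
    )
    def test_brute_force_oracle(self, positions, window, step):
        if step > window:
            window, step = step, window
        variants = [snp(pos=p) for p in positions]
        track = window_density(variants, "1", 5000, window_size=window, step=step)
        assert track.counts["all"].tolist() == self.brute_force(positions, 5000, window, step)

    def test_tiling_windows_sum_to_total(self):
        rng = np.random.default_rng(0)
        variants = [snp(pos=int(p)) for p in rng.integers(1, 100_000, size=200)] + [
            VariantRecord("1", int(p), "CA", "C", Zygosity.HOM_ALT)
            for p in rng.integers(1, 100_000, size=50)
        ]
        track = window_density(variants, "1", 100_000, window_size=1_000, step=1_000)
        for label, group in [
            ("all", variants),
            ("SNP", [v for v in variants if v.variant_class is VariantClass.SNP]),
            ("INDEL", [v for v in variants if v.variant_class is VariantClass.INDEL]),
        ]:
            assert track.counts[label].sum() == len(group)

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            window_density([], "1", 0)
        with pytest.raises(ValueError):
            window_density([], "1", 100, window_size=10, step=20)

    def test_tsv_output(self, tmp_path):
        track = window_density([snp(pos=10)], "1", 100, window_size=50, step=50)
        out = tmp_path / "density.tsv"
        track.to_tsv(str(out))
        lines = out.read_text().splitlines()
        assert lines[0].startswith("#")
        assert lines[1].split("\t") == ["window_start", "class", "count"]


class TestBed:
    def test_roundtrip_coordinates(self, tmp_path):
        bed = tmp_path / "iv.bed"
        bed.write_text("6\t80217216\t125356646\ttabw2a\n")
        (iv,) = read_bed_intervals(str(bed))
        assert (iv.chrom, iv.start, iv.end, iv.name) == ("6", 80_217_217, 125_356_646, "tabw2a")
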