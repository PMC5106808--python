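import pytest
from hypothesis import given
from hypothesis import strategies as st

from strainvar.deleterious import (
    AminoAcidChange,
    CodonChange,
    consensus,
    deleterious_filter,
    interval_summary,
    pathogenic_filter,
    per_gene_counts,
    provean_call,
    scores_call,
    sift_call,
    tabw2_missense_table,
    translate_codon_change,
)
from strainvar.variants import (
    ConsequenceAnnotation,
    GenomicInterval,
    VariantRecord,
    Zygosity,
)


def missense_variant(pos=100, sift=None, provean=None, gene="G1", chrom="6", extra_tx=()):
    anns = [
        ConsequenceAnnotation(
            transcript_id="TX1",
            gene_id=gene,
            so_terms=frozenset({"missense_variant"}),
            sift_score=sift,
            provean_score=provean,
        )
    ]
    for i, (s, p) in enumerate(extra_tx, start=2):
        anns.append(
            ConsequenceAnnotation(
                transcript_id=f"TX{i}",
                gene_id=gene,
                so_terms=frozenset({"missense_variant"}),
                sift_score=s,
                provean_score=p,
            )
        )
    return VariantRecord(chrom, pos, "C", "A", Zygosity.HOM_ALT, annotations=anns)


class TestPredictorCalls:
    @pytest.mark.parametrize("score,expected", [(0.03, True), (0.05, False), (0.0, True), (None, None)])
    def test_sift_strict_threshold(self, score, expected):
        assert sift_call(score) is expected

    def test_sift_range_checked(self):
        with pytest.raises(ValueError):
            sift_call(1.2)

    @pytest.mark.parametrize("score,expected", [(-5.85, True), (-2.04, False), (-2.5, False), (None, None)])
    def test_provean_strict_threshold(self, score, expected):
        assert provean_call(score) is expected


class TestConsensus:
    @pytest.mark.parametrize(
        "sift,provean,either,both",
        [
            (0.0, -5.41, True, True),  # deleterious by both
            (0.09, -2.66, True, False),  # PROVEAN only
            (None, -4.67, True, False),  # SIFT missing: can never reach both
            (0.05, -2.5, False, False),  # boundary scores are tolerated
            (0.5, 1.0, False, False),
        ],
    )
    def test_score_pairs(self, sift, provean, either, both):
        call = scores_call(sift, provean)
        assert call.either is either and call.both is both

    def test_variant_consensus_uses_most_deleterious_transcript(self):
        v = missense_variant(sift=0.5, provean=0.0, extra_tx=[(0.01, -4.0)])
        call = consensus(v)
        assert call.both

    def test_non_missense_rejected(self):
        v = VariantRecord(
            "6",
            10,
            "C",
            "A",
            Zygosity.HOM_ALT,
            annotations=[
                ConsequenceAnnotation("TX1", "G1", frozenset({"intron_variant"}))
            ],
        )
        with pytest.raises(ValueError):
            consensus(v)

    @given(
        sift=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        provean=st.one_of(st.none(), st.floats(-12, 12, allow_nan=False)),
    )
    def test_both_implies_either(self, sift, provean):
        call = scores_call(sift, provean)
        assert call.either or not call.both


# A frozen excerpt of the standard genetic code, independent of the
# translation library used by the implementation.
GENETIC_CODE = {
    "CGT": "R",
    "AGT": "S",
    "GAC": "D",
    "GGC": "G",
    "AAA": "K",
    "AAG": "K",
    "ATG": "M",
    "ATA": "I",
    "TGC": "C",
    "TGG": "W",
    "CTG": "L",
    "CTA": "L",
}


class TestCodonTranslation:
    def test_cidec_r46s(self):
        change = translate_codon_change(CodonChange(136, "CGT", "AGT"))
        assert str(change) == "R46S"
        assert not change.synonymous

    def test_apobr_style_first_codon_change(self):
        change = translate_codon_change(CodonChange(4, "GAC", "GGC"))
        assert (change.ref_aa, change.residue_index, change.alt_aa) == ("D", 2, "G")

    def test_synonymous_change(self):
        change = translate_codon_change(CodonChange(3, "AAA", "AAG"))
        assert change.synonymous and change.ref_aa == "K"

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            CodonChange(1, "AXG", "AAG")
        with pytest.raises(ValueError):
            CodonChange(1, "AAA", "AAA")

    @given(
        codons=st.tuples(
            st.sampled_from(sorted(GENETIC_CODE)), st.sampled_from(sorted(GENETIC_CODE))
        ).filter(lambda c: c[0] != c[1]),
        cds_pos=st.integers(1, 3000),
    )
    def test_translation_matches_reference_code_table(self, codons, cds_pos):
        ref, alt = codons
        change = translate_codon_change(CodonChange(cds_pos, ref, alt))
        assert change.ref_aa == GENETIC_CODE[ref]
        assert change.alt_aa == GENETIC_CODE[alt]
        assert change.residue_index == (cds_pos + 2) // 3
        assert change.synonymous == (GENETIC_CODE[ref] == GENETIC_CODE[alt])


class TestAggregation:
    def test_per_gene_counts(self):
        variants = [
            missense_variant(pos=1, sift=0.5, provean=0.0, gene="A"),
            missense_variant(pos=2, sift=0.5, provean=0.0, gene="A"),
            missense_variant(pos=3, sift=0.5, provean=0.0, gene="B"),
        ]
        counts = per_gene_counts(variants, pathogenic_filter())
        assert counts == {"A": 2, "B": 1}

    def test_multi_gene_variant_counts_in_each_gene(self):
        v = missense_variant(pos=1, sift=0.5, provean=0.0, gene="A")
        v.annotations.append(
            ConsequenceAnnotation("TXB", "B", frozenset({"missense_variant"}), sift_score=0.5)
        )
        counts = per_gene_counts([v], pathogenic_filter())
        assert counts == {"A": 1, "B": 1}
        assert sum(counts.values()) >= 1

    def test_interval_summary_additive_over_disjoint_intervals(self):
        variants = [
            missense_variant(pos=p, sift=0.01, provean=-3.0) for p in (10, 20, 110, 120)
        ]
        left = GenomicInterval("L", "6", 1, 100)
        right = GenomicInterval("R", "6", 101, 200)
        whole = GenomicInterval("W", "6", 1, 200)
        df = interval_summary(variants, [left, right, whole])
        df = df.set_index("interval")
        for col in df.columns:
            assert df.loc["L", col] + df.loc["R", col] == df.loc["W", col]

    def test_empty_interval_all_zero(self):
        df = interval_summary(
            [missense_variant(pos=10, sift=0.5, provean=0.0)],
            [GenomicInterval("empty", "6", 1000, 2000)],
        )
        assert (df.drop(columns="interval").iloc[0] == 0).all()

    def test_deleterious_filter_modes(self):
        v = missense_variant(pos=1, sift=0.01, provean=0.0)
        assert deleterious_filter("sift")(v)
        assert deleterious_filter("either")(v)
        assert not deleterious_filter("both")(v)
        assert not deleterious_filter("provean")(v)


class TestCuratedTable:
    def test_shape_and_missing_scores(self):
        table = tabw2_missense_table()
        assert len(table) == 41
        assert table["chrom"].eq("6").all()
        assert table["sift"].isna().sum() == 6  # N/A SIFT rows
        assert table["provean"].isna().sum() == 1  # N/A PROVEAN row
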