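"""Gene model construction, SNV classification, and class-rate aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denovotest.genes import (
    BASES,
    GeneModel,
    GeneModelError,
    IndelParams,
    RateTableError,
    TrinucleotideRateTable,
    build_gene_model,
    classify_snv,
    compute_class_rates,
    site_weights,
)

ORF_30 = "ATGAAACCCGGGTTTCACGAAGATTGGTAG"


class TestBuildGeneModel:
    def test_single_exon_orf(self):
        m = build_gene_model("g", [(100, 130)], ORF_30)
        assert m.coding_length == 30
        assert m.n_introns == 0

    def test_two_exon_coordinate_mapping(self):
        m = build_gene_model("g", [(0, 9), (20, 29)], "ATGAAACCCGGGTTTTAG")
        assert m.coding_to_genomic(8) == 8
        assert m.coding_to_genomic(9) == 20
        assert m.coding_to_genomic(17) == 28

    def test_minus_strand_mapping(self):
        m = build_gene_model("g", [(0, 9), (20, 29)], "ATGAAACCCGGGTTTTAG",
                             strand="-")
        # translation order starts at the end of the last genomic exon
        assert m.coding_to_genomic(0) == 28
        assert m.coding_to_genomic(8) == 20
        assert m.coding_to_genomic(9) == 8

    @pytest.mark.parametrize(
        "exons,seq,msg",
        [
            ([(0, 10), (5, 15)], "A" * 20, "overlap"),
            ([(0, 10)], "A" * 9, "length"),
            ([(0, 9)], "ATGAANTAG", "non-ACGT"),
            ([(0, 2)], "AT", "codon"),
        ],
    )
    def test_invalid_models_rejected(self, exons, seq, msg):
        with pytest.raises(GeneModelError, match=msg):
            build_gene_model("g", exons, seq)


class TestClassifySnv:
    @pytest.mark.parametrize(
        "pos,alt,expected",
        [
            (3, "T", "nonsense"),    # AAA -> TAA
            (5, "G", "synonymous"),  # AAA -> AAG (Lys/Lys)
            (4, "G", "missense"),    # AAA -> AGA (Lys -> Arg)
            (8, "A", "synonymous"),  # TAG -> TAA (stop retained)
            (7, "C", "missense"),    # TAG -> TCG (stop lost, default class)
            (1, "C", "missense"),    # ATG -> ACG (start lost -> missense)
        ],
    )
    def test_consequences_follow_the_codon_table(self, toy_gene, pos, alt, expected):
        assert classify_snv(toy_gene, pos, alt) == expected

    def test_stop_lost_class_configurable(self, toy_gene):
        assert classify_snv(toy_gene, 7, "C", stop_lost_class="stop_lost") == "stop_lost"

    def test_alt_equal_to_ref_rejected(self, toy_gene):
        with pytest.raises(ValueError, match="equals reference"):
            classify_snv(toy_gene, 3, "A")

    def test_position_out_of_range_rejected(self, toy_gene):
        with pytest.raises(IndexError):
            classify_snv(toy_gene, 9, "A")

    def test_invariant_to_exon_splitting(self):
        flat = build_gene_model("a", [(0, 30)], ORF_30, flank_5="A", flank_3="A")
        split = build_gene_model(
            "b", [(0, 7), (100, 110), (200, 213)], ORF_30, flank_5="A", flank_3="A"
        )
        for pos in range(30):
            ref = flat.ref_base(pos)
            for alt in BASES:
                if alt == ref:
                    continue
                assert classify_snv(flat, pos, alt) == classify_snv(split, pos, alt)


def brute_force_class_rates(model, rates):
    """Independent oracle: enumerate all 3L substitutions one by one."""
    totals = {"synonymous": 0.0, "missense": 0.0, "nonsense": 0.0}
    for pos in range(model.coding_length):
        ref = model.ref_base(pos)
        ctx = model.context(pos)
        assert ctx is not None
        for alt in "ACGT":
            if alt == ref:
                continue
            totals[classify_snv(model, pos, alt)] += rates[(ctx, alt)]
    return totals


class TestComputeClassRates:
    def test_matches_brute_force_enumeration(self, uniform_rates):
        # also with non-uniform rates on a longer gene
        from denovotest.simulate import gen_gene, gen_rate_table

        gene = gen_gene(100, seed=11)
        rates = gen_rate_table("cpg_elevated", base_rate=2e-9, seed=12)
        got = compute_class_rates(gene, rates)
        want = brute_force_class_rates(gene, rates)
        for cls in ("synonymous", "missense", "nonsense"):
            assert got.rate(cls) == pytest.approx(want[cls], rel=1e-12)

    def test_uniform_rate_counts_substitutions(self, toy_gene, uniform_rates):
        cr = compute_class_rates(toy_gene, uniform_rates)
        counts = {"synonymous": 0, "missense": 0, "nonsense": 0}
        for pos in range(9):
            ref = toy_gene.ref_base(pos)
            for alt in BASES:
                if alt != ref:
                    counts[classify_snv(toy_gene, pos, alt)] += 1
        for cls, n in counts.items():
            assert cr.rate(cls) == pytest.approx(n * 1e-9, rel=1e-12)

    def test_rate_conservation(self, uniform_rates):
        from denovotest.simulate import gen_gene

        gene = gen_gene(80, seed=3)
        cr = compute_class_rates(gene, uniform_rates)
        total_sites = math.fsum(
            uniform_rates[(gene.context(p), a)]
            for p in range(gene.coding_length)
            for a in BASES
            if a != gene.ref_base(p)
        )
        snv_total = cr.synonymous + cr.missense + cr.nonsense
        assert snv_total == pytest.approx(total_sites, rel=1e-12)

    def test_indel_rates_scale_nonsense(self, toy_gene, uniform_rates):
        cr = compute_class_rates(
            toy_gene, uniform_rates, IndelParams(frameshift_multiplier=1.25,
                                                 inframe_fraction=0.1)
        )
        assert cr.frameshift == pytest.approx(1.25 * cr.nonsense)
        assert cr.inframe_indel == pytest.approx(0.1 * cr.frameshift)
        assert cr.lof == cr.nonsense + cr.splice_site + cr.frameshift
        assert cr.functional == cr.lof + cr.missense + cr.inframe_indel

    def test_splice_rate_counts_intron_ends(self, uniform_rates):
        one = build_gene_model("a", [(0, 30)], ORF_30, flank_5="A", flank_3="A")
        three = build_gene_model("b", [(0, 10), (50, 60), (100, 110)], ORF_30,
                                 flank_5="A", flank_3="A")
        cr1 = compute_class_rates(one, uniform_rates)
        cr3 = compute_class_rates(three, uniform_rates)
        assert cr1.splice_site == 0.0
        assert cr3.splice_site == pytest.approx(4 * 2 * 3e-9, rel=1e-12)

    def test_missing_flanks_use_mean_site_rate(self, uniform_rates):
        with_flanks = build_gene_model("a", [(0, 30)], ORF_30, flank_5="A",
                                       flank_3="A")
        without = build_gene_model("b", [(0, 30)], ORF_30)
        cr_w = compute_class_rates(with_flanks, uniform_rates)
        cr_wo = compute_class_rates(without, uniform_rates)
        # uniform table: boundary fallback equals the true uniform rate
        total_w = cr_w.synonymous + cr_w.missense + cr_w.nonsense
        total_wo = cr_wo.synonymous + cr_wo.missense + cr_wo.nonsense
        assert total_wo == pytest.approx(total_w, rel=1e-12)


class TestRateTable:
    def test_uniform_table_is_complete(self):
        table = TrinucleotideRateTable.uniform(1e-8)
        assert len(dict(table.items())) == 192

    def test_incomplete_table_rejected(self):
        rates = dict(TrinucleotideRateTable.uniform(1e-8).items())
        rates.pop(("ACA", "G"))
        with pytest.raises(RateTableError, match="192"):
            TrinucleotideRateTable(rates)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -1e-9])
    def test_out_of_range_rate_rejected(self, bad):
        rates = dict(TrinucleotideRateTable.uniform(1e-8).items())
        rates[("ACA", "G")] = bad
        with pytest.raises(RateTableError, match="in \\(0, 1\\)"):
            TrinucleotideRateTable(rates)


class TestSiteWeights:
    def test_weights_cover_only_the_requested_class(self, toy_gene, uniform_rates):
        table = site_weights(toy_gene, uniform_rates, "missense")
        for pos, alt in zip(table.positions, table.alts):
            assert classify_snv(toy_gene, pos, alt) == "missense"
        n_missense = sum(
            1
            for p in range(9)
            for a in BASES
            if a != toy_gene.ref_base(p) and classify_snv(toy_gene, p, a) == "missense"
        )
        assert len(table.positions) == n_missense
        assert table.total_weight == pytest.approx(n_missense * 1e-9, rel=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=4, max_value=40), st.integers(min_value=0, max_value=2**31))
def test_generated_genes_classify_consistently_across_exon_splits(n_codons, seed):
    """Exon structure never changes a substitution's consequence."""
    from denovotest.simulate import gen_gene

    flat = gen_gene(n_codons, seed=seed, n_exons=1)
    split = gen_gene(n_codons, seed=seed, n_exons=3)
    assert flat.cds_sequence == split.cds_sequence
    for pos in range(0, flat.coding_length, 5):
        ref = flat.ref_base(pos)
        for alt in BASES:
            if alt != ref:
                assert classify_snv(flat, pos, alt) == classify_snv(split, pos, alt)
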