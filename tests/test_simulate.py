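"""Construct assembly, excision products, outcome draws and FASTQ output."""

import numpy as np
import pytest
from Bio import SeqIO

from loxscreen import RbeVariant, TruthRecord, build_construct, excision_products
from loxscreen.sequences import (
    LOX2272_ANCHOR,
    LOXP_ANCHOR,
    LOXP_SITE,
    reverse_complement,
)
from loxscreen.simulate import (
    default_truth_model,
    draw_markers,
    generate_fastq,
    simulate_outcomes,
    simulate_read_pairs,
    truth_table,
)


def count_occurrences(text, pattern):
    n = start = 0
    while (pos := text.find(pattern, start)) != -1:
        n += 1
        start = pos + 1
    return n


class TestConstruct:
    def test_wild_type_sites_are_canonical(self, wt_variant, markers):
        c = build_construct(wt_variant, markers)
        assert c.element_seq("loxP_1") == c.element_seq("loxP_2") == LOXP_SITE

    def test_variant_at_both_right_rbe_coordinates(self, markers):
        v = RbeVariant("GATGTCAAGATAG")
        c = build_construct(v, markers)
        for name in ("loxP_1", "loxP_2"):
            assert c.element_seq(name)[21:] == v.sequence

    def test_anchor_census(self, markers):
        """The uncleaved cassette has exactly two anchors of each kind."""
        c = build_construct(RbeVariant("AAAACGAAGTTAT"), markers)
        assert count_occurrences(c.sequence, LOXP_ANCHOR) == 2
        assert count_occurrences(c.sequence, LOX2272_ANCHOR) == 2

    def test_amplicon_fits_read_pair(self, wt_variant, markers):
        c = build_construct(wt_variant, markers)
        assert len(c.sequence) <= 280

    def test_deterministic_from_seed(self, wt_variant):
        a = build_construct(wt_variant, 9)
        b = build_construct(wt_variant, 9)
        assert a.sequence == b.sequence

    def test_marker_tags_disjoint_and_anchor_free(self, markers):
        for tag in (markers.marker_a, markers.marker_b):
            assert LOXP_ANCHOR[:13] not in tag
        assert markers.marker_a != markers.marker_b


class TestExcisionProducts:
    @pytest.fixture()
    def products(self, markers):
        return excision_products(build_construct(RbeVariant("GATGTCAAGATAG"), markers)), markers

    def test_marker_logic(self, products):
        prods, m = products
        assert m.marker_a in prods["loxP_cleaved"]
        assert m.marker_b not in prods["loxP_cleaved"]
        assert m.marker_b in prods["lox2272_cleaved"]
        assert m.marker_a not in prods["lox2272_cleaved"]
        assert m.marker_a in prods["uncleaved"] and m.marker_b in prods["uncleaved"]

    def test_variant_survives_every_outcome(self, products):
        prods, _ = products
        for seq in prods.values():
            assert LOXP_ANCHOR + "GATGTCAAGATAG" in seq

    def test_excision_leaves_single_hybrid_site(self, products):
        prods, _ = products
        assert count_occurrences(prods["loxP_cleaved"], LOXP_ANCHOR) == 1
        assert count_occurrences(prods["lox2272_cleaved"], LOX2272_ANCHOR) == 1


class TestSimulateOutcomes:
    def test_conservation(self, wt_variant):
        t = TruthRecord(wt_variant, 0.3, 0.4, 12345)
        c = simulate_outcomes(t, seed=0)
        assert c.n_uncleaved + c.n_loxP_cleaved + c.n_lox2272_cleaved == 12345

    def test_degenerate_probabilities(self, wt_variant):
        all_unc = simulate_outcomes(TruthRecord(wt_variant, 1.0, 0.5, 500), seed=1)
        assert all_unc.n_uncleaved == 500
        no_loxp = simulate_outcomes(TruthRecord(wt_variant, 0.0, 0.0, 500), seed=1)
        assert no_loxp.n_loxP_cleaved == 0

    def test_moments_within_three_sigma(self, wt_variant):
        n, p_nc, p_lp = 100_000, 0.035, 0.3
        c = simulate_outcomes(TruthRecord(wt_variant, p_nc, p_lp, n), seed=3)
        p = (1 - p_nc) * p_lp
        assert abs(c.n_loxP_cleaved - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_validation(self, wt_variant):
        with pytest.raises(ValueError):
            TruthRecord(wt_variant, 1.5, 0.5, 100)
        with pytest.raises(ValueError):
            TruthRecord(wt_variant, 0.5, 0.5, 0)


class TestReadGeneration:
    def test_noiseless_mate1_contains_anchor_and_rbe(self, wt_variant, markers):
        lib = [TruthRecord(wt_variant, 1.0, 0.5, 1)]
        (_, r1, _), = simulate_read_pairs(lib, markers, seed=0)
        assert LOXP_ANCHOR + wt_variant.sequence in r1

    def test_mates_are_opposite_ends(self, wt_variant, markers):
        lib = [TruthRecord(wt_variant, 1.0, 0.5, 1)]
        (_, r1, r2), = simulate_read_pairs(lib, markers, seed=0)
        amplicon = excision_products(build_construct(wt_variant, markers))["uncleaved"]
        assert amplicon.startswith(r1)
        assert amplicon.endswith(reverse_complement(r2))

    def test_error_rate_validation(self, wt_variant, markers):
        lib = [TruthRecord(wt_variant, 1.0, 0.5, 1)]
        with pytest.raises(ValueError):
            list(simulate_read_pairs(lib, markers, error_rate=0.5))
        with pytest.raises(ValueError):
            list(simulate_read_pairs([], markers))

    def test_fastq_deterministic_and_parseable(self, small_truth, tmp_path):
        p1 = generate_fastq(small_truth, tmp_path / "a", seed=5)
        p2 = generate_fastq(small_truth, tmp_path / "b", seed=5)
        assert p1["r1"].read_bytes() == p2["r1"].read_bytes()
        assert p1["r2"].read_bytes() == p2["r2"].read_bytes()
        n_molecules = sum(t.n_molecules for t in small_truth)
        records = list(SeqIO.parse(str(p1["r1"]), "fastq"))
        assert len(records) == n_molecules
        assert all(q == 37 for q in records[0].letter_annotations["phred_quality"])

    def test_truth_table_roundtrip(self, small_truth):
        df = truth_table(small_truth)
        assert list(df["true_cleavage_rate_pct"]) == pytest.approx([50.0, 17.3, 29.7])


class TestDefaultTruthModel:
    def test_rates_clipped_and_decreasing_in_expectation(self):
        variants = [RbeVariant("TATACGAAGTTAT"), RbeVariant("GATGTCAAGATAG")]
        recs = default_truth_model(variants, seed=0)
        assert all(0.005 <= r.p_loxP_given_cleaved <= 0.60 for r in recs)

    def test_wild_type_near_symmetric(self):
        """Many jittered draws for WT average close to the symmetric 0.5."""
        wt = RbeVariant("TATACGAAGTTAT")
        recs = default_truth_model([wt] * 300, seed=1)
        mean = np.mean([r.p_loxP_given_cleaved for r in recs])
        assert mean == pytest.approx(0.5, abs=0.03)
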