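"""Read-pair classification: extraction, outcome calls, tallies, rates."""

import numpy as np
import pytest

from loxscreen import RbeVariant, TruthRecord
from loxscreen.classify import (
    LOX2272_CLEAVED,
    LOXP_CLEAVED,
    UNCLASSIFIED,
    UNCLEAVED,
    OutcomeCounts,
    UndefinedRateError,
    classify_pair,
    cleavage_rate,
    estimate_library,
    estimates_from_tally,
    extract_variant,
    non_cleavage_rate,
    tally,
)
from loxscreen.sequences import LOXP_ANCHOR, reverse_complement
from loxscreen.simulate import generate_fastq, simulate_outcomes, simulate_read_pairs

RBE = "GATGTCAAGATAG"
PAD = "CCGGTTAACCGGTTAA"


class TestExtractVariant:
    def test_forward_match(self):
        assert extract_variant(PAD + LOXP_ANCHOR + RBE + PAD, PAD) == RBE

    def test_reverse_complement_only(self):
        mate = reverse_complement(PAD + LOXP_ANCHOR + RBE + PAD)
        assert extract_variant(mate, PAD) == RBE

    def test_no_anchor(self):
        assert extract_variant(PAD * 5, PAD * 5) is None

    def test_discordant_duplicates_fail(self):
        other = "AAAACGAAGTTAT"
        mate1 = LOXP_ANCHOR + RBE + PAD
        mate2 = LOXP_ANCHOR + other + PAD
        assert extract_variant(mate1, mate2) is None

    def test_concordant_duplicates_succeed(self):
        mate = LOXP_ANCHOR + RBE + PAD + LOXP_ANCHOR + RBE
        assert extract_variant(mate, PAD) == RBE

    def test_truncated_hit_ignored(self):
        # anchor too close to the 3' end for a full 13-mer
        assert extract_variant(PAD + LOXP_ANCHOR + RBE[:7], PAD) is None


class TestClassifyPair:
    A, B = "GGATCCTAGGCAATTGCCTAGGAT", "TTCGAACGGTACTAGCATGCTAGC"

    @pytest.mark.parametrize(
        "content, expected",
        [
            (A + PAD + B, UNCLEAVED),
            (A + PAD, LOXP_CLEAVED),
            (B + PAD, LOX2272_CLEAVED),
            (PAD * 3, UNCLASSIFIED),
        ],
    )
    def test_marker_logic(self, content, expected):
        assert classify_pair(content, PAD, self.A, self.B) == expected

    def test_marker_on_reverse_strand(self):
        mate2 = reverse_complement(PAD + self.A + PAD)
        assert classify_pair(PAD, mate2, self.A, self.B) == LOXP_CLEAVED

    def test_marker_split_across_mates(self):
        assert classify_pair(self.A, self.B, self.A, self.B) == UNCLEAVED

    def test_identical_markers_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(PAD, PAD, self.A, self.A)


class TestRates:
    @pytest.mark.parametrize(
        "loxp, lox2272, expected",
        [(173, 827, 17.3), (0, 500, 0.0), (425, 277, 60.5), (500, 500, 50.0)],
    )
    def test_cleavage_rate(self, loxp, lox2272, expected):
        c = OutcomeCounts(n_loxP_cleaved=loxp, n_lox2272_cleaved=lox2272)
        assert round(cleavage_rate(c), 1) == expected

    def test_non_cleavage_rate(self):
        c = OutcomeCounts(n_uncleaved=35, n_loxP_cleaved=300, n_lox2272_cleaved=665)
        assert non_cleavage_rate(c) == pytest.approx(3.5)

    def test_unclassified_excluded_from_denominators(self):
        c = OutcomeCounts(
            n_uncleaved=10, n_loxP_cleaved=45, n_lox2272_cleaved=45, n_unclassified=900
        )
        assert cleavage_rate(c) == pytest.approx(50.0)
        assert non_cleavage_rate(c) == pytest.approx(10.0)

    def test_undefined_rates(self):
        with pytest.raises(UndefinedRateError):
            cleavage_rate(OutcomeCounts(n_uncleaved=10))
        with pytest.raises(UndefinedRateError):
            non_cleavage_rate(OutcomeCounts(n_unclassified=10))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            OutcomeCounts(n_uncleaved=-1)


class TestTally:
    def test_empty_input(self):
        res = tally([], "GGATCCTAGGCAATTGCCTAGGAT", "TTCGAACGGTACTAGCATGCTAGC")
        assert res.counts == {} and res.n_extraction_failures == 0

    def test_zero_noise_counts_equal_simulation_truth(self, small_truth, markers):
        """Oracle equivalence: classified tallies match the multinomial draw."""
        pairs = [
            (r1, r2)
            for _, r1, r2 in simulate_read_pairs(small_truth, markers, seed=17)
        ]
        res = tally(pairs, markers.marker_a, markers.marker_b)
        assert res.n_extraction_failures == 0
        rng = np.random.default_rng(17)
        for t in small_truth:
            expected = simulate_outcomes(t, rng)
            got = res.counts[t.variant.sequence]
            assert (got.n_uncleaved, got.n_loxP_cleaved, got.n_lox2272_cleaved) == (
                expected.n_uncleaved,
                expected.n_loxP_cleaved,
                expected.n_lox2272_cleaved,
            )

    def test_count_conservation(self, small_truth, markers):
        pairs = [
            (r1, r2)
            for _, r1, r2 in simulate_read_pairs(small_truth, markers, seed=3)
        ]
        res = tally(pairs, markers.marker_a, markers.marker_b)
        classified = sum(c.total for c in res.counts.values())
        assert classified + res.n_extraction_failures == res.n_pairs == len(pairs)

    def test_pair_without_anchor_counts_as_failure(self, markers):
        res = tally([(PAD * 8, PAD * 8)], markers.marker_a, markers.marker_b)
        assert res.n_extraction_failures == 1 and res.counts == {}

    def test_errors_increase_extraction_failures(self, small_truth, markers):
        def failure_fraction(error_rate):
            pairs = [
                (r1, r2)
                for _, r1, r2 in simulate_read_pairs(
                    small_truth, markers, error_rate=error_rate, seed=23
                )
            ]
            res = tally(pairs, markers.marker_a, markers.marker_b)
            return res.n_extraction_failures / res.n_pairs

        assert failure_fraction(0.0) == 0.0
        assert failure_fraction(0.01) < failure_fraction(0.05)


class TestEstimateLibrary:
    def test_end_to_end_recovers_truth(self, small_truth, markers, tmp_path):
        paths = generate_fastq(small_truth, tmp_path, seed=11)
        est = estimate_library(paths["r1"], paths["r2"], paths["markers"], cutoff=500)
        assert len(est) == 3
        assert list(est["cleavage_rate_pct"]) == sorted(est["cleavage_rate_pct"])
        for t in small_truth:
            row = est[est["variant_sequence"] == t.variant.sequence].iloc[0]
            p = t.p_loxP_given_cleaved
            n_cleaved = row["n_loxP"] + row["n_lox2272"]
            sigma = 100 * np.sqrt(p * (1 - p) / n_cleaved)
            assert abs(row["cleavage_rate_pct"] - 100 * p) <= 3 * sigma
            assert row["passes_cutoff"]  # depth 800 > 500

    def test_cutoff_is_strict(self):
        res = tally([], "A" * 24, "C" * 24)
        res.counts["GATGTCAAGATAG"] = OutcomeCounts(n_loxP_cleaved=200, n_lox2272_cleaved=300)
        res.counts["AAAACGAAGTTAT"] = OutcomeCounts(n_loxP_cleaved=200, n_lox2272_cleaved=301)
        est = estimates_from_tally(res, cutoff=500)
        by_seq = est.set_index("variant_sequence")
        assert not by_seq.loc["GATGTCAAGATAG", "passes_cutoff"]  # exactly 500
        assert by_seq.loc["AAAACGAAGTTAT", "passes_cutoff"]  # 501

    def test_no_reads_is_fatal(self):
        res = tally([], "A" * 24, "C" * 24)
        with pytest.raises(ValueError):
            estimates_from_tally(res)
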