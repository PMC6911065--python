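"""Homopolymer statistics and trinucleotide-context mismatch profiling."""
import numpy as np
import pysam
import pytest

from somaticstack.mismatch import (
    MismatchCounts,
    collapse_to_six,
    downsample_reads,
    longest_runs,
    mismatch_rate,
    profile_mismatches,
    run_length_distribution,
)
from somaticstack.simulate import ErrorProfile, read_strand_sequence, simulate_reads


class TestLongestRuns:
    def test_basic(self):
        assert longest_runs("AAAT") == {"A": 3, "C": 0, "G": 0, "T": 1}

    def test_empty(self):
        assert longest_runs("") == {"A": 0, "C": 0, "G": 0, "T": 0}

    def test_n_breaks_run(self):
        assert longest_runs("GGANGG")["G"] == 2

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError):
            longest_runs("ACGX")


class TestRunLengthDistribution:
    def test_point_mass(self):
        out = run_length_distribution({"R1": ["AAAA", "AAAA"]})
        assert out[("A", 4, "R1")] == 1.0

    def test_fractions_sum_to_one(self):
        out = run_length_distribution({"R1": ["AAAT", "AATT", "GGGG"]})
        for base in "ACGT":
            total = sum(frac for (b, _, _), frac in out.items() if b == base)
            assert total == pytest.approx(1.0)

    def test_g_run_inflation_right_shifts(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), size=20_000))
        plain, _ = simulate_reads(ref, 4, ErrorProfile.uniform(0.0), seed=1)
        inflated, _ = simulate_reads(ref, 4, ErrorProfile.uniform(0.0), seed=1,
                                     g_run_inflation=0.5)

        def mean_g_run(reads):
            return np.mean([longest_runs(read_strand_sequence(r))["G"] for r in reads])

        assert mean_g_run(inflated) > mean_g_run(plain) + 1.0


def make_read(seq, start=0, reverse=False, quals=None, cigar=None, name="r1",
              mapq=60, **flags):
    header = pysam.AlignmentHeader.from_references(["chr1"], [10_000])
    a = pysam.AlignedSegment(header=header)
    a.query_name = name
    a.query_sequence = seq
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = cigar or [(0, len(seq))]
    a.is_reverse = reverse
    a.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in (quals or [30] * len(seq))))
    for flag, value in flags.items():
        setattr(a, flag, value)
    return a


REF = "ACGTACGTACGTACGT"


class TestProfileMismatches:
    def test_perfect_read_zero_mismatches(self):
        counts = profile_mismatches([make_read(REF[2:10], start=2)], {"chr1": REF})
        assert counts.total == 0
        assert counts.eligible_bases == 6  # 8 aligned minus 2 context-less ends

    def test_forward_mismatch_channel(self):
        # middle base G->T under reference context A[G]T
        ref2 = "CCAGTCC"
        read = make_read("ATT", start=2)
        counts = profile_mismatches([read], {"chr1": ref2})
        assert counts.counts == {("G", "T", "A", "T"): 1}

    def test_reverse_alignment_reverse_complements(self):
        # the same genomic event on a reverse-strand alignment reports C>A
        # in the reverse-complemented context: A[G>T]T -> A[C>A]T
        ref2 = "CCAGTCC"
        read = make_read("ATT", start=2, reverse=True)
        counts = profile_mismatches([read], {"chr1": ref2})
        assert counts.counts == {("C", "A", "A", "T"): 1}

    @pytest.mark.parametrize("flag", ["is_duplicate", "is_supplementary", "is_qcfail"])
    def test_excluded_flags_skip_read(self, flag):
        read = make_read(REF[2:10], start=2, **{flag: True})
        counts = profile_mismatches([read], {"chr1": REF})
        assert counts.eligible_bases == 0

    def test_low_mapping_quality_skips_read(self):
        read = make_read(REF[2:10], start=2, mapq=9)
        assert profile_mismatches([read], {"chr1": REF}).eligible_bases == 0

    def test_low_base_quality_position_ineligible(self):
        quals = [30] * 8
        quals[4] = 5
        read = make_read(REF[2:10], start=2, quals=quals)
        counts = profile_mismatches([read], {"chr1": REF})
        assert counts.eligible_bases == 5

    def test_indel_adjacent_bases_excluded(self):
        # 4M 2D 4M: bases flanking the deletion drop out of the denominator
        read = make_read(REF[2:6] + REF[8:12], start=2, cigar=[(0, 4), (2, 2), (0, 4)])
        counts = profile_mismatches([read], {"chr1": REF})
        assert counts.total == 0
        # 8 aligned - 2 read ends - 2 deletion-adjacent
        assert counts.eligible_bases == 4

    def test_raising_bq_never_increases_counts(self):
        rng = np.random.default_rng(3)
        ref = "".join(rng.choice(list("ACGT"), size=5_000))
        reads, _ = simulate_reads(ref, 5, ErrorProfile.uniform(0.01), seed=4,
                                  lowq_rate=0.2)
        prev = None
        for bq in (0, 10, 20, 40):
            c = profile_mismatches(reads, {"chr1": ref}, bq_min=bq)
            if prev is not None:
                assert c.eligible_bases <= prev.eligible_bases
                assert all(c.counts.get(ch, 0) <= prev.counts.get(ch, 0)
                           for ch in prev.counts)
            prev = c

    def test_reference_too_short_rejected(self):
        read = make_read("ACGTACGT", start=2)
        with pytest.raises(ValueError):
            profile_mismatches([read], {"chr1": "ACGTA"})


class TestCollapse:
    def test_purine_channel_maps_to_revcomp(self):
        counts = MismatchCounts(counts={("G", "T", "A", "T"): 1}, eligible_bases=10)
        out = collapse_to_six(counts)
        assert out.counts == {("C", "A", "A", "T"): 1}

    def test_pyrimidine_channels_unchanged(self):
        counts = MismatchCounts(counts={("C", "A", "G", "G"): 2}, eligible_bases=10)
        assert collapse_to_six(counts).counts == {("C", "A", "G", "G"): 2}

    def test_total_and_eligible_conserved(self):
        rng = np.random.default_rng(7)
        ref = "".join(rng.choice(list("ACGT"), size=10_000))
        reads, _ = simulate_reads(ref, 5, ErrorProfile.uniform(0.01), seed=8)
        counts = profile_mismatches(reads, {"chr1": ref})
        out = collapse_to_six(counts)
        assert out.total == counts.total
        assert out.eligible_bases == counts.eligible_bases
        assert all(r in "CT" for (r, _, _, _) in out.counts)


class TestRateAndDownsampling:
    def test_rate_arithmetic(self):
        counts = MismatchCounts(counts={("C", "A", "A", "A"): 24}, eligible_bases=10_000)
        assert mismatch_rate(counts) == pytest.approx(0.0024)

    def test_zero_mismatches(self):
        assert mismatch_rate(MismatchCounts(eligible_bases=100)) == 0.0

    def test_zero_eligible_missing(self):
        assert mismatch_rate(MismatchCounts()) is None

    def test_rate_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        ref = "".join(rng.choice(list("ACGT"), size=60_000))
        rate = 0.002
        reads, _ = simulate_reads(ref, 10, ErrorProfile.uniform(rate), seed=12)
        counts = profile_mismatches(reads, {"chr1": ref})
        se = (rate * (1 - rate) / counts.eligible_bases) ** 0.5
        assert abs(mismatch_rate(counts) - rate) < 3 * se

    def test_downsample_reproducible_and_calibrated(self):
        rng = np.random.default_rng(13)
        ref = "".join(rng.choice(list("ACGT"), size=30_000))
        reads, _ = simulate_reads(ref, 16, ErrorProfile.uniform(0.0), seed=14)
        a = downsample_reads(reads, genome_size=30_000, target_depth=8, seed=1)
        b = downsample_reads(reads, genome_size=30_000, target_depth=8, seed=1)
        assert [r.query_name for r in a] == [r.query_name for r in b]
        keep_p = 8 / 16
        n = len({r.query_name for r in reads})
        se = (n * keep_p * (1 - keep_p)) ** 0.5
        assert abs(len({r.query_name for r in a}) - keep_p * n) < 3 * se

    def test_target_above_current_rejected(self):
        rng = np.random.default_rng(15)
        ref = "".join(rng.choice(list("ACGT"), size=10_000))
        reads, _ = simulate_reads(ref, 4, ErrorProfile.uniform(0.0), seed=16)
        with pytest.raises(ValueError):
            downsample_reads(reads, genome_size=10_000, target_depth=8)
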