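"""Pileup allele counting, final count selection and the somatic filters."""
import numpy as np
import pytest

from somaticstack.counts import (
    ReadEvidence,
    all_somatic,
    apply_somatic_filters,
    assign_final_counts,
    pileup_counts,
    select_final_counts,
)
from somaticstack.model import SampleCounts, SmallVariant


def ev(frag, allele, mq=60, bq=30, **flags):
    return ReadEvidence(fragment_id=frag, allele=allele, mapping_quality=mq,
                        base_quality=bq, **flags)


class TestPileup:
    def test_basic_tally(self):
        evidence = [ev(f"a{i}", "ALT") for i in range(6)] + \
                   [ev(f"r{i}", "REF") for i in range(4)]
        c = pileup_counts(evidence)
        assert (c.alt_count, c.ref_count, c.depth) == (6, 4, 10)
        assert c.vaf == pytest.approx(0.6)

    def test_read_pair_counts_once(self):
        c = pileup_counts([ev("f1", "ALT"), ev("f1", "ALT")])
        assert c.alt_count == 1 and c.depth == 1

    def test_disagreeing_mates_dropped(self):
        c = pileup_counts([ev("f1", "ALT"), ev("f1", "REF"), ev("f2", "REF")])
        assert (c.alt_count, c.ref_count, c.depth) == (0, 1, 1)

    @pytest.mark.parametrize("kwargs", [
        {"mq": 9}, {"bq": 9},
        {"is_duplicate": True}, {"is_supplementary": True},
        {"is_qcfail": True}, {"is_unmapped": True},
    ])
    def test_exclusions(self, kwargs):
        c = pileup_counts([ev("f1", "ALT", **kwargs)])
        assert c.depth == 0

    def test_boundary_quality_ten_included(self):
        c = pileup_counts([ev("f1", "ALT", mq=10, bq=10)])
        assert c.alt_count == 1

    def test_other_allele_in_depth_only(self):
        c = pileup_counts([ev("f1", "OTHER"), ev("f2", "REF")])
        assert (c.ref_count, c.alt_count, c.depth) == (1, 0, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        evidence = []
        for i in range(60):
            frag = f"f{int(rng.integers(0, 40))}"
            evidence.append(ReadEvidence(
                fragment_id=frag,
                allele=str(rng.choice(["REF", "ALT", "OTHER"])),
                mapping_quality=int(rng.integers(0, 61)),
                base_quality=int(rng.integers(0, 41)),
                is_duplicate=bool(rng.random() < 0.1)))
        got = pileup_counts(evidence)
        surviving = {}
        for e in evidence:
            if e.is_duplicate or e.mapping_quality < 10 or e.base_quality < 10:
                continue
            surviving.setdefault(e.fragment_id, set()).add(e.allele)
        unanimous = {f: next(iter(a)) for f, a in surviving.items() if len(a) == 1}
        assert got.depth == len(unanimous)
        assert got.alt_count == sum(1 for a in unanimous.values() if a == "ALT")
        assert got.ref_count == sum(1 for a in unanimous.values() if a == "REF")

    @pytest.mark.parametrize("seed", range(3))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed + 50)
        evidence = [ReadEvidence(f"f{i}", "ALT", int(rng.integers(0, 61)),
                                 int(rng.integers(0, 41))) for i in range(50)]
        prev = None
        for mq in (0, 10, 20, 40):
            c = pileup_counts(evidence, mq_min=mq)
            if prev is not None:
                assert c.alt_count <= prev.alt_count and c.depth <= prev.depth
            prev = c


def variant(ref, alt, callers=("strelka2",)):
    return SmallVariant(chrom="chr1", pos=100, ref=ref, alt=alt,
                        caller_support=set(callers))


PILEUP = SampleCounts(10, 10, 21, source="PILEUP")
CALLER = {c: SampleCounts(12, 8, 20, source="CALLER")
          for c in ("strelka2", "mutect2", "lancet")}


class TestFinalCountSelection:
    def test_snv_uses_pileup(self):
        c = select_final_counts(variant("A", "G"), CALLER, PILEUP)
        assert c.source == "PILEUP"

    def test_small_deletion_uses_pileup(self):
        c = select_final_counts(variant("ACTGTA", "A"), CALLER, PILEUP)  # 5 nt
        assert c.source == "PILEUP"

    def test_large_indel_caller_priority(self):
        v = variant("A", "A" + "T" * 15, callers=("mutect2", "lancet"))
        available = {c: CALLER[c] for c in ("mutect2", "lancet")}
        c = select_final_counts(v, available, PILEUP)
        assert c.source == "MUTECT2"

    def test_strelka2_outranks_mutect2(self):
        v = variant("A", "A" + "T" * 12)
        c = select_final_counts(v, CALLER, PILEUP)
        assert c.source == "STRELKA2"

    def test_svaba_only_large_indel_has_no_counts(self):
        v = variant("A", "A" + "T" * 15, callers=("svaba",))
        c = select_final_counts(v, {}, PILEUP)
        assert c.source == "NONE" and c.vaf is None

    def test_complex_event_uses_caller_path(self):
        v = variant("ACT", "AGGTT")  # both alleles > 1 nt, unequal
        c = select_final_counts(v, CALLER, PILEUP)
        assert c.source == "STRELKA2"

    def test_length_switch_boundary(self):
        # net change 9 -> pileup; net change 10 -> caller counts
        nine = variant("A" + "T" * 9, "A")
        ten = variant("A" + "T" * 10, "A")
        assert select_final_counts(nine, CALLER, PILEUP).source == "PILEUP"
        assert select_final_counts(ten, CALLER, PILEUP).source == "STRELKA2"


def counted(t_ref, t_alt, n_ref, n_alt, t_depth=None, n_depth=None):
    v = variant("A", "G")
    v.tumor_counts = SampleCounts(t_ref, t_alt, t_depth or t_ref + t_alt, source="PILEUP")
    v.normal_counts = SampleCounts(n_ref, n_alt, n_depth or n_ref + n_alt, source="PILEUP")
    return v


class TestSomaticFilters:
    def test_low_tumor_vaf(self):
        v = counted(99_999, 4, 100, 0)  # vaf 4e-5
        apply_somatic_filters([v])
        assert "LOW_TUMOR_VAF" in v.filter_tags

    def test_tumor_vaf_boundary_passes(self):
        v = counted(9_999, 1, 100, 0)  # exactly 1e-4
        apply_somatic_filters([v])
        assert "LOW_TUMOR_VAF" not in v.filter_tags

    def test_high_normal_vaf(self):
        v = counted(50, 50, 75, 25)  # normal vaf 0.25
        apply_somatic_filters([v])
        assert "HIGH_NORMAL_VAF" in v.filter_tags

    def test_normal_vaf_boundary_passes(self):
        v = counted(50, 50, 80, 20)  # exactly 0.2
        apply_somatic_filters([v])
        assert "HIGH_NORMAL_VAF" not in v.filter_tags

    def test_low_depth_either_sample(self):
        v = counted(0, 1, 100, 0)
        apply_somatic_filters([v])
        assert "LOW_DEPTH" in v.filter_tags
        w = counted(60, 40, 1, 0)
        apply_somatic_filters([w])
        assert "LOW_DEPTH" in w.filter_tags

    def test_depth_two_passes(self):
        v = counted(1, 1, 2, 0)
        apply_somatic_filters([v])
        assert "LOW_DEPTH" not in v.filter_tags

    def test_normal_exceeds_tumor(self):
        v = counted(90, 10, 88, 12)  # 0.10 vs 0.12
        apply_somatic_filters([v])
        assert "NORMAL_GT_TUMOR" in v.filter_tags

    def test_no_counts_stays_in_all_somatic(self):
        v = variant("A", "A" + "T" * 15, callers=("svaba",))
        assign_final_counts(v, None, None)
        apply_somatic_filters([v])
        assert "NO_COUNTS" in v.filter_tags
        assert v in all_somatic([v])

    def test_idempotent(self):
        v = counted(50, 50, 75, 25)
        apply_somatic_filters([v])
        tags = set(v.filter_tags)
        apply_somatic_filters([v])
        assert v.filter_tags == tags

    def test_all_somatic_excludes_tagged(self):
        good = counted(50, 50, 100, 0)
        bad = counted(50, 50, 75, 25)
        out = all_somatic(apply_somatic_filters([good, bad]))
        assert out == [good]
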