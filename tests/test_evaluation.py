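"""Concordance, TP/FP/FN classification and base-level CNV comparison."""
import numpy as np
import pytest

from somaticstack.evaluation import (
    classify,
    classify_svs,
    cnv_base_compare,
    concordance,
    precision_recall_f1,
    recall_by_vaf_bin,
)
from somaticstack.model import CNVSegment, EvalCounts


class TestConcordance:
    def test_identical_sets(self):
        assert concordance({1, 2, 3}, {1, 2, 3}) == 100.0

    def test_disjoint_sets(self):
        assert concordance({1}, {2}) == 0.0

    def test_partial_overlap(self):
        assert concordance({1, 2, 3}, {2, 3, 4}) == 50.0

    def test_both_empty_missing(self):
        assert concordance(set(), set()) is None

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        a = set(rng.integers(0, 30, size=15).tolist())
        b = set(rng.integers(0, 30, size=15).tolist())
        assert concordance(a, b) == concordance(b, a)
        assert 0.0 <= concordance(a, b) <= 100.0
        assert (concordance(a, b) == 100.0) == (a == b)


class TestClassify:
    def test_perfect_recovery(self):
        hc = {("chr1", 1), ("chr1", 2)}
        c = classify(hc, hc | {("chr1", 9)}, hc)
        assert (c.tp, c.fp, c.fn, c.ignored) == (2, 0, 0, 0)

    def test_all_somatic_only_calls_ignored(self):
        ref_hc = {("chr1", 1)}
        ref_all = ref_hc | {("chr1", 5)}
        c = classify({("chr1", 1), ("chr1", 5)}, ref_all, ref_hc)
        assert c.ignored == 1 and c.fp == 0

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError):
            classify(set(), set(), {("chr1", 1)})

    @pytest.mark.parametrize("seed", range(5))
    def test_brute_force_set_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        universe = list(range(40))
        test = set(rng.choice(universe, 15, replace=False).tolist())
        ref_all = set(rng.choice(universe, 20, replace=False).tolist())
        ref_hc = set(rng.choice(sorted(ref_all), 10, replace=False).tolist())
        c = classify(test, ref_all, ref_hc)
        assert c.tp == len(test & ref_hc)
        assert c.fp == len(test - ref_all)
        assert c.fn == len(ref_hc - test)
        assert c.tp + c.fp + c.ignored == len(test)


class TestMetrics:
    def test_worked_example(self):
        m = precision_recall_f1(EvalCounts(tp=9, fp=1, fn=3))
        assert m["precision"] == pytest.approx(0.9)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 * 0.9 * 0.75 / 1.65)

    def test_zero_denominators_missing(self):
        m = precision_recall_f1(EvalCounts())
        assert m == {"precision": None, "recall": None, "f1": None}

    def test_perfect_scores(self):
        m = precision_recall_f1(EvalCounts(tp=5))
        assert m == {"precision": 1.0, "recall": 1.0, "f1": 1.0}


class TestSvClassification:
    def test_matching_is_membership(self, make_sv):
        ref = [make_sv(start1=10_000, start2=20_000)]
        test = [make_sv(start1=10_100, start2=20_100)]
        c = classify_svs(test, ref, ref)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_unmatched_is_fp_and_fn(self, make_sv):
        ref = [make_sv(start1=10_000, start2=20_000)]
        test = [make_sv(start1=500_000, start2=520_000)]
        c = classify_svs(test, ref, ref)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)


def seg(chrom, start, end, category):
    return CNVSegment(chrom, start, end, obs_log2=0.0, category=category)


class TestCnvBaseCompare:
    def test_identical_segments(self):
        segs = [seg("chr1", 0, 100, "DEL"), seg("chr1", 200, 300, "DEL")]
        c = cnv_base_compare(segs, [s for s in segs], "DEL")
        assert (c.tp, c.fp, c.fn) == (200, 0, 0)

    def test_partial_overlap(self):
        c = cnv_base_compare([seg("chr1", 0, 100, "DEL")],
                             [seg("chr1", 50, 150, "DEL")], "DEL")
        assert (c.tp, c.fp, c.fn) == (50, 50, 50)

    def test_category_specific(self):
        test = [seg("chr1", 0, 100, "AMP")]
        ref = [seg("chr1", 0, 100, "DEL")]
        c = cnv_base_compare(test, ref, "AMP")
        assert (c.tp, c.fp, c.fn) == (0, 100, 0)

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            cnv_base_compare([seg("chr1", 0, 100, "DEL"), seg("chr1", 50, 80, "DEL")],
                             [], "DEL")

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_array_oracle(self, seed):
        """Interval arithmetic agrees with a per-base boolean array."""
        rng = np.random.default_rng(seed)
        L = 10_000

        def random_tiling():
            cuts = np.sort(rng.choice(np.arange(1, L), size=8, replace=False))
            bounds = [0, *cuts.tolist(), L]
            return [seg("chr1", s, e, str(rng.choice(["AMP", "DEL", "NEUTRAL"])))
                    for s, e in zip(bounds, bounds[1:])]

        test, ref = random_tiling(), random_tiling()
        for category in ("AMP", "DEL"):
            c = cnv_base_compare(test, ref, category)
            t_mask = np.zeros(L, dtype=bool)
            r_mask = np.zeros(L, dtype=bool)
            for s in test:
                if s.category == category:
                    t_mask[s.start:s.end] = True
            for s in ref:
                if s.category == category:
                    r_mask[s.start:s.end] = True
            assert c.tp == int((t_mask & r_mask).sum())
            assert c.fp == int((t_mask & ~r_mask).sum())
            assert c.fn == int((~t_mask & r_mask).sum())


class TestRecallByVafBin:
    def test_single_bin_is_overall_recall(self):
        ref = {("chr1", i): 0.1 * i for i in range(1, 10)}
        test = set(list(ref)[:6])
        out = recall_by_vaf_bin(test, ref, [0.0, 1.0])
        assert out[(0.0, 1.0)] == pytest.approx(6 / 9)

    def test_low_bin_misses_stay_local(self):
        ref = {("chr1", 1): 0.1, ("chr1", 2): 0.15, ("chr1", 3): 0.6, ("chr1", 4): 0.8}
        test = {("chr1", 3), ("chr1", 4)}
        out = recall_by_vaf_bin(test, ref, [0.0, 0.2, 1.0])
        assert out[(0.0, 0.2)] == 0.0
        assert out[(0.2, 1.0)] == 1.0

    def test_out_of_range_vaf_rejected(self):
        with pytest.raises(ValueError):
            recall_by_vaf_bin(set(), {("chr1", 1): 1.5}, [0, 1])

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_partition(self, seed):
        rng = np.random.default_rng(seed)
        ref = {("chr1", i): float(rng.random()) for i in range(30)}
        test = {k for k in ref if rng.random() < 0.5}
        edges = [0.0, 0.25, 0.5, 1.0]
        out = recall_by_vaf_bin(test, ref, edges)
        for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
            last = i == len(edges) - 2
            members = {k for k, v in ref.items() if lo <= v < hi or (last and v == hi)}
            if members:
                assert out[(lo, hi)] == pytest.approx(len(members & test) / len(members))
            else:
                assert out[(lo, hi)] is None
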