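"""Concordance and precision/recall evaluation against a reference run.

Test callsets are compared with the callsets of a deep, pure reference run:
calls matching the reference high-confidence set are true positives, calls
absent from the permissive (AllSomatic) set are false positives, and calls
that match the permissive set but not its high-confidence subset are
*ignored* — they cannot be confidently labelled either way.  CNVs are
compared base-by-base within a category.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .merge_sv import sv_match
from .model import CNVSegment, EvalCounts


def expand_to_snv_keys(keys) -> set:
    """Decompose MNV keys into per-base SNV keys for set comparisons.

    Callers disagree on whether adjacent substitutions are one phased event
    or separate SNVs; comparing at SNV resolution removes the representation
    dependence.  Indel keys pass through unchanged.
    """
    out = set()
    for chrom, pos, ref, alt in keys:
        if len(ref) == len(alt) and len(ref) > 1:
            out.update((chrom, pos + i, r, a)
                       for i, (r, a) in enumerate(zip(ref, alt)) if r != a)
        else:
            out.add((chrom, pos, ref, alt))
    return out


def concordance(a: set, b: set) -> Optional[float]:
    """Jaccard concordance as a percentage: 100 * |a ∩ b| / |a ∪ b|."""
    union = a | b
    if not union:
        return None
    return 100.0 * len(a & b) / len(union)


def classify(test: set, ref_all: set, ref_hc: set) -> EvalCounts:
    """TP/FP/FN/ignored tallies for a test callset against a reference run."""
    if not ref_hc <= ref_all:
        raise ValueError("reference high-confidence set must be a subset of the permissive set")
    test, ref_all, ref_hc = set(test), set(ref_all), set(ref_hc)
    return EvalCounts(
        tp=len(test & ref_hc),
        fp=len(test - ref_all),
        fn=len(ref_hc - test),
        ignored=len(test & (ref_all - ref_hc)),
    )


def classify_svs(test: Sequence, ref_all: Sequence, ref_hc: Sequence,
                 slop: int = 300, reciprocal: float = 0.5) -> EvalCounts:
    """SV classification with match-based membership.

    A test SV is "seen in" a reference set when it matches any member under
    the merge criteria; exact coordinates differ between runs.
    """

    def seen(sv, ref):
        return any(sv_match(sv, r, slop=slop, reciprocal=reciprocal) for r in ref)

    counts = EvalCounts()
    for sv in test:
        if seen(sv, ref_hc):
            counts.tp += 1
        elif seen(sv, ref_all):
            counts.ignored += 1
        else:
            counts.fp += 1
    counts.fn = sum(0 if seen(r, test) else 1 for r in ref_hc)
    return counts


def precision_recall_f1(c: EvalCounts) -> dict:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 their harmonic mean."""
    return {"precision": c.precision, "recall": c.recall, "f1": c.f1}


def _category_intervals(segments: Iterable[CNVSegment], category: str) -> dict:
    by_chrom = {}
    for seg in segments:
        if seg.category == category:
            by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segments on {chrom}: [{s1},{e1}) and [{s2},{e2})")
    return by_chrom


def _intersect_len(a: list, b: list) -> int:
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def cnv_base_compare(test: Iterable[CNVSegment], ref: Iterable[CNVSegment],
                     category: str) -> EvalCounts:
    """Base-level TP/FP/FN for one CNV category.

    TP bases carry the category in both runs; FP bases only in the test run;
    FN bases only in the reference run.  Inputs must be non-overlapping
    within each run.
    """
    test_ivs = _category_intervals(test, category)
    ref_ivs = _category_intervals(ref, category)
    counts = EvalCounts()
    chroms = set(test_ivs) | set(ref_ivs)
    for chrom in chroms:
        t = test_ivs.get(chrom, [])
        r = ref_ivs.get(chrom, [])
        inter = _intersect_len(t, r)
        t_len = sum(e - s for s, e in t)
        r_len = sum(e - s for s, e in r)
        counts.tp += inter
        counts.fp += t_len - inter
        counts.fn += r_len - inter
    return counts


def recall_by_vaf_bin(test: set, ref_hc_vafs: dict, bin_edges: Sequence[float]) -> dict:
    """Recall inside left-closed VAF bins of the reference high-confidence set.

    ``ref_hc_vafs`` maps each reference variant key to its VAF as measured in
    the reference (deep) data.  Bins are [e_i, e_{i+1}) with the final bin
    closed on the right.
    """
    edges = list(bin_edges)
    for vaf in ref_hc_vafs.values():
        if not 0.0 <= vaf <= 1.0:
            raise ValueError(f"VAF out of range: {vaf}")
    out = {}
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        last = i == len(edges) - 2
        members = {k for k, vaf in ref_hc_vafs.items()
                   if (lo <= vaf < hi) or (last and vaf == hi)}
        if members:
            out[(lo, hi)] = len(members & set(test)) / len(members)
        else:
            out[(lo, hi)] = None
    return out
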