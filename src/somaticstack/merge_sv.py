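"""Structural-variant size filtering and cross-caller BEDPE merging.

Events are matched with padded breakend-interval overlap (slop), identical
strand orientation, matching type, and reciprocal span overlap — the same
criteria ``bedtools pairtopair`` applies — and merged as connected components
of the match graph.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional

from .model import CALLER_PRIORITY_SV, BreakendPair

DEFAULT_MIN_SIZE = 500
DEFAULT_SLOP = 300
DEFAULT_RECIPROCAL = 0.5


def sv_span(sv: BreakendPair) -> Optional[int]:
    """Event span in bp using the outer interval bounds.

    Undefined (None) for interchromosomal events and insertions, whose
    genomic footprint is not an interval.
    """
    if not sv.is_intrachromosomal or sv.svtype in ("TRA", "INS"):
        return None
    return sv.end2 - sv.start1


def filter_min_size(svs: Iterable[BreakendPair], min_size: int = DEFAULT_MIN_SIZE) -> list:
    """Drop intrachromosomal events with span strictly below ``min_size``.

    Events with undefined span (translocations, insertions) are retained.
    """
    out = []
    for sv in svs:
        span = sv_span(sv)
        if span is not None and span < min_size:
            continue
        out.append(sv)
    return out


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return min(a_end, b_end) - max(a_start, b_start)


def sv_match(a: BreakendPair, b: BreakendPair,
             slop: int = DEFAULT_SLOP, reciprocal: float = DEFAULT_RECIPROCAL) -> bool:
    """Decide whether two SVs describe the same event.

    Requires matching type, identical strand orientation at both ends,
    slop-padded overlap of the corresponding breakend intervals on the same
    chromosomes, and — when both spans are defined — reciprocal span overlap
    of at least ``reciprocal`` of each event.
    """
    if a.svtype != b.svtype:
        return False
    if a.strand1 != b.strand1 or a.strand2 != b.strand2:
        return False
    if a.chrom1 != b.chrom1 or a.chrom2 != b.chrom2:
        return False
    if _overlap(a.start1 - slop, a.end1 + slop, b.start1 - slop, b.end1 + slop) <= 0:
        return False
    if _overlap(a.start2 - slop, a.end2 + slop, b.start2 - slop, b.end2 + slop) <= 0:
        return False
    span_a, span_b = sv_span(a), sv_span(b)
    if span_a is not None and span_b is not None:
        ov = _overlap(a.start1, a.end2, b.start1, b.end2)
        if ov < reciprocal * span_a or ov < reciprocal * span_b:
            return False
    return True


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_svs(svs: list, slop: int = DEFAULT_SLOP,
                reciprocal: float = DEFAULT_RECIPROCAL,
                match=sv_match) -> list:
    """Connected components of the match graph; returns lists of indices."""
    n = len(svs)
    uf = _UnionFind(n)
    buckets = {}
    for i, sv in enumerate(svs):
        key = (sv.chrom1, sv.chrom2, sv.svtype, sv.strand1, sv.strand2)
        buckets.setdefault(key, []).append(i)
    for idxs in buckets.values():
        idxs.sort(key=lambda i: svs[i].start1)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                # start1-sorted: once breakend-1 pads cannot overlap, no later j can match
                if svs[j].start1 - slop >= svs[i].end1 + slop:
                    break
                if match(svs[i], svs[j], slop=slop, reciprocal=reciprocal):
                    uf.union(i, j)
    comps = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: c[0])


def _representative(members: list) -> BreakendPair:
    prio = {c: i for i, c in enumerate(CALLER_PRIORITY_SV)}

    def rank(sv):
        best = min((prio.get(c, len(prio)) for c in sv.caller_support), default=len(prio))
        return (best, sv.chrom1, sv.start1, sv.chrom2, sv.start2)

    return min(members, key=rank)


def merge_sv_callsets(callsets: dict, slop: int = DEFAULT_SLOP,
                      reciprocal: float = DEFAULT_RECIPROCAL) -> list:
    """Merge per-caller SV callsets into consensus breakend pairs.

    Each connected component of the match graph over the pooled events
    becomes one record: coordinates from the highest-priority caller present
    (manta > lumpy > svaba), caller support the union over the component,
    split-read support the maximum reported.
    """
    pooled = []
    for caller in sorted(callsets):
        pooled.extend(callsets[caller])
    out = []
    for comp in cluster_svs(pooled, slop=slop, reciprocal=reciprocal):
        members = [pooled[i] for i in comp]
        rep = _representative(members).copy()
        rep.caller_support = set().union(*(m.caller_support for m in members))
        rep.filter_tags = set().union(*(m.filter_tags for m in members))
        tsr = [m.tumor_split_reads for m in members if m.tumor_split_reads is not None]
        nsr = [m.normal_split_reads for m in members if m.normal_split_reads is not None]
        rep.tumor_split_reads = max(tsr) if tsr else None
        rep.normal_split_reads = max(nsr) if nsr else None
        out.append(rep)
    return sorted(out, key=lambda s: (s.chrom1, s.start1, s.chrom2, s.start2, s.svtype))
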