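"""Panel-of-Normals construction and application, plus common-germline filters.

The PON catalogs positions (small variants) or events (SVs) recurrently
called across unrelated normal samples; anything matching an entry seen in
two or more individuals is tagged as a likely technical artifact.  Filters
annotate records with tags rather than deleting them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .merge_sv import cluster_svs, sv_match
from .model import BreakendPair, CNVSegment, SmallVariant

DEFAULT_MIN_INDIVIDUALS = 2
DEFAULT_SV_MAX_DISTANCE = 300
DEFAULT_GERMLINE_MAF = 0.01


@dataclass
class SmallPon:
    """Position-keyed small-variant panel: (chrom, pos) -> individual count."""

    site_counts: dict = field(default_factory=dict)

    def __contains__(self, site) -> bool:
        return site in self.site_counts

    def __len__(self) -> int:
        return len(self.site_counts)


@dataclass
class SvPon:
    """Merged SV panel; each event carries its distinct-individual count."""

    events: list = field(default_factory=list)  # (BreakendPair, n_individuals)


def build_small_pon(per_individual_sites: dict,
                    min_individuals: int = DEFAULT_MIN_INDIVIDUALS) -> SmallPon:
    """Count (chrom, pos) sites across individuals and keep recurrent ones.

    Each individual contributes a site at most once regardless of how many
    alleles it reported there; sites seen in ``min_individuals`` or more
    distinct individuals enter the panel.
    """
    counts = {}
    for _, variants in sorted(per_individual_sites.items()):
        seen = {(v.chrom, v.pos) for v in variants}
        for site in seen:
            counts[site] = counts.get(site, 0) + 1
    return SmallPon({s: n for s, n in counts.items() if n >= min_individuals})


def apply_small_pon(variants: Iterable[SmallVariant], pon: SmallPon) -> list:
    """Tag variants whose position is in the panel with ``PON``.

    Keying is by location only, not allele, so a different alternate allele
    at a panel site is still tagged.  Idempotent; nothing is deleted.
    """
    out = list(variants)
    for v in out:
        if (v.chrom, v.pos) in pon:
            v.filter_tags.add("PON")
    return out


def _pon_match(a, b, max_distance):
    if a.svtype != b.svtype or a.strand1 != b.strand1 or a.strand2 != b.strand2:
        return False
    if a.chrom1 != b.chrom1 or a.chrom2 != b.chrom2:
        return False
    return (abs(a.start1 - b.start1) <= max_distance
            and abs(a.start2 - b.start2) <= max_distance)


def build_sv_pon(per_individual_svs: dict,
                 max_distance: int = DEFAULT_SV_MAX_DISTANCE) -> SvPon:
    """Cluster normal-sample SV calls into a panel.

    Events merge (connected components) when they share type and strand
    orientation and both corresponding breakends lie within ``max_distance``
    of each other.  No minimum size is applied.  Each panel event records the
    number of distinct individuals contributing to its component.
    """
    pooled, owners = [], []
    for individual, svs in sorted(per_individual_svs.items()):
        for sv in svs:
            pooled.append(sv)
            owners.append(individual)

    def match(a, b, slop=None, reciprocal=None):
        return _pon_match(a, b, max_distance)

    events = []
    for comp in cluster_svs(pooled, slop=max_distance, reciprocal=0.0, match=match):
        members = [pooled[i] for i in comp]
        individuals = {owners[i] for i in comp}
        rep = members[0].copy()
        events.append((rep, len(individuals)))
    return SvPon(events)


def apply_sv_pon(svs: Iterable[BreakendPair], pon: SvPon,
                 min_individuals: int = DEFAULT_MIN_INDIVIDUALS,
                 slop: int = 300, reciprocal: float = 0.5) -> list:
    """Tag SVs matching a recurrent panel event with ``PON``.

    Matching reuses the cross-caller criteria (slop 300 bp, same strand
    orientation, 50% reciprocal overlap); only panel events seen in
    ``min_individuals`` or more individuals count.
    """
    out = list(svs)
    recurrent = [e for e, n in pon.events if n >= min_individuals]
    for sv in out:
        if any(sv_match(sv, e, slop=slop, reciprocal=reciprocal) for e in recurrent):
            sv.filter_tags.add("PON")
    return out


def germline_af_filter(variants: Iterable[SmallVariant],
                       threshold: float = DEFAULT_GERMLINE_MAF) -> list:
    """Tag small variants with population MAF >= threshold in any database."""
    out = list(variants)
    for v in out:
        if any(af >= threshold for af in v.population_af.values()):
            v.filter_tags.add("COMMON_GERMLINE")
    return out


def germline_sv_filter(svs: Iterable[BreakendPair], catalog: Iterable[BreakendPair],
                       slop: int = 300, reciprocal: float = 0.5) -> list:
    """Tag SVs matching a germline SV catalog with ``COMMON_GERMLINE``."""
    out = list(svs)
    catalog = list(catalog)
    for sv in out:
        if any(sv_match(sv, g, slop=slop, reciprocal=reciprocal) for g in catalog):
            sv.filter_tags.add("COMMON_GERMLINE")
    return out


def annotate_cnv_germline(segments: Iterable[CNVSegment],
                          catalog: Iterable[tuple]) -> list:
    """Mark CNV segments overlapping germline catalog intervals.

    Annotation only — segment categories and membership never change.
    ``catalog`` holds (chrom, start, end) intervals, 0-based half-open.
    """
    out = list(segments)
    by_chrom = {}
    for chrom, start, end in catalog:
        by_chrom.setdefault(chrom, []).append((start, end))
    for seg in out:
        for start, end in by_chrom.get(seg.chrom, ()):
            if start < seg.end and seg.start < end:
                seg.germline_overlap = True
                break
    return out
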