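"""Cross-caller consensus for SNVs, MNVs and indels.

Some callers emit adjacent substitutions as phased multi-nucleotide variants
(MNVs) while others emit the component SNVs.  Consensus is therefore computed
at SNV resolution: MNVs are decomposed before merging and re-constituted
afterwards only when every component SNV ends up with the same caller
support.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from .model import SmallVariant, VariantError

_mnv_counter = itertools.count()


@dataclass(frozen=True)
class MnvOrigin:
    """Provenance of an MNV call decomposed into SNVs."""

    origin_mnv_id: str
    caller: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if len(self.ref) != len(self.alt) or len(self.ref) < 2:
            raise VariantError("MNV origin requires equal-length alleles of length > 1")


def decompose_mnv(v: SmallVariant) -> tuple:
    """Split an MNV into per-position SNVs sharing an origin id.

    Positions where the reference and alternate base agree are silent and are
    not emitted.  Non-MNV input is returned unchanged with no origin.
    """
    if v.vtype != "MNV":
        return [v], None
    caller = next(iter(v.caller_support)) if v.caller_support else "unknown"
    origin_id = f"mnv_{caller}_{v.chrom}_{v.pos}_{v.ref}_{v.alt}_{next(_mnv_counter)}"
    origin = MnvOrigin(origin_id, caller, v.chrom, v.pos, v.ref, v.alt)
    parts = []
    for i, (rb, ab) in enumerate(zip(v.ref, v.alt)):
        if rb == ab:
            continue
        parts.append(SmallVariant(
            chrom=v.chrom, pos=v.pos + i, ref=rb, alt=ab,
            caller_support=set(v.caller_support),
            origin_mnv_id=origin_id,
            per_caller_counts=dict(v.per_caller_counts),
        ))
    return parts, origin


def decompose_callset(variants) -> tuple:
    """Decompose every MNV in a callset; returns (variants, origins)."""
    out, origins = [], []
    for v in variants:
        parts, origin = decompose_mnv(v)
        out.extend(parts)
        if origin is not None:
            origins.append(origin)
    return out, origins


def merge_small_callsets(callsets: dict) -> list:
    """Merge per-caller callsets on exact (chrom, pos, ref, alt) identity.

    Caller support is the union over callers reporting the key; per-caller
    reported counts are retained for later final-count selection.  MNVs must
    already be decomposed.
    """
    merged = {}
    for caller in sorted(callsets):
        for v in callsets[caller]:
            cur = merged.get(v.key)
            if cur is None:
                cur = v.copy()
                cur.caller_support = set(v.caller_support) or {caller}
                merged[v.key] = cur
            else:
                cur.caller_support |= v.caller_support or {caller}
                cur.per_caller_counts.update(v.per_caller_counts)
                if cur.origin_mnv_id is None:
                    cur.origin_mnv_id = v.origin_mnv_id
    return sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def reconstitute_mnvs(merged, origins) -> list:
    """Re-merge decomposed SNVs back into MNVs where support allows.

    For each origin MNV (longest first) the constituent SNVs are replaced by
    a single MNV record iff all constituents are present with identical
    caller support; each SNV is consumed by at most one origin.  Otherwise
    the constituents stay as individual SNVs.
    """
    by_key = {v.key: v for v in merged}
    consumed = set()
    out = []
    for origin in sorted(origins, key=lambda o: (-len(o.ref), o.chrom, o.pos, o.ref, o.alt, o.caller)):
        keys = [
            (origin.chrom, origin.pos + i, rb, ab)
            for i, (rb, ab) in enumerate(zip(origin.ref, origin.alt))
            if rb != ab
        ]
        if any(k not in by_key or k in consumed for k in keys):
            continue
        supports = [frozenset(by_key[k].caller_support) for k in keys]
        if len(set(supports)) != 1:
            continue
        consumed.update(keys)
        rep = by_key[keys[0]]
        mnv = SmallVariant(
            chrom=origin.chrom, pos=origin.pos, ref=origin.ref, alt=origin.alt,
            caller_support=set(supports[0]),
            per_caller_counts=dict(rep.per_caller_counts),
        )
        out.append(mnv)
    for v in merged:
        if v.key not in consumed:
            w = v.copy()
            w.origin_mnv_id = None
            out.append(w)
    return sorted(out, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))


def merge_small(callsets: dict) -> list:
    """decompose -> merge -> reconstitute, the full small-variant consensus."""
    decomposed, origins = {}, []
    for caller, vs in callsets.items():
        dvs, origs = decompose_callset(vs)
        decomposed[caller] = dvs
        origins.extend(origs)
    return reconstitute_mnvs(merge_small_callsets(decomposed), origins)
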