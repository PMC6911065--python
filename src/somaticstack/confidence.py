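"""High-confidence annotation of small variants and SVs.

A call is high confidence when two or more callers agree, or when a
single-caller call carries orthogonal evidence: targeted local-assembly
validation or small-SV corroboration for SNVs/indels; a nearby copy-number
changepoint or tumor-only split-read support for manta/lumpy SVs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .model import BreakendPair, SmallVariant

DEFAULT_MAX_CP_DIST = 1000
DEFAULT_MIN_SPLIT = 3


@dataclass
class SupportEvidence:
    """Orthogonal evidence consumed by the high-confidence rules."""

    #: small-variant keys confirmed by targeted re-calling around singletons
    lancet_validation: set = field(default_factory=set)
    #: small-variant keys corroborated by manta's small-SV output
    manta_small: set = field(default_factory=set)
    #: SV name -> (tumor split reads, normal split reads)
    splazers: dict = field(default_factory=dict)
    #: chrom -> sorted CNV boundary coordinates
    changepoints: dict = field(default_factory=dict)


def hc_small(v: SmallVariant, ev: SupportEvidence) -> bool:
    """High-confidence rule for SNVs/MNVs/indels."""
    if len(v.caller_support) >= 2:
        return True
    return len(v.caller_support) == 1 and (
        v.key in ev.lancet_validation or v.key in ev.manta_small
    )


def changepoint_distance(sv: BreakendPair, changepoints: dict) -> float:
    """Distance from the nearest breakend to the nearest CNV boundary.

    Breakend coordinate is the interval start; the minimum is taken over
    both breakends against boundaries on the same chromosome.  Infinite when
    no boundary shares a chromosome with either breakend.
    """
    best = math.inf
    for chrom, coord in ((sv.chrom1, sv.start1), (sv.chrom2, sv.start2)):
        for cp in changepoints.get(chrom, ()):
            best = min(best, abs(coord - cp))
    return best


def hc_sv(sv: BreakendPair, ev: SupportEvidence,
          max_cp_dist: int = DEFAULT_MAX_CP_DIST,
          min_split: int = DEFAULT_MIN_SPLIT) -> bool:
    """High-confidence rule for SVs.

    Two or more callers suffice.  A single-caller manta or lumpy call needs
    either a CNV changepoint within ``max_cp_dist`` bp of a breakend, or at
    least ``min_split`` split reads in the tumor with none in the normal.
    """
    if len(sv.caller_support) >= 2:
        return True
    if len(sv.caller_support) != 1 or not sv.caller_support <= {"manta", "lumpy"}:
        return False
    if changepoint_distance(sv, ev.changepoints) <= max_cp_dist:
        return True
    tsr = sv.tumor_split_reads
    nsr = sv.normal_split_reads
    if tsr is None:
        tsr, nsr = ev.splazers.get(sv.name, (None, None))
    return tsr is not None and tsr >= min_split and (nsr or 0) == 0


def write_support(ev: SupportEvidence, out_dir: str) -> None:
    """Persist orthogonal evidence as four small TSV files."""
    import os

    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    cols = ["chrom", "pos", "ref", "alt"]
    for attr in ("lancet_validation", "manta_small"):
        rows = [dict(zip(cols, key)) for key in sorted(getattr(ev, attr))]
        pd.DataFrame(rows, columns=cols).to_csv(
            os.path.join(out_dir, f"{attr}.tsv"), sep="\t", index=False)
    rows = [{"name": n, "tumor_sr": t, "normal_sr": s}
            for n, (t, s) in sorted(ev.splazers.items())]
    pd.DataFrame(rows, columns=["name", "tumor_sr", "normal_sr"]).to_csv(
        os.path.join(out_dir, "splazers.tsv"), sep="\t", index=False)
    rows = [{"chrom": c, "pos": p} for c in sorted(ev.changepoints)
            for p in ev.changepoints[c]]
    pd.DataFrame(rows, columns=["chrom", "pos"]).to_csv(
        os.path.join(out_dir, "changepoints.tsv"), sep="\t", index=False)


def read_support(in_dir: str) -> SupportEvidence:
    import os

    import pandas as pd

    ev = SupportEvidence()
    for attr in ("lancet_validation", "manta_small"):
        df = pd.read_csv(os.path.join(in_dir, f"{attr}.tsv"), sep="\t", dtype=str)
        getattr(ev, attr).update(
            (r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples(index=False))
    df = pd.read_csv(os.path.join(in_dir, "splazers.tsv"), sep="\t", dtype=str)
    for r in df.itertuples(index=False):
        ev.splazers[r.name] = (int(r.tumor_sr), int(r.normal_sr))
    df = pd.read_csv(os.path.join(in_dir, "changepoints.tsv"), sep="\t", dtype=str)
    for r in df.itertuples(index=False):
        ev.changepoints.setdefault(r.chrom, []).append(int(r.pos))
    for c in ev.changepoints:
        ev.changepoints[c].sort()
    return ev


def annotate_high_confidence(variants: Iterable[SmallVariant],
                             svs: Iterable[BreakendPair],
                             ev: SupportEvidence,
                             max_cp_dist: int = DEFAULT_MAX_CP_DIST,
                             min_split: int = DEFAULT_MIN_SPLIT) -> None:
    """Set ``high_confidence`` flags in place.

    High confidence is a tier within the somatic callset, so records outside
    AllSomatic are never flagged.
    """
    for v in variants:
        v.high_confidence = v.in_all_somatic() and hc_small(v, ev)
    for sv in svs:
        sv.high_confidence = sv.in_all_somatic() and hc_sv(
            sv, ev, max_cp_dist=max_cp_dist, min_split=min_split)
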