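"""Final allele-count selection and the count-based somatic filters.

Counts for SNVs and small indels come from a fragment-level pileup (unique
read-pairs, mapping and base quality >= 10); larger indels fall back to the
counts reported by the callers in priority order strelka2 > mutect2 >
lancet.  Large indels called only by svaba carry no counts because that
caller does not report a reference allele count.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .model import COUNT_FILTER_TAGS, SampleCounts, SmallVariant

DEFAULT_MQ_MIN = 10
DEFAULT_BQ_MIN = 10
#: Indels with net length change below this use pileup counts; at or above,
#: caller-reported counts.
INDEL_PILEUP_MAXLEN = 10
COUNT_CALLER_PRIORITY = ("strelka2", "mutect2", "lancet")

DEFAULT_TUMOR_VAF_MIN = 0.0001
DEFAULT_NORMAL_VAF_MAX = 0.2
DEFAULT_MIN_DEPTH = 2


@dataclass
class ReadEvidence:
    """One read's evidence at a locus in one sample."""

    fragment_id: str
    allele: str  # REF | ALT | OTHER
    mapping_quality: int
    base_quality: int
    is_duplicate: bool = False
    is_supplementary: bool = False
    is_qcfail: bool = False
    is_unmapped: bool = False

    @property
    def flagged(self) -> bool:
        return self.is_duplicate or self.is_supplementary or self.is_qcfail or self.is_unmapped


def pileup_counts(evidence: Iterable[ReadEvidence],
                  mq_min: int = DEFAULT_MQ_MIN,
                  bq_min: int = DEFAULT_BQ_MIN) -> SampleCounts:
    """Unique-fragment allele counts at one locus for one sample.

    Flagged reads (duplicate, supplementary, QC-fail, unmapped) and reads
    below the quality thresholds are excluded.  A read pair counts once; a
    pair whose mates disagree on the allele is dropped entirely.  Depth is
    the number of surviving fragments, including third-allele fragments.
    """
    fragments = {}
    for ev in evidence:
        if ev.flagged or ev.mapping_quality < mq_min or ev.base_quality < bq_min:
            continue
        fragments.setdefault(ev.fragment_id, set()).add(ev.allele)
    ref_c = alt_c = depth = 0
    for alleles in fragments.values():
        if len(alleles) > 1:
            continue  # mates disagree
        depth += 1
        allele = next(iter(alleles))
        if allele == "REF":
            ref_c += 1
        elif allele == "ALT":
            alt_c += 1
    return SampleCounts(ref_count=ref_c, alt_count=alt_c, depth=depth, source="PILEUP")


def read_evidence_table(path: str) -> dict:
    """Load a locus evidence TSV into {(chrom, pos, sample): [ReadEvidence]}.

    Columns: chrom, pos, sample, fragment_id, allele, mq, bq, flags — where
    flags is a comma list over {dup, supp, qcfail, unmapped} or '.'.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        flags = set() if row.flags == "." else set(row.flags.split(","))
        ev = ReadEvidence(
            fragment_id=row.fragment_id, allele=row.allele,
            mapping_quality=int(row.mq), base_quality=int(row.bq),
            is_duplicate="dup" in flags, is_supplementary="supp" in flags,
            is_qcfail="qcfail" in flags, is_unmapped="unmapped" in flags,
        )
        out.setdefault((row.chrom, int(row.pos), row.sample), []).append(ev)
    return out


def write_evidence_table(evidence: dict, path: str) -> None:
    """Write {(chrom, pos, ...): {"tumor": [...], "normal": [...]}} as TSV."""
    rows = []
    for key in sorted(evidence):
        chrom, pos = key[0], key[1]
        for sample in ("tumor", "normal"):
            for ev in evidence[key][sample]:
                flags = ",".join(f for f, on in (
                    ("dup", ev.is_duplicate), ("supp", ev.is_supplementary),
                    ("qcfail", ev.is_qcfail), ("unmapped", ev.is_unmapped)) if on) or "."
                rows.append({"chrom": chrom, "pos": pos, "sample": sample,
                             "fragment_id": ev.fragment_id, "allele": ev.allele,
                             "mq": ev.mapping_quality, "bq": ev.base_quality,
                             "flags": flags})
    pd.DataFrame(rows, columns=["chrom", "pos", "sample", "fragment_id",
                                "allele", "mq", "bq", "flags"]).to_csv(
        path, sep="\t", index=False)


def evidence_by_locus(table: dict) -> dict:
    """Regroup a read_evidence_table result into {(chrom, pos): {sample: [...]}}."""
    out = {}
    for (chrom, pos, sample), evs in table.items():
        locus = out.setdefault((chrom, pos), {"tumor": [], "normal": []})
        locus[sample].extend(evs)
    return out


def select_final_counts(v: SmallVariant, caller_counts: dict,
                        pileup: Optional[SampleCounts],
                        indel_pileup_maxlen: int = INDEL_PILEUP_MAXLEN) -> SampleCounts:
    """Choose the final counts for one sample of one variant.

    SNVs, MNVs and indels with net length change below ``indel_pileup_maxlen``
    take the pileup counts.  Larger indels and complex events take the first
    available caller-reported counts in priority order; if none of the
    priority callers reported the variant (svaba-only), no counts are kept.
    """
    use_pileup = (v.vtype in ("SNV", "MNV")
                  or (not v.is_complex and v.indel_length < indel_pileup_maxlen))
    if use_pileup:
        return pileup if pileup is not None else SampleCounts()
    for caller in COUNT_CALLER_PRIORITY:
        counts = caller_counts.get(caller)
        if counts is not None and counts.has_counts:
            return SampleCounts(ref_count=counts.ref_count, alt_count=counts.alt_count,
                                depth=counts.depth, source=caller.upper())
    return SampleCounts()


def assign_final_counts(v: SmallVariant,
                        tumor_pileup: Optional[SampleCounts] = None,
                        normal_pileup: Optional[SampleCounts] = None,
                        indel_pileup_maxlen: int = INDEL_PILEUP_MAXLEN) -> SmallVariant:
    """Set ``tumor_counts``/``normal_counts`` from pileup or caller reports."""
    tumor_cc = {c: tc for c, (tc, _) in v.per_caller_counts.items()}
    normal_cc = {c: nc for c, (_, nc) in v.per_caller_counts.items()}
    v.tumor_counts = select_final_counts(v, tumor_cc, tumor_pileup, indel_pileup_maxlen)
    v.normal_counts = select_final_counts(v, normal_cc, normal_pileup, indel_pileup_maxlen)
    return v


def apply_somatic_filters(variants: Iterable[SmallVariant],
                          tumor_vaf_min: float = DEFAULT_TUMOR_VAF_MIN,
                          normal_vaf_max: float = DEFAULT_NORMAL_VAF_MAX,
                          min_depth: int = DEFAULT_MIN_DEPTH) -> list:
    """Apply the count-based somatic filters, tagging failures.

    Tags: LOW_TUMOR_VAF (tumor VAF < 0.0001), HIGH_NORMAL_VAF (normal VAF >
    0.2), LOW_DEPTH (depth < 2 in either sample), NORMAL_GT_TUMOR (normal
    VAF > tumor VAF).  Records lacking counts in a sample get NO_COUNTS but
    stay in AllSomatic — they cannot be judged.  Idempotent.
    """
    out = list(variants)
    for v in out:
        v.filter_tags -= COUNT_FILTER_TAGS | {"NO_COUNTS"}
        t, n = v.tumor_counts, v.normal_counts
        if not t.has_counts or not n.has_counts:
            v.filter_tags.add("NO_COUNTS")
            continue
        if t.vaf is not None and t.vaf < tumor_vaf_min:
            v.filter_tags.add("LOW_TUMOR_VAF")
        if n.vaf is not None and n.vaf > normal_vaf_max:
            v.filter_tags.add("HIGH_NORMAL_VAF")
        if t.depth < min_depth or n.depth < min_depth:
            v.filter_tags.add("LOW_DEPTH")
        if t.vaf is not None and n.vaf is not None and n.vaf > t.vaf:
            v.filter_tags.add("NORMAL_GT_TUMOR")
    return out


def all_somatic(variants: Iterable[SmallVariant]) -> list:
    """The AllSomatic callset: records with no excluding filter tag."""
    return [v for v in variants if v.in_all_somatic()]
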