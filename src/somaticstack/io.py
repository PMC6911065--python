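"""Readers and writers for the formats the pipeline touches.

Small variants travel as VCF (pysam), structural variants as 16-column BEDPE,
copy-number segments and panel-of-normals lists as tab-separated tables.
Writing then reading any collection reproduces every typed field.
"""
from __future__ import annotations

import logging
import os
import re
from typing import Iterable, Optional

import pandas as pd
import pysam

from .model import (
    SMALL_CALLERS,
    SV_CALLERS,
    BreakendPair,
    CNVSegment,
    SampleCounts,
    SmallVariant,
    normalize_alleles,
)

log = logging.getLogger(__name__)

BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype",
    "callers", "filters", "hc", "splitreads_t", "splitreads_n",
]

SEGMENT_COLUMNS = ["chrom", "start", "end", "obs_log2", "adj_log2", "t_cn", "n_cn", "category"]

_BND_ALT = re.compile(r"^([ACGTNacgtn]*)([\[\]])([^\[\]]+)([\[\]])([ACGTNacgtn]*)$")


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# per-caller small-variant VCFs


def _sample_indices(vcf: pysam.VariantFile) -> tuple:
    samples = list(vcf.header.samples)
    if not samples:
        return None, None
    upper = [s.upper() for s in samples]
    ti = upper.index("TUMOR") if "TUMOR" in upper else 0
    ni = upper.index("NORMAL") if "NORMAL" in upper else (1 if len(samples) > 1 else None)
    return samples[ti], samples[ni] if ni is not None else None


def _counts_from_sample(sample) -> SampleCounts:
    try:
        ad = sample.get("AD")
        dp = sample.get("DP")
    except (KeyError, AttributeError):
        return SampleCounts()
    if ad is None or ad[0] is None:
        return SampleCounts()
    ref_c, alt_c = int(ad[0]), int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
    depth = int(dp) if dp is not None else ref_c + alt_c
    src = sample.get("CS") or "CALLER"
    return SampleCounts(ref_count=ref_c, alt_count=alt_c, depth=depth, source=str(src))


def read_caller_small_vcf(
    path: str,
    caller: str,
    include_nonpass: bool = False,
    reference: Optional[dict] = None,
) -> list:
    """Read one caller's somatic VCF into normalized :class:`SmallVariant`s.

    Multi-allelic records are split into one variant per alternate allele;
    alleles are parsimony-trimmed and, when ``reference`` (a mapping
    contig -> sequence) is supplied, left-aligned so cross-caller keys match.
    Only PASS records are kept unless ``include_nonpass``.
    """
    if caller not in SMALL_CALLERS:
        raise ValueError(f"unknown small-variant caller {caller!r}; expected one of {SMALL_CALLERS}")
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    tname, nname = _sample_indices(vcf)
    out = []
    try:
        records = list(vcf)
    except (ValueError, OSError) as exc:
        raise ParseError(f"malformed record in {path}: {exc}") from exc
    for rec in records:
        filters = list(rec.filter.keys())
        is_pass = not filters or filters == ["PASS"]
        if not is_pass and not include_nonpass:
            continue
        if rec.alts is None:
            continue
        for alt in rec.alts:
            if alt is None or "<" in alt or "[" in alt or "]" in alt or alt == "*":
                continue
            seq = reference.get(rec.chrom) if reference else None
            pos, ref, alt_n = normalize_alleles(rec.pos, rec.ref, alt, seq)
            v = SmallVariant(chrom=rec.chrom, pos=pos, ref=ref, alt=alt_n,
                             caller_support={caller})
            if tname is not None:
                tc = _counts_from_sample(rec.samples[tname])
                nc = _counts_from_sample(rec.samples[nname]) if nname else SampleCounts()
                if tc.has_counts or nc.has_counts:
                    v.per_caller_counts[caller] = (tc, nc)
            out.append(v)
    return out


# ---------------------------------------------------------------------------
# SV VCF -> BEDPE


def _bnd_strands(alt: str) -> tuple:
    """Breakend strands from bracket notation.

    t[p[ -> (+,-); t]p] -> (+,+); ]p]t -> (-,-); [p[t -> (-,+).
    """
    m = _BND_ALT.match(alt)
    if not m:
        raise ParseError(f"unparseable BND ALT {alt!r}")
    leading, bracket, locus, _, trailing = m.groups()
    t_first = bool(leading)
    s1 = "+" if t_first else "-"
    if t_first:
        s2 = "+" if bracket == "]" else "-"
    else:
        s2 = "+" if bracket == "[" else "-"
    chrom2, pos2 = locus.rsplit(":", 1)
    return s1, s2, chrom2, int(pos2)


_SVTYPE_STRANDS = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INS": ("+", "-"), "INV": ("+", "+")}


def _interval(pos0: int, ci) -> tuple:
    if ci is None:
        return pos0, pos0 + 1
    lo, hi = int(ci[0]), int(ci[1])
    return pos0 + lo, pos0 + hi + 1


def read_sv_vcf_as_bedpe(path: str, caller: str) -> list:
    """Read an SV VCF (symbolic or BND notation) into :class:`BreakendPair`s.

    BND mates are paired via MATEID and emitted once; unpaired mates are
    dropped with a warning.  Confidence intervals come from CIPOS/CIEND when
    present, else single-base intervals.
    """
    if caller not in SV_CALLERS:
        raise ValueError(f"unknown SV caller {caller!r}; expected one of {SV_CALLERS}")
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF {path}: {exc}") from exc
    out = []
    bnd = {}
    n_unpaired = 0
    for rec in vcf:
        svtype = rec.info.get("SVTYPE")
        if svtype == "BND":
            bnd[rec.id] = rec
            continue
        if svtype not in _SVTYPE_STRANDS:
            continue
        end = rec.info.get("END", rec.stop)
        s1, s2 = _SVTYPE_STRANDS[svtype]
        start1, end1 = _interval(rec.pos - 1, rec.info.get("CIPOS"))
        start2, end2 = _interval(int(end) - 1, rec.info.get("CIEND"))
        out.append(BreakendPair(rec.chrom, start1, end1, rec.chrom, start2, end2,
                                s1, s2, svtype, caller_support={caller},
                                name=rec.id or "."))
    seen = set()
    for rid, rec in bnd.items():
        if rid in seen:
            continue
        mate_id = rec.info.get("MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0]
        mate = bnd.get(mate_id)
        if mate is None:
            n_unpaired += 1
            continue
        seen.add(rid)
        seen.add(mate_id)
        s1, s2, chrom2, pos2 = _bnd_strands(rec.alts[0])
        start1, end1 = _interval(rec.pos - 1, rec.info.get("CIPOS"))
        start2, end2 = _interval(pos2 - 1, mate.info.get("CIPOS"))
        if chrom2 != rec.chrom:
            svtype = "TRA"
        else:
            svtype = {("+", "-"): "DEL", ("-", "+"): "DUP"}.get((s1, s2), "INV")
        out.append(BreakendPair(rec.chrom, start1, end1, chrom2, start2, end2,
                                s1, s2, svtype, caller_support={caller},
                                name=rid or "."))
    if n_unpaired:
        log.warning("%d unpaired BND mate record(s) dropped in %s", n_unpaired, path)
    return out


# ---------------------------------------------------------------------------
# merged small-variant VCF (pipeline output)


def _merged_header(variants: Iterable[SmallVariant], contigs: Optional[dict] = None):
    header = pysam.VariantHeader()
    vs = list(variants)
    if contigs is None:
        contigs = {}
        for v in vs:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref) + 1000)
    for name, length in contigs.items():
        header.contigs.add(name, length=int(length))
    header.info.add("CALLERS", ".", "String", "Callers supporting the variant")
    header.info.add("HC", 1, "Integer", "1 if the variant is high confidence")
    header.info.add("OMNV", 1, "String", "Identifier of the originating MNV call")
    header.info.add("PAF", ".", "String", "Population allele frequencies as db:af")
    header.formats.add("AD", "R", "Integer", "Unique fragment counts for ref,alt alleles")
    header.formats.add("DP", 1, "Integer", "Fragment depth")
    header.formats.add("CS", 1, "String", "Source of the final allele counts")
    tags = sorted({t for v in vs for t in v.filter_tags})
    for t in tags:
        header.filters.add(t, None, None, f"Filter tag {t}")
    header.add_sample("TUMOR")
    header.add_sample("NORMAL")
    return header, vs


def write_small_vcf(variants: Iterable[SmallVariant], path: str,
                    contigs: Optional[dict] = None) -> None:
    header, vs = _merged_header(variants, contigs)
    order = {c: i for i, c in enumerate(header.contigs)}
    vs.sort(key=lambda v: (order.get(v.chrom, 1 << 30), v.pos, v.ref, v.alt))
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in vs:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["CALLERS"] = ",".join(sorted(v.caller_support))
            rec.info["HC"] = 1 if v.high_confidence else 0
            if v.origin_mnv_id:
                rec.info["OMNV"] = v.origin_mnv_id
            if v.population_af:
                rec.info["PAF"] = ",".join(
                    f"{db}:{af:.6g}" for db, af in sorted(v.population_af.items())
                )
            if v.filter_tags:
                for t in sorted(v.filter_tags):
                    rec.filter.add(t)
            else:
                rec.filter.add("PASS")
            for sample, counts in (("TUMOR", v.tumor_counts), ("NORMAL", v.normal_counts)):
                rec.samples[sample]["CS"] = counts.source
                if counts.has_counts:
                    rec.samples[sample]["AD"] = (counts.ref_count, counts.alt_count)
                    rec.samples[sample]["DP"] = counts.depth
            out.write(rec)


def read_small_vcf(path: str) -> list:
    """Read a merged VCF written by :func:`write_small_vcf`."""
    vcf = pysam.VariantFile(path)
    out = []
    for rec in vcf:
        filters = [f for f in rec.filter.keys() if f != "PASS"]
        paf = rec.info.get("PAF")
        if isinstance(paf, str):
            paf = (paf,)
        pop = {}
        for item in paf or ():
            db, af = item.split(":")
            pop[db] = float(af)
        counts = {}
        for sample in ("TUMOR", "NORMAL"):
            s = rec.samples[sample]
            src = s.get("CS")
            if src is None or src == "NONE":
                counts[sample] = SampleCounts()
            else:
                ad = s.get("AD")
                counts[sample] = SampleCounts(
                    ref_count=int(ad[0]), alt_count=int(ad[1]),
                    depth=int(s.get("DP")), source=str(src))
        omnv = rec.info.get("OMNV")
        out.append(SmallVariant(
            chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
            caller_support=set(rec.info["CALLERS"]) if isinstance(rec.info["CALLERS"], set)
            else set(",".join(rec.info["CALLERS"]).split(","))
            if isinstance(rec.info["CALLERS"], tuple)
            else set(rec.info["CALLERS"].split(",")),
            origin_mnv_id=str(omnv) if omnv else None,
            tumor_counts=counts["TUMOR"], normal_counts=counts["NORMAL"],
            filter_tags=set(filters),
            high_confidence=bool(rec.info.get("HC", 0)),
            population_af=pop,
        ))
    return out


# ---------------------------------------------------------------------------
# BEDPE


def write_bedpe(svs: Iterable[BreakendPair], path: str) -> None:
    rows = []
    for sv in sorted(svs, key=lambda s: (s.chrom1, s.start1, s.chrom2, s.start2)):
        rows.append({
            "chrom1": sv.chrom1, "start1": sv.start1, "end1": sv.end1,
            "chrom2": sv.chrom2, "start2": sv.start2, "end2": sv.end2,
            "name": sv.name, "score": ".",
            "strand1": sv.strand1, "strand2": sv.strand2, "svtype": sv.svtype,
            "callers": ",".join(sorted(sv.caller_support)) or ".",
            "filters": ",".join(sorted(sv.filter_tags)) or "PASS",
            "hc": int(sv.high_confidence),
            "splitreads_t": "." if sv.tumor_split_reads is None else sv.tumor_split_reads,
            "splitreads_n": "." if sv.normal_split_reads is None else sv.normal_split_reads,
        })
    pd.DataFrame(rows, columns=BEDPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_bedpe(path: str) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(BreakendPair(
            chrom1=row.chrom1, start1=int(row.start1), end1=int(row.end1),
            chrom2=row.chrom2, start2=int(row.start2), end2=int(row.end2),
            strand1=row.strand1, strand2=row.strand2, svtype=row.svtype,
            caller_support=set() if row.callers == "." else set(row.callers.split(",")),
            filter_tags=set() if row.filters == "PASS" else set(row.filters.split(",")),
            high_confidence=bool(int(row.hc)),
            tumor_split_reads=None if row.splitreads_t == "." else int(row.splitreads_t),
            normal_split_reads=None if row.splitreads_n == "." else int(row.splitreads_n),
            name=row.name,
        ))
    return out


# ---------------------------------------------------------------------------
# segment tables


def write_segments(segments: Iterable[CNVSegment], path: str) -> None:
    rows = []
    for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
        rows.append({
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "obs_log2": repr(s.obs_log2),
            "adj_log2": "." if s.adj_log2 is None else repr(s.adj_log2),
            "t_cn": "." if s.t_cn is None else repr(s.t_cn),
            "n_cn": s.n_cn, "category": s.category,
        })
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path: str) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        out.append(CNVSegment(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            obs_log2=float(row.obs_log2),
            adj_log2=None if row.adj_log2 == "." else float(row.adj_log2),
            t_cn=None if row.t_cn == "." else float(row.t_cn),
            n_cn=int(row.n_cn), category=row.category,
        ))
    return out


# ---------------------------------------------------------------------------
# panel-of-normals tables


def write_small_pon(pon, path: str) -> None:
    rows = [{"chrom": c, "pos": p, "n_individuals": n}
            for (c, p), n in sorted(pon.site_counts.items())]
    pd.DataFrame(rows, columns=["chrom", "pos", "n_individuals"]).to_csv(
        path, sep="\t", index=False)


def read_small_pon(path: str):
    from .pon import SmallPon

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int, "n_individuals": int})
    return SmallPon({(r.chrom, int(r.pos)): int(r.n_individuals)
                     for r in df.itertuples(index=False)})


def write_merged_outputs(variants, svs, segments, out_dir: str,
                         contigs: Optional[dict] = None) -> dict:
    """Write the three merged collections under ``out_dir``.

    Returns the paths written: small variants as VCF, SVs as BEDPE, CNV
    segments as a tab-separated table.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "small": os.path.join(out_dir, "somatic.small.vcf"),
        "sv": os.path.join(out_dir, "somatic.sv.bedpe"),
        "cnv": os.path.join(out_dir, "somatic.cnv.tsv"),
    }
    write_small_vcf(variants, paths["small"], contigs)
    write_bedpe(svs, paths["sv"])
    write_segments(segments, paths["cnv"])
    return paths
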