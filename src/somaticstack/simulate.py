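"""Synthetic truth sets, mock caller outputs, mixtures and error-profiled reads.

The generator stands in for the cell-line benchmarking data: it fabricates a
somatic truth set on small contigs, draws fragment-level evidence for
tumor/normal mixtures of any tumor read fraction, turns the evidence into
per-caller callsets through parameterized sensitivity/false-positive
profiles, and synthesizes aligned reads with a configurable 192-channel
context error profile.  Every generator is a pure function of its parameters
and seed.

Mixing is simulated at the fragment-count level: at a locus with ``c_alt``
mutant of ``c_tot`` tumor copies, a mixture with tumor read fraction
``t_frac`` has expected VAF

    v_mix = t_frac * c_alt / (t_frac * c_tot + (1 - t_frac) * n_cn)

which is the copy-number-weighted allele dosage of the pooled reads.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

from .cnv import expected_log2
from .confidence import SupportEvidence
from .counts import ReadEvidence
from .mismatch import BASES, revcomp
from .model import BreakendPair, CNVSegment, SampleCounts, SmallVariant

#: tumor/normal coverage pairings of the default purity dilution series
#: (tumor 10..70X against normal 70..10X; t_frac 0.125 .. 0.875)
DEFAULT_PURITY_LADDER = tuple((t, 80 - t) for t in range(10, 80, 10))
#: default coverage ladder pairings
DEFAULT_COVERAGE_LADDER = tuple(
    (t, n) for t in (10, 20, 30, 40, 60, 80, 90) for n in (10, 20, 30, 40)
)


class ConfigError(ValueError):
    """Inconsistent simulation parameters."""


@dataclass
class SimParams:
    """Knobs of the truth-set generator."""

    contigs: dict = field(default_factory=lambda: {"chr1": 120_000, "chr2": 80_000})
    n_snv: int = 120
    n_mnv: int = 12
    n_indel: int = 40
    n_sv: int = 10
    indel_max: int = 14
    mnv_max: int = 3
    segments_per_contig: int = 4
    copy_number_choices: tuple = (1, 2, 2, 2, 3, 4)
    clone_fractions: tuple = (1.0,)
    #: when set, pure-tumor VAFs are drawn Beta(a, b) directly instead of
    #: from the copy-state model
    vaf_beta: Optional[tuple] = None
    sv_size_range: tuple = (1_000, 20_000)

    def validate(self) -> None:
        if not self.contigs or any(l <= 0 for l in self.contigs.values()):
            raise ConfigError("contigs must be nonempty with positive lengths")
        if any(not 0 < f <= 1 for f in self.clone_fractions):
            raise ConfigError("clone fractions must be in (0, 1]")
        if min(self.copy_number_choices) < 0:
            raise ConfigError("copy numbers must be >= 0")


@dataclass
class TruthVariant:
    """A somatic small variant with its copy state and clonality."""

    chrom: str
    pos: int
    ref: str
    alt: str
    c_alt: float
    c_tot: float
    clone_frac: float

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pure_vaf(self) -> float:
        return self.clone_frac * self.c_alt / self.c_tot


@dataclass
class TruthSet:
    reference: dict
    variants: list
    svs: list
    segments: list
    t_ploidy: float
    clone_fractions: tuple

    def small_keys(self) -> set:
        return {v.key for v in self.variants}


def v_mix(t_frac: float, c_alt: float, c_tot: float, n_cn: int = 2) -> float:
    """Expected mixture VAF from copy-number-weighted allele dosage."""
    denom = t_frac * c_tot + (1.0 - t_frac) * n_cn
    return t_frac * c_alt / denom if denom > 0 else 0.0


def _random_sequence(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _tile_segments(rng, chrom: str, length: int, n: int, cn_choices) -> list:
    cuts = sorted(rng.choice(np.arange(1, length), size=n - 1, replace=False)) if n > 1 else []
    bounds = [0] + [int(c) for c in cuts] + [length]
    segs = []
    for s, e in zip(bounds, bounds[1:]):
        t_cn = int(rng.choice(cn_choices))
        segs.append(CNVSegment(chrom=chrom, start=s, end=e, obs_log2=0.0, t_cn=t_cn))
    return segs


def simulate_truth(params: SimParams, seed: int) -> TruthSet:
    """Generate a reproducible somatic truth set.

    Contigs are tiled by copy-number segments with integer tumor copy
    numbers; small variants land only where at least one tumor copy exists,
    and their pure-tumor VAFs reflect clone fraction and copy state.  Segment
    ``obs_log2`` is the pure-tumor expectation for its copy number.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    reference = {c: _random_sequence(rng, l) for c, l in params.contigs.items()}
    segments = []
    for chrom, length in params.contigs.items():
        segments.extend(_tile_segments(rng, chrom, length,
                                       params.segments_per_contig,
                                       params.copy_number_choices))
    total_len = sum(s.length for s in segments)
    t_ploidy = sum(s.t_cn * s.length for s in segments) / total_len
    for seg in segments:
        seg.obs_log2 = expected_log2(seg.t_cn, 1.0, t_ploidy) if seg.t_cn > 0 else -8.0

    def seg_at(chrom, pos0):
        for s in segments:
            if s.chrom == chrom and s.start <= pos0 < s.end:
                return s
        raise AssertionError("position outside segments")

    contig_names = list(params.contigs)
    lengths = np.array([params.contigs[c] for c in contig_names], dtype=float)
    weights = lengths / lengths.sum()
    used = set()
    variants = []

    def draw_locus(span):
        for _ in range(10_000):
            chrom = contig_names[int(rng.choice(len(contig_names), p=weights))]
            pos0 = int(rng.integers(2, params.contigs[chrom] - span - 2))
            if any((chrom, p) in used for p in range(pos0 - 1, pos0 + span + 1)):
                continue
            if seg_at(chrom, pos0).t_cn < 1:
                continue
            for p in range(pos0 - 1, pos0 + span + 1):
                used.add((chrom, p))
            return chrom, pos0
        raise ConfigError("could not place variants; contigs too small")

    def copy_state(chrom, pos0):
        clone = float(rng.choice(params.clone_fractions))
        if params.vaf_beta is not None:
            a, b = params.vaf_beta
            vaf = float(rng.beta(a, b))
            return 2.0 * vaf, 2.0, 1.0
        c_tot = float(seg_at(chrom, pos0).t_cn)
        return 1.0, c_tot, clone

    for _ in range(params.n_snv):
        chrom, pos0 = draw_locus(1)
        ref = reference[chrom][pos0]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        c_alt, c_tot, clone = copy_state(chrom, pos0)
        variants.append(TruthVariant(chrom, pos0 + 1, ref, alt, c_alt, c_tot, clone))
    for _ in range(params.n_mnv):
        span = int(rng.integers(2, params.mnv_max + 1))
        chrom, pos0 = draw_locus(span)
        ref = reference[chrom][pos0:pos0 + span]
        alt = "".join(str(rng.choice([b for b in BASES if b != rb])) for rb in ref)
        c_alt, c_tot, clone = copy_state(chrom, pos0)
        variants.append(TruthVariant(chrom, pos0 + 1, ref, alt, c_alt, c_tot, clone))
    for _ in range(params.n_indel):
        dlen = int(rng.integers(1, params.indel_max + 1))
        chrom, pos0 = draw_locus(dlen + 1)
        anchor = reference[chrom][pos0]
        if rng.random() < 0.5:  # deletion
            ref = reference[chrom][pos0:pos0 + 1 + dlen]
            alt = anchor
        else:
            ref = anchor
            alt = anchor + _random_sequence(rng, dlen)
        c_alt, c_tot, clone = copy_state(chrom, pos0)
        variants.append(TruthVariant(chrom, pos0 + 1, ref, alt, c_alt, c_tot, clone))

    svs = []
    for i in range(params.n_sv):
        chrom = contig_names[int(rng.choice(len(contig_names), p=weights))]
        clen = params.contigs[chrom]
        size = int(rng.integers(params.sv_size_range[0], min(params.sv_size_range[1], clen // 2)))
        start = int(rng.integers(0, clen - size - 1))
        svtype = str(rng.choice(["DEL", "DUP", "INV"]))
        s1, s2 = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+")}[svtype]
        svs.append(BreakendPair(chrom, start, start + 1, chrom, start + size,
                                start + size + 1, s1, s2, svtype,
                                name=f"truth_sv_{i}"))
    variants.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return TruthSet(reference=reference, variants=variants, svs=svs,
                    segments=segments, t_ploidy=t_ploidy,
                    clone_fractions=params.clone_fractions)


# ---------------------------------------------------------------------------
# fragment-level evidence for a tumor/normal mixture


def simulate_sample_counts(truth: TruthSet, tumor_depth: float, normal_depth: float,
                           t_frac: float, seed: int,
                           flag_rate: float = 0.01, lowq_rate: float = 0.01) -> dict:
    """Draw per-locus fragment evidence for a mixed tumor and a pure normal.

    Tumor-sample alt fragments are Binomial(depth, v_mix) with v_mix from the
    copy-weighted dosage at the locus; the normal sample is germline-only
    (no somatic alt fragments).  A small fraction of fragments carries
    excluded flags or sub-threshold qualities.
    """
    if tumor_depth <= 0 or normal_depth <= 0:
        raise ConfigError("depths must be positive")
    if not 0.0 <= t_frac <= 1.0:
        raise ConfigError("t_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = {}

    def fragments(label, n_alt, n_tot):
        evs = []
        for i in range(n_tot):
            allele = "ALT" if i < n_alt else "REF"
            mq, bq = 60, 35
            dup = supp = False
            if rng.random() < lowq_rate:
                if rng.random() < 0.5:
                    mq = int(rng.integers(0, 10))
                else:
                    bq = int(rng.integers(0, 10))
            if rng.random() < flag_rate:
                dup = True
            evs.append(ReadEvidence(fragment_id=f"{label}_{i}", allele=allele,
                                    mapping_quality=mq, base_quality=bq,
                                    is_duplicate=dup))
        return evs

    for v in truth.variants:
        vm = v_mix(t_frac, v.clone_frac * v.c_alt, v.c_tot)
        d_t = int(rng.poisson(tumor_depth))
        a_t = int(rng.binomial(d_t, min(vm, 1.0))) if d_t else 0
        d_n = int(rng.poisson(normal_depth))
        out[v.key] = {
            "tumor": fragments(f"t_{v.chrom}_{v.pos}", a_t, d_t),
            "normal": fragments(f"n_{v.chrom}_{v.pos}", 0, d_n),
        }
    return out


# ---------------------------------------------------------------------------
# mock caller outputs


_DEFAULT_CALLS = {
    "strelka2": {"SNV", "INDEL"},
    "mutect2": {"SNV", "MNV", "INDEL"},
    "lancet": {"SNV", "MNV", "INDEL"},
    "svaba": {"INDEL"},
}


@dataclass
class CallerProfile:
    """Detection behavior of one mock caller.

    ``sensitivity(alt)`` = s_max * alt / (alt + half_k): a saturating curve
    in the drawn alt fragment count (identically s_max when half_k = 0).
    False positives are placed uniformly at fp_per_mb, with alternate
    alleles reweighted by a 96-channel trinucleotide context bias when one
    is supplied (e.g. an elevated T>G weight for a NovaSeq-like profile).
    """

    name: str
    s_max: float = 0.98
    half_k: float = 3.0
    fp_per_mb: float = 0.5
    context_bias: Optional[dict] = None
    count_noise: float = 1.5
    coord_jitter: int = 20
    calls: Optional[set] = None

    def __post_init__(self):
        if not 0.0 <= self.s_max <= 1.0:
            raise ConfigError("s_max must be in [0, 1]")
        if self.calls is None:
            self.calls = set(_DEFAULT_CALLS.get(self.name, {"SNV", "MNV", "INDEL"}))

    def sensitivity(self, alt_count: float) -> float:
        if self.half_k == 0:
            return self.s_max
        if alt_count <= 0:
            return 0.0
        return self.s_max * alt_count / (alt_count + self.half_k)


def default_small_profiles(**overrides) -> dict:
    profs = {name: CallerProfile(name=name) for name in _DEFAULT_CALLS}
    profs.update(overrides)
    return profs


def default_sv_profiles(**overrides) -> dict:
    profs = {name: CallerProfile(name=name, calls={"DEL", "DUP", "INV", "INS", "TRA"})
             for name in ("manta", "lumpy", "svaba")}
    profs.update(overrides)
    return profs


@dataclass
class SimulatedCallsets:
    small: dict
    sv: dict
    support: SupportEvidence


def _noisy_counts(rng, counts: SampleCounts, sd: float, source: str) -> SampleCounts:
    def jitter(x):
        return max(0, int(round(x + rng.normal(0.0, sd)))) if sd > 0 else x

    alt = jitter(counts.alt_count)
    ref = jitter(counts.ref_count)
    return SampleCounts(ref_count=ref, alt_count=alt, depth=max(ref + alt, counts.depth),
                        source=source)


def simulate_caller_outputs(truth: TruthSet, evidence: dict, profiles: dict,
                            seed: int, sv_profiles: Optional[dict] = None,
                            tumor_depth: float = 80.0, t_frac: float = 1.0) -> SimulatedCallsets:
    """Turn truth + evidence into per-caller callsets and orthogonal evidence.

    Detection is Bernoulli per variant per caller at the sensitivity for the
    drawn alt count; callers that cannot represent MNVs emit the component
    SNVs instead.  Caller-reported counts are the true tallies plus
    reporting noise.  Fabricated support evidence mirrors what the targeted
    validation caller, small-SV calls and a split-read tool would supply.
    """
    rng = np.random.default_rng(seed)
    genome_mb = sum(len(s) for s in truth.reference.values()) / 1e6
    small = {}
    for name in sorted(profiles):
        prof = profiles[name]
        calls = []
        for v in truth.variants:
            vtype = ("SNV" if len(v.ref) == len(v.alt) == 1
                     else "MNV" if len(v.ref) == len(v.alt) else "INDEL")
            emits_decomposed = vtype == "MNV" and "MNV" not in prof.calls and "SNV" in prof.calls
            if vtype not in prof.calls and not emits_decomposed:
                continue
            evs = evidence.get(v.key)
            alt_t = sum(1 for e in evs["tumor"] if e.allele == "ALT") if evs else 0
            if rng.random() >= prof.sensitivity(alt_t):
                continue
            d_t = len(evs["tumor"]) if evs else 0
            d_n = len(evs["normal"]) if evs else 0
            tc = _noisy_counts(rng, SampleCounts(d_t - alt_t, alt_t, d_t, source="CALLER"),
                               prof.count_noise, "CALLER")
            nc = SampleCounts(d_n, 0, d_n, source="CALLER")
            if emits_decomposed:
                for i, (rb, ab) in enumerate(zip(v.ref, v.alt)):
                    if rb == ab:
                        continue
                    calls.append(SmallVariant(v.chrom, v.pos + i, rb, ab,
                                              caller_support={name},
                                              per_caller_counts={name: (tc, nc)}))
            else:
                calls.append(SmallVariant(v.chrom, v.pos, v.ref, v.alt,
                                          caller_support={name},
                                          per_caller_counts={name: (tc, nc)}))
        n_fp = int(rng.poisson(prof.fp_per_mb * genome_mb))
        for _ in range(n_fp):
            chrom, ref_seq = sorted(truth.reference.items())[
                int(rng.integers(0, len(truth.reference)))]
            pos0 = int(rng.integers(1, len(ref_seq) - 1))
            ref = ref_seq[pos0]
            alt = _biased_alt(rng, ref_seq, pos0, prof.context_bias)
            if alt is None:
                continue
            alt_c = 1 + int(rng.poisson(2))
            d = max(alt_c + 1, int(rng.poisson(tumor_depth)))
            tc = SampleCounts(d - alt_c, alt_c, d, source="CALLER")
            nc = SampleCounts(d, 0, d, source="CALLER")
            calls.append(SmallVariant(chrom, pos0 + 1, ref, alt,
                                      caller_support={name},
                                      per_caller_counts={name: (tc, nc)}))
        small[name] = calls

    sv = {}
    support = SupportEvidence()
    for seg in truth.segments:
        support.changepoints.setdefault(seg.chrom, [])
        for b in (seg.start, seg.end):
            if b not in support.changepoints[seg.chrom]:
                support.changepoints[seg.chrom].append(b)
    for chrom in support.changepoints:
        support.changepoints[chrom].sort()

    sv_profiles = sv_profiles or {}
    for name in sorted(sv_profiles):
        prof = sv_profiles[name]
        calls = []
        for tsv in truth.svs:
            if tsv.svtype not in prof.calls:
                continue
            s = int(rng.poisson(max(tumor_depth * t_frac * 0.4, 0.01)))
            if rng.random() >= prof.sensitivity(s):
                continue
            j = prof.coord_jitter
            call = tsv.copy()
            call.caller_support = {name}
            call.name = f"{name}_{tsv.name}"
            if j > 0:
                d1 = int(rng.integers(-j, j + 1))
                d2 = int(rng.integers(-j, j + 1))
                call.start1 = max(0, call.start1 + d1)
                call.end1 = call.start1 + 1
                call.start2 = max(call.start1 + 1, call.start2 + d2)
                call.end2 = call.start2 + 1
            calls.append(call)
            support.splazers[call.name] = (s, 0)
        sv[name] = calls

    # targeted re-calling confirms most true single-caller variants
    all_small_keys = {v.key for calls in small.values() for v in calls}
    for v in truth.variants:
        if len(v.ref) == len(v.alt):  # SNV/MNV: validation keys at SNV resolution
            keys = [(v.chrom, v.pos + k, r2, a2)
                    for k, (r2, a2) in enumerate(zip(v.ref, v.alt)) if r2 != a2]
        else:
            keys = [v.key]
        for key in keys:
            if key in all_small_keys and rng.random() < 0.9:
                support.lancet_validation.add(key)
        if len(v.ref) != len(v.alt) and rng.random() < 0.5:
            support.manta_small.add(v.key)
    return SimulatedCallsets(small=small, sv=sv, support=support)


def _biased_alt(rng, ref_seq: str, pos0: int, context_bias: Optional[dict]):
    ref = ref_seq[pos0]
    if ref not in BASES:
        return None
    alts = [b for b in BASES if b != ref]
    if context_bias is None or pos0 == 0 or pos0 == len(ref_seq) - 1:
        return str(rng.choice(alts))
    five, three = ref_seq[pos0 - 1], ref_seq[pos0 + 1]
    if five not in BASES or three not in BASES:
        return str(rng.choice(alts))
    weights = []
    for alt in alts:
        r, a, f, t = ref, alt, five, three
        if r in "AG":  # look up on the pyrimidine strand
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            r, a, f, t = comp[r], comp[a], comp[t], comp[f]
        weights.append(context_bias.get((r, a, f, t), 0.0))
    w = np.array(weights, dtype=float)
    if w.sum() == 0:
        return None
    return str(rng.choice(alts, p=w / w.sum()))


# ---------------------------------------------------------------------------
# error-profiled aligned reads


class ErrorProfile:
    """Per-base substitution rates over the 192 read-strand channels."""

    def __init__(self, rates: dict):
        self.rates = dict(rates)

    @classmethod
    def uniform(cls, total_rate: float) -> "ErrorProfile":
        from .mismatch import CHANNELS_192

        # a site offers 3 alt channels, so per-channel rate is a third of the
        # per-base rate
        return cls({ch: total_rate / 3.0 for ch in CHANNELS_192})

    @classmethod
    def from_weights(cls, total_rate: float, weights: dict) -> "ErrorProfile":
        z = sum(weights.values())
        # weights are channel proportions; a uniform-composition reference
        # exposes each (ref, 5', 3') combination at 1/64 of sites, so scale
        # by 64 to make the average per-base error rate equal total_rate
        return cls({ch: total_rate * 64.0 * w / z for ch, w in weights.items()})

    def site_rates(self, ref: str, five: str, three: str) -> dict:
        return {alt: self.rates.get((ref, alt, five, three), 0.0)
                for alt in BASES if alt != ref}


def simulate_reads(reference: str, depth: float, error_profile: ErrorProfile,
                   read_length: int = 150, seed: int = 0,
                   reverse_frac: float = 0.5, g_run_inflation: float = 0.0,
                   base_qual: int = 35, lowq_rate: float = 0.0,
                   dup_rate: float = 0.0, contig: str = "chr1") -> tuple:
    """Synthesize aligned reads tiling a reference with context errors.

    Errors are drawn in read-strand orientation from the 192-channel profile,
    so the mismatch profiler recovers the profile directly.  With
    ``g_run_inflation`` > 0, a fraction of reads has a G homopolymer run
    written into it, emulating run-length artifacts.  Returns (reads,
    header) with pysam alignment records; all reads align full-length.
    """
    if len(reference) < read_length:
        raise ConfigError("reference shorter than the read length")
    rng = np.random.default_rng(seed)
    header = pysam.AlignmentHeader.from_references([contig], [len(reference)])
    n_reads = int(math.ceil(depth * len(reference) / read_length))
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, len(reference) - read_length + 1))
        template = reference[start:start + read_length]
        is_reverse = rng.random() < reverse_frac
        work = revcomp(template) if is_reverse else template
        bases = list(work)
        for j in range(1, read_length - 1):
            site = error_profile.site_rates(work[j], work[j - 1], work[j + 1])
            p_err = sum(site.values())
            if p_err > 0 and rng.random() < p_err:
                alts, probs = zip(*site.items())
                probs = np.array(probs) / p_err
                bases[j] = str(rng.choice(alts, p=probs))
        if g_run_inflation > 0 and rng.random() < g_run_inflation:
            run = 3 + int(rng.geometric(0.3))
            j0 = int(rng.integers(0, read_length - run))
            bases[j0:j0 + run] = "G" * run
        read_seq = "".join(bases)
        a = pysam.AlignedSegment(header=header)
        a.query_name = f"frag_{i}"
        a.query_sequence = revcomp(read_seq) if is_reverse else read_seq
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigartuples = [(0, read_length)]
        a.is_reverse = is_reverse
        a.is_read1 = i % 2 == 0
        a.is_read2 = not a.is_read1
        a.is_paired = True
        quals = np.full(read_length, base_qual, dtype=np.uint8)
        if lowq_rate > 0:
            mask = rng.random(read_length) < lowq_rate
            quals[mask] = 5
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in quals))
        if dup_rate > 0 and rng.random() < dup_rate:
            a.is_duplicate = True
        reads.append(a)
    return reads, header


def read_strand_sequence(read) -> str:
    """The sequence as sequenced (reverse-complemented for reverse reads)."""
    return revcomp(read.query_sequence) if read.is_reverse else read.query_sequence
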