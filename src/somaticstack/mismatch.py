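"""Read-level mismatch and homopolymer profiling.

Sequencing platforms leave characteristic error fingerprints: the rate and
trinucleotide context of single-base mismatches to the reference, and the
distribution of homopolymer run lengths within reads.  Mismatches are
represented in *read-strand* orientation — for a reverse-strand alignment
the reference base, read base and flanking context are all
reverse-complemented — giving 12 substitution types x 16 contexts = 192
channels, collapsible to the conventional 96 (6 types x 16 contexts).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pysam

DEFAULT_MQ_MIN = 10
DEFAULT_BQ_MIN = 10
BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: all 192 (ref, alt, 5', 3') channels in canonical order
CHANNELS_192 = [
    (r, a, f, t)
    for r in BASES for a in BASES if a != r
    for f in BASES for t in BASES
]
CHANNELS_96 = [(r, a, f, t) for (r, a, f, t) in CHANNELS_192 if r in "CT"]


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class MismatchCounts:
    """Mismatch tallies over the 192 read-strand channels."""

    counts: dict = field(default_factory=dict)
    eligible_bases: int = 0
    read_index: str = "combined"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def channel_fractions(self) -> dict:
        t = self.total
        return {ch: n / t for ch, n in self.counts.items()} if t else {}


def longest_runs(seq: str) -> dict:
    """Length of the longest homopolymer run of each base; N breaks runs."""
    runs = {b: 0 for b in BASES}
    prev, length = None, 0
    for ch in seq.upper():
        if ch == "N":
            prev, length = None, 0
            continue
        if ch not in runs:
            raise ValueError(f"unexpected symbol {ch!r} in read sequence")
        if ch == prev:
            length += 1
        else:
            prev, length = ch, 1
        runs[ch] = max(runs[ch], length)
    return runs


def run_length_distribution(reads_by_index: dict) -> dict:
    """Empirical distribution of longest-run length per (base, read index).

    ``reads_by_index`` maps a read-index label (R1/R2/combined) to an
    iterable of read sequences.  Returns {(base, length, read_index):
    fraction}; fractions sum to 1 within each (base, read_index).
    """
    out = {}
    for idx, seqs in reads_by_index.items():
        tallies = {b: {} for b in BASES}
        n = 0
        for seq in seqs:
            n += 1
            for b, length in longest_runs(seq).items():
                tallies[b][length] = tallies[b].get(length, 0) + 1
        for b, hist in tallies.items():
            for length, count in hist.items():
                out[(b, length, idx)] = count / n
    return out


def _matched_positions(read):
    """(query_pos, ref_pos) for M/=/X cigar positions, excluding indel-adjacent bases."""
    matched = []
    bad = set()
    next_bad = False
    qpos = rpos = 0
    rpos = read.reference_start
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                if next_bad:
                    bad.add(len(matched))
                    next_bad = False
                matched.append((qpos + k, rpos + k))
            qpos += length
            rpos += length
        elif op == 1:  # I
            if matched:
                bad.add(len(matched) - 1)
            next_bad = True
            qpos += length
        elif op == 2 or op == 3:  # D, N
            if op == 2:
                if matched:
                    bad.add(len(matched) - 1)
                next_bad = True
            rpos += length
        elif op == 4:  # S
            qpos += length
        # H, P consume nothing relevant
    return matched, bad


def profile_mismatches(alignments: Iterable, reference,
                       mq_min: int = DEFAULT_MQ_MIN,
                       bq_min: int = DEFAULT_BQ_MIN,
                       read_index: str = "combined") -> MismatchCounts:
    """Tally read-strand mismatches against the reference.

    Duplicate, unmapped, supplementary and QC-failed reads are skipped, as
    are reads below ``mq_min``.  Eligible positions are aligned match
    positions with base quality >= ``bq_min``, both reference flanks present,
    and no N in base or context; indel-adjacent bases are excluded.
    ``reference`` is a contig-name -> sequence mapping (or a bare sequence
    for single-contig data).
    """
    result = MismatchCounts(read_index=read_index)
    for read in alignments:
        if (read.is_unmapped or read.is_duplicate or read.is_supplementary
                or read.is_qcfail or read.mapping_quality < mq_min):
            continue
        if read_index == "R1" and not read.is_read1:
            continue
        if read_index == "R2" and not read.is_read2:
            continue
        refseq = reference[read.reference_name] if isinstance(reference, dict) else reference
        if read.reference_end > len(refseq):
            raise ValueError(
                f"reference {read.reference_name} shorter than alignment span of {read.query_name}")
        seq = read.query_sequence
        quals = read.query_qualities
        matched, bad = _matched_positions(read)
        matched_set = set(matched)
        for i, (qpos, rpos) in enumerate(matched):
            if i in bad:  # indel-adjacent
                continue
            # context-less positions (read ends, alignment-block edges) are
            # ineligible: both neighbors must be aligned too
            if (qpos - 1, rpos - 1) not in matched_set or (qpos + 1, rpos + 1) not in matched_set:
                continue
            if rpos == 0 or rpos == len(refseq) - 1:
                continue
            if quals is not None and quals[qpos] < bq_min:
                continue
            rb = refseq[rpos].upper()
            ab = seq[qpos].upper()
            five, three = refseq[rpos - 1].upper(), refseq[rpos + 1].upper()
            if read.is_reverse:
                rb, ab = _COMP[rb], _COMP[ab]
                five, three = _COMP[refseq[rpos + 1].upper()], _COMP[refseq[rpos - 1].upper()]
            if any(b not in BASES for b in (rb, ab, five, three)):
                continue
            result.eligible_bases += 1
            if ab != rb:
                ch = (rb, ab, five, three)
                result.counts[ch] = result.counts.get(ch, 0) + 1
    return result


def collapse_to_six(counts: MismatchCounts) -> MismatchCounts:
    """Collapse 12 substitution types to the 6 pyrimidine-reference types.

    Purine-reference channels are added into their reverse complements
    (alleles complemented, 5'/3' context swapped and complemented).  Total
    count and eligible bases are conserved.
    """
    out = MismatchCounts(eligible_bases=counts.eligible_bases,
                         read_index=counts.read_index)
    for (r, a, f, t), n in counts.counts.items():
        if r in "AG":
            r, a = _COMP[r], _COMP[a]
            f, t = _COMP[t], _COMP[f]
        ch = (r, a, f, t)
        out.counts[ch] = out.counts.get(ch, 0) + n
    return out


def mismatch_rate(counts: MismatchCounts) -> Optional[float]:
    """Total mismatches per eligible base; None when nothing was eligible."""
    if counts.eligible_bases == 0:
        return None
    return counts.total / counts.eligible_bases


def downsample_reads(reads: list, genome_size: int, target_depth: float = 8.0,
                     seed: int = 0, current_depth: Optional[float] = None) -> list:
    """Uniform fragment-level subsampling to an expected target depth.

    Fragments (reads sharing a query name) are kept or dropped together,
    each with probability target/current.
    """
    reads = list(reads)
    if current_depth is None:
        current_depth = sum(len(r.query_sequence or "") for r in reads) / genome_size
    if target_depth > current_depth:
        raise ValueError(f"target depth {target_depth} exceeds current {current_depth:.2f}")
    p = target_depth / current_depth
    rng = np.random.default_rng(seed)
    names = sorted({r.query_name for r in reads})
    keep = {n for n in names if rng.random() < p}
    return [r for r in reads if r.query_name in keep]


def read_sam(path: str) -> tuple:
    """Load alignments from a SAM file; returns (reads, header)."""
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        reads = list(fh)
        return reads, fh.header


def counts_to_matrix(counts: MismatchCounts, collapsed: bool = False) -> "np.ndarray":
    """Channel counts as a vector in canonical channel order (192 or 96)."""
    channels = CHANNELS_96 if collapsed else CHANNELS_192
    return np.array([counts.counts.get(ch, 0) for ch in channels], dtype=float)
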