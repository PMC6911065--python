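"""Domain types shared by every pipeline stage.

Coordinate conventions: small variants are 1-based (VCF); breakend pairs and
copy-number segments are 0-based half-open (BED/BEDPE).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

SMALL_CALLERS = ("strelka2", "mutect2", "lancet", "svaba")
SV_CALLERS = ("manta", "lumpy", "svaba")

#: Priority used when one caller's record must represent a merged event and
#: when caller-reported allele counts are chosen for large indels.
CALLER_PRIORITY_SMALL = ("strelka2", "mutect2", "lancet", "svaba")
CALLER_PRIORITY_SV = ("manta", "lumpy", "svaba")

SV_TYPES = ("DEL", "DUP", "INV", "INS", "TRA")

#: Count-based filter tags; a record carrying any of these is excluded from
#: the AllSomatic callset.
COUNT_FILTER_TAGS = frozenset(
    {"LOW_TUMOR_VAF", "HIGH_NORMAL_VAF", "LOW_DEPTH", "NORMAL_GT_TUMOR"}
)
EXCLUDING_TAGS = COUNT_FILTER_TAGS | {"PON", "COMMON_GERMLINE"}


class VariantError(ValueError):
    """An invalid variant record."""


def classify_alleles(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as SNV, MNV or INDEL."""
    if ref == alt:
        raise VariantError(f"ref == alt ({ref})")
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    return "INDEL"


@dataclass
class SampleCounts:
    """Final allele counts for one sample at one locus.

    ``ref_count``/``alt_count`` are unique fragment (read-pair) counts;
    ``depth`` counts all surviving fragments including those supporting a
    third allele.  ``source`` records where the numbers came from.
    """

    ref_count: int = 0
    alt_count: int = 0
    depth: int = 0
    vaf: Optional[float] = None
    source: str = "NONE"

    def __post_init__(self) -> None:
        if self.source != "NONE":
            denom = self.ref_count + self.alt_count
            self.vaf = self.alt_count / denom if denom > 0 else None
        else:  # no count source: counts are meaningless
            self.ref_count = self.alt_count = self.depth = 0
            self.vaf = None

    @property
    def has_counts(self) -> bool:
        return self.source != "NONE"


@dataclass
class SmallVariant:
    """One SNV, MNV or indel with its caller support and filter state."""

    chrom: str
    pos: int  # 1-based position of the first altered base
    ref: str
    alt: str
    caller_support: set = field(default_factory=set)
    origin_mnv_id: Optional[str] = None
    tumor_counts: SampleCounts = field(default_factory=SampleCounts)
    normal_counts: SampleCounts = field(default_factory=SampleCounts)
    filter_tags: set = field(default_factory=set)
    high_confidence: bool = False
    population_af: dict = field(default_factory=dict)
    #: caller -> (tumor SampleCounts, normal SampleCounts) as reported by that
    #: caller; retained through the merge for final count selection.
    per_caller_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"pos must be >= 1, got {self.pos}")
        self.vtype  # validates ref != alt

    @property
    def vtype(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def indel_length(self) -> int:
        """Net allele-length change (0 for SNV/MNV)."""
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_complex(self) -> bool:
        """Both alleles longer than one base with unequal lengths."""
        return len(self.ref) > 1 and len(self.alt) > 1 and len(self.ref) != len(self.alt)

    def in_all_somatic(self) -> bool:
        """AllSomatic membership: no count/PON/germline filter tag."""
        return not (self.filter_tags & EXCLUDING_TAGS)

    def copy(self) -> "SmallVariant":
        return replace(
            self,
            caller_support=set(self.caller_support),
            filter_tags=set(self.filter_tags),
            population_af=dict(self.population_af),
            per_caller_counts=dict(self.per_caller_counts),
        )


@dataclass
class BreakendPair:
    """A structural variant as a pair of breakend confidence intervals.

    Intervals are 0-based half-open.  Intrachromosomal events are stored with
    breakend 1 upstream of breakend 2.
    """

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    strand1: str
    strand2: str
    svtype: str
    caller_support: set = field(default_factory=set)
    tumor_split_reads: Optional[int] = None
    normal_split_reads: Optional[int] = None
    filter_tags: set = field(default_factory=set)
    high_confidence: bool = False
    name: str = "."

    def __post_init__(self) -> None:
        if self.end1 <= self.start1 or self.end2 <= self.start2:
            raise VariantError("breakend intervals must satisfy start < end")
        if self.svtype not in SV_TYPES:
            raise VariantError(f"unknown svtype {self.svtype!r}")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise VariantError("strands must be '+' or '-'")
        if self.chrom1 == self.chrom2 and self.start2 < self.start1:
            self.start1, self.start2 = self.start2, self.start1
            self.end1, self.end2 = self.end2, self.end1
            self.strand1, self.strand2 = self.strand2, self.strand1

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    def in_all_somatic(self) -> bool:
        return not (self.filter_tags & EXCLUDING_TAGS)

    def copy(self) -> "BreakendPair":
        return replace(
            self,
            caller_support=set(self.caller_support),
            filter_tags=set(self.filter_tags),
        )


@dataclass
class CNVSegment:
    """A copy-number segment with observed and purity-adjusted log2 ratios."""

    chrom: str
    start: int
    end: int
    obs_log2: float
    adj_log2: Optional[float] = None
    t_cn: Optional[float] = None
    n_cn: int = 2
    category: str = "UNDEFINED"
    flags: set = field(default_factory=set)
    germline_overlap: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise VariantError("segment must satisfy start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PurityMixtureSpec:
    """A tumor/normal read mixture and the tumor purity it implies.

    Mixing a fraction ``t_frac`` of tumor-library reads with normal-library
    reads dilutes tumor DNA according to the ploidies of the two genomes:

        T_purity = T_frac * N_ploidy
                   / ((1 - T_frac) * T_ploidy + T_frac * N_ploidy)
    """

    t_frac: float
    t_ploidy: float
    n_ploidy: float = 2.0
    t_purity: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_frac <= 1.0:
            raise ValueError("t_frac must be in [0, 1]")
        if self.t_ploidy <= 0 or self.n_ploidy <= 0:
            raise ValueError("ploidies must be positive")
        num = self.t_frac * self.n_ploidy
        den = (1.0 - self.t_frac) * self.t_ploidy + num
        self.t_purity = num / den if den > 0 else 0.0


@dataclass
class EvalCounts:
    """TP/FP/FN tallies with derived precision, recall and F1.

    ``ignored`` counts test calls that matched the permissive reference set
    but not its high-confidence subset; they enter neither numerator nor
    denominator.  Metrics are ``None`` when their denominator is zero.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    ignored: int = 0

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2.0 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "ignored": self.ignored,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def normalize_alleles(pos, ref, alt, seq=None):
    """Left-align and parsimony-trim an allele pair.

    ``seq`` is the reference contig sequence (indexable, 0-based) and is
    required only for left-alignment of indels; without it the alleles are
    trimmed but not shifted.  Returns ``(pos, ref, alt)`` with ``pos``
    1-based.  Identical cross-caller representations of the same indel reduce
    to the same key, which the consensus merge depends on.
    """
    if ref == alt:
        raise VariantError("cannot normalize ref == alt")
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (
            ref[-1] == alt[-1]
            and (len(ref) == 1 or len(alt) == 1)
            and seq is not None
            and pos > 1
        ):
            prev = seq[pos - 2].upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def default_n_cn(chrom: str, sex: str = "female") -> int:
    """Normal copy number for a contig: 2 on autosomes, 1 on X/Y in males."""
    name = chrom.removeprefix("chr")
    if name in ("X", "Y") and sex == "male":
        return 1
    if name == "Y":
        return 0 if sex == "female" else 1
    return 2
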