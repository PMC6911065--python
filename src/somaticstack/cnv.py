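"""CNV categorization and purity/ploidy adjustment of log2 copy ratios.

Segmenters report the log2 tumor/normal depth ratio of the bulk sample; in
an impure tumor every somatic copy-number change is attenuated toward zero.
Given the tumor purity and average ploidies, the observed ratio inverts to
an absolute tumor copy number

    T_CN = T_ploidy * N_CN * (2^Obs_log2 - (1 - T_purity)) / (N_ploidy * T_purity)

from which a purity-free ratio is recomputed:

    Adj_log2 = log2((T_CN / T_ploidy) * (N_ploidy / N_CN))

Categorization uses fixed thresholds chosen so a single-copy change in a
diploid genome at 30% purity is still detected.
"""
from __future__ import annotations

import math
from typing import Iterable

from .model import CNVSegment, PurityMixtureSpec

AMP_THRESHOLD = 0.2
DEL_THRESHOLD = -0.235


def categorize(log2_value: float,
               amp_threshold: float = AMP_THRESHOLD,
               del_threshold: float = DEL_THRESHOLD) -> str:
    """AMP above the gain threshold, DEL below the loss threshold (strict)."""
    if not isinstance(log2_value, (int, float)) or not math.isfinite(log2_value):
        return "UNDEFINED"
    if log2_value > amp_threshold:
        return "AMP"
    if log2_value < del_threshold:
        return "DEL"
    return "NEUTRAL"


def purity_from_mixture(t_frac: float, t_ploidy: float, n_ploidy: float = 2.0) -> float:
    """Tumor purity implied by mixing a read fraction ``t_frac`` from the tumor.

    Reads are drawn in proportion to DNA content, so a tumor of higher ploidy
    contributes more reads per cell and the cell-level purity is below the
    read fraction.
    """
    return PurityMixtureSpec(t_frac=t_frac, t_ploidy=t_ploidy, n_ploidy=n_ploidy).t_purity


def tumor_copy_number(obs_log2: float, t_purity: float, t_ploidy: float,
                      n_ploidy: float = 2.0, n_cn: int = 2) -> float:
    """Absolute tumor copy number implied by an observed log2 ratio.

    Can be non-positive when the observed ratio is lower than pure normal
    contamination allows (2^obs <= 1 - purity); callers should flag, not
    clamp, such segments.
    """
    if not 0.0 < t_purity <= 1.0:
        raise ValueError("t_purity must be in (0, 1]")
    if t_ploidy <= 0 or n_ploidy <= 0:
        raise ValueError("ploidies must be positive")
    return (t_ploidy * n_cn * (2.0 ** obs_log2 - (1.0 - t_purity))) / (n_ploidy * t_purity)


def expected_log2(t_cn: float, t_purity: float, t_ploidy: float,
                  n_ploidy: float = 2.0, n_cn: int = 2) -> float:
    """Forward model: observed log2 ratio for a segment of tumor copy number t_cn.

    Exact algebraic inverse of :func:`tumor_copy_number`: tumor cells
    contribute depth in proportion to t_cn normalized by the tumor's average
    ploidy, admixed normal cells contribute their full diploid-normalized
    share.
    """
    ratio = t_purity * t_cn * n_ploidy / (t_ploidy * n_cn) + (1.0 - t_purity)
    if ratio <= 0:
        raise ValueError("non-positive expected depth ratio")
    return math.log2(ratio)


def adjust_log2(seg: CNVSegment, t_purity: float, t_ploidy: float,
                n_ploidy: float = 2.0,
                amp_threshold: float = AMP_THRESHOLD,
                del_threshold: float = DEL_THRESHOLD) -> CNVSegment:
    """Set ``t_cn`` and ``adj_log2`` on a segment and re-categorize it.

    A non-positive inferred copy number leaves ``adj_log2`` undefined; such
    segments are categorized DEL and flagged NONPOS_TCN.  At purity 1 the
    adjustment is the identity on ``obs_log2``.
    """
    t_cn = tumor_copy_number(seg.obs_log2, t_purity, t_ploidy, n_ploidy, seg.n_cn)
    seg.t_cn = t_cn
    if t_cn <= 0:
        seg.adj_log2 = None
        seg.category = "DEL"
        seg.flags.add("NONPOS_TCN")
    else:
        seg.adj_log2 = math.log2((t_cn / t_ploidy) * (n_ploidy / seg.n_cn))
        seg.category = categorize(seg.adj_log2, amp_threshold, del_threshold)
    return seg


def categorize_segments(segments: Iterable[CNVSegment],
                        amp_threshold: float = AMP_THRESHOLD,
                        del_threshold: float = DEL_THRESHOLD) -> list:
    """Categorize each segment from its active log2 value (adjusted if set)."""
    out = list(segments)
    for seg in out:
        active = seg.adj_log2 if seg.adj_log2 is not None else seg.obs_log2
        if "NONPOS_TCN" not in seg.flags:
            seg.category = categorize(active, amp_threshold, del_threshold)
    return out


def adjust_segments(segments: Iterable[CNVSegment], t_purity: float, t_ploidy: float,
                    n_ploidy: float = 2.0) -> list:
    return [adjust_log2(s, t_purity, t_ploidy, n_ploidy) for s in segments]
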