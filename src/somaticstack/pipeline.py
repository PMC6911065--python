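"""End-to-end orchestration of the post-calling stages.

Stage order is fixed: small-variant merge -> SV merge -> panel-of-normals ->
common-germline filter -> final allele counts -> count-based somatic filters
-> high-confidence annotation -> CNV categorization/adjustment.  Filters tag
records instead of deleting them, so the AllSomatic and HighConfidence tiers
are views over one annotated collection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from . import cnv, counts as counts_mod, pon as pon_mod
from .confidence import SupportEvidence, annotate_high_confidence
from .config import DEFAULTS
from .merge_small import merge_small
from .merge_sv import filter_min_size, merge_sv_callsets

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    variants: list = field(default_factory=list)
    svs: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)

    @property
    def all_somatic(self) -> list:
        return [v for v in self.variants if v.in_all_somatic()]

    @property
    def all_somatic_svs(self) -> list:
        return [s for s in self.svs if s.in_all_somatic()]

    @property
    def high_confidence(self) -> list:
        return [v for v in self.variants if v.high_confidence]

    @property
    def high_confidence_svs(self) -> list:
        return [s for s in self.svs if s.high_confidence]


def run_stages(small_callsets: dict,
               sv_callsets: Optional[dict] = None,
               segments: Optional[list] = None,
               pileup_evidence: Optional[dict] = None,
               support: Optional[SupportEvidence] = None,
               small_pon=None,
               sv_pon=None,
               germline_sv_catalog=None,
               cnv_germline_catalog=None,
               purity: Optional[float] = None,
               ploidy: Optional[float] = None,
               config: Optional[dict] = None) -> PipelineResult:
    """Run the post-calling stack on in-memory caller outputs."""
    cfg = dict(DEFAULTS)
    if config:
        cfg.update(config)
    support = support or SupportEvidence()
    res = PipelineResult(segments=list(segments or []))

    res.variants = merge_small(small_callsets)
    res.stage_counts["merged_small"] = len(res.variants)

    svs = []
    for caller, calls in (sv_callsets or {}).items():
        svs.extend(filter_min_size(calls, cfg["sv_min_size"]))
    by_caller = {}
    for sv in svs:
        for c in sv.caller_support:
            by_caller.setdefault(c, []).append(sv)
    res.svs = merge_sv_callsets(by_caller, slop=cfg["sv_slop"],
                                reciprocal=cfg["sv_reciprocal"])
    res.stage_counts["merged_sv"] = len(res.svs)

    if small_pon is not None:
        pon_mod.apply_small_pon(res.variants, small_pon)
    else:
        log.info("small-variant PON stage skipped (no panel supplied)")
    if sv_pon is not None:
        pon_mod.apply_sv_pon(res.svs, sv_pon,
                             min_individuals=cfg["pon_min_individuals"],
                             slop=cfg["sv_slop"], reciprocal=cfg["sv_reciprocal"])
    else:
        log.info("SV PON stage skipped (no panel supplied)")

    pon_mod.germline_af_filter(res.variants, threshold=cfg["germline_maf"])
    if germline_sv_catalog is not None:
        pon_mod.germline_sv_filter(res.svs, germline_sv_catalog,
                                   slop=cfg["sv_slop"], reciprocal=cfg["sv_reciprocal"])
    if cnv_germline_catalog is not None:
        pon_mod.annotate_cnv_germline(res.segments, cnv_germline_catalog)

    locus_index = {}
    for key, ev in (pileup_evidence or {}).items():
        locus_index[key] = ev
        locus_index.setdefault((key[0], key[1]), ev)
    for v in res.variants:
        ev = locus_index.get(v.key) or locus_index.get((v.chrom, v.pos))
        tp = np_ = None
        if ev is not None:
            tp = counts_mod.pileup_counts(ev["tumor"], cfg["pileup_mq"], cfg["pileup_bq"])
            np_ = counts_mod.pileup_counts(ev["normal"], cfg["pileup_mq"], cfg["pileup_bq"])
        counts_mod.assign_final_counts(v, tp, np_, cfg["pileup_indel_maxlen"])
    counts_mod.apply_somatic_filters(res.variants,
                                     tumor_vaf_min=cfg["tumor_vaf_min"],
                                     normal_vaf_max=cfg["normal_vaf_max"],
                                     min_depth=cfg["min_depth"])
    res.stage_counts["all_somatic"] = len(res.all_somatic)

    annotate_high_confidence(res.variants, res.svs, support,
                             max_cp_dist=cfg["hc_changepoint_dist"],
                             min_split=cfg["hc_min_split_reads"])
    res.stage_counts["high_confidence"] = len(res.high_confidence)

    if purity is not None and ploidy is not None:
        cnv.adjust_segments(res.segments, purity, ploidy)
    cnv.categorize_segments(res.segments,
                            amp_threshold=cfg["amp_threshold"],
                            del_threshold=cfg["del_threshold"])
    res.stage_counts["segments"] = len(res.segments)
    return res


def run_purity_ladder(params=None, ladder=None, seeds=range(10),
                      normal_depth: float = 40.0, config: Optional[dict] = None) -> dict:
    """Recall of the consensus callsets and of each mock caller along a
    purity dilution series.

    For every (tumor, normal) coverage pairing the truth set is held fixed
    per seed while fragment evidence, caller detection and the whole stack
    are re-drawn.  Recall is measured against the truth at SNV-decomposed
    resolution.  Returns {t_frac: {"hc": [...], "all_somatic": [...],
    "callers": {name: [...]}}} with one entry per seed.
    """
    from .evaluation import expand_to_snv_keys
    from .simulate import (DEFAULT_PURITY_LADDER, SimParams,
                           default_small_profiles, default_sv_profiles,
                           simulate_caller_outputs, simulate_sample_counts,
                           simulate_truth)

    params = params or SimParams()
    ladder = ladder or DEFAULT_PURITY_LADDER
    out = {}
    for t_cov, n_cov in ladder:
        t_frac = t_cov / (t_cov + n_cov)
        entry = {"hc": [], "all_somatic": [], "callers": {}}
        for seed in seeds:
            truth = simulate_truth(params, seed)
            truth_keys = expand_to_snv_keys(truth.small_keys())
            mix_depth = t_cov + n_cov
            evidence = simulate_sample_counts(truth, mix_depth, normal_depth,
                                              t_frac, seed * 1000 + t_cov)
            sim = simulate_caller_outputs(truth, evidence, default_small_profiles(),
                                          seed * 1000 + t_cov + 1,
                                          sv_profiles=default_sv_profiles(),
                                          tumor_depth=mix_depth, t_frac=t_frac)
            res = run_stages(sim.small, sim.sv, support=sim.support,
                             pileup_evidence=evidence, config=config)
            hc = expand_to_snv_keys({v.key for v in res.high_confidence})
            asm = expand_to_snv_keys({v.key for v in res.all_somatic})
            entry["hc"].append(len(hc & truth_keys) / len(truth_keys))
            entry["all_somatic"].append(len(asm & truth_keys) / len(truth_keys))
            for caller, calls in sim.small.items():
                keys = expand_to_snv_keys({v.key for v in calls})
                entry["callers"].setdefault(caller, []).append(
                    len(keys & truth_keys) / len(truth_keys))
        out[t_frac] = entry
    return out
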