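# Methods

This note documents the models, conventions and numerical choices behind
`somaticstack`, and what the synthetic-data generator does and does not
emulate.

## Data model and conventions

Small variants are stored 1-based (VCF convention); breakend pairs and
copy-number segments 0-based half-open (BED convention), matching the native
convention of each format a stage touches. Filters never delete records:
they add tags (`PON`, `COMMON_GERMLINE`, `LOW_TUMOR_VAF`, `HIGH_NORMAL_VAF`,
`LOW_DEPTH`, `NORMAL_GT_TUMOR`, `NO_COUNTS`), and the **AllSomatic** callset
is defined as the records carrying none of the excluding tags. This keeps an
audit trail and makes the high-confidence tier (`HighConfidence ⊆
AllSomatic`, enforced at annotation time) a view rather than a copy.

At ingest, multi-allelic records are split one variant per alternate allele,
and alleles are parsimony-trimmed and — when a reference sequence is
available — left-aligned. Cross-caller merging is by exact
(chrom, pos, ref, alt) key; without normalization, identical indels reported
in different right-shifted forms by different callers would fail to merge.
No fuzzy matching is applied to small variants.

## MNV handling

Callers disagree on whether adjacent substitutions are one phased event or
separate SNVs. Consensus is therefore computed at SNV resolution: MNVs are
decomposed into their non-silent component SNVs (each tagged with an origin
id), merged, and re-constituted into an MNV only when every component exists
in the merged set with an identical caller-support set. Reconstitution is
attempted per origin, longest origin first, each SNV consumed at most once —
a deterministic greedy rule covering the case of overlapping MNVs of
different lengths, which the equal-support rule alone leaves open. MNVs and
overlapping indels do not interact.

## SV matching and merging

Two SVs match when they share type and strand orientation at both ends,
their breakend intervals padded by `sv_slop` (default 300 bp) overlap on the
same chromosomes, and — for events with a defined span — the spans overlap
reciprocally by at least `sv_reciprocal` (default 0.5) of each event. Span
is the outer-bound distance `end2 − start1`, undefined for translocations
and insertions, for which the reciprocal condition is waived; insertions are
also exempt from the 500 bp minimum-size filter, since their genomic
footprint does not measure inserted-sequence length. DUP and DEL never merge
even at identical coordinates: the type check is explicit rather than
strand-implied because caller notations are heterogeneous. Merging takes
connected components of the match graph (union-find over
per-(chromosome-pair, type, strands) buckets); the representative
coordinates come from the highest-priority caller present (manta > lumpy >
svaba), caller support is the component union, split-read support the
maximum reported.

The SV panel of normals clusters normal-sample calls with a simpler rule —
same type, same strands, both breakend *points* within `pon_sv_max_distance`
(300 bp) — with no size filter, and records the number of distinct
individuals per cluster. Application back onto a somatic callset reuses the
pairtopair-style match against panel events seen in ≥ `pon_min_individuals`
(2) individuals. The small-variant panel is keyed by position only, not
allele: a somatic call at a panel site with a different alternate allele is
still tagged (an allele-aware mode exists behind the keying function but is
not the default).

## Allele counts and count filters

Pileup counts are unique-fragment tallies: duplicate, supplementary,
QC-failed, unmapped and sub-threshold reads (mapping or base quality < 10)
are excluded, a read pair counts once, and pairs whose mates disagree on the
allele are dropped entirely. Depth is the number of surviving fragments
including third-allele fragments; VAF = alt/(ref+alt). The depth < 2 filter
uses this post-filter depth — the only depth the stack computes.

Indel length is the net allele-length change |len(ref) − len(alt)|. Lengths
below 10 use pileup counts; 10 and above, and complex substitutions (both
alleles > 1 nt, unequal), use caller-reported counts in priority order
strelka2 > mutect2 > lancet. Variants whose only caller reports no usable
counts keep `source = NONE`, receive `NO_COUNTS`, and *remain* in AllSomatic:
they cannot be judged by the count filters. Boundary semantics are literal:
tumor VAF exactly 10⁻⁴ passes, normal VAF exactly 0.2 passes, depth exactly
2 passes.

## High confidence

Two or more callers always suffice, including caller pairs with no
orthogonal evidence. A single-caller small variant is rescued by membership
in the targeted-validation set or the small-SV-derived set. A single-caller
SV is rescued only if that caller is manta or lumpy and either a CNV
changepoint lies within 1000 bp (inclusive) of a breakend (breakend
coordinate = interval start), or split-read support is ≥ 3 in the tumor with
exactly 0 in the normal. "Tumor only" is encoded literally as zero normal
split reads; both constants are configurable. The targeted validation set is
consumed as evidence rather than produced by running a caller; the simulator
fabricates it.

## CNV model

Categorization uses strict inequalities: log2 > 0.2 is AMP, log2 < −0.235 is
DEL, ties are NEUTRAL, non-finite input is UNDEFINED. The −0.235 constant is
adopted exactly as the operative default (its motivating quantity, the
log2 of a single-copy loss at 30% purity in a diploid genome, is −0.2345 at
four decimals; the VAF equivalent of that configuration is 0.15, and a
single-copy gain rounds to the 0.2 amplification threshold at one decimal).

The purity adjustment inverts the observed ratio to an absolute tumor copy
number and recomputes a purity-free ratio (equations in the README). The
forward model used by the simulator and the round-trip property is the exact
algebraic inverse of the T_CN equation:

    2^obs = T_purity · c · N_ploidy / (T_ploidy · N_CN) + (1 − T_purity)

so integer copy numbers are recovered to machine precision for any purity in
(0, 1] and any positive ploidies, and the adjustment is the identity at
purity 1. A non-positive inferred copy number (possible when 2^obs ≤ 1 −
purity) is flagged `NONPOS_TCN` and categorized DEL with `adj_log2` left
undefined — flagged rather than clamped so downstream evaluation can count
such segments explicitly. Normal copy number defaults to 2 on autosomes and
1 on X/Y for males, supplied via configuration.

The mixture purity equation weights each compartment by its DNA content:
reads are drawn in proportion to genome mass, so a tetraploid tumor at read
fraction 0.5 is only 1/3 of the *cells*. For a diploid tumor, purity equals
the read fraction; the 10X + 70X ladder point gives t_frac = 0.125.

## Evaluation

Classification against a reference run uses three labels: TP (matches the
reference high-confidence set), FP (absent from the reference permissive
set), and *ignored* (matches the permissive set only) — such calls cannot be
confidently labelled true or false and enter no metric. |test| = TP + FP +
ignored always. Small-variant identity is the exact key; MNVs are decomposed
to SNVs before set comparison so representation differences between runs do
not masquerade as discordance. SV membership is match-based (an SV is "seen
in" a set if it matches any member under the merge criteria), since exact
coordinates differ between runs. CNV comparison is per-base within a
category, computed with sorted-interval intersection and cross-checked
against a dense per-base oracle in tests. VAF-binned recall partitions the
reference high-confidence set into left-closed bins using the VAFs measured
in the reference data, with the final bin closed.

## Mismatch profiling

Mismatches are represented in read-strand orientation: for reverse-strand
alignments the reference base, read base and both context flanks are
reverse-complemented, which is what makes the 12 uncollapsed substitution
types informative. Eligible positions are aligned match positions on
non-excluded reads (mapping quality ≥ 10) with base quality ≥ 10, both
reference flanks, no N in base or context, and both immediate neighbors also
aligned — read ends and indel-adjacent bases are excluded from numerator and
denominator alike so the rate is internally consistent. Collapse to the six
pyrimidine-reference types adds each purine channel into its reverse
complement (alleles complemented, 5′/3′ swapped and complemented), conserving
totals. Homopolymer run statistics are computed on the read sequence as
sequenced, independent of alignment; N breaks a run. Downsampling to a
target depth keeps fragments (reads sharing a name) together with
probability target/current.

## Synthetic-data generator

The generator defines the study conditions for all tests:

- **Truth sets**: two contigs (120 kb + 80 kb) tiled by copy-number segments
  with integer tumor copy numbers drawn from {1, 2, 2, 2, 3, 4} (tumor
  ploidy is their length-weighted mean, ~2–2.5); 120 SNVs, 12 MNVs, 40
  indels (1–14 nt), 10 SVs of 1–20 kb by default. Variants land only on
  segments with at least one tumor copy; pure-tumor VAF = clone_fraction ·
  c_alt / c_tot. An optional Beta draw replaces the copy-state VAF model
  when a target VAF distribution is wanted directly.
- **Mixtures** are simulated at the fragment-count level rather than by
  manipulating reads: tumor-sample alt fragments are Binomial(depth, v_mix)
  with v_mix = t_frac·c_alt / (t_frac·c_tot + (1−t_frac)·n_cn), the
  copy-number-weighted allele dosage. The default dilution series mirrors a
  tumor 10–70X against normal 70–10X grid (t_frac 0.125–0.875), analyzed
  against a 40X normal; a coverage ladder grid is also provided.
- **Mock callers** detect each truth variant with probability
  s_max·alt/(alt+k) at the drawn alt count (defaults s_max 0.98, k 3),
  report true counts plus Gaussian noise, emit MNVs decomposed when the
  caller cannot represent them (strelka2), call only indels when that is the
  caller's remit (svaba small variants), and add Poisson false positives
  whose alternate alleles can be reweighted by a 96-channel context bias
  (e.g. an elevated T>G weight emulating a platform artifact).
- **Reads** tile a reference with errors drawn per-site from a 192-channel
  profile *in read-strand space* (reverse reads are generated from the
  reverse-complemented template and flipped back), so the profiler recovers
  the profile directly; an optional knob writes G homopolymer runs into a
  fraction of reads.

All generators are pure functions of (parameters, seed). What the generator
does **not** emulate: sequence-level insert-size and GC structure, mapping
ambiguity, germline variation in the normal (the normal is variant-free at
somatic loci), caller-specific error modes beyond the sensitivity/FP/bias
knobs, and segmentation noise (truth segments are exact). Passing tests
therefore demonstrate the correctness of the post-calling logic and the
qualitative purity/coverage behavior of the ensemble — not calibrated
performance on real sequencing data.

## Problem sizes and statistical checks

The dilution-series check runs the full stack on 7 ladder points × 10 seeds
with ~120 truth small variants per run, asserting that mean high-confidence
recall is non-increasing as purity falls (within two standard errors of the
seed-to-seed spread) and that the merged callset's recall is at least every
single mock caller's at every purity. The error-profile recovery check uses
~1.1 million eligible bases at a 0.5% total error rate; with 192
simultaneous per-channel 3-SE bounds, up to two channels marginally outside
(and none beyond 4 SE) is the expected multiple-comparison behavior and is
accepted as consistent. Monte-Carlo tests are seeded; property tests run
derandomized.

## Known limitations

- Left-alignment requires a reference; without one, only parsimony trimming
  applies and pathological right-shifted indel representations may fail to
  merge.
- The SV PON breakend distance is measured between interval start points,
  which for wide confidence intervals is stricter than interval distance.
- `classify_svs` is quadratic in callset size (match-based membership); fine
  at the intended scales.
- The CLI's `run` subcommand consumes SV callsets as BEDPE, not VCF; use
  `read_sv_vcf_as_bedpe`/`merge-sv` to convert first.
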