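# somaticstack

A post-calling stack for tumor–normal somatic variant pipelines. Research
cancer-genomics pipelines run an ensemble of variant callers (MuTect2,
Strelka2, Lancet and SvABA for SNVs/MNVs/indels; Manta, Lumpy and SvABA for
structural variants; a read-depth segmenter for copy number) and then face the
real work: reconciling the callsets into one somatic catalog, filtering
recurrent artifacts and germline leakage, deciding which calls to trust, and
quantifying how performance degrades with tumor purity and coverage.
`somaticstack` implements that post-calling half as a tested Python library
with a thin CLI, exercisable entirely on synthetic data.

## What it does

- **Consensus merging.** MNVs are split to SNVs, merged across callers on
  exact normalized keys (multi-allelic split, parsimony trim, left-align),
  and re-merged to MNVs only when every component has identical caller
  support. SVs below 500 bp are excluded, the rest merged as connected
  components under pairtopair-style criteria: 300 bp slop, same strand
  orientation, 50% reciprocal span overlap.
- **Filtering.** A position-keyed panel of normals (sites seen in ≥ 2
  individuals) and a SURVIVOR-style SV panel (same type/strands, breakends
  within 300 bp); a common-germline filter at population MAF ≥ 1%; and
  count-based filters on final allele counts — tumor VAF < 10⁻⁴, normal VAF
  > 0.2, depth < 2 in either sample, or normal VAF exceeding tumor VAF.
  Filters tag records rather than delete them; the tag-free tier is the
  **AllSomatic** callset.
- **Allele counts.** SNVs and indels under 10 nt get unique-fragment pileup
  counts (mapping and base quality ≥ 10, discordant pairs dropped); larger
  indels take caller-reported counts in the order Strelka2 > MuTect2 >
  Lancet; SvABA-only large indels carry no counts.
- **High confidence.** ≥ 2 callers, or one caller plus orthogonal evidence:
  targeted-validation/small-SV hits for small variants; a CNV changepoint
  within 1000 bp or ≥ 3 tumor-only split reads for Manta/Lumpy SVs.
- **CNV purity/ploidy adjustment.** Segments categorize as amplification
  (log2 > 0.2) or deletion (log2 < −0.235). With tumor purity and ploidy the
  observed ratio inverts to an absolute copy number and a purity-free ratio:

      T_CN     = T_ploidy · N_CN · (2^Obs_log2 − (1 − T_purity)) / (N_ploidy · T_purity)
      Adj_log2 = log2((T_CN / T_ploidy) · (N_ploidy / N_CN))

  For in-silico mixtures of tumor and normal reads, the true purity follows
  from the mixed read fraction:

      T_purity = T_frac · N_ploidy / ((1 − T_frac) · T_ploidy + T_frac · N_ploidy)

- **Evaluation.** Jaccard concordance (100·|∩|/|∪|); TP/FP/FN classification
  against a reference run in which calls matching the permissive but not the
  high-confidence reference tier are *ignored*; precision = TP/(TP+FP),
  recall = TP/(TP+FN), F1 their harmonic mean; base-level CNV comparison;
  recall by VAF bin.
- **Read profiling.** Longest homopolymer runs per read, and read-strand
  mismatch spectra over 192 trinucleotide channels (12 substitution types ×
  16 contexts), collapsible to the conventional 96.
- **Synthetic data.** `somaticstack.simulate` fabricates truth sets, mixture
  evidence at any tumor read fraction, mock caller outputs with sensitivity
  curves / false-positive context biases, and error-profiled aligned reads —
  every stage of the stack can be driven end to end from a seed.

## Worked example

Simulate a half-purity tumor–normal pair and run the whole stack:

```
$ somaticstack simulate --out-dir demo --seed 11 --t-frac 0.5 \
      --n-snv 40 --n-indel 12 --n-sv 5
simulated 64 small variants, 5 SVs into demo
$ somaticstack run --config demo/run.yaml --out-dir demo/out
{"merged_small": 64, "merged_sv": 5, "all_somatic": 64, "high_confidence": 64, "segments": 8}
```

The run merges the four mock small-variant callsets into 64 consensus
records and the three SV callsets into 5 breakend pairs; at 80X mixed
coverage all of them survive the count filters (AllSomatic) and reach high
confidence. `demo/out/` holds the annotated VCF, BEDPE and segment table;
the segment table shows the purity adjustment recovering integer tumor copy
numbers from the diluted log2 ratios:

```
chrom  start  end    obs_log2   adj_log2   t_cn  n_cn  category
chr1   0      8766   -0.0267    -0.0550    2.0   2     NEUTRAL
```

The same machinery is available as a library:

```python
from somaticstack.cnv import purity_from_mixture, tumor_copy_number, expected_log2

purity = purity_from_mixture(t_frac=0.125, t_ploidy=2.0)   # 0.125
obs = expected_log2(t_cn=1, t_purity=purity, t_ploidy=2.0) # attenuated loss
tumor_copy_number(obs, purity, 2.0)                        # 1.0 recovered
```

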