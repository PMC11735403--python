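# allelichrom

Allele-specific chromatin and expression inference for tumor cohorts.

Some tumors silence one copy of a gene not by deleting or mutating it but by
epigenetic means: the active enhancer mark H3K27ac stays on one allele while
the repressive Polycomb mark H3K27me3 is deposited on the homologous allele
— a *trans* "hemizygous" chromatin state that produces mono-allelic
expression despite two intact gene copies. Detecting this requires reading
sequencing libraries allele by allele at germline heterozygous SNPs.
`allelichrom` implements that analysis as a tested, reusable pipeline for
epigenomics researchers working with matched tumor/normal WGS, histone-mark
ChIP-seq, RNA-seq and HiChIP loop data, and ships a synthetic-cohort
generator with ground truth so every stage can be benchmarked without
access to patient data.

## What it computes

- **Germline het-SNP filtering** from a tumor/normal VCF: total allele depth
  ≥ 10 in tumor and ≥ 7 in normal, alt-allele fraction within the open
  intervals (0.3, 0.7) in blood and (0.2, 0.8) in tumor, bi-allelic sites
  only, InDels shorter than three nucleotides.
- **Allelic imbalance** per library at each het SNP:
  `r = |AF_REF − AF_ALT| = |ref − alt| / (ref + alt)` ∈ [0, 1].
- **Trans hemizygous chromatin-state calls**: within the per-sample
  H3K27ac–H3K27me3 "hemizygous region" (base-wise peak intersection), a SNP
  supports the trans state when both libraries have ≥ 10 reads, r ≥ 0.6, and
  opposite majority alleles; a locus is `hemizygous_trans` when ≥ 1 SNP
  supports trans and none contradicts it.
- **Super-enhancers**: peaks stitched at ≤ 12.5 kb gaps, ranked by signal
  with the slope-1 tangent (hockey-stick) cutoff, merged into subgroup
  consensus sets at ≥ 2 recurrence. An SE is **mono-allelic** when phased
  H3K27ac reads pooled onto haplotypes give a major-haplotype fraction
  ≥ 0.9; recurrently mono-allelic SEs need n ≥ 3 samples for G4 and n ≥ 2
  for other subgroups.
- **Mono-allelic expression** from RNA reads at exonic het SNPs, same
  pooled ≥ 0.9 rule, with cohort summaries per subgroup × gene.
- **Subgroup-enriched / subgroup-recurrent peaks** across a labeled cohort
  (rank-sum + BH + fold-change, or presence thresholds), including
  SHH/WNT- and G3/G4-shared categories.
- **Significantly correlated loops (SCLs)**: high-confidence loops
  (intrachromosomal, Q < 0.01, > 5 reads, 5 kb–20 Mb) linked to
  (enhancer, promoter) pairs; a pair is an SCL when enhancer H3K27ac signal
  correlates positively with target-gene expression at BH-adjusted P < 0.1.
- Batched two-tailed Fisher exact tests with Hochberg correction and
  two-tailed Mann–Whitney U comparisons for cohort statistics.

## Worked example

Simulate a cohort with known truth, run the pipeline, and score recovery:

```bash
allelichrom simulate --seed 1 --outdir cohort/
printf 'input_dir: cohort\noutput_dir: out\n' > cfg.yaml
allelichrom run --config cfg.yaml
```

which prints `wrote reports for 30 samples to out`. In Python:

```python
from allelichrom import SimulationConfig, simulate_cohort
from allelichrom import benchmarks

cohort = simulate_cohort(SimulationConfig(seed=1))
print(benchmarks.benchmark_chromatin(cohort))
print(benchmarks.benchmark_mono_se(cohort))
```

prints

```
RecoveryScore(sensitivity=1.0, specificity=1.0, accuracy=1.0,
              n_true_positive=64, n_true_negative=56, n_uninformative=0)
RecoveryScore(sensitivity=0.9797297297297297, specificity=1.0, accuracy=0.99,
              n_true_positive=148, n_true_negative=152, n_uninformative=0)
```

i.e. at the default simulation conditions (read depth ~ Poisson(30) per SNP
and library, skewed allele fraction 0.95) every planted trans hemizygous
locus in the 30-sample cohort is recovered and none is invented, and
mono-allelic SE calling recovers 145 of the 148 planted mono-allelic SE
states (sensitivity 0.98) with zero false positives among the 152
bi-allelic ones. `out/report_per_sample.tsv` lists, per sample, the
chromatin state, SE allelism and expression allelism side by side — the
three evidence channels can legitimately disagree and are never collapsed.

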