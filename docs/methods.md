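# Methods

## Problem and model

A diploid tumor genome carries two haplotypes, A and B. Sequencing reads
covering a germline heterozygous SNP can be assigned to alleles (REF/ALT)
and — given phased genotypes — to haplotypes. For one library, the
informative reads at a SNP are the REF- and ALT-matching reads; bases
matching neither allele are tallied separately and never enter allele
fractions. The imbalance statistic is

    r = |AF_REF − AF_ALT| = |ref − alt| / (ref + alt),

0 for a balanced site, 1 for complete skew. Under the null of no allelic
bias, read counts are modeled Binomial(n, 0.5) in each library,
independently between libraries.

The package infers three per-sample allelic states:

1. **Trans hemizygous chromatin** — H3K27ac on one haplotype, H3K27me3 on
   the other. Evidence is restricted to the sample's "hemizygous region",
   the base-wise intersection of its H3K27ac and H3K27me3 peak sets. A SNP
   is `trans_biased` when both libraries have ≥ 10 informative reads,
   r ≥ 0.6 in both (inclusive), and the majority alleles differ;
   `same_allele_biased` with equal majorities; `balanced` below threshold;
   `uninformative` below the read floor. A locus is `hemizygous_trans` iff
   both marks have peaks there, ≥ 1 SNP is trans-biased and 0 are
   same-allele-biased; loci with contradictory SNPs are surfaced as
   `ambiguous` rather than resolved, and SNPs below the r threshold count
   only as heterozygosity evidence, never as trans evidence.
2. **Mono-allelic super-enhancer** — phased het SNPs inside the SE
   contribute their H3K27ac REF/ALT reads to haplotypes via phase; counts
   are pooled across SNPs and the normalized allelic fraction is
   max(hapA, hapB)/(hapA + hapB). Mono-allelic iff ≥ 0.9 (inclusive), with
   ≥ 10 pooled reads and ≥ 1 phased SNP required; per-SNP averaging was
   rejected in favor of pooling because pooling weights SNPs by coverage
   and is what a single haplotype-level count would give.
3. **Mono-allelic expression** — the same pooled rule on RNA reads at
   exonic het SNPs. The 0.9 threshold for RNA is a declared package
   decision mirroring the SE rule (exposed as a parameter); with a single
   covered SNP phase is unnecessary since the major allele is the major
   haplotype, while multiple covered SNPs pool only phased ones.

Under the binomial null at depth 30, a false trans-biased SNP requires
opposite ≥ 24/30 splits in two independent libraries
(2·P(X ≥ 24)² ≈ 8×10⁻⁶), which is why a single supporting SNP with zero
contradictions suffices at cohort scale; the test suite checks the
simulated false-positive rate against this exact tail computation.

## Cohort-level procedures

* **Het-SNP filter** (tumor/normal VCF): caller QC pass; bi-allelic;
  InDels of at most 2 inserted/deleted bases ("shorter than three
  nucleotides"); total allele depth ≥ 10 (tumor) and ≥ 7 (normal),
  inclusive; alt fraction inside the OPEN intervals (0.3, 0.7) in normal
  and (0.2, 0.8) in tumor — parenthesis notation read as strict
  inequality, so a blood fraction of exactly 0.3 is rejected. Alt fraction
  (not minor-allele fraction) is used; the intervals are symmetric so the
  two coincide. Records with zero informative reads in a compartment are
  dropped with a logged reason.
* **Super-enhancers**: peaks whose gaps (next.start − prev.end, half-open)
  are ≤ 12,500 bp are stitched transitively. Regions are ranked by signal;
  both axes of the ascending rank–signal curve are scaled to [0, 1] and the
  cutoff is the point where the tangent slope equals 1, found as the argmin
  of (scaled signal − scaled rank); regions strictly above the cutoff
  signal are super. Degenerate cases are fixed conventions: a flat curve
  has no super regions; fewer than three regions are all flagged super with
  a warning. Consensus per subgroup: overlap-clusters supported by ≥ 2
  distinct samples, reported as the genomic union. TSS-proximal peak
  exclusion is off by default (available as an option). Recurrently
  mono-allelic SEs require n ≥ 3 samples in G4 and n ≥ 2 elsewhere.
* **Peak categories**: peaks called in < 2 samples cohort-wide are dropped.
  Subgroup-ENRICHED peaks beat every comparison subgroup under a one-sided
  rank-sum per comparison with BH across peaks (q < 0.05) and median
  fold-change ≥ 2 on CPM-normalized counts (pseudocount 0.5); the
  enrichment statistic is a package choice — no specific test is canonical
  here — and is parameterized so a count-model test can be swapped in.
  Shared pair categories (SHH/WNT, G3/G4) are peaks enriched against both
  distant subgroups but not against the partner. Subgroup-RECURRENT peaks
  are present in ≥ 3 target samples and ≤ 0 samples of every other
  subgroup (both configurable).
* **SCLs**: loops must be intrachromosomal with Q < 0.01 (strict), read
  count > 5 (strict), and anchor-midpoint distance in [5 kb, 20 Mb]. A pair
  is emitted for every (enhancer, gene) whose enhancer and promoter
  (TSS ± 2 kb, a declared default) overlap opposite anchors. Pearson
  correlation of enhancer signal vs expression across shared samples
  (≥ 5 required), two-sided p, BH across tested pairs; SCL iff r > 0 and
  adjusted p < 0.1. Zero-variance pairs are untestable and excluded from
  the BH family. BH was chosen for the "adjusted P < 0.1" style criterion;
  Hochberg (FWER) is used where batched Fisher tests are reported.
* **Rounding**: cohort percentages are printed half-up at an explicit
  number of decimals (integer or one decimal), passed as an argument so
  summaries are reproducible to the digit and always recompute exactly
  from their own counts.

## Synthetic cohorts

The generator emulates the statistical structure the inference assumes:
phased diploid samples on a toy genome (2 × 1 Mb), with fixed SNP positions
shared across samples (as annotated common SNPs would be). Chromatin-state
loci (40 kb, 3 SNPs) carry peaks for both marks; with probability 0.5 a
sample×locus is trans (H3K27ac skewed toward one haplotype at allele
fraction 0.95, H3K27me3 toward the other), otherwise both marks are
balanced at 0.5. SE regions (10 × 40 kb, 3 SNPs) and genes (10, 2 exonic
SNPs) are mono-allelic with probability 0.5 at the same skew. Depths are
Poisson: λ = 60 for WGS (comfortably above the depth filters), λ = 30 for
ChIP and RNA — a realistic per-SNP coverage for targeted allelic analysis
and deliberately not so deep that classification is trivial. Reads are
Binomial given depth; no overdispersion by default (a beta-binomial knob
would loosen every band, so it is off for benchmarking). The SCL block
simulates 1000 enhancer–gene pairs across 30 samples, 100 with planted
Pearson correlation 0.8 (y = r·x + √(1−r²)·ε on standard normals) and the
rest independent, each with a loop record passing the loop filters.

Everything derives from one integer seed via a single PCG64 stream, and the
emitted file bundle (VCF/BED/BEDPE/TSV, all plain text) is byte-identical
across runs. Truth labels are written as TSVs beside the inputs so tests
never reach into generator internals.

What passing benchmarks do and do not show: with three independent SNPs per
feature at these depths the binomial model makes the planted states nearly
separable (expected sensitivity ≈ 0.96–0.99, specificity ≈ 1 by the
binomial tails), so the benchmarks validate correctness of the decision
rules and plumbing, not robustness to mapping bias, copy-number change,
tumor impurity, subclonality or ChIP overdispersion — none of which the
generator models.

## Default problem sizes

The default cohort is 30 samples (4 WNT / 8 SHH / 8 G3 / 10 G4), giving
120 sample×locus chromatin calls, 300 SE calls and 300 expression calls,
with a 1000-pair SCL block — enough for stable rate estimates while the
whole benchmark suite runs in seconds.

## Numerical and design notes

* Coordinates: VCF is 1-based, all intervals 0-based half-open; conversion
  happens only in the I/O layer. Chromosome names are taken verbatim.
* Per-allele depths come from the standard AD field; records lacking it
  are rejected, not imputed. Phase is read from the normal (germline)
  sample's pipe-separated genotype.
* Counts with an other-base fraction above 0.2 are flagged unreliable;
  BAM-based counting applies a base-quality floor of 20, mirroring common
  variant-caller settings (configurable).
* Mann–Whitney comparisons use the exact null for ≤ 8 observations per
  group without ties, otherwise the tie-corrected normal approximation.
* Ranking ties are broken by stable sort; ranks are always a permutation
  of 1..N.

## Known limitations

No correction for reference-mapping bias (WASP-style remapping is future
work); no modeling of copy-number state, purity or subclonality, so a
skewed site cannot be distinguished from allelic copy gain without external
CNA calls; the enrichment test for subgroup peaks is a pragmatic default,
not a claim about the optimal count model; loop calling, peak calling,
alignment and phasing are consumed as inputs, never re-implemented.
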