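# Methods

## Model and procedure

`fstscan` implements a three-population empirical-outlier selection scan.
The chain of computation is:

1. **Per-locus pairwise θ.** For each population pair, the Weir–Cockerham
   two-population estimator is evaluated per locus from the non-missing
   genotypes: with per-population sample sizes n_i, alt-allele frequencies
   p_i and observed heterozygote frequencies h_i (r = 2 populations),

   n̄ = Σn_i / r,  n_c = (r·n̄ − Σn_i² / (r·n̄)) / (r − 1),
   p̄ = Σn_i p_i / (r·n̄),  s² = Σn_i (p_i − p̄)² / ((r − 1) n̄),
   h̄ = Σn_i h_i / (r·n̄),

   a = (n̄/n_c)·[s² − (p̄(1−p̄) − s²(r−1)/r − h̄/4) / (n̄−1)],
   b = (n̄/(n̄−1))·[p̄(1−p̄) − s²(r−1)/r − h̄(2n̄−1)/(4n̄)],
   c = h̄/2,  θ = a/(a+b+c).

   A locus is *defined* for a pair when both populations have ≥ 2
   genotyped individuals and a+b+c > 0 (loci monomorphic across the pooled
   pair are undefined). Negative θ is retained. The genome-wide pairwise
   estimate is the ratio of sums Σa/Σ(a+b+c) — multilocus weighting, not a
   mean of per-locus ratios (a mean-of-ratios option exists for
   sensitivity checks).

2. **Per-locus breed statistics.** Loci with θ defined for all three pairs
   enter the scan. LSBL_A = (θ_AB + θ_AC − θ_BC)/2 (cyclic for B, C);
   d_A = z_AB + z_AC with z_ij = (θ_ij − E_ij)/sd_ij, where E_ij and the
   sample (n−1) sd_ij are computed over exactly the triple-defined locus
   set. Using that one locus set for both the scores and the
   standardisation constants makes each breed's mean d identically zero
   over the scanned loci, which is the natural centering diagnostic.

3. **Windows.** Each autosome is tiled from coordinate 0 into
   non-overlapping 300-kb windows (0-based half-open internally; a 1-based
   position `pos` maps to window `(pos−1)//300000`). The window statistic
   per breed is the arithmetic **mean** of the per-SNP values; the maximum
   is available behind `ScanConfig.window_stat="max"`, but the mean is the
   default aggregator. Windows with fewer than three defined SNPs are
   dropped; survivors are numbered 1..N in (chromosome, start) order.
   Each window records a per-breed peak SNP: the argmax of per-SNP LSBL,
   ties resolved to the lowest position (d_i peaks are not used; LSBL is
   the more breed-specific statistic).

4. **Outlier calling.** For each breed and statistic the selected windows
   are the top ⌈(1 − 0.99)·N⌉ by window statistic, ties at the cutoff
   broken by lower window index — a deterministic realisation of "the
   upper 99th percentile of the empirical distribution" that yields
   exactly 78 windows for a 7,734-window genome. The merged candidate set
   per breed is the intersection of its LSBL and d_i lists; windows in
   two or more breeds' merged sets are reported separately and excluded
   from breed-specific gene screens.

5. **Agreement diagnostics.** Overall Pearson r between LSBL and d per
   breed over all scanned loci, plus per-bin r after sorting loci by LSBL
   descending in bins of 5,000 (final partial bin kept if ≥ 3 loci;
   constant bins flagged undefined).

## Quality control and pruning

QC retains loci with pooled-sample MAF strictly > 0.01, pooled exact
Hardy–Weinberg p strictly > 1e-6 and chromosome in 1..26; removal counts
attribute each dropped locus to the first failing criterion in the order
MAF, HWE, autosome. The HWE test is the exact conditional test: given the
observed allele counts, the p-value sums the probabilities of every
heterozygote count no more probable than the observed one (probabilities
by the standard two-directional recurrence from the distribution's mode;
a relative 1e-7 guard treats numerically equal probabilities as ties).
Testing is done on the pooled sample because the filter precedes any
per-breed analysis; note that pooling structured populations removes some
loci through the Wahlund effect, which mirrors common chip-QC practice. A
per-population variant can be obtained by subsetting samples first.

LD pruning follows indep-pairwise semantics on genotype dosages (phase
unknown): per chromosome a 25-SNP window advances by 5 SNPs over the
surviving loci; within a window, while any pair has r² > 0.1 (squared
Pearson correlation over pairwise-complete calls; monomorphic loci count
as r² = 0), the highest-r² pair is resolved by removing its lower-MAF
member (MAF ties: the later map position). The sweep over windows repeats
until a pass removes nothing. The fixed point makes pruning idempotent
and guarantees that no surviving within-window pair exceeds the threshold
in the final state; a single pass over a static locus order guarantees
neither, because windows shift as loci are removed. Which of the several
defensible pair orderings is used barely changes the retained count, but
the chosen one is deterministic and documented so results are exactly
reproducible.

PCA (a stratification check, computed on the pruned set) mean-imputes
missing dosages per locus, centres, scales by 1/√(p̄(1−p̄)) (unscaled
option available), and eigendecomposes via SVD; variance proportions are
over all components and sum to 1.

## Synthetic data

The simulator emulates the statistical structure of a three-breed
SNP-chip dataset, not any real demography:

- Loci are placed per chromosome at exponential gaps (default mean
  50 kb over 26 autosomes), so a 300-kb window holds ~6 SNPs on average,
  matching chip density.
- Ancestral frequencies are Uniform(0.05, 0.95); population k's frequency
  is Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) — the Balding–Nichols model,
  parameterised so the drift coefficient F is also the model's fixation
  index. The default F = 0.15 reproduces the moderate divergence regime
  (pairwise F_ST ≈ 0.13–0.19) typical of distinct livestock breeds;
  per-population F values are accepted.
- Sweeps are deterministic frequency displacements: inside each planted
  block one breed's frequency becomes the ancestral p shifted by δ
  (default 0.45) toward the farther boundary, clamped to [0.01, 0.99].
  The shift direction is evaluated per locus from its ancestral p. This
  plants exactly the allele-frequency architecture the scan targets,
  without simulating hitchhiking dynamics.
- Genotypes are Binomial(2, p_k) (Hardy–Weinberg within populations, no
  LD beyond sampling noise); missingness is independent per call.
- One seeded generator is consumed in a fixed order (positions →
  ancestral frequencies → population frequencies → sweep placement →
  genotypes → missingness), so a config reproduces its output exactly.

What the simulator does **not** emulate — within-population LD and
haplotype structure, ascertainment bias of chip SNPs, family structure,
realistic site-frequency spectra, genotyping error beyond missingness —
limits what passing tests show about real data: they validate the
estimators, the windowing and the outlier logic, not robustness to those
real-data features. In particular, LD pruning on simulated data removes
almost nothing (by construction loci are quasi-independent), so pruning
behaviour is exercised mainly on crafted correlated fixtures.

## Numerical and design choices

- Percentile rule as top-⌈0.01·N⌉ by count (with an epsilon guard against
  binary-float artifacts in (1−p)·N), not a quantile-threshold crossing:
  for N = 7,734 this yields exactly 78 windows, and ties cannot make the
  set size data-dependent.
- Strict inequalities at the MAF and HWE boundaries (a locus at MAF
  exactly 0.01 is removed).
- Coordinates: locus tables are 1-based inclusive (PLINK/VCF convention);
  windows are 0-based half-open internally and reported with both bp and
  Mb bounds.
- PLINK `.map` files carry no allele columns, so `read_plink` infers
  allele roles from the data; when a locus's observed alleles are a
  subset of {A, B} the convention ref = A / alt = B is used (this is the
  writer's coding, making write→read round trips bit-exact), otherwise
  the observed alleles are taken in alphabetical order.
- "Near a peak SNP" for gene annotation defaults to 50 kb — the order of
  the chip's inter-SNP spacing — and is configurable.
- Degenerate inputs error early and specifically: < 2 individuals per
  population (θ undefined), zero surviving QC loci, zero per-pair F_ST
  standard deviation, non-three-population scans, empty genotype writes.

## Known limitations

- Exactly three populations for LSBL/d_i (the estimator layer itself is
  pairwise and general); more-than-three-population d_i is not
  implemented.
- d_i is intrinsically less breed-specific than LSBL: a sweep in breed A
  inflates θ_AB and θ_AC and hence d_B and d_C at the same loci, so
  single-statistic d_i candidate lists overlap across breeds far more
  than LSBL lists, and even merged (LSBL ∩ d_i) sets occasionally
  cross-flag another breed's swept region. In simulations with planted
  sweeps the merged sets detect essentially all true blocks, while the
  cross-flagging rate fluctuates from seed to seed around the few-percent
  scale per block. This asymmetry is a property of the statistics, not an
  implementation artifact.
- Haplotype-based scans (iHS/XP-EHH-family), permutation-calibrated
  p-values, multiallelic loci and sex chromosomes are out of scope; the
  outlier rule is purely empirical and carries no significance claim.
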