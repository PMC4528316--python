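# Methods

## The scan

`bsascan` tests, at every SNP, whether the reference-parent allele
frequency differs between DNA pools built from the two phenotypic tails
of a segregating population.  Frequencies are plug-in ratios of
quality-prefiltered read counts; no genotype-likelihood model is used, so
each pool's counts at a SNP are treated as binomial draws from the pool's
allele frequency.  The per-SNP statistic is the classical two-proportion
z with a pooled variance estimate.  It is undefined (and the SNP drops
out of the scan) when either pool has zero depth or when the pooled
frequency is 0 or 1.

The window statistic Z′ is the unweighted mean of z over a centered
window of d = 15 consecutive participating SNPs on the same chromosome,
and is compared two-sided to N(0, 1) **without** a √d rescaling.  Since
the mean of d near-independent standard normals has standard deviation
≈ 1/√d, the resulting p-values are strongly conservative; this is
intentional — the windowed profile is used with an *empirical* outlier
threshold, so only the ranking of Z′ matters, and the unscaled reference
keeps single-SNP and windowed profiles on comparable scales.  A
`scale_window` switch provides the √d-calibrated variant for users who
want nominally sized windowed p-values.

Windows run over the index sequence of participating SNPs, not over
physical distance: missing cells are removed *before* windowing, windows
never span chromosomes, and SNPs without ⌊d/2⌋ = 7 participating
neighbours on each side get no Z′.  The alternative convention
(propagating missing values into windows) would silently thin the scan
near every filtered cell; excluding them keeps every window at exactly d
informative SNPs.

## Filters

Three rules precede the scan, with all bound comparisons strict so that
boundary values survive:

| rule | default | acts on |
| --- | --- | --- |
| SNP calling | pooled depth ≥ 10 and pooled minor-allele frequency ≥ 0.25 | whole site |
| coverage window | per-pool depth < 20 or > mean + 1 SD ⇒ cell missing | (SNP, pool) cell |
| control band | control frequency missing, < 0.25 or > 0.75 ⇒ site discarded | whole site |

The upper coverage bound guards against collapsed repeats (excess
coverage), the lower against unstable frequency estimates; the mean and
sample SD (n − 1) are computed over all (SNP, pool) depth cells jointly,
and the SNP-calling depth is summed across pools.  The control band
removes sites whose segregation is already aberrant before selection.
Because cells are masked per pool, each two-pool contrast uses only SNPs
non-missing in *both* of its pools, so different trait contrasts retain
different SNP subsets of the same table.

## Thresholding and region calling

The significance threshold is the empirical 99.5th percentile of the
scanned −log10(p) values, computed by the nearest-rank rule (the value at
rank ⌈(1 − q)·N⌉ of the sorted vector).  Nearest-rank was chosen over
interpolating quantile definitions for determinism and because the
threshold is a rank statement, not an estimate; significance is strict
("above the threshold"), so a constant vector yields zero significant
SNPs.

Regions are built per chromosome: maximal runs of significant SNPs are
extended by 7 scan SNPs on each side (the window half-width — those
neighbours carried the evidence for the last significant SNP), clipped at
the chromosome's first/last scan SNP; then, scanning left to right, a
region is merged into its predecessor when the bp gap between boundary
SNPs is under 5 Mb.  Note the deliberate mix of spaces: extension is in
scan-SNP index space, merging in physical bp.  The peak is the maximum
−log10(p) in the region, leftmost on ties; the region's direction is the
sign of the windowed frequency difference at the peak.  Interval lengths
are reported in kb, rounded half away from zero — the convention that
reproduces all 27 published flowering-time and plant-height interval
lengths checked in the test suite.

## Map expansion

Effective recombination events per individual scale across population
designs by the factors j/2 + (2^i − 1)/2^i (intermated then inbred) and
(2^(i+1) − 1)/2^i (inbred only), with i inbreeding and j intermating
generations.  The package defaults to the fully-inbred limit i = ∞
(factors j/2 + 1 and 2): that convention reproduces the standard
57 → 152 endpoint for j = 4 → 14 (ratio 8/3).  Taking i = 0 literally for
a noninbred intermated population would instead give 57 × (7/3) = 133;
both are available through the explicit `i` parameter, and the choice of
default follows the convention used when that endpoint is quoted.

## The simulator

The generator emulates the full study design rather than an abstract
coalescent, because truncation selection on a phenotype is the essential
mechanism:

- **Population.** Two fully homozygous founders; all F1 identical and
  heterozygous everywhere; F2 by random F1 × F1 matings; then t = 14
  generations of random mating with two distinct parents per offspring,
  N = 10,000 by default.  Meiosis is Haldane: Poisson crossover counts
  with mean equal to the chromosome's genetic length in Morgans, uniform
  positions, no interference.  The genetic map is a constant 0.5 cM/Mb
  unless given explicitly; the real maize map is not bundled.
- **Trait.** Genetic value g = Σ a(c − 1) + a·k·[c = 1] over planted QTL
  (c = reference-allele copies, a additive effect, k dominance degree,
  default 0 — dominance is known to weaken pooled-extreme designs and is
  left to the user).  Environmental noise is normal with variance set so
  Var(g)/Var(phenotype) equals the target heritability (default 0.7).
- **Selection.** The 46 highest and 46 lowest phenotypes per tail
  (ties broken by index) plus 92 random controls drawn from all N
  (overlap with the tails permitted, as controls are sampled before
  phenotyping in the field design).
- **Sequencing.** Per SNP and pool, depth ~ Poisson(λ = 40) and
  reference reads ~ Binomial(depth, f(1 − e) + (1 − f)e) with symmetric
  error e = 0.001.  There is no read-level or mapping-bias model: the
  two-reference competitive-mapping step that removes reference bias in
  real data is upstream of this package's scope, so counts are taken as
  already unbiased.

A single seed drives everything; each stage derives a child generator by
`SeedSequence` spawning, so experiments are exactly reproducible.

What passing simulator-based tests does **not** show: robustness to
mapping bias, index hopping, unequal pool DNA contributions, segregation
distortion, or real maize LD structure — none of which the generator
emulates.

## Null behaviour and the desk-scale coverage floor

With both pools sequenced from identical underlying frequencies, per-SNP
z is close to standard normal (measured on 10,000 SNPs at depth 40: mean
0.006, SD 1.008, |z| > 1.96 fraction 0.050) and the unscaled windowed
p-values are conservative (0% below 0.05 in the same run).

Under the full zero-QTL pipeline the outlier rule still, by construction,
flags ~0.5% of SNPs.  How much of the *genome* those calls cover depends
on marker density.  At depth 40 read noise dominates Z′, so null
excursions above the threshold decorrelate beyond the 15-SNP window and
come in clusters of ~3 SNPs; each cluster then carries its 14 flanking
SNPs, putting a floor of roughly q·(1 + 14/3) ≈ 2–3% under the covered
fraction at desk-scale spacing (measured: mean 2.5% over 20 replicates of
the 2 × 150 Mb / 5,000 SNP design, plus 5-Mb merging effects).  At
real-data densities (markers every few kb, spacing far below the LD
scale) the between-pool sampling component dominates Z′, excursions span
hundreds of SNPs, the flank overhead vanishes, and coverage approaches q
itself.  The property test therefore bounds the desk-scale null coverage
at 6% rather than asserting the real-data regime.

## Problem sizes used in the test suite

Simulation-backed tests run at reduced scale chosen to keep the suite
fast while preserving the design's structure: populations of 500–2,000,
genomes of 2 × 100–150 Mb, 3,000–10,000 SNPs, and 20 replicates for the
recovery and null-coverage properties.  At those sizes a single planted
QTL explaining 20% of phenotypic variance is recovered (within 5 Mb) in
every replicate of the recovery check; the binding constraint on
detection in this design is the number of selected individuals (46 per
tail), which caps the allele-frequency contrast available to sequencing.

## Degenerate inputs and numerical conventions

- Two-sided p-values are floored at 1e−300 before log10.
- Zero-depth cells yield missing frequencies, never division errors.
- A single-cell coverage table has undefined sample SD; it is taken as 0.
- Zero genetic variance with h² < 1 falls back to unit noise variance
  (with a warning) instead of dividing by zero.
- Sync records where more than two bases carry reads, and VCF records
  with more than one ALT allele, are rejected and counted in the log —
  the two parental alleles are not resolvable there.
- Interval overlap lengths use the bp-difference convention
  (min(right) − max(left)), matching how region sizes are reported.

## Limitations

- The unscaled window statistic's p-values are not nominal probabilities;
  they are a ranking device for the empirical threshold.
- The empirical threshold guarantees outliers even under the null; region
  counts are not an error-controlled discovery count.
- Pool allele frequencies are estimated with ~40 reads per SNP from 46
  individuals; the individual-sampling component of variance is not
  separated from read noise, which is why the per-SNP z under selection
  nulls (random pools of different individuals) is overdispersed.
- Linkage-mapping intervals are consumed only as plain interval files for
  overlap reporting; no linkage analysis is performed.
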