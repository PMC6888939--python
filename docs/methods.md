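# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions.

## Ancestry mosaics and the co-segmentation test

Local ancestry along a haplotype is represented as a partition of each
chromosome into maximal single-ancestry tracts (0-based half-open bp
coordinates). Adjacent tracts with the same label are merged on load, so
"fragment" always means a maximal run; windows of unknown ancestry carry the
label `UNK` and break adjacency (a fragment bordering `UNK` has a missing
neighbour on that side, as do chromosome ends).

**Flanking statistic.** For a target ancestry (European) and a flank
ancestry (North African), the statistic is the proportion of target
fragments whose immediate neighbours carry the flank label. Two readings of
"flanked" are exposed: `any_side` (≥1 of the existing non-UNK neighbours;
the default) and `both_sides` (both neighbours exist and both carry the
flank label). Under independently placed ancestries at proportions
(0.13, 0.19, 0.68) the expected any-side value for an interior European
fragment is `1 − (1 − 0.19/0.87)² ≈ 0.39`, and the both-sides value
`(0.19/0.87)² ≈ 0.047`; an observed enrichment *below* 0.39 but far above
0.047 is therefore only interpretable in the both-sides reading — a reason
both modes are first-class.

**Fragment bootstrap.** The within-dataset null resamples, without
replacement from all fragments of all ancestries, sets equal in size to the
target-fragment set, and recomputes the flanking proportion on each set
(default 9,999 replicates; empirical p uses the add-one estimator, so p is
never 0 and never below `1/(R+1)`). Because the resampled sets mix fragment
labels whose conditional flank rates differ (a West African fragment is
N-flanked far more often than a European one, and a North African fragment
never is), the bootstrap null is *not* exchangeable with the
target-conditional observed statistic: under independent ancestry placement
its mean sits near 0.47 (any-side) while the observed European value sits
near 0.39, making the bootstrap p conservative (≈1) rather than uniform.
The test is kept in this form because it is the classical genome-fragment
resampling design; the calibrated alternative is the simulation test below.

**Independent-admixture simulation test.** Each replicate draws a full
synthetic dataset — 53 diploid individuals, 10,000 equal-length fragments
per haploid genome, labels i.i.d. at the genome-wide proportions, same-label
neighbours merged — and recomputes the same statistic. Observed and
replicate values are exchangeable under the null by construction, so the
add-one p is calibrated; with the default 100 replicates the smallest
attainable p is 1/101 < 0.01. Fragment lengths are immaterial because the
statistic is adjacency-based.

## Admixture-mosaic generator

Tract structure follows the standard exponential model: an admixture pulse
`T` generations ago leaves ancestry switch points at rate `T` per Morgan.
The `nested` scenario draws two levels — (combined Eurasian source vs West
African) at rate `t2 = 63` per Morgan (1828 years at 29 years/generation),
then (European vs North African, weight 0.13/0.32) inside source tracts at
rate `t1 = 103` per Morgan (≈3000 years of European–North African contact) —
and so couples European fragments to North African flanks. The
`independent` scenario draws one level with three labels at rate `t2`. The
default stand-in genome is four 100-Mb chromosomes at a uniform 1 cM/Mb; a
piecewise-linear bp→cM map can be supplied. Merged tract lengths then
follow the exponential-with-merging law (mean genetic length
`1/(T·(1−Σp²))`), which the tests check at `t2 = 63`.

What this generator does not emulate: real recombination-map heterogeneity,
ancestry-inference error (RFMix miscalls), drift in ancestry proportions,
and selection on ancestry — so passing tests show correctness of the
*statistics*, not robustness to local-ancestry caller artifacts.

## Ancestry-dosage scan

The dosage of an ancestry at a base pair is the fraction of haplotypes
assigned that ancestry there; the track is an exact step function over the
union of tract breakpoints (no binning), and genome-wide mean/SD are
bp-weighted over the whole genome with the candidate region included.
Region scores are `z = (region mean − genome mean)/genome SD`. A constant
track (zero SD) is an error, not a zero.

## EHH, iHS, XP-EHH

EHH at extension `x` from a core SNP is the probability that two carrier
haplotypes drawn at random are identical over the whole interval between
core and `x`: `Σ_g C(n_g,2)/C(n,2)` over haplotype groups `g`. Extension
stops when EHH drops below 0.05 or when the next inter-SNP gap exceeds
200,000 bp; the first below-threshold point is included in the curve. iHH
is the trapezoid integral of EHH over physical distance, summed over both
sides. Raw iHS is `ln(iHH_ancestral/iHH_derived)`, standardized within 2%
derived-allele-frequency bins (bins with <10 SNPs merged with their
neighbour); two-sided normal p-values. Ancestral alleles come from a
supplied annotation table, never inferred. XP-EHH uses site-EHH (initial
partition by the core allele) over all haplotypes of each population,
`ln(iHH_A/iHH_B)` standardized genome-wide; positive means longer
homozygosity in A. Peaks are non-overlapping windows of 10 consecutive
SNPs (never spanning chromosomes; a short trailing window is flagged
partial) ranked by mean −log10 p, ties broken by genomic order. The EHH
walk is a compiled (numba) kernel; group refinement uses counting rather
than sorting, O(n) per SNP step.

## Forward Wright–Fisher sweep generator

Founder haplotypes come from a neutral msprime coalescent (default
Ne = 10,000, μ = 1.25e-8); the forward phase is a diploid Wright–Fisher
simulation with fitnesses w(AA)=w(Aa)=1+s, w(aa)=1 (dominant; additive
1, 1+s, 1+2s) at one focal SNP, and gamete recombination between adjacent
SNPs with probability `r × spacing`. Defaults mirror the study scenario of
post-admixture selection: the allele enters on copies of a *single donor
haplotype* at 16% of haplotypes (admixture fraction 0.214 × source
frequency 0.74), N = 500 diploids, s = 0.05, 63 generations, a 2-Mb region
of 2,000 SNPs at r = 1e-7/bp (0.01 cM between SNPs — the genetic spacing of
a dense genotyping array, compressed to desk scale). `carrier_init =
"standing"` instead starts from an existing standing variant (soft sweep).
Allele loss or fixation is reported, never raised.
`simulate_scan_genome` appends neutrally evolved chromosomes generated
under the same forward demography, so genome-wide standardization of scan
scores compares like with like.

Two structural properties of this small-N regime matter for interpreting
scan results, and are established quantitatively by the test suite:

* pooled standardized iHS on neutral genomes is accurately N(0,1)
  (KS p ≈ 0.3 on ~7,000 pooled scores), and the planted sweep is
  recovered as a top-ranked window region;
* however, 63 generations at 2N = 1,000 give every haplotype pair a ~6%
  chance of a recent common ancestor, which puts a homozygosity floor near
  the 0.05 EHH truncation threshold. That floor caps standardized scores
  at |z| ≈ 2–3 and spreads the sweep signature over many adjacent windows,
  so which window within the swept region ranks exactly first is close to
  a lottery: the focal window is reliably in the top ~2% of windows but
  ranks first in only a minority of replicates. This is a property of the
  simulated population size and time depth, not of the scan implementation
  (on a noise-free planted sweep the same code yields raw iHS ≈ −5.3, a
  200-fold iHH ratio).

## Selection coefficient

`forward_frequency` iterates the deterministic one-locus recursion from
Hardy–Weinberg genotype frequencies and the fitness scheme above;
`solve_s` inverts it by bracketed root finding (Brent, tolerance 1e-8) on
s ∈ [0, 1], which is valid because the final frequency is strictly
increasing in s. The initial frequency of an admixture-introduced allele is
`α × f_source` (recipient assumed allele-free). With α = 0.214,
f_source = 0.74, target 0.48 and 63 generations, the dominant fit gives
s ≈ 0.038; the source allele frequency is an assumption, so this number is
a consistency anchor rather than an estimate.

## LTT phenotype and GWAS

The phenotype is the maximal rise of blood glucose over the 20/40/60-min
post-ingestion measurements relative to baseline, as a raw difference
(negative rises allowed). Classes: intolerant < 1.1 mmol/l, intermediate
1.1–1.7, tolerant ≥ 1.7, boundaries assigned upward because the strict
inequalities of the classical definition leave them undefined. The
quantitative rise is the default association phenotype; the {0,1,2} class
score is an alternative coding.

QC removes SNPs by call rate (< 0.95), minor allele frequency (< 0.1) and
an exact Hardy–Weinberg test (p < 1e-8; the conditional het-count
distribution is computed by a stable multiplicative recurrence and
cross-checked in the tests against exact integer enumeration). The scan
residualizes the phenotype on covariates (study group, optionally sex, plus
any conditioning SNP dosages) and applies a per-SNP 1-df Wald chi-square of
the centred additive dosage against the residualized phenotype —
asymptotically equivalent to the classical score test for quantitative
traits; conditioning SNPs are excluded from output. Effect sizes are
adjusted R² (as percentages) from an OLS fit of the covariate-residualized
phenotype on the SNP dosage(s), reported as-is (slightly negative values
possible). For two unlinked causal SNPs the per-SNP effect sizes add to
the combined one only up to the sampling noise of the dosage cross-term,
whose SD is `2·sqrt(a·b/n)`; the tests use three such SDs as "simulation
error".

The phenotype generator plants a dominant focal effect (carrier rise 2.1
vs non-carrier 0.7 mmol/l, straddling the class thresholds), an additive
second-locus effect (0.45 mmol/l per allele), group offsets and Gaussian
noise (SD 0.35); the 40-min value carries the peak exactly, so the maximal
rise equals the linear predictor. It does not emulate measurement rounding,
repeat-test variability, or covariance between baseline and rise.

## Pipeline

`PipelineConfig` gathers every stage parameter with the defaults above and
round-trips through YAML; `run_pipeline` derives stage seeds from the
single config seed with fixed offsets, so a demo run is bit-reproducible.
Stage problem sizes in the demo (and the acceptance script) are scaled to
run on a single CPU in minutes: 53 individuals on a four-chromosome 400-Mb
stand-in genome for the tract analyses, 120 individuals × ~2,400 SNPs for
the GWAS, and N = 500 forward sweeps of 2,000 + 4×1,000 SNPs for the scans.
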