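# Methods

## The synthetic intercross

The generator emulates an advanced intercross line (AIL): two founder
lines fixed for alternative alleles at every marker (R = Red Junglefowl,
W = White Leghorn), an F1 that is heterozygous everywhere, and random
mating thereafter. Meiosis follows **Haldane's model** — crossovers
without interference — implemented exactly as a two-state phase Markov
chain that switches between parental haplotypes with probability
r = (1 − e^(−2d/100))/2 per marker interval of d cM. This matches the
map function used by the scan engine, keeping simulation and inference
consistent.

Generation counting includes the founders: `n_generations = 2` yields
the F1 and the default of 9 yields an F8 mapping population.
Intermediate generations pair the entire pool with equalized litter
sizes, which keeps drift modest (effective size near twice the census
size); the final generation is expanded from `n_breeding_pairs`
(default 30) litters, whose identities supply the **family** covariate
standing in for "population structure". A litter cap of 20 offspring
per pair per generation bounds what can be bred without selfing.

Defaults are a scaled-down version of the study design used throughout
the tests: 5 chromosomes × 200 cM with markers every 10 cM
(105 markers) and 300 F8 individuals. `full_scale_config()` gives the
study scale: 10 × 920 cM at 16 cM spacing (580 markers, ~9,200 cM
total) and 326 birds. Physical coordinates are an affine image of the
genetic map (default 300 kb/cM), giving a deterministic cM↔bp bridge
for the closest-marker interval conversion.

Phenotypes are `y = μ + Σ(a·x_a + d·x_d) + covariates + ε` with
x_a ∈ {−1, 0, +1} (W-allele dose − 1) and x_d the heterozygote
indicator, evaluated at the marker nearest each planted QTL. Covariates
are balanced sex (0/1), a 4-level batch, pedigree family, and Gaussian
body weight (1800 ± 250 g, the scale of an adult chicken); batch and
family contribute per-level Gaussian effects of a configurable SD.
`noise_sd_for_pve` solves var(g)/(var(g)+σ²) = PVE for the *realized*
genetic values, so the target variance explained holds in expectation
for the population at hand.

Outline populations are generated in coefficient space
(mean + dose·effect + noise, inverted by the Fourier series), and
expression as baseline + cis dose term + trans dose terms + per-batch
effects + noise, with ground-truth cis/trans labels returned. Planted
cis effects act at the marker nearest the probe; trans effects at a
regulator position elsewhere.

What the generator does **not** emulate: sequence-level variation or LD
beyond map-distance recombination, selection during breeding, marker
ascertainment, array normalization artifacts, or the photographic
segmentation noise of real silhouettes. Tests passing on this
generator therefore validate the statistical machinery and its
calibration, not robustness to those real-data complications.

## Morphometrics

Tracing is Moore-neighbor boundary following with Jacob's stopping
criterion on the largest 8-connected foreground component. Traced
pixel chains carry a staircase whose inflated arc length biases the
Fourier parameterization; `smooth_outline` (default 20 iterations of
(¼, ½, ¼) neighbor averaging) removes it while leaving wavelengths of
tens of samples essentially untouched — with it, mask → trace → EFA
recovers planted per-harmonic amplitudes within 1% at 512 px for
harmonics 1–5.

Outlines are resampled to k points equally spaced by cumulative arc
length (default 16,570, the resolution of the comb data set) and
aligned by generalized Procrustes analysis: center, scale to unit
centroid size, rotate (no reflection) to the iteratively re-estimated
mean, stopping at a 1e-8 mean-shape change or 100 iterations.

EFA uses the Kuhl–Giardina segment integrals of the piecewise-linear
outline with **equal parameter increments** per sampled point. On
arc-length-resampled outlines — the pipeline's invariant input — this
is identical to the classical chord-length parameterization; on a
parametric curve sampled at equal parameter values it reproduces the
analytic coefficients exactly (a 2:1 ellipse gives |a1| = 2, |d1| = 1
with >99.99% of power in harmonic 1). Orientation is normalized to
counterclockwise before decomposition; no first-harmonic size/phase
normalization is applied because outlines are pre-aligned. H harmonics
yield 4H coefficients; the two offsets (A0, C0) are excluded from PCA.
The default H = 26 captures >99% of harmonic power on comb-like
outlines. PCA centers columns but does not rescale them (coefficients
share units).

## QTL and eQTL scanning

Genotype probabilities come from a three-state forward–backward pass
with F2-type transition matrices built from the Haldane map function;
`error_prob` (default 0) allows for genotyping error, and `step > 0`
inserts a pseudomarker grid (default: markers only). The F8 is scanned
with the F2 three-genotype model on the supplied map, without an AIL
map-expansion correction: the cross file is expressed on the same map
the simulator uses, so simulation and inference agree by construction.
The practical consequence of real F8 recombination is visible in the
scans — LOD decays steeply away from peaks, and 1.8-LOD-drop intervals
are often a single marker wide.

Haley–Knott regression was chosen over an EM mixture likelihood because
the model statement is a fixed-effects regression and ordinary least
squares is deterministic and oracle-checkable; the suite verifies every
scan LOD against an independent normal-equations solve to 1e-8. Small
differences from mixture-based engines are expected at heavily missing
genotypes.

Permutation thresholds shuffle individual labels: trait and covariate
rows move together against genotype rows, preserving trait–covariate
association under the no-linkage null. Internally this is computed by
relabeling the covariate basis and residualized trait (via the
Frisch–Waugh decomposition, exploiting that the genotype Gram matrix is
label-invariant), which makes 1,000 permutations a few BLAS calls.
Defaults: 1,000 permutations, 0.95 significant / 0.80 suggestive
quantiles (linear-interpolation convention; ties at the threshold count
as exceeding), genome-wide p = fraction of permuted maxima ≥ observed.

Interactive-covariate scans (e.g. sex) report the full-with-interactions
model against the covariate null as their own `ScanResult`, not a
subtracted curve. Missing genotypes are handled by the HMM; missing
phenotypes/covariates by listwise deletion per trait. `%Var` is defined
as the partial R² of (x_a, x_d) given the covariates, ×100.

eQTL scans share one set of label shuffles across probes (each probe
still gets its own genome-wide max-LOD null), keep each probe's single
best peak, retain both suggestive and significant records with the tier
recorded, and classify **cis** iff the probe lies on the peak's
chromosome within 50 cM (boundary inclusive); probes without a map
position are flagged unclassifiable rather than erroring. The
cis distance is measured in cM, and same-chromosome is required.

## Colocalization

Support intervals are converted to physical coordinates by taking the
bp position of the marker closest to each cM endpoint (ties break to
the lower position). Overlap uses closed intervals — touching
endpoints overlap — on either axis, never mixed.

The enrichment null places n_A and n_B random regions of the observed
sets' mean lengths uniformly on the genome: a start is drawn on the
concatenated per-chromosome axis and intervals running past a
chromosome end are shifted back to fit, so no region spans a chromosome
join. "Number of overlapping regions" is resolved as the count of B
regions (eQTL or sweeps) overlapping at least one A region (QTL); the
counting rule is recorded in the result. The one-tailed p uses the +1
correction, (1 + #{null ≥ observed}) / (1 + iterations), so it is never
zero. Pearson correlations between colocalized expression and
phenotype use the two-sided t test with n − 2 df; per-pair p-values are
reported raw (no multiple-testing correction), with a 0.05 significance
flag mirroring the retention rule for reported pairs.

## Problem sizes and calibration checks

The acceptance-style checks run at desk scale: null calibration and
planted-QTL recovery use the default 5 × 200 cM / n = 300 design with
1,000 permutations per replicate (200 replicates in the test suite, 100
in `scripts/acceptance.py`); eQTL checks use n = 200 with planted
effects of 3 noise-SD; enrichment self-calibration draws 500 observed
values against 2,000-iteration nulls with 10 QTL-sized and 300
eQTL-sized regions on a 5 × 50 Mb genome (the region count is chosen
large enough that the discrete overlap count has wide support, a
prerequisite for a near-uniform p-value). All randomness flows from
explicit seeds; identical seeds reproduce results bit-for-bit.

## Known limitations

- The F2-model scan of an F8 population is internally consistent here
  but understates map expansion for real AIL data expressed on an
  F2-scale map.
- Single-marker support intervals (common at this marker spacing and
  generation number) make CI-overlap colocalization conservative.
- The enrichment p is approximately uniform only when the null overlap
  count has reasonably wide support; with very few regions its
  discreteness makes the test conservative.
- No X-chromosome handling, multiple-QTL models, epistasis scans, or
  assembly liftover.
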