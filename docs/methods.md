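# Methods

This note records the models behind each `pollenpop` module, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that affect results.

## Synthetic panel (`simdata`)

**Genotypes.** Two subpopulations labelled *feral* (A) and *domesticated*
(B). Ancestral allele frequencies are uniform on [0.05, 0.95]; each
population's frequency is drawn from the Balding–Nichols Beta distribution
with parameters p(1−F)/F and (1−p)(1−F)/F, which has mean p and variance
F·p(1−p). This is the simplest drift model with a known F_ST expectation
(E[θ] ≈ F), which makes it usable as an oracle: simulating at F = 0.05
must yield a genome-wide Weir–Cockerham estimate near 0.05, and the test
suite asserts exactly that. Genotypes are Binomial(2, p) per individual;
read depths Poisson (default mean 19, a typical mid-coverage
genotyping-by-sequencing panel); missingness is independent Bernoulli
(default 2%).

**Sweeps.** A planted sweep at (chromosome, position, strength s) pushes
the domesticated-population frequency deterministically toward fixation,
p′ = p + w(1−p) with w = s·max(0, 1 − d/1 Mb). A deterministic push with
linear decay creates localized differentiation, diversity loss and
composite-likelihood signal over roughly the window scale the scan uses,
without coalescent machinery; it does not generate the haplotype structure
a real sweep leaves, so haplotype-based statistics are out of scope.

**Tetraploids** are emulated purely as inflated apparent heterozygosity
(doubled heterozygote probability, capped at 1) in diploid-coded calls,
because the downstream ploidy call uses heterozygosity proportion alone.

**Phenotypes.** y = Xβ + shift + e with n_qtl causal SNPs (default 200 of
2000, a polygenic architecture), β standard normal on the dosage scale,
and Var(e) scaled against the realized Var(Xβ) so the realized additive
fraction equals the target h² up to Monte-Carlo error in e. The
between-group shift is expressed in phenotypic standard deviations and
applied to population B. Defaults: h² = 0.8 (the scale of a strongly
heritable floral trait), no shift.

**Cytometry particles.** Default 600 particles per individual. Fertile
particles carry every feature strictly inside its gate; per-individual
mean pollen length is spread uniformly over 39–57 μm (the within-species
span of the emulated panel) with 2 μm within-individual SD, elongatedness
uniform on 1–1.3, and area π/4·L·W. Fluorescence channels are correlated
log-normals (a shared log-scale factor giving pairwise r ≈ 0.9); no
biochemical realism is claimed — the generator has no model for what the
intensities *are*, only for their correlation structure. Each contaminant
class (default 5% each) violates exactly one designated gate: aborted →
median-pixel, stacked → symmetry 3, debris → diameter, blurred → gradient
RMS. This makes fertile-class precision and recall exactly 1.0 a
*construction invariant*, so the gating tests certify the cascade logic,
not the instrument: passing them says nothing about how well the real
gates separate real aborted pollen from fertile pollen.

**Randomness.** One integer seed; each generator draws from a sub-stream
derived with a fixed component offset, so genotypes, phenotypes and
particles are individually reproducible.

## Gating (`gating`)

Gates are applied in cascade order (diameter; brightfield + median pixel;
symmetry 3 + 4; correlation mean + gradient RMS) and all ranges are closed
intervals — endpoint values pass, matching the usual semantics of
cytometry-software regions. Negative brightfield values are accepted
verbatim (background-subtracted arbitrary units). The 1%/99% pollen-length
trim is computed on the pooled retained particles with
linear-interpolation quantiles; particles strictly outside the band are
removed. A per-individual trim is available behind
`GateConfig.trim_per_individual` because the pooled reading of "removed
from the data set" is not the only defensible one. The instrument's
acquisition stop rule (5000 particles or 6 minutes) is acquisition, not
analysis, and is not modelled. Anther medians expect six measurements per
individual and log a warning otherwise.

## Variant QC (`variantqc`)

Per-genotype depth masking precedes the site-level filters, so a site can
fail the call-rate rule purely through masking — the semantics of running
per-genotype `--minDP` and per-site filters in a single VCFtools-style
pass. Rule order is: depth mask → biallelic/indel drop → call-rate →
MAF (computed on called genotypes only). The order matters and is
reported per rule; filtering is idempotent. Ploidy classification assigns
each individual the ploidy of the nearest reference-class mean
heterozygosity, with midpoint ties broken toward the lower ploidy
(conservative, logged). LD decay uses squared Pearson correlation of
dosages on pairwise-complete observations; pairs with an effectively
monomorphic member are skipped because r is undefined.

## Population structure (`popstruct`)

Genotypes are standardized per site (centered at 2p, scaled by
√(2p(1−p))); missing values are set to zero *after* centering, i.e. to
their expectation, which is unbiased under missing-at-random and is the
common convention for genotype PCA. Monomorphic sites are rejected rather
than skipped, forcing an explicit MAF filter. Eigenvectors are sign-fixed
(largest-magnitude loading positive) so output is deterministic.

## Heritability and GWAS (`gwas`)

**GRM.** VanRaden: A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)),
missing dosages mean-imputed.

**GREML.** Single genetic component, y = μ + g + e with g ~ N(0, σ²_g K).
The GRM is eigendecomposed once so every iteration is O(n). Updates are
average-information steps, truncated at the parameter boundary and
step-halved if the restricted likelihood would decrease, with an
expectation-maximization step as fallback (EM is monotone, so the
trajectory never decreases). Convergence: relative log-likelihood change
< 10⁻⁶, at most 100 iterations, error (with the trajectory attached)
otherwise. The h² standard error comes from the inverse AI matrix by the
delta method. A GRM numerically proportional to the identity is rejected
as unidentifiable. At n ≈ 100 the null likelihood over h² can be nearly
flat and single-draw estimates scatter widely (the profile likelihood
between h² = 0 and h² = 1 can differ by under two units); null-recovery
properties are therefore stated at n = 400, where the spread collapses.

**Iterative scan.** Iteration 0 is a vectorized per-marker least-squares
t-test given the base covariates. The genome is cut into 10 Mb bins; the
most significant SNP per bin with p < 10⁻⁴ becomes a pseudo-QTL
*candidate*, and the set actually used is the p-ordered prefix of
candidates maximizing the likelihood of the random-effect model
y = μ + u + e with kinship built from those SNPs (profiled over a fixed
h² grid, evaluated with a low-rank Woodbury identity so no n×n
decomposition is needed). Later iterations re-test every SNP with the
pseudo-QTLs as fixed covariates, excluding any pseudo-QTL in the tested
SNP's own bin; the loop stops when the set repeats. This is faithful to
the published two-model loop but is not a re-implementation of GAPIT
internals (no bin-size ladder, no SUPER kinship); the prefix search is
this package's convention. Significance is Bonferroni at α = 0.05 over
the tested SNP count. Per-SNP explained variance (PVE) is defined as the
R² increment of adding the SNP to the final covariate model — the
literature rarely prints its formula, so the convention is stated here.
Collinear covariates are dropped with a warning.

**Validation wrappers.** Subsampling re-runs the full scan on a random
95% of individuals per run and reports per-SNP detection rates;
permutation shuffles phenotype labels and reports the experiment-wise
false-positive rate. Under Bonferroni the nominal experiment-wise level
is 1 − (1 − 0.05/m)^m ≈ 0.049. Note that in a structured panel a SNP
strongly correlated with a causal SNP through drift can be "detected" in
subsample runs; that is proxy detection, not a type-I error.

## Selection scan (`selscan`)

Windows are 1 Mb with 250 Kb overlap, read literally as step = 750 Kb
(the step-250 Kb alternative is a config option). Only windows containing
at least one SNP are kept. Per-site Weir–Cockerham components a, b, c are
the standard two-population estimator; windowed F_ST is the ratio of sums,
and negative per-site components are retained (no clipping). Per-site
π = 2p(1−p)·n/(n−1) with n the called allele count; the window value
divides by window length in bp. DRI = π_feral/π_domesticated, undefined
(and excluded from ranking) where the denominator is zero.

The XP-CLR variant models the object (domesticated) frequency given the
reference (feral) frequency as truncated-Normal(p₀, ω·p₀(1−p₀)) on [0,1],
with the drift variance ω estimated genome-wide by method of moments. A
sweep of coefficient s at the window center lets a site at genetic
distance d (physical distance × a uniform 1 cM/Mb in the absence of a
map) escape with probability c = 1 − exp(−d/s); the non-escaping mass
adds (1−c)/4 to the variance, a bounded stand-in for the
near-fixation/near-loss mass a hitchhike produces. The window score is
2·(max over the s grid {0, 10⁻⁴, 10⁻³, 10⁻², 10⁻¹} − neutral), hence
non-negative, and — like the published statistic — comparable only within
a run, which suffices for percentile-based outlier calling. Significance
for all three statistics is "strictly above the genome-wide 95th
percentile", requiring at least 20 defined windows; Z(F_ST) standardizes
the windowed values by their genome-wide mean and SD (windowed, because
published tracks are windowed). QTL screening asks whether any flagged
window overlaps ±5 Mb of the QTL position, per statistic.

## P_ST–F_ST (`pstfst`)

Variance components come from the one-way ANOVA method of moments:
σ²_w = MSW, σ²_b = (MSB − MSW)/n₀ with the standard unbalanced-design
n₀; a negative σ²_b is truncated to zero and flagged. P_ST follows the
formula above with csh = c/h² (default 1, the common-garden assumption).
The bootstrap resamples individuals with replacement within groups — the
cited implementations do not print their resampling unit, so this choice
is recorded as the package's convention — using a percentile CI (no BCa
correction, matching the plain "1000 bootstraps, 95% CI" recipe);
degenerate resamples (a constant group) are redrawn and counted. The
verdict compares the CI against the genome-wide ratio-of-sums
Weir–Cockerham F_ST of the same two groups: selection if the CI lies
above it, drift if the CI contains it, and an "inconclusive" flag (with
a warning) if the CI lies below, which the drift/selection dichotomy does
not anticipate.

## Dispersal (`dispersal`)

Stokes' law for terminal velocity and a ballistic distance D = h_r ū/V_set.
Constants: g = 9.81 m/s², air density 1.225 kg/m³, air viscosity
1.78×10⁻⁵ Pa·s, pollen density 988 kg/m³ (0.988 g/cm³ converted once to
SI), wind 3 m/s. The model assumes the Stokes regime (no Reynolds-number
correction), still-air settling, and a uniform wind; d is a
Stokes-equivalent sphere diameter, so elongated grains require a
caller-chosen effective diameter — there is deliberately no silent
length→diameter conversion. Neutral buoyancy (ρ_p = ρ_m) is allowed and
gives V_set = 0.

## Problem sizes and test design

The validation suite runs each stage at the sizes its statistical claims
need rather than at field scale: 2×50–2×200 individuals, 2000 SNPs over
two 30 Mb chromosomes (≈33 SNPs/Mb, the same order as a GBS panel's
SNP density), 10 seeds for recovery checks, 60 subsample and 200
permutation runs, and 1000-draw bootstraps. These sizes were chosen so
that every Monte-Carlo assertion has comfortable margins under its stated
bound. Because the generator has no within-population linkage
disequilibrium, association signals localize to the causal SNP itself
(plus drift-correlated proxies) rather than to LD blocks; detection-rate
and window-assignment logic is therefore tested in an easier regime than
real data presents.

## Known limitations

* No coalescent or recombination-explicit simulation; no haplotype
  statistics (iHS, XP-EHH) and no genetic-map inference.
* The XP-CLR normalisation differs across published implementations;
  scores here rank windows within a run and are not comparable across
  datasets.
* GREML is single-component; no dominance, epistasis or multi-trait
  models.
* No exact numerical parity with GAPIT/GCTA/VCFtools binaries is claimed
  anywhere; the procedures are implemented from first principles and
  validated against oracles and simulations instead.
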