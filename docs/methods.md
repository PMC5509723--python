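# Methods

This note records the models, estimators, numerical choices and known
limitations behind `refugia`, in the order data flow through the
package.

## Sequence statistics

All per-site statistics divide by the *effective length*: the number of
alignment columns retained after the site filter. The default filter
(`exclude-gap-columns`) removes every column containing a gap or an `N`
in any sequence (complete deletion); `pairwise-deletion` is available
for pairwise distances. The effective length is reported next to every
per-site quantity, so analyses with different filters remain comparable.

Haplotype diversity uses the unbiased estimator
*Hd* = *n*/(*n*−1)(1 − Σ*p*ᵢ²) with Nei's (1987) sampling variance

V = 2/(n(n−1)) [ 2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)² ].

θ̂π is the mean number of pairwise differences per retained site with
Tajima's total variance (which includes both sampling and evolutionary
components); θ̂S is *S*/(*a*₁*L*) with Var(*S*) = *a*₁θL + *a*₂θL².
Pooling the bundled reference haplotype counts gives *Hd* = 0.6286 at
full precision, which prints as 0.629 rather than the source table's
0.628 — rounding inside the original analysis software; the package
always reports full precision.

The haplotype network is the minimum spanning tree on pairwise Hamming
distances between haplotype representative sequences, with every
non-tree edge retained (flagged `alternative`) when its weight ties the
maximum edge weight along the tree path between its endpoints — the
usual minimum-spanning-network convention.

## Neutrality tests and their null

Tajima's *D* follows the 1989 normalization. Fu's *F*s is computed from
exact Ewens sampling probabilities: unsigned Stirling numbers of the
first kind are built as exact big integers and combined in log space, so
*F*s is accurate to machine precision for any *n* the package will ever
see (the exactness is tested to 1e−10 against an independent recursion
for *n* ≤ 8). *R*₂ uses the folded definition of singletons: a site
counts for the sequence carrying the minor allele when the minor count
is 1.

P-values come from constant-size coalescent simulation, left tail for
all three statistics, with a +1 pseudocount. Two conditionings are
offered:

* `fixed-S` (default): the null is the *conditional* distribution given
  the observed number of segregating sites. Genealogies are drawn from
  the standard coalescent and then importance-resampled with weight
  Poisson(*S*; θ̂_W·L/2) before exactly *S* mutations are placed
  multinomially by branch length. Plain uniform placement over
  unweighted genealogies (the common shortcut) is measurably
  conservative for *F*s and *R*₂ (type-I ≈ 0.037 at nominal 0.05 in our
  calibration runs); the importance weighting restores nominal size
  (D 0.052, Fs 0.059, R2 0.048 over 3000 replicates at n = 20, θ = 5).
* `fixed-theta`: unconditional simulation at a supplied θ.

## Mismatch distribution and expansion dating

The sudden (stepwise) demographic-expansion model has a closed-form
expected mismatch spectrum. Writing time in units where the expected
number of pairwise differences accumulated equals the elapsed time, a
pair coalesces at hazard 1/θ₁ in the recent epoch and 1/θ₀ beyond τ, and
the count of differences is Poisson with mean equal to the coalescence
time, giving

F_j = F̂_j(θ₁) · P(j+1, λ₁τ) + e^{−λ₁τ} Σ_{i≤j} τ^{j−i}/(j−i)! · F̂_i(θ₀),

with F̂_j(θ) = θ^j/(1+θ)^{j+1}, λ₁ = 1 + 1/θ₁ and P the regularized
lower incomplete gamma function. Model frequencies are renormalized over
the observed classes 0..d_max before comparison. A three-parameter
spatial (infinite-island) variant is available behind `model="spatial"`:
within-deme pairs either coalesce (hazard 1/θ) or irreversibly separate
into different demes (hazard M/θ) during the recent epoch, with a single
ancestral deme of size θ beyond τ.

Fitting minimizes the sum of squared deviations (SSD) between observed
and expected class frequencies from a coarse grid start (τ over 12
values up to d_max; θ₀ ∈ {0.01, k̄}; θ₁ over three scales) refined by
Nelder–Mead; θ₁ is capped at 1e5 (effectively infinite). Raggedness is
Σ(x_{i+1} − x_i)² over the observed frequency classes. Bootstrap
p-values for SSD, raggedness and the Kolmogorov–Smirnov distance
simulate coalescent replicates under the fitted model (θ₁ as current θ,
growth θ₁/θ₀ capped at 1e6, expansion at coalescent time τ/θ₁), refit
each replicate, and count statistics at least as extreme; the default
B = 1000 can be lowered for exploratory runs and the Monte-Carlo
resolution is 1/(B+1).

Dating uses *t* = τ/(2·μ_gen·k) with μ_gen = μ_year × generation time.
The output distinguishes generations from years (t_years =
t_generations × generation time): published applications of this formula
sometimes label the generations-scale output "years", so both scales are
always reported and confidence limits for τ map through the same linear
transform.

## Dominant-marker frequency estimation

Band absence is the recessive phenotype, so *q*² equals the absence
probability under Hardy–Weinberg. The square-root estimator is
q̂ = √(absence fraction), with the zero-class correction
q̂ = √(1/(2(n+1))) when no absence is observed. The Bayesian estimator
places a Beta(a, b) prior on *q*, with (a, b) fitted per population by
method of moments to the distribution of square-root estimates across
loci, and evaluates the posterior mean exactly: the posterior kernel
q^{a+2x−1}(1−q)^{b+g−1}(1+q)^g (x absences among n scored, g = n − x)
integrates as a binomial sum of Beta functions, computed in log space.

The two estimators serve different purposes. The Bayesian posterior mean
is the default for within-population gene diversity (H_E = mean over
loci of 2p̂q̂), where shrinkage stabilizes small samples. For FST the
shrinkage is harmful: pulling each population's estimate toward its own
population-level prior compresses exactly the between-population
variance being measured (in calibration runs it deflated a true FST of
0.15 to ≈ 0.09), so all FST paths default to square-root estimates.

## FST and the Lynch–Milligan restriction

Per locus, the among-population variance component is the sample-size-
weighted among-population sum of squares minus the expected
contribution of frequency-estimation noise (delta-method variance
(1 − q²)/(4n) per population), divided by the usual Weir–Cockerham
size factor; the denominator estimates p̄(1 − p̄) of the underlying
population frequencies including a correction for the variance of the
weighted mean. Multi-locus FST is the ratio of summed numerators to
summed denominators; negative values are retained (and flagged in
pairwise matrices) so averages stay unbiased.

Loci whose pooled band-absence fraction falls below 3/(mean
per-population sample size) are excluded from FST estimation (the
Lynch–Milligan rule): below that point the square-root estimator is
pinned at its zero-class floor and contributes pure noise — with them
included, calibration runs underestimated a true FST of 0.15 by ~40%;
with the restriction the estimator is close to unbiased across FST
0.05–0.25 at the package's design scale (8 × 15 × 500).

AMOVA Φ_ST uses squared Euclidean distances between band profiles (pairs
rescaled by the fraction of mutually scored loci), the standard
two-level variance decomposition with n_c-weighted among component, and
a label permutation test with +1 correction. Sequence-mode Φ_ST applies
the same decomposition to pairwise difference matrices, so the pairwise
sequence Φ_ST of two populations equals the two-population AMOVA by
construction. Clustering (DAPC-style) runs PCA retaining ≥ 90% variance,
k-means with 20 restarts per K, BIC = n·ln(WSS/n) + K·ln(n), and linear
discriminant axes on the retained components with per-axis
discriminated-variance fractions.

## Outlier scans

**FDIST-style scan.** Observed per-locus FST and mean per-population
heterozygosity 2q̂(1−q̂) are compared against a neutral cloud simulated
from a Balding–Nichols island model: ancestral band frequencies are
resampled from the observed locus means, per-population frequencies are
Beta-distributed at the model FST, dominant phenotypes are binomial, and
the *same* estimation pipeline (square-root frequencies, noise-corrected
variance components, Lynch–Milligan restriction) is applied to the
simulated loci. The model FST is calibrated (≤ 20 iterations, tolerance
0.005) so the simulated 30%-trimmed mean FST matches the observed
trimmed mean. The default cloud is 10⁵ loci. The empirical p of a locus
is the raw exceedance fraction of the cloud within its heterozygosity
bin (20 equal-width bins, merged upward until ≥ 30 members), so a locus
beyond the entire cloud gets p = 0. Two flags are reported:
`outlier_95` (p ≤ 0.05, the conditional 95% level — the flag whose
type-I error and power are calibrated in the test suite) and
`outlier_fdist` (additionally Benjamini–Hochberg q ≤ 0.05 — a much
stricter conjunctive rule; with a few hundred tested loci and a single
moderate outlier its power is intrinsically limited, which is why the
two flags are kept separate). This Balding–Nichols envelope is a
deliberate simplification of a full coalescent island-model simulator:
it matches the two moments the envelope conditions on and runs at desk
scale.

**Bayesian scan.** A reversible-jump MCMC over the hierarchical model
logit(F_ij) = α_i + β_j: β_j is the genome-wide differentiation of
population j (Normal(−1, 1.8²) prior on the logit scale), α_i a
locus-specific selection effect present only when a per-locus indicator
is on (prior odds 10:1 for neutrality; α ~ Normal(0, 1)). Per-population
allele frequencies are integrated against their Balding–Nichols prior by
32-node Gauss–Legendre quadrature inside the dominant-binomial
likelihood. Updates are vectorized across loci (ancestral frequencies,
α, and the jump move factorize given β). Posterior odds are the ratio of
posterior model probabilities, capped at the number of retained samples
rather than infinity. Defaults (burn-in 1000, 4000 samples) are
desk-scale; the chain settings of a production run should be scaled up
via `McmcConfig`. With no data (all calls missing) the sampler recovers
the prior odds (log₁₀PO ≈ −1), which is tested.

**Adaptive call.** A locus is adaptive iff (FDIST flag OR Bayesian flag)
AND at least one significant environmental association — the
intersection rule. It is monotone in its inputs: adding a flag can never
remove a locus from the adaptive set.

## Environmental association

Individuals inherit their population's environmental values (covariates
exist per locality). One logistic regression per locus × variable is
fitted by a damped Newton/IRLS core vectorized across loci (tolerance
1e−8; statsmodels is the independent oracle in the test suite).
Significance requires both the Wald and likelihood-ratio (G) tests below
α/(L×V) with α = 0.01 and L counting *all* loci, polymorphic or not
(monomorphic loci are skipped with a recorded reason but still widen the
Bonferroni divisor; at 521 loci × 7 variables the per-test threshold is
0.01/3647 ≈ 2.742e−6). Complete separation is detected (non-converged
fit that already classifies perfectly, or |β₁| > 15) and flagged; a
Firth-penalized single-model fallback is available. Predictors enter on
their raw scale — p-values and G are invariant to affine rescaling.

A caveat that shapes how these results must be read: with structured
populations (island-model FST ≈ 0.15) and population-level covariates,
individuals are pseudo-replicates and the per-test size is grossly
inflated — in calibration runs essentially every structured null dataset
produced at least one Bonferroni-significant pair. The nominal
family-wise control (≤ α) holds only for unstructured data, which is
what the calibration test verifies; on structured data the association
scan is a *ranking* device whose output must be intersected with the
FST-based scans, exactly as the adaptive-call rule does.

## Variation partitioning

The response is the centered 0/1 band matrix (Hellinger transform
available but off by default); environmental predictors are standardized
so fractions are scale-free; geography is raw longitude and latitude
with no polynomial or spatial-eigenvector expansion. Fractions come from
adjusted R² (Ezekiel correction) of three RDA fits: a = [a+b+c] − [b+c],
c = [a+b+c] − [a+b], b by difference, d = 1 − [a+b+c]; slightly negative
fractions are reported as computed. Rank-deficient predictor blocks drop
collinear columns with a warning. Permutation tests use the vegan-style
pseudo-F: marginal fractions permute response rows; the partial
fractions [a] and [c] use Freedman–Lane permutation of reduced-model
residuals; fraction [b] has no direct test and requesting one raises.
Default 9999 permutations with +1 correction.

## Synthetic data

The coalescent generator draws standard exponential waiting times
(rates multiplied by the growth factor beyond the expansion time for the
sudden-expansion demography) and places Poisson(θ·branch/2) infinite-
sites mutations, each on a fresh alignment column over a monomorphic
background; it errors rather than recycling columns when the requested
length cannot hold the realized segregating sites. Verified properties:
mean pair-coalescence time 1.0, Watterson estimator recovers θ within
5%, uniform p-values under the conditional null, unimodal mismatch
spectra with mode near τ under expansion.

The dominant-marker generator is a Balding–Nichols island model:
ancestral band frequencies from Beta(1, 1) restricted to (0.05, 0.95) by
rejection (so loci are informative at the design scale — dominant
markers outside that range carry almost no frequency information at
n = 15), per-population frequencies Beta-distributed at the background
FST (default 0.15, the middle of the range this design targets), band
phenotypes Bernoulli(1 − (1 − p)²). Planted loci replace the
Balding–Nichols draw with logit(p_j) = logit(p̄) + coeff × standardized
environmental value. Defaults: 8 populations × 15 individuals × 500
loci.

The environment generator lays 8 localities along a lon/lat transect
(Taiwan-scale coordinates by default) and builds each variable as
gradient × standardized transect position (alternating sign across
variables) + Normal(0, 0.5) noise — spatially structured covariates that
are correlated with each other through the shared gradient, as real
bioclimatic variables are.

What the generators do **not** emulate: recombination, isolation by
distance beyond the island model, marker ascertainment and scoring
error, spatially autocorrelated residual environmental variation, and
individual-level covariates. Passing calibration tests therefore
demonstrates correctness of the estimators under the stated models, not
robustness to those real-data complications.

## Reference fixtures

`make_table1_fixture()` returns the published eight-population haplotype
count table (92 sequences, 16 haplotypes) and `table1_reference()` the
printed per-population n, Hd, θπ and θS — inputs for desk-scale
reproduction checks (the printed values themselves are not recomputable
without the deposited sequences). Recomputed Hd matches all eight
printed values to 3 decimals; the Pearson correlation between Hd and
sample size is −0.4977 at full precision, one unit in the third decimal
from the printed −0.497.
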