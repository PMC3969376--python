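# Methods

This note records the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducing results.

## Dominant-marker frequency estimation

A dominant locus exposes only the recessive homozygote: an individual
lacks the band with probability q² under Hardy–Weinberg, where q is the
null-allele frequency. With x band-absent individuals of n, the
likelihood is (q²)^x (1−q²)^(n−x); under a uniform prior on q the
posterior mean has the closed form

    q̂ = B(x+1, n−x+1) / B(x+½, n−x+1),

evaluated with log-Beta arithmetic for stability at large n (the test
suite checks it against numerical quadrature to 1e−8). q̂ is strictly
inside (0,1) — even a monomorphic locus retains a small nonzero
heterozygosity, a prior effect that shrinks as n grows — and is
monotone in x. The posterior variance, from the same Beta-ratio
family, doubles as an estimate of the sampling variance of q̂.

## Heterozygosity and F_ST

Expected heterozygosity is 2pq with p = 1−q. H_T uses frequencies
estimated from the pooled sample; H_W averages within-site values over
sites, then loci. Per-locus F_ST is Nei's G_ST,
(H_T − H_S)/H_T, whose numerator equals twice the among-site variance
of q̂.

**Sampling-variance correction (default on).** With ~18 individuals
per site, the sampling noise of q̂ inflates the among-site variance and
biases G_ST upward by roughly +0.03 — larger than a typical neutral
signal. By default the mean posterior variance of the per-site
estimates is subtracted from the among-site variance before dividing
by H_T. On simulated island-model data with true F_ST = 0.02 at 20
sites × 18 individuals, the corrected trimmed-mean global estimate is
within ±0.015 of truth; the uncorrected estimator lands near 0.046.
Set `bias_correction=False` for the naive form. The null cloud used by
the outlier scan applies the identical estimator, so the scan is
internally consistent under either setting.

Per-locus values are clamped to [0,1] for reporting; the unclamped
estimates are retained (`per_locus_fst_raw`) because rank-based
empirical p-values need the continuous lower tail — clamping puts a
point mass at zero that would distort the null distribution (for loci
with positive observed F_ST the high-tail p is identical either way).
The global mean symmetrically trims 30% of per-locus values from each
end; the untrimmed mean is reported alongside. Pairwise site distances
are untrimmed means of two-site G_ST over the locus subset, with
negatives clamped before averaging; sites with fewer than `min_n = 4`
individuals are dropped, since below that the estimate is mostly prior.

## Simulated neutral null and empirical p-values

The neutral reference is a cloud of (heterozygosity, F_ST) pairs from
an island-model simulation: ancestral band-allele frequency uniform on
(0.05, 0.95), per-deme frequencies Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F), dominant phenotypes binomially sampled at
the observed per-site sample sizes, then re-estimated exactly as the
real data. Because estimation distorts the realized mean, the
Balding–Nichols F is calibrated by bisection on pilot batches (common
random numbers make the realized-vs-F curve monotone) until the
realized trimmed-mean F_ST matches the observed target; calibration
failure to bracket raises with diagnostics rather than returning a
mis-calibrated cloud.

Each empirical locus is compared with the `window_k = 2000` simulated
loci nearest in heterozygosity — a smooth, parameter-light alternative
to fixed binning. One-tailed p-values use the +1/(k+1) convention
(never exactly zero); the low tail (balancing selection) is reported
but not used for classification, since the intersection rule below is
directional. Benjamini–Hochberg step-up at q = 0.10 controls the FDR
across loci; the pre-FDR flag at α = 0.05 is also reported, and which
flag feeds the intersection is configurable (`use_fdr_flag`).

## Bayesian locus-effect scan

The hierarchical model decomposes differentiation locus-by-population:

    logit F_ST(i,j) = γ_i α_i + β_j,
    p_ij ~ Beta(μ_i (1−F)/F, (1−μ_i)(1−F)/F),
    x_ij ~ Binomial(n_j, (1−p_ij)²),

with μ_i the ancestral band-allele frequency (uniform prior), β_j the
population effect (N(−1, 1.8²) prior), and a spike-and-slab locus
effect: γ_i ~ Bernoulli(1/11) (prior inclusion odds 1:10) and
α_i ~ N(0, 2²) when included. All updates are Metropolis-within-Gibbs,
vectorised across loci and sites; the model-indicator jump draws its
candidate α from the slab prior so prior and proposal cancel and the
acceptance ratio is the likelihood ratio times the prior odds. A
prior-only mode (likelihood dropped) must recover the prior inclusion
probability, which is the standard correctness check for the jump move
and part of the test suite.

The per-locus posterior inclusion probability is the evidence for
selection; the flag threshold is 0.95. Defaults are 6000 iterations,
2000 burn-in, thinning 5. Split-chain R̂ on β_j is reported and the
result flagged (never silently returned) when max R̂ > 1.1. A caveat:
when per-site drift is weak, the likelihood flattens as β_j → −∞ and
the chain wanders in that prior-bounded tail, so R̂ values of 1.2–1.8
are common in low-F_ST data while the inclusion probabilities — the
quantity of interest — remain stable across seeds.

Classification is the intersection rule: flagged by both scans →
outlier; by neither → neutral; by exactly one → ambiguous, and
ambiguous loci are excluded from every downstream stage. Direction
(directional vs balancing) follows the sign of the posterior mean α.

## Linkage disequilibrium among outliers

Within each site, association between two band-phenotype columns is
the 2×2 chi-square; the null permutes one column within the site 1000
times after 1000 warm-up draws of the generator. Sites where either
column is monomorphic are skipped. The summary is the fraction of
(pair, site) combinations significant at 0.01.

## Mantel tests

Distances: environmental = |x_i − x_j| on one variable at a time;
geographic = straight-line Euclidean from site coordinates (the
package does not model along-stream distance); genetic = mean pairwise
two-site G_ST at outlier loci. The Mantel statistic is the Pearson
correlation of upper-triangle entries; the null permutes rows and
columns of one matrix simultaneously (3000 randomizations by default;
an exhaustive mode enumerates all permutations for ≤8 sites and is the
oracle for the sampled p). One-tailed p-values test positive
association — isolation increasing with distance — with the +1/(n+1)
convention.

The partial test conditions on geography by residual permutation
(Smouse–Long–Sokal): both matrices are regressed entrywise on the
conditioning matrix, the observed statistic is the correlation of
residuals (algebraically the first-order partial correlation r_p), and
the null permutes the residual matrix of the first. When the
conditioning matrix is uncorrelated with both, r_p equals the simple r
exactly. Per-variable results carry a Holm-adjusted column; the
headline significance flag is the stricter p < 0.001.

## Specialization index

S = σ_g/σ_s with sample (n−1) standard deviations; S is invariant to
affine rescaling of the variable. Significance comes from randomizing
site subsets of the same size as the occupancy (999 draws, one-tailed
for large S, +1/(n+1)). A variable constant at the occupied sites
yields S = +inf with the minimum attainable p; a variable constant
everywhere is uninformative and skipped. Species present at fewer than
3 sites are rejected — one site short of that, a standard deviation is
meaningless.

Variable pruning (optional, off by default since the generator emits
uncorrelated variables) greedily eliminates one member of the worst
correlated pair (|r| > 0.7) — the member with the larger mean |r| to
all other variables, ties broken by name order. A caveat observed in
testing: with noisy empirical correlations the rule cannot distinguish
a factor from a high-r copy of it, so recovery of planted structure is
guaranteed only up to substitution within a correlated group (exactly
one representative per group survives).

Presence derivation from survey counts requires ≥ `min_count`
individuals in at least one season; the default is 2, the literal
reading of a "more than one individual in either season" rule, with
`min_count=1` available.

## Concordance

Per species the arg-max variables of S and of r_p are intersected
(ties kept and flagged; a match is counted if the tied sets
intersect). A match under random ranking has probability 1/V over the
V variables tested; non-matches contribute p = 1. Fisher's statistic
−2Σ ln p is compared with the chi-square upper tail on 2k df,
evaluated in closed form for even df as exp(−x/2) Σ_{j<k} (x/2)^j/j!
(cross-checked against scipy's survival function). The discreteness of
the per-species p-values makes the combination conservative — the true
rejection rate at nominal 0.05 is far below 0.05 — and this is
documented rather than corrected.

## Synthetic-data generator

The generator emulates a multi-species field study in a heterogeneous
landscape: 62 sites uniform on an ~11 km square (a ~120 km² region),
15 environmental variables with standard-normal marginals and an
exchangeable correlation (0 by default; the matrix is rejected if the
requested correlation is not positive definite). Each species has a
Gaussian niche on one limiting variable: presence probability
baseline × exp(−(z−z_c)²/2w²) in SD units. The default four species
span a generalist (width 1.2, ~41 occupied sites) down to narrow
specialists (width 0.45, ~12 sites), with marker panels of 129, 220,
128 and 473 loci, 6–21 selected loci each, neutral F_ST 0.02, and 18
individuals per occupied site — matching the scale of the field-study
design the analysis targets. A dispersion knob (`n_dispersion`) adds
spread around the mean per-site sample size; the default keeps it
fixed because only the mean is reported for the target design.

Neutral loci drift by the Balding–Nichols approximation to the island
model — chosen over explicit coalescent simulation because it matches
the marginal F_ST structure the scan conditions on and runs in
milliseconds. Selected loci follow a deterministic logistic cline in
the limiting variable (logit-scale slope keeps frequencies in (0,1)
for any slope). Because a narrow niche compresses the occupied slice
of the gradient (SD ≈ w/√(1+w²)), the default scenario scales each
species' cline slope to 2/occupied-SD so that selected-locus F_ST
lands in the 0.2–0.35 outlier band for specialists and generalists
alike. Phenotypes come from diploid sampling with dominance (band
present iff ≥1 band allele). One master seed fans out to fixed
per-stage streams, so any stage can be reproduced in isolation.

What the generator does **not** emulate: fragment-size homoplasy and
scoring error (real AFLP data carry a ~0.3% replicate error rate),
spatially autocorrelated environmental variables, correlated niches
across species, a two-season sampling calendar, and selection acting
through anything other than a monotone cline. Passing tests therefore
demonstrate estimator correctness and calibration under the idealised
island-plus-cline model, not robustness to those real-data features.

## Problem sizes used in the test suite

The acceptance-style tests run scaled-down but structurally faithful
configurations chosen as sensible desk-scale defaults: null clouds of
6000–10000 simulated loci (pilot batches of 3000–4000), MCMC chains of
2500 iterations with 1000 burn-in, Mantel tests with 499
randomizations, LD tests with 1000 permutations, 10–20 replicates for
calibration rates, and three full four-species pipeline replicates for
the end-to-end concordance check. The pipeline defaults
(50 000 simulated loci, 3000 randomizations, 6000 MCMC iterations,
999 S-randomizations) correspond to the full-scale analysis.

## Known limitations

- The Bayesian scan is a spike-and-slab Metropolis-within-Gibbs
  approximation of the reversible-jump original; posterior inclusion
  probabilities target the same quantity but mixing diagnostics (R̂ on
  β_j) should be checked on low-information data.
- The sampling-variance correction uses the posterior variance as a
  plug-in for the sampling variance of q̂; it removes most but not all
  of the small-sample bias, and the Bayesian shrinkage of extreme
  frequencies leaves a mild downward bias at high F_ST.
- Geographic distance is straight-line; watercourse distance, likely
  more relevant for stream organisms, is out of scope.
- Mantel-family tests are used as the field standard for
  distance-matrix association despite their known sensitivity to
  autocorrelation; likelihood and mixed-model alternatives are not
  implemented.
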