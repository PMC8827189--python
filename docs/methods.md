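# Methods

This note documents the models implemented in `thermogc`, their
assumptions, the numerical choices behind them, what the synthetic data
emulate, and the limitations a user should know before trusting a result.

## Trees and phylogenetic covariance

All comparative machinery is built on a rooted tree with branch lengths in
time-like units. For tips i, j the base covariance is the shared
root-to-MRCA path length `C_ij`; the diagonal holds root-to-tip distances,
and patristic distance is `C_ii + C_jj − 2 C_ij`. Polytomies are accepted
throughout — no analysis requires a binary resolution. Zero-length terminal
branches are legal input; when they make C numerically singular, matrix
solves retry once with a logged diagonal jitter of `1e-10 × mean(diag)` and
fail loudly if that is not enough. All solves go through Cholesky
factorizations; a non-positive-definite model covariance is an error, never
silently regularized beyond that one logged jitter. Input trees are treated
as authoritative: no re-rooting or rescaling is applied before analysis.

Four trait-evolution models transform C into the GLS error covariance
(σ² factored out and profiled):

- **BM**: `V = C`.
- **Pagel's lambda**: off-diagonals multiplied by λ ∈ [0, 1]; λ = 1 is BM,
  λ = 0 a star phylogeny.
- **OU, fixed root** (ancestral state estimated at the root, not assumed
  stationary): `V_ij = (2α)⁻¹ (1 − e^{−2α t_ij}) e^{−α d_ij}` with shared
  time `t_ij = C_ij` and patristic distance `d_ij`.
- **Early burst**: `V_ij = (e^{r t_ij} − 1)/r`, with the analytic `r → 0`
  limit `t_ij` used below `|r| < 1e-9`.

## PGLS, signal, paired t-test

For a fixed model parameter θ the GLS coefficients and the ML rate have
closed forms, so fitting reduces to a one-dimensional bounded ML search:
λ ∈ [0, 1], log α ∈ [−10, 10], r ∈ [−10, 1], each started from a five-point
grid and refined by bounded scalar minimization — cheap insurance against
local optima, which do occur for OU on nearly star-like data. Slope
standard errors use the unbiased residual variance (denominator n − p);
t-tests use df = n − p. AIC is `2k − 2 logL` with k counting coefficients,
σ², and the model parameter where the model has one. Under a Brownian null
on a 300-tip tree this yields empirical type-I error at the nominal 5%
(measured 0.050/0.050/0.060/0.055 for BM/λ/OU/EB over 200 replicates in the
acceptance suite).

Phylogenetic signal is the same machinery with a mean-only design: ML over
λ with a likelihood-ratio test against λ = 0 on one χ² degree of freedom.
On a star tree the λ-likelihood is flat; the estimate is reported as 0 with
a warning rather than an arbitrary interior point.

The phylogenetic paired t-test models the within-tip difference d = x1 − x2
as Brownian with its own ML λ, estimates the mean difference by GLS, and
tests it with df = n − 2 (mean and variance both estimated; the variance
uses denominator n − 1). A likelihood-ratio alternative is available behind
a flag (`use_lrt=True`); ML-vs-REML conventions differ between reference
implementations, so the choice is documented rather than hidden.

BH adjustment is the standard step-up, applied within caller-declared
families; the headline-regression convention groups the eight GC indexes
per (domain × temperature index), m = 8. P values are never floored by the
package; a published reporting floor such as 2.2e-16 enters only as an
input literal when reproducing printed tables. Note that the BH map is not
idempotent (re-adjusting adjusted values inflates them); the tested
invariants are monotonicity in sorted order, the cap at one, and the
step-up formula itself.

## Composition indexes

Coordinates are 1-based closed (GFF3 convention), converted once at the
parser boundary. GC fractions exclude ambiguity codes from numerator and
denominator; an empty effective length is a missing value (NaN), never 0.
GC_non is defined by exclusion: positions covered by no feature of any type
on either strand, with set semantics for overlaps. GC_4 counts a third
codon position iff the first two bases place the codon in a
fourfold-degenerate family of translation table 11 (CTN, GTN, TCN, CCN,
ACN, GCN, CGN, GGN); the final codon of each CDS is treated as the stop and
excluded; CDS with frame violations, internal stops, or ambiguity in codon
positions 1–2 are skipped and logged. Whether published GC_p values include
stop codons, and how UTRs were separated from intergenic DNA, is generally
unstated in the literature; here GC_p includes the entire annotated CDS and
both UTR and intergenic DNA fall in the unannotated complement.
Dinucleotides are counted on the given strand with overlapping windows (no
wraparound, ambiguous windows skipped) and pooled into ten
reverse-complement classes, which equals double-strand counting up to edge
effects.

Temperature ranks use half-open intervals: <20, [20, 45), [45, 80), ≥80 °C,
coded 1–4. Core families have presence fraction ≥ 1.0 by default; accessory
families fall strictly below 0.05 (both thresholds are arguments, and
raising the accessory threshold can only grow the accessory set).

## Sister pairs and resampling

Pair extraction is a post-order traversal: an internal node pairs iff every
tip below it is still unused and those tips carry exactly two distinct
ranks; same-rank tips pool into one member represented by their mean value;
all tips of a formed pair are marked used. Post-order means the shallowest
qualifying clades pair first, maximizing the pair count; clades spanning
three or more ranks never pair at that node but their sub-clades may have.
The resulting pairs are disjoint, hence phylogenetically independent.

The Wilcoxon signed-rank test drops zero differences, averages tied ranks,
and computes the exact two-sided P for n ≤ 20 by dynamic-programming
convolution over all 2ⁿ sign assignments (tie-averaged ranks doubled to
integers); beyond that, a normal approximation with tie and continuity
corrections. scipy's implementation refuses exact Ps under ties, which is
why the enumeration lives here; it is tested against brute-force sign
enumeration and against scipy in the tie-free regime.

Resampling draws m tips without replacement per round from an RNG substream
keyed (seed, round) — individual rounds are reproducible and adding rounds
never perturbs earlier ones — prunes the tree, and tallies PGLS slope sign ×
significance. A note on power: with evolutionary correlation 0.6 between
the traits, PGLS is essentially fully powered even at m = 40, so the
power-versus-sample-size trend is only visible at weaker correlations; the
acceptance suite demonstrates the strict trend at correlation 0.15
(detection rising from ~0.45 at m = 40 to ~0.99 at m = 150 over 200
rounds), which is the regime where sample size genuinely decides the
outcome.

## Lévy jumps

The generative model adds to Brownian motion a compound Poisson process:
along a branch of length t, K ~ Poisson(λ_J t) jumps, each N(0, σ_J²)
(zero-mean Gaussian jump sizes; no Laplace variant). Conditional on the
per-branch jump counts k the tips are jointly Gaussian with covariance
`σ²C + σ_J² Σ_b k_b m_b m_bᵀ`, m_b the indicator of tips descending from
branch b.

The marginal likelihood is estimated by Monte Carlo over jump
configurations drawn from the Poisson prior (M draws; default 300 for
fitting). Common random numbers — fixed uniforms inverted through each
candidate intensity's CDF — make the estimate continuous enough for
Nelder-Mead over (log σ², log λ_J, log σ_J², μ0), initialized from the
closed-form BM fit. Each configuration's Gaussian density is evaluated by a
Woodbury rank-r update of the Brownian base factorization, so the O(n³)
cost is paid once per tree, not per draw; identical configurations are
deduplicated and the rest batched by jump-set size. Per-branch counts are
capped at 10 per draw (the prior mass beyond is negligible at the
intensities used here; the cap is logged when it binds). AIC compares the
jump model (k = 4) against BM (k = 2: rate and root state).

Per-branch posterior probabilities of ≥ 1 jump are self-normalized
importance-sampling averages under the same prior draws; the effective
sample size is attached, with a warning below 50 — prior proposals are a
blunt instrument, and when the posterior concentrates on few
configurations the pp vector is driven by the dominant draws (which is
usually exactly the planted configuration, as the acceptance suite shows,
but the warning is honest). The Monte-Carlo SE of the log-likelihood
scales as 1/√M only while the importance weights are light-tailed —
roughly, while λ_J × (total tree length) stays around one; at high
intensities the variance estimate itself becomes unstable.

Threshold calibration simulates datasets under the fitted parameters,
recomputes pp against the simulated truth, and reports precision (TP over
called) and recall (TP over truly jumped branches) on a pp-threshold grid,
plus the smallest threshold reaching a requested precision. Precision is
undefined (NaN) at thresholds that call nothing.

Jump–change correlation takes the signed per-branch changes of both traits
— GLS (ML) ancestral state under BM at the child minus at the parent,
observed values at tips — at the called branches and reports Spearman's
rho with an exact permutation P for n ≤ 10 (all n! orderings, evaluated in
chunks) and the t-approximation otherwise. Ancestral GLS under BM is this
package's documented choice of reconstruction; signed changes (not
magnitudes) are correlated.

A statistical caveat found while validating: a jump planted on a branch of
near-zero length is unidentifiable from its neighbour — the posterior mass
lands one branch over. The planted-jump recovery checks therefore place
jumps on branches sampled proportionally to branch length, which is the
measure under which the compound-Poisson process itself drops jumps;
under that measure localization succeeds in ≥ 90% of replicates.

## Penalized-spline mixed model

`y ~ β0 + s(x) + (1|genus) + ε` with s a cubic B-spline smooth
(`basis_dim = 10` basis functions, knots at quantiles) penalized by the
exact integrated squared second derivative (computed per inter-knot
interval with two-point Gauss–Legendre, which is exact for the piecewise-
linear second derivatives of cubics). The penalty's null space — constant
and linear functions — joins the fixed effects; the penalized components
and the genus intercepts become random effects with variances τ_s², τ_g²
estimated by REML over the two variance ratios (grid search then
Nelder-Mead; all algebra reduced to the (q + G)-dimensional random-effect
space by Woodbury identities, so a 500-point fit takes tens of
milliseconds). The edf of the smooth is the trace of its block of the
penalized hat matrix, including the unpenalized linear column: 1 at
infinite penalty, basis_dim − 1 at zero penalty. The P for the smooth is a
Wald statistic on the smooth's coefficients against the Bayesian posterior
covariance σ²(FᵀF + P)⁻¹, referred to χ² with edf degrees of freedom —
approximate by construction, and labelled as such.

Cross-checked against R's mgcv (`gam(y ~ s(x, bs="cr", k=10) +
s(genus, bs="re"), method="REML")`) on a fixed dataset: variance
components agree to three decimals (genus sd 5.647 vs 5.647, residual sd
1.006 vs 1.007); edf differs moderately (7.07 vs 7.65) because the basis
families differ, which is why edf conclusions here are treated as
scale-level (linear vs moderately vs strongly nonlinear), not exact
values.

## Synthetic data

The generators stand in for the curated growth-temperature databases,
assembled genomes and reference phylogenies a field study would download.

- **Trees**: birth–death simulations conditioned on the tip count
  (default birth 1.0, death 0.0), rescaled to unit depth. The simulator
  stops at the n-th birth, which leaves twin tips on zero-length branches;
  one extra tip is simulated and the newest dropped so all terminal
  branches are positive and the covariance is well-conditioned.
- **Traits**: exact bivariate Brownian draws (matrix-normal with
  Kronecker covariance Σ ⊗ C), optional compound-Poisson jumps added to
  the GC trait, an optional constant GC offset on the lowest-Topt clade of
  a requested size (the halophile-outlier pattern), then affine maps into
  plausible measurement ranges (Topt → [5, 105] °C, GC → [25, 75]%),
  recorded in the truth. Ranks derive from the mapped Topt.
- **Genomes**: toy replicons assembled as spacer/gene alternations. CDS
  bodies draw codons from three pools (GC-rich fourfold, medium fourfold,
  AT-only non-fourfold) whose mixture is solved analytically so the
  chromosome hits a whole-genome GC target; fourfold third positions and
  spacers use exact-count base sampling, so GC_4, GC_non and RNA-gene GC
  targets are hit to well under one percentage point. Composition targets
  are chromosome-level: an AT-shifted plasmid legitimately drags the
  pooled value below them. Plus-/minus-strand CDS alternate to exercise
  strand correction. These genomes have no realistic codon usage,
  amino-acid composition, or along-tree sequence evolution — passing the
  round-trip tests validates the index arithmetic and parsers, not any
  biological realism.
- **Presence/absence matrices**: planted core (fraction 1.0), accessory
  (strictly below the threshold) and intermediate families, exactly
  recoverable.

Every generator is a pure function of (config, seed), with RNG substreams
keyed (seed, component, index) so adding one genome never perturbs another.

## Problem sizes

The validation suite and `scripts/acceptance.py` use: 300-tip trees with
200 replicates for PGLS slope recovery and type-I calibration; a 128-tip
tree with 100 replicates for λ-signal recovery (Brownian vs tip-permuted);
100-tip trees with 50 replicates per scenario for Brownian-vs-jumps AIC
selection, jump-intensity recovery (M = 200 Monte-Carlo draws per
likelihood evaluation) and planted-jump posterior recovery (M = 2000);
n = 500 with 50 replicates for the spline edf checks; and 200 resampling
rounds per subsample size. These sizes give stable rates while keeping a
full run in the minutes range on a single CPU.

## Known limitations

- The OU model is the fixed-root form only; no stationary-root or
  multi-optimum variants.
- Prior-proposal importance sampling for the jump model degrades (low ESS,
  unstable SE) at high jump intensities or very large trees; EM-based
  implementations of the same generative model scale better there.
  Per-branch pp values are comparable to those tools property-wise
  (planted-jump recovery), not numerically.
- The paired t-test and PGLS use ML variance profiles; no REML option for
  the regression models.
- Exact Wilcoxon and Spearman enumerations are for small n by design
  (n ≤ 20 and n ≤ 10); beyond that the documented approximations take over.
- `fit_gamm` fits one smooth plus one random intercept — no tensor
  products, multiple smooths, or non-Gaussian families.
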