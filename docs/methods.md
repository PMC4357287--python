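# Methods

This note documents the models implemented in `plastevol`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
affect results.

## Trees and time

Trees arrive from outside (Newick/NEXUS; single tree or a posterior
sample) with branch lengths in expected substitutions per site.  All
rates in the package are therefore *per unit of operational time*, not
per year; no absolute-time calibration is attempted.  Internally a tree
is an array structure (tips first, root last; every non-root node owns
the edge to its parent), which makes post-order peeling, branch painting
and path bookkeeping O(n) and deterministic.  Polytomies are handled
natively by the pruning and peeling code — no zero-length resolution is
needed.  Rescaling a tree to total length 1 (used before placing priors
on the overall character-change rate) preserves all proportions; mapped
histories are carried back to the original lengths by proportional
segment rescaling.

## Geometric morphometrics

Eleven fixed 2-D landmarks per specimen.  Centroid size (CS) is the root
summed squared landmark-to-centroid distance.  Generalized Procrustes
analysis centers each configuration, scales it to unit CS, and
iteratively rotates it to the running consensus (2-D orthogonal
Procrustes by SVD with a determinant correction — reflections are
forbidden because biological left/right is meaningful); convergence is a
consensus RMS change below 1e-10 (cap 100 iterations).

Specimens are averaged into species units (or species-morph units for
dimorphic species, suffixed `_St`/`_Eu`) by a within-unit GPA followed by
averaging of aligned coordinates; the unit means are then superimposed
together.  Averaging raw coordinates across specimen orientations would
be ill-defined, which fixes this order.  Raw centroid sizes are averaged
arithmetically and enter form space as a natural-log column appended to
the 22 shape coordinates.  PCA is covariance-matrix PCA (mixed-scale
form space is intentional: log CS should dominate when size varies
most).  Phylogenetic PCA computes the GLS mean under the shared
path-length matrix C, eigen-decomposes the C-weighted covariance of the
deviations, and projects the deviations; on a star tree it reduces
exactly to ordinary PCA.  The St morph represents dimorphic species in
phylogenetic PCA, and PC1 of the phylogenetic form PCA is the trait
carried into the rate analyses.

## Disparity

Two morphospace-occupation metrics on the PC axes that each explain more
than 5% of variance: the sum of per-axis sample variances (n−1
denominator), and the PCA volume — the product of positive eigenvalues
(tolerance 1e-12 × leading eigenvalue) of the Gower-centered pairwise
squared-distance matrix, divided by n².  Group estimates rarefy to the
smallest group *inside* a bootstrap loop: each replicate resamples the
group with replacement, then subsamples without replacement (rarefaction
subsamples; the bootstrap resamples).  Pairwise tests report
`p = 2·min(P(Δ* ≤ 0), P(Δ* ≥ 0))` over bootstrap differences, capped at
1.  The bootstrap unit is the species (or morph) within a group.  Neither
metric corrects for phylogenetic non-independence; the rate analyses do
that job.

## Character mapping

The dimorphism evolves by a two-state continuous-time chain with gain
rate `q01` and loss rate `q10`, bridged to an (overall rate, bias) pair
by `q01 = 2λβ`, `q10 = 2λ(1−β)` — so λ is the expected number of
transitions per unit length at stationarity when β = ½.  Likelihoods use
Felsenstein pruning with closed-form 2×2 transition matrices and
per-node scaling; the root is integrated against the stationary
distribution by default (flat or fixed distributions are options).

Prior calibration runs a Metropolis chain over (λ, β) on the tree
rescaled to unit length, with an Exponential(mean 10) hyperprior on λ and
a flat prior on β, then moment-matches a gamma to the λ draws and a beta
to the β draws and discretizes both into equal-mass categories
represented by bin medians (90 rate and 31 bias categories, the
discrete-gamma convention).  The calibration objective of the historical
mapping software is not published; moment matching is this package's
documented stand-in.  An effective-sample-size check warns below 100.

Stochastic maps draw (λ, β) per map from the grids (or use a fixed
model), sample joint node states root-to-tip from the pruning
conditionals, and fill in each branch with an endpoint-conditioned path
by uniformization — exact, and immune to the stalling of rejection
sampling on long branches with unlikely endpoints.  Summaries are the
gain/loss count distribution and a per-branch time-weighted probability
of the derived state (the density map).

## Evolutionary rates

**ML non-censored rate test.**  For a painting of the tree into regimes
(Rh / Dm / Mn), the trait covariance is `V = Σ_g σ²_g C_g`; the root is
profiled by GLS and rates are optimized in log space (bounds 1e-10 to
1e10, three starts seeded by the single-rate closed form).  Five
regime-to-rate models are compared by AICc with `n` = number of tips and
`K` = number of rates + 1 (the root counts as a free parameter — stated
explicitly because AICc values depend on it).  ΔAICc > 4 flags a model
as much less supported.  Likelihood-ratio tests (chi-square, df = ΔK)
are computed **only for nested pairs** — nestedness is partition
coarsening — and ΔAICc serves for non-nested pairs; a chi-square
comparison of non-nested models is not statistically defensible, so this
package does not produce one.  Model averaging across mapped histories
(and optionally across models by Akaike weights) yields per-group mean
rates with SDs.

**Branch-rate MCMC.**  A relaxed Brownian model with at most three local
clocks: rate shifts sit on edges, and every edge inherits the clock of
its nearest ancestral shift.  Moves are clock-rate scaling (uniform
kernel of width 1.5 on the log rate), shift relocation, and birth/death
of a shift with the new rate proposed around the rate currently painting
the chosen edge.  Priors: truncated Poisson(ln 2) on the number of
shifts, uniform over shift placements given the count, log-normal(0, 2)
on each clock rate.  The Poisson default matters: with a flat prior on
the clock count, an extra, nearly unidentifiable clock costs nothing and
the count posterior collapses to its prior, so single-rate data would
never concentrate on one clock.  The sampler was validated against
numerically integrated exact marginal posteriors of the clock count on a
small tree (agreement of posterior odds to ~1%).  The likelihood is the
O(n) peeling form of the profiled BM likelihood, verified to machine
precision against the dense GLS route.  Group summaries weight branch
rates by branch length; HPD intervals use the shortest-interval rule;
group differences get two-tailed randomization p-values from permuting
branch-to-group labels.

## Trait correlation

**Threshold model.**  The binary trait is the sign of a latent liability
evolving with the observed complexity index under bivariate BM.
Identifiability is the standard normalization (liability rate 1,
threshold 0).  Per sweep, liabilities are Gibbs-sampled from their
truncated-normal full conditionals (O(n) per tip via cached C⁻¹ rows)
and (r, rate, two roots) get Metropolis updates; r carries a flat prior
on (−1, 1).  Runs from different seeds (and different trees when a tree
set is supplied) are pooled after burn-in; the point estimate is the
posterior mean, with median and histogram mode also reported because the
"ML estimate from MCMC output" convention is ambiguous.  The complexity
index (0–9) is treated as observed and continuous.

**Random walk + Bayes factor.**  The 0/1-coded dimorphism and the
complexity index evolve under bivariate BM with free rates and
covariance (dependent) or zero covariance (independent); root values are
GLS-profiled, so the likelihood depends on the data only through a 2×2
scatter.  `log BF = 2·(lnML_dep − lnML_indep)`, with >10 read as very
strong support — the convention must be fixed for that cutoff to mean
anything, and this is the one used throughout.  The marginal likelihood
uses the harmonic-mean estimator for comparability with the classical
workflow, with a warm-started stepping-stone ladder (16 power-posterior
rungs, β spaced as (k/K)^(1/0.3)) as the more stable cross-check.  At
desk-scale chain lengths both estimators carry Monte-Carlo uncertainty
of roughly ±2 log units; conclusions should rest on the sign and
magnitude class, not the digit.  The regression coefficient
`b = cov_phylo(x, y)/var_phylo(x)` is also reported.

## Complexity and induction statistics

The complexity index is the row sum of a binary structure matrix (25
structure columns in the reference design).  The image-level scoring
rules (vertex < 135°, iterative and bilaterally duplicated structures
collapsed to one) are applied when the matrix is built and are out of
computational scope here.  Induction experiments pool replicate plates
into one 2×2 table; the test is Fisher's exact (probability-mass
two-tailed rule) and the effect size is the conditional maximum-
likelihood odds ratio of the noncentral hypergeometric model — the
estimate Fisher's-exact frameworks report, not the sample cross-product
ratio — infinite when the observed count sits at the edge of its
support.

## The synthetic-data generator

`reference_dataset` emulates the study design: 36 outgroup Rhabditina
tips + 54 diplogastrid tips (pure-birth subtrees joined with stems that
equalize depths), a dimorphism gained once on the radiation stem and
lost exactly ten times, group rates σ² = (1, 3, 9) for (Rh, Dm, Mn),
about five landmark specimens per species or morph, and induction
fractions (34% treatment, 6% control) at 200 individuals per plate in
triplicate — the published pooled fractions of the reproducible starved
assay.

The loss history is sampled constructively: ten loss events on distinct,
non-nested ingroup edges chosen with probability proportional to edge
length (the placement law of a low-rate loss process conditioned on its
count), each at a uniform position.  Candidates are rejected until
(i) every loss founds its own maximal monomorphic clade, (ii) the
Sankoff parsimony minimum equals 11 transitions — so no delayed-gain or
merged-loss reconstruction explains the tips more cheaply — and (iii)
the monomorphic group has 22–38 tips (the study counted 31 monomorphic
vs 23 dimorphic diplogastrids).  Without (i)–(ii) the mapped gain/loss
posterior would legitimately concentrate on cheaper histories than the
generating one; these conditions encode the fact that the study's data
themselves evidence ten independent losses.  The preset's nominal Mk2
rates (q01 = 0.01, q10 = 0.15) are the mapping model for recovery
experiments; the generating root state is 0 (outgroups lack the
dimorphism), so recovery experiments condition the root accordingly.

Landmark units are the template plus a group deformation (Eu widened and
shallowed; Mn tilted) plus per-unit scatter, with specimens drawn under
a log-normal size, random rotation/translation, and isotropic landmark
noise; the Mn scatter (SD 0.09 vs 0.035) and broader size distribution
create the inflated monomorphic disparity of the study.  The complexity
index is drawn around group baselines (Rh 1, Dm 6, Mn 3, SD 1, clipped
to 0–9) and realized as a random subset of the 25 structure columns.
Within-species landmark variance was not reported by the study, so the
noise levels are free choices; they are fixed once in `SimConfig`.

**What passing tests do and do not show.**  The generator produces
Gaussian landmark noise, exactly binary morphs, a clock-like pure-birth
tree, and a trait that follows the multirate BM model exactly.  Real
data violate all of these (digitization error is not isotropic, trees
carry inference error, traits are PC scores of a finite sample), so the
recovery experiments demonstrate correctness of the machinery under its
own assumptions, not robustness to their violation.

## Problem sizes and determinism

Every stochastic routine takes a seed and is reproducible bit-for-bit;
the dataset generator draws from named substreams so one stage's
parameters do not perturb another's draws.  Study-scale settings
(10 maps × 500 trees, 5000 fits, 10,000/100,000 bootstraps, 30M-
generation MCMC, 50 × 500,000-generation threshold runs) are the
pipeline defaults; `RunConfig.desk_scale()` — used by the examples, the
acceptance script and the heavier tests — runs the same code at reduced
lengths (20 trees, 200 fits, 15–40k-generation chains, 2–5k bootstraps),
sizes chosen so a full pipeline pass completes in minutes on one core
while keeping the recovery experiments' error bands useful.

## Known limitations

* The harmonic-mean marginal likelihood is retained only for
  comparability; treat its Bayes factors as order-of-magnitude.
* The threshold sampler updates liabilities one tip at a time; on trees
  far larger than ~500 tips a blocked sampler would mix better.
* The rjMCMC explores at most `max_clocks` rate classes; scattered
  fast-rate clades beyond that budget share clocks, biasing group
  contrasts toward zero (visible as near-ties in small monomorphic
  groups).
* Prior calibration fits gamma/beta shapes by moment matching, which can
  understate heavy posterior tails at low information.
* Disparity metrics ignore phylogeny by construction.
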