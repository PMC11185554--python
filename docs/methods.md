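# Methods

## The regression problem

All predictors address `y = Xβ + e` with `y` the n-vector of line-mean
phenotypes and `X` the n×m expression matrix, both centered; expression
columns are additionally scaled to unit sample variance (n−1 denominator)
by default, so results are comparable across methods and the
transcriptomic relationship matrix has trace exactly n−1. Centering and
scaling are always learned on the training fold and applied to test rows:
test phenotypes never touch the fit.

Line means average many individuals per genotype, so most residual
phenotypic variance is genetic; the prior calibrations below therefore
target an expected explained-variance share R² = 0.8, matching the
broad-sense heritability of the kind of trait (starvation resistance in
an inbred fly panel) this pipeline is designed around.

## Penalized and dimension-reduction methods

Objectives are scaled as `(1/2n)·RSS + penalty`, which makes the LASSO's
critical penalty `λ_max = max_j |x_j'y|/n` independent of n. The default
tuning grid is 100 log-spaced values from λ_max down to 0.01·λ_max
(ridge reuses the same grid shape on the same surrogate λ_max). The
inner tuner is plain seeded 5-fold CV minimizing validation MSE; exact
ties go to the more regularized candidate (larger λ, fewer components) —
the least-surprising deterministic rule. The minimum-error rule (rather
than one-standard-error) is used throughout.

- Ridge is solved in closed form through the n×n dual system when m > n;
  λ = 0 returns the minimum-norm least-squares solution.
- LASSO uses scikit-learn's coordinate descent (the objective is
  identical); solutions are verified against the KKT subgradient
  conditions at 1e−6 in the tests.
- PCR regresses y on the top-k left singular vectors; PLSR uses the
  wide-kernel recursion on K = XX' so per-component cost never scales
  with m², and is tested to agree with naive NIPALS to machine precision.
  Components are capped at min(n_train − n_folds, 50) so inner folds
  retain rank.
- The sparse group LASSO solves the two-group objective
  `(1/2n)‖y−Xβ‖² + λ[α‖β‖₁ + (1−α)Σ_g √m_g‖β_g‖₂]` by blockwise
  FISTA with a group-level screening rule, to KKT tolerance 1e−6;
  default α = 0.05.

## Spike-and-slab Gibbs sampling

The single-site sampler draws, for each gene, an inclusion indicator and
effect from their full conditionals, then the slab variance σ_β² and the
residual variance σ_e² from scaled-inverse-χ² full conditionals (df = 5)
and π from its Beta full conditional (prior mean 0.5, weight 10 counts;
π can be fixed instead). Hyperprior scales are set so the prior mode of
the residual variance is (1−R²)·var(y) and the prior mode of the
explained variance is R²·var(y), given Σ_j var(x_j) and the prior mean
of π — the convention of the established Bayesian regression samplers in
quantitative genetics. The two-group (GO) variant samples separate
(π, σ_β²) per group and splits the prior explained variance equally
between groups.

Default chain lengths mirror the published protocol for this model
family: 130,000 iterations, 30,000 burn-in, thinning 50 (2,000 retained
draws; the kernel models use 85,000/10,000/50 → 1,500). The benchmark
harness and acceptance script run 3,000/500/5 chains instead: for these
n ≈ 200 problems the retained-draw Monte Carlo error of a mean prediction
is then well below the split-to-split standard error of the accuracy
metric, which is what the benchmark resolves. Convergence is monitored
by trace means and Monte Carlo standard errors exposed in
`PosteriorSummary.diagnostics` (no plots are emitted; the summaries are
the machine-checkable equivalent).

A retained draw is taken when `(it − burn_in + 1) % thin == 0`, giving
exactly `floor((n_iter − burn_in)/thin)` draws.

## Variational spike-and-slab

Mean-field coordinate ascent over (α_j, μ_j, s_j²) per gene, with
closed-form empirical-Bayes updates of the residual variance and slab
scale after every sweep; every update is an exact block maximization of
the evidence lower bound, so the ELBO is non-decreasing (checked at 1e−8
every iteration; a decrease raises). The prior inclusion log-odds runs
over a 9-point base-10 grid spanning [−log₁₀(m), −1]; grid points are
combined by softmax weights on their ELBOs. Iteration stops when the
ELBO improves by less than 1e−6.

## Variational empirical-Bayes mixture of normals

The adaptive-shrinkage prior is a point mass plus K = 20 normal
components with variances geometric between (0.01·ŝ)² and (2·ŝ)²,
ŝ = max_j |x_j'y|/n. The E-step computes each gene's exact
single-coordinate posterior (responsibilities and moments) given the
others; the M-step re-estimates the simplex of weights and σ_e². The
ELBO is evaluated at the stored variational state and is provably
non-decreasing. Stopping: relative ELBO change below 1e−8 or 1,000
sweeps — the weight-EM tail is extremely flat (near-duplicate small
components are statistically indistinguishable), so the cap usually
binds on large problems; effects and predictions are converged long
before. Warm-starting from LASSO estimates (the benchmark default)
follows the established usage of this model family.

On null data the mixture weight ties among the spike and the components
far below the likelihood noise floor; the identifiable statement — and
what the tests assert — is that ≥90% of the mass sits on effectively-null
components and the fitted effects explain <2% of variance.

## Kernel models

`build_trm` computes T = WW'/m over any gene subset of a standardized
matrix; group kernels are each divided by their own gene count, keeping
every kernel's trace at n−1 and making variance components comparable
(the alternative total-m scaling is a constant rescaling of σ_t² and can
be had by constructing `Kernel` directly). Sampling runs in each
kernel's eigenbasis: transformed effects have independent normal full
conditionals, so a sweep costs O(n²) for the rotations. Prediction for
held-out lines builds the kernel over train∪test lines, masks the test
phenotypes, and imputes them from N(t, σ_e²) each sweep — the posterior
mean of the masked lines' genetic values is the prediction. The
closed-form conditional mean `T_test,train (T_train,train + ρI)⁻¹ y` at a
fixed variance ratio ρ is retained as the test oracle, along with the
identity to ridge regression on W.

## The evaluation scheme

25 random 90/10 splits (test size = round(0.10·n); 198 lines → 20 test,
178 train), each replicate seeded as base_seed + r. Accuracy is the
Pearson correlation between observed and predicted test phenotypes
(linear predictors make Pearson the natural choice); the summary reports
mean ± standard error across splits, labeled as SE explicitly. Constant
predictions score 0 with a flag rather than NaN so aggregation stays
total; a method that raises on a split is excluded from its summary with
the reason recorded. Per-method RNG seeds derive deterministically from
(base_seed, replicate), so a full run is byte-for-byte reproducible on a
fixed BLAS configuration.

## The GO pipeline

Terms are filtered to ≥5 genes present in the expression matrix (sizes
always mean sizes after intersection). The scan fits one term at a time
under the same split plan for every term, so per-term accuracies are
comparable; results are independent of term order. Top-term selection
keeps floor(0.01·n_terms) terms, minimum 1, ranked by mean r with ties
broken by term id. Gene counting thresholds default to the smallest
count keeping ≤5% of counted genes (a reproducible stand-in for choosing
a cutoff by eye from the count distribution); per-run thresholds can be
set explicitly. Enrichment uses the one-sided (greater) exact
hypergeometric tail by default — enrichment is a directional claim —
with a two-sided option; the background is the expression matrix's gene
universe and the annotation list (e.g. protein kinases) is user-supplied.

## The synthetic-data generator

Expression is block-equicorrelated Gaussian: genes split into
near-equal contiguous blocks, pairwise correlation ρ within a block
(shared-factor construction), independence across blocks. Defaults —
198 lines, 2,000 genes, 100 blocks, ρ = 0.5 — mimic the scale and
redundancy of a filtered panel transcriptome; real co-expression is not
block-diagonal or equicorrelated, so passing tests show method behavior
under correlated-predictor regimes, not calibrated DGRP realism. Gene
sets are sampled with replacement across terms (overlap allowed), sizes
uniform in a configurable range; when the range dips below 5 a
sub-threshold term is guaranteed so the filter is always exercised.

Traits: dense (every gene N(0, 1/m)), sparse (n_causal genes carry
everything), mixture (three-component scale mixture: 80% tiny, 15%
moderate, 5% large relative variance), and GO-concentrated (causal genes
drawn only from a named term). The genetic values and the residual draw
are each rescaled so the realized-sample variance share equals the
target heritability exactly (not merely in expectation), which makes
small-n recovery tests sharp; heritability 0 zeroes the effects, and
heritability 1 with a zero effect draw raises. Line means are simulated
directly — no within-line replicate structure, no count-level noise, no
sex-specific transcriptomes.

The GO-concentrated benchmark scenario spreads H² = 0.8 over ~40 causal
genes filling most of a 30–50-gene term: the term's genes are jointly
but not individually predictive, which is precisely the regime where
annotation carries information. With only a few strong causal genes,
plain spike-and-slab regression finds the signal unaided and annotation
adds nothing — an expected property, not a failure.

## Numerical choices and edge cases

- Zero-variance expression columns are rejected at standardization with
  the offending gene ids; duplicated ids are rejected at load.
- Kernel eigenvalues are clipped at 0; matrices with eigenvalues below
  −1e−8·λ_max are rejected as non-PSD.
- Degenerate Fisher margins (annotation = background) report an infinite
  odds-ratio flag and p = 1.
- All samplers and the generator run on explicit seeds
  (`numpy.random.Generator` or the numba-internal RNG); identical
  (data, schedule, seed) gives identical output.

## Known limitations

- The benchmark's shortened MCMC schedules trade a little Monte Carlo
  error for wall time; single-fit inference (variance components,
  PIPs) intended for interpretation should use the full-length default
  schedules.
- The VEB mixture reports weights, not identified components; only
  functionals robust to near-duplicate components (effects, predictions,
  effectively-null mass) should be interpreted.
- The generator's Gaussian equicorrelated blocks understate the
  heavy-tailed, hub-structured correlation of real expression data.
- Random-forest and neural-network baselines are not implemented;
  external regressors can be registered as plug-in methods.
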