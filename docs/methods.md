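# Methods

This note documents the models implemented in `dysbiome`, the choices made
where the design was genuinely open, and what the synthetic cohorts do and
do not establish about real data.

## Data model and quality control

The unit of analysis is a genus-level 16S count table (samples × taxa,
non-negative integers) tagged with a body compartment (oral, lung, gut).
Samples with fewer than 1000 reads are removed (the threshold is inclusive:
exactly 1000 reads passes). Gut samples flagged as unsoiled rectal swabs are
removed regardless of depth, because such swabs under-represent stool
communities. Taxa are then filtered: a taxon is kept iff its total count
exceeds 1 (no singletons) and it reaches relative abundance ≥ 1e-4 in at
least 5% of samples. The filter wording admits two readings; we implement
the only one that actually removes rare taxa (keep iff prevalent at the
abundance threshold) and it is idempotent.

## Diversity and compositional transforms

Alpha diversity is the Shannon index in natural-log units, averaged over 100
random rarefactions to 1000 reads. Rarefaction subsamples reads *without*
replacement (multivariate hypergeometric), so a sample whose depth equals
the rarefaction depth is passed through unchanged. The Monte-Carlo standard
error shrinks as 1/√reps; `reps` and the log base are parameters.

The centered log-ratio (CLR) transform adds a pseudocount of 0.5 to every
count before taking logs and centering:
`clr(x)_t = ln(x_t + 0.5) − mean_s ln(x_s + 0.5)`. Rows sum to zero by
construction. The pseudocount is configurable; 0.5 is symmetric additive
smoothing, the simplest documented choice. Exact scale invariance of the
CLR holds only in the no-pseudocount limit; at sequencing-scale counts the
deviation is negligible (tested numerically).

Bray-Curtis dissimilarity, d(i,j) = Σ|x_i − x_j| / Σ(x_i + x_j), is computed
on relative abundances by default. Computing it on raw CLR values is
ill-defined (CLR values are negative), so a `clr_shifted` mode that
min-shifts the CLR matrix to non-negative values is provided for
compatibility with pipelines described that way; the default is the sound
one. PCoA uses Gower double-centering of −d²/2 with a symmetric
eigendecomposition; coordinates are returned for positive eigenvalues and
negative eigenvalues are reported, never corrected away.

PERMANOVA uses the distance-based sum-of-squares decomposition with the
pseudo-F statistic and the add-one permutation convention
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), which guarantees p ∈ (0, 1].
Family-wise correction across compartment comparisons is Bonferroni
(min(1, m·p)). The null calibration (type-I error 0.05 ± 0.02, uniform
p-values by Kolmogorov–Smirnov) is verified by simulation in the test suite.

## Dirichlet-multinomial mixture (DMM) community typing

Counts are modeled as a K-component mixture: z_i ~ Categorical(π),
p_i ~ Dirichlet(α_{z_i}), x_i ~ Multinomial(n_i, p_i), giving the
Dirichlet-multinomial marginal per component. Fitting is by EM:

* E-step: responsibilities r_ik ∝ π_k · DirMult(x_i | α_k).
* M-step: π_k = mean_i r_ik; each α_k is updated by Minka's fixed-point
  iteration with responsibility weights (three inner iterations per EM
  step). This is a generalized EM whose observed-data log-likelihood is
  non-decreasing; the code asserts monotonicity at every iteration.
* Initialization: the first restart seeds hard assignments with k-means on
  CLR-transformed counts; further restarts use random assignments. The best
  of `n_init` restarts by final log-likelihood wins. α is floored at 1e-10.

**Model selection.** The number of components maximizes a Laplace
approximation to the log model evidence,
log p(x) ≈ log posterior at the mode + (d/2)·ln 2π − ½·ln det H, with
d = K·T + (K−1) free parameters and H the Hessian of the negative log
posterior. Dirichlet parameters are handled on the log scale; the component
blocks are analytic (responsibility-weighted, exact at K=1 — verified
against a brute-force finite-difference Hessian to 1e-4), the mixture-weight
block is finite-differenced, and cross-component curvature is neglected
(block-diagonal approximation). The posterior includes a weak
Gamma(0.1, 0.1) prior on every α (the convention of the DMM software
lineage this follows) and a uniform prior on the weights: with a flat
improper prior the "evidence" barely penalizes extra components and
overfits K upward, which we observed directly on the separated fixture. A
prevalence rule discards any K whose smallest hard-assigned cluster holds
fewer than 10% of samples; if every K is discarded the fit falls back to
K=1 with a warning. K is searched over 1..5 by default on the
post-filtering table (both knobs configurable — the search range used in
the original analysis is not stated).

Clusters are named by mean member (rarefied) Shannon index in descending
order: High, Intermediate, Low (for K≠3: High, Intermediate-i…, Low). Ties
break by component index with a warning.

## Dysbiosis Index

The index is a multinomial logistic regression from a sample's features to
its DMM cluster, with High-Diversity as the reference class. For feature
vector f, X = exp(b1·[1,f]) and Y = exp(b2·[1,f]) give
P(H) = 1/(1+X+Y), P(I) = X/(1+X+Y), P(L) = Y/(1+X+Y); the prediction is the
argmax. The implementation evaluates these through log-sum-exp, which is
algebraically identical and overflow-safe; equivalence with the naive
closed form is tested to 1e-12 on 1000 random inputs per packaged model.
Argmax ties resolve Low > Intermediate > High — the clinically conservative
direction.

**Derivation pipeline.** Candidate features are the 50 most abundant taxa
(ranked by mean relative abundance across the compartment's QC-passing
samples; CLR ranking is available) as CLR values, plus the rarefied Shannon
index. Data are split 80/20 stratified by cluster label with a fixed seed;
selection and fitting see only the training 80%.

The published analysis screened features with a constraint-based causal
discovery algorithm (FCI-MAX, keeping the Markov blanket of the cluster
variable). We do not re-implement a causal-discovery stack; the default
surrogate is **stability selection**: 50 L1-penalized multinomial fits on
random half-samples of standardized features, keeping features with nonzero
coefficients in ≥70% of fits. A lighter conditional-independence screen
(marginal one-way ANOVA at level α, then re-tested after residualizing on
the strongest feature) is available as `method="ci_tests"`. On synthetic
data the surrogate keeps deterministic separators always and excludes
independent noise features with high probability (tested).

The multinomial model is fit by maximum likelihood (Newton); detected
quasi-separation (non-convergence, non-finite or runaway coefficients)
triggers a refit with a small ridge penalty and the model is flagged.
Accuracy on the held-out 20% is reported with an exact Clopper–Pearson 95%
CI and a 3×3 confusion matrix.

The three published compartment coefficient tables ship verbatim
(`dysbiome/data/dysbiosis_index/*.tsv`) and are loaded with
`load_paper_model`. Taxon names match exactly on the published spellings —
no fuzzy matching; remapping is the caller's job. Because the published
description does not state whether prediction-time taxon features are CLR
values from the full table or the top-50 subset, every serialized model
carries an explicit `feature_space` descriptor (CLR pseudocount, Shannon
variant, ranking) rather than hiding the assumption.

## Composition summaries

Taxa aggregate under two annotation schemes: oxygen requirement (obligate
anaerobes, aerobes, facultative anaerobes, microaerophiles, variable,
unclassifiable) and plausible respiratory pathogenicity (respiratory
pathogens, oral commensals, other). Class CLR aggregates are computed by
CLR-transforming the class-summed composition — CLR is not additive, so
summing per-taxon CLR values would be wrong. Unannotated taxa fall into the
scheme's catch-all bucket with a warning. Two per-sample flags use strict
inequalities, as the "greater than" wording implies: gut-origin enrichment
(gut-origin taxa > 30% of the sample) and single-taxon dominance (> 50%).
Taxa–biomarker association uses pairwise complete-case Pearson correlations
(top-20 taxa by mean relative abundance) with Benjamini–Hochberg adjustment
across all defined pairs; constant biomarkers are reported as undefined and
excluded from the adjustment.

## Moderated differential abundance

Per taxon, two-group comparison of CLR values gives logFC (difference of
group mean CLR, natural-log units — reported as-is, with the unit
documented, since CLR was computed once upstream) and a pooled variance
s_g² on d_g = n1+n2−2 df. Variances shrink toward a prior:
s̃² = (d0·s0² + d_g·s_g²)/(d0+d_g), with (d0, s0²) estimated by
moment-matching the distribution of ln s_g² (digamma/trigamma identities
for the scaled-F marginal; trigamma inversion by Newton). When the observed
spread of ln s² does not exceed what sampling alone predicts, d0 = ∞ and s0²
is the arithmetic mean of the s_g² — the conventions of the reference
empirical-Bayes implementation, against which this module is verified to
1e-6 on fixed fixtures. The total df is capped at the pooled residual df
across taxa. t = logFC/(s̃·√(1/n1+1/n2)); p-values are BH-adjusted and a
taxon is significant iff |logFC| > 1.5 and adjusted p < 0.05. Setting the
prior df to 0 reproduces the ordinary two-sample t-test exactly.
Observation weights are accepted (weighted group means and residual sums of
squares) and default to 1.

## Longitudinal, survival, and joint models

Longitudinal dysbiosis features use a linear mixed model with a random
patient intercept (ML by default, REML optional), via statsmodels.
Survival uses the Kaplan–Meier product-limit estimator with the log-rank
test (lifelines) and a Cox proportional-hazards model maximized by Newton
iteration with step-halving on the partial likelihood. Efron tie handling
is the default with Breslow behind a flag; the in-house Newton solver
exists precisely to expose that flag, and is cross-checked against both a
grid-search maximization of the partial likelihood (to 1e-4) and the
installed survival library. Monotone likelihoods (separation) are detected
by runaway coefficients and refit with ridge 0.1, flagged.

The joint model shares the longitudinal random intercept with the hazard:

    y_ij = x_ij'β + b_i + ε_ij,   b_i ~ N(0, σ_b²),  ε ~ N(0, σ_e²)
    λ_i(t) = λ0 · exp(z_i'γ + ν·b_i)

with a constant baseline hazard (exponential — one-interval
piecewise-constant; adequate under administrative censoring at 60 days) and
marginal maximum likelihood: b_i is integrated out by adaptive Gauss–Hermite
quadrature (15 nodes, centered per subject on the closed-form
longitudinal-only posterior mode of b_i), optimized by Nelder–Mead with a
BFGS polish. The association coefficient ν captures informative censoring:
ν > 0 means higher latent trajectories die faster. At ν = 0 the marginal
likelihood factorizes into the mixed-model and survival likelihoods; the
implementation reproduces that identity to ~1e-6 (quadrature error), which
pins down the integration machinery. Which association structure
(current-value vs shared random effect) the original analysis used is not
stated; shared random intercept follows from the random-intercept-only
longitudinal submodel and is flagged as an assumption. The 95% CI for ν is
the percentile interval over subject-level bootstrap refits (100 by
default), warm-started at the point estimate; failures are counted and
reported, and no CI is returned if fewer than half succeed.

2×2 cluster co-membership uses the sample odds ratio (a·d)/(b·c) with a
Haldane–Anscombe 0.5 correction when any cell is zero, a Woolf log-OR CI,
and the two-sided Fisher exact p by hypergeometric enumeration. The point
estimate is deliberately the corrected sample OR, not the conditional MLE
some environments report; the difference is documented because the two
disagree on extreme tables.

The "Low-Diversity persister" contrast is a derived binary covariate (Low
cluster at baseline AND middle interval) fed to an age-adjusted Cox model —
implemented in the pipeline rather than as a bespoke estimator.

## Synthetic cohort generator

The generator is first-class, tested code that emulates the structure the
analysis assumes, at the study's stated conditions: three compartments,
three visit intervals (baseline day ~2, middle days 3–6, late days 7–12),
depths uniform on 2000–10000 reads (so every sample clears the 1000-read
QC), K=3 community types with mixing weights (0.45, 0.35, 0.20), 60-day
administrative censoring, and a baseline hazard of 0.00524/day chosen so
that unit-multiplier subjects show ≈27% 60-day mortality, matching the
cohort case mix the annotations and covariate distributions also mirror
(age ~N(60,13), 54% male, 22% COPD, 22% immunosuppression, SOFA ~Poisson(6),
23% hyperinflammatory). Hazard multipliers default to (1.0, 1.2, 2.2) —
the Low-cluster value mirrors the adjusted hazard ratio scale reported for
lung communities.

Design choices: (i) components are diversity-graded — High is near-symmetric
over all taxa, Intermediate tilts toward its 5-taxon block, Low concentrates
>90% of its Dirichlet mass on the pathogen block — so the Shannon gradient,
pathogen enrichment and anaerobe depletion all emerge from one α matrix;
the "well-separated" test fixture instead puts 70% of each component's mass
on a disjoint 5-taxon block, which guarantees recoverability. (ii) A
subject-level latent community type is shared across compartments with an
85% per-compartment concordance, inducing the strong oral–lung cluster
co-membership; per-visit labels evolve by a sticky transition chain
(persistence 0.8, in the range of the reported 75–84% Low-cluster
persistence — within-cluster transition probabilities beyond that are not
reported, so the persistence is an exposed parameter, not a fixed constant).
(iii) Dropout at follow-up visits is logistic in the cluster and the latent
(uncensored) event time, plus structural loss after death — the informative
censoring mechanism joint models exist to handle. (iv) Biomarkers are
linear loadings on the pathogen-class CLR abundance plus Gaussian noise.
All randomness flows from one root seed through named
`numpy.random.SeedSequence` children, one stream per ingredient, so any
output is reproducible in isolation.

**What passing tests show — and don't.** The generator produces exact DMM
data: clean Dirichlet-multinomial components, exponential hazards, linear
biomarker links. Success on it demonstrates the estimators are implemented
correctly (parameter recovery, calibration, closed-form identities), not
that real respiratory microbiome data satisfy the DMM, proportional-hazards
or linearity assumptions. Real 16S data add contamination, taxonomic
misassignment, zero-inflation beyond the multinomial, batch effects and
non-exponential hazards, none of which are emulated. Held-out index
accuracies on the separated fixtures (≈0.95–1.0) exceed the published
cohort accuracies (0.80–0.82) for the same reason: the synthetic clusters
are cleanly separated by construction.

## Numerical choices and degenerate inputs

EM convergence: relative log-likelihood change < 1e-6, max 500 iterations,
non-convergence returned with a flag and warning. Responsibility ties in
hard assignment go to the lowest component index. Singular or indefinite
evidence Hessians raise with advice to reduce K; in `select_k` such K are
skipped. Zero-depth samples yield all-zero relative abundances rather than
NaN. Zero-variance taxa are reported with undefined p and excluded from BH.
Cox Wald CIs may overflow to infinity with very sparse events — reported as
such (serialized as null in JSON). Survival times are floored at 1e-6 days
to keep them strictly positive. The pipeline report rounds floats to 10
decimals and sorts keys so identical config+seed reproduces the JSON byte
for byte.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as
the sizes at which every estimator's behavior is already unambiguous:
DMM fixtures of 200–400 samples × 25–40 taxa with K searched to 5; index
derivation on 400 (lung-style) and 250 (gut-style) samples; joint-model
cohorts of 120–150 subjects × 3 visits with 10–50 bootstrap refits;
500-replicate PERMANOVA and 200-replicate FDR calibrations.

## Known limitations

* The Laplace evidence neglects cross-component curvature
  (block-diagonal Hessian) and evaluates at the MLE with the weak prior
  added, rather than re-solving for the MAP mode; at desk scale the induced
  error is far below between-K evidence gaps (hundreds of nats).
* The joint model supports one longitudinal marker, a random intercept
  only, and an exponential baseline hazard; no current-value association,
  competing risks, or time-varying coefficients.
* The moderated-t module handles two groups with optional weights, not
  arbitrary design matrices.
* BIOM ingestion is not implemented; TSV is canonical.
* The published cohort-level effect sizes (e.g. co-membership OR 7.67,
  adjusted HR 2.22) depend on the actual patient data and are not
  reproducible from synthetic cohorts; the pipeline reports the analogous
  quantities on simulated data as qualitative direction checks only.
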