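# Methods

This note records the model as implemented, the defaults and why they are
set where they are, the sampler's numerical choices, what the synthetic
data generator does and does not emulate, and the design decisions made
where more than one reasonable construction existed.

## Model

For subjects i = 1…n with ROI intensity vectors **x**_i ∈ ℝ^R (z-score-like,
standardized against a healthy reference), binary outcomes y_i and optional
covariates **u**_i ∈ ℝ^q, the joint factorizes through a latent state
η_i ∈ {1…K}:

* η_i ~ Categorical(π), π ~ Dirichlet(α);
* **x**_i | η_i = k ~ N(μ_k, Σ_k) with Σ_k diagonal: variance σ_k on
  regions with γ_j = 1, σ_0 on the rest; μ_{k,j} = 0 when γ_j = 0;
* slab prior on selected means: intrinsic CAR on the connectivity graph S,
  μ_{k,j} | rest ~ N(mean of neighbors' μ_{k,·}, c_k / d_j); an isolated
  region (d_j = 0) falls back to a N(0, c_k) slab;
* σ_k ~ IG(a_k, b_k), σ_0 ~ IG(a_0, b_0);
* p(γ) ∝ exp(e 1ᵀγ + f γᵀSγ) (Ising / MRF; S symmetric, so the quadratic
  form counts each edge twice and the single-site conditional logit is
  e + 2f · (selected-neighbor count));
* logit P(y_i = 1) = ξ_iᵀβ, ξ_i = (1, ρ_i, **u**_i) with ρ_i the K−1 state
  indicators (state K is the reference), β ~ N(m_β, V_β), augmented with
  ω_i ~ PG(1, ξ_iᵀβ).

The neighborhood matrix S is built by thresholding the absolute value of an
inter-regional correlation matrix at the smallest grid value (step 0.001)
whose induced mean degree does not exceed a target (default 5, giving a
lattice-like graph); absolute values are used because negatively coupled
regions are still functionally linked.

## Default hyperparameters

| parameter | default | meaning / rationale |
|---|---|---|
| K | 2 | number of latent states; scan a grid with `select_k` |
| α | (1,…,1) | vague Dirichlet on the mixture weights |
| e | −4.5 | Ising sparsity; gives an isolated region a logistic(−4.5) ≈ 1.1% prior selection probability, a deliberate ≥1% floor |
| f | 0.1 | Ising smoothness; keep well below the phase transition of E\|γ\| (locate it with `phase_transition_scan`; on a 47-region, degree-5 network the sharp rise starts around f ≈ 0.6–0.7 at e = −4.5) |
| c_k | 5 | unscaled ICAR slab variance (conditional variance c_k/d_j) |
| a_k, b_k | 2, 1 | IG prior on σ_k, weakly informative, prior mean 1 (intensities are z-scores) |
| a_0, b_0 | 2, 1 | same for the non-discriminatory variance σ_0 |
| m_β, V_β | 0, 5·I | vague conjugate prior on the logistic coefficients |

MCMC defaults mirror a full analysis: 100,000 sweeps, 50,000 burn-in, two
chains started from different numbers of selected regions and different
allocations, thinning 1, fixed seed. Initial values are μ = 0, σ_k = σ_0 = 1,
β = 0. Tests and the acceptance script use scaled-down chains
(800–6,000 sweeps) and document their sizes inline; these are the
package's reference problem sizes for a single-CPU run.

## Sampler

Per sweep, in order: ω (exact PG(1, ξᵀβ) draws via a Devroye-type
alternating-series rejection sampler, implemented in `polya_gamma.py` and
oracle-tested against the series moments), β (conjugate Gaussian), η (exact
collapsed logistic term rather than the ω-augmented Gaussian form — a valid
partially collapsed step because ω is refreshed before its next use; this
avoids η/ω incoherence), π (Dirichlet), γ (R add–delete–swap Metropolis
proposals), μ (single-site Gibbs over selected regions in randomized
order), σ (inverse-gamma).

Selection moves choose a type uniformly among those feasible (add requires
\|γ\| < R, delete \|γ\| > 0, swap both), propose new μ components from their
full conditionals, and accept with the joint-posterior ratio times the
proposal and selection-probability corrections. The incremental ratio
computation is verified against the full joint density in the test suite
(`check_moves=True` recomputes every Δ from `joint_log_posterior`).

**ICAR propriety.** The intrinsic CAR slab has no proper joint density. The
joint evaluation in `joint_log_posterior` uses the pseudo-likelihood
product of the CAR full conditionals; within-dimension μ updates use the
exact conditionals. The two coincide on edgeless graphs, where all
joint-distribution correctness checks are run; on connected graphs the
trans-dimensional moves target the pseudo-likelihood joint, the standard
practical choice for spike-and-slab CAR priors. Empty clusters are allowed
(n_k = 0): their means follow the prior; no component deletion.

**Label switching.** Sampling is constraint-free. `relabel_draws` permutes
each draw's labels to best match a reference partition (default: the
per-subject modal state of the first chain) and re-expresses β against the
permuted reference state. All label-dependent summaries use relabeled
draws; PPIs and the median model are label-invariant.

## Model comparison

DIC uses the state-marginalized observed-data deviance
D(θ) = −2 Σ_i log Σ_k π_k N(x_i; μ_k, Σ_k) p(y_i | k, β), with the
effective parameter count estimated as half the posterior variance of the
deviance. The plug-in form (deviance at the posterior mean) was rejected
after testing: when K exceeds the number of states the data support,
residual label ambiguity among the redundant components blurs the
posterior-mean parameters, inflates the plug-in deviance and thereby
*lowers* DIC, systematically favoring overfitted models; the variance-based
penalty is label-invariant and grows with the extra wandering components.
`select_k` fits each K with identical seeds, picks the smallest K within
2 DIC units of the minimum (parsimony), and reports the posterior Bayes
factor — the ratio of posterior-averaged likelihoods, computed by
log-mean-exp of per-draw log-likelihoods — of the chosen model against
each alternative. Multimodality is real at small sample sizes: run
multiple chains (k-means allocation initialization is available via
`init_allocation="kmeans"`) and heed the Geweke/PSRF convergence flags in
the report before trusting a comparison.

## Prediction and cross-validation

For a new subject, each posterior draw classifies
P(η_f = k | x_f) ∝ π_k N(x_f; μ_k, Σ_k) and the outcome is simulated
through the logistic model (three-step sampler); the Rao-Blackwellized
average Σ_k P(η_f = k | x_f) · logistic(ξ_f(k)ᵀβ) is computed alongside and
is the lower-variance estimate of the same quantity. New-subject
covariates are required whenever the model was fit with covariates.

Leave-one-out cross-validation reuses the full-data posterior as an
importance-sampling density for the posterior without subject i's outcome:
weights w_t ∝ 1/p(y_i | η_i^{(t)}, β^{(t)}) (the outcome-only contribution;
the measurement rows stay in the conditioning set), self-normalized, with
the weight effective sample size reported per subject and flagged below
10% of the draw count. The test suite verifies IS-LOO against explicit
refits with the outcome held out.

ROC analysis evaluates predicted probabilities on the threshold grid
0, 0.05, …, 1 (trapezoidal AUC over the grid points) and additionally at
every distinct probability (`auc_dense`, which equals the Mann-Whitney
concordance statistic exactly and is the preferred number when
probabilities bunch within grid bins). The Youden threshold maximizes
TPR − FPR, ties toward the smaller threshold.

A caution established while validating the cross-validation: exact LOO
predictive probabilities are slightly *anti*-concordant with the held-out
outcomes on null data, because removing y_i shifts subject i's prediction
away from its own outcome by O(1/n) and, in a latent-class model, subjects
in the same state have otherwise identical predictions. With continuous
per-subject variation (covariates) and n ≈ 100 the effect is negligible
and null cross-validated AUC sits near 0.5; at n ≈ 20 without covariates it
can drive null AUC far below 0.5. This is a property of leave-one-out
itself, not of the importance-sampling approximation (which matches
explicit refits).

## Synthetic data

`make_network` plants a random geometric graph at a target mean degree
(default 5) and a consistent correlation-like matrix (edges get \|r\| in
0.55–0.9, non-edges below 0.35, random signs) so that `build_network`
recovers the planted graph. `make_truth` grows a connected discriminatory
support (default 8 regions) on the network; state 1 and 2 means are
±d/2 on the support with d = effect_size·√σ_k — `effect_size` is the
per-region standardized separation (Cohen's d per region; the total
Mahalanobis separation is then effect_size·√(support size)), constant over
the support and hence maximally smooth over neighbors. The outcome model
uses intercept −1.5 and state log-odds ratio log(5.2) by default, giving
event prevalence ≈ 0.36 at equal mixture weights — the class balance of
the motivating study; covariate coefficients default to zero so the
between-state odds ratio is directly interpretable (logistic effects are
non-collapsible otherwise). Covariates emulate plausible clinical ranges
(age ~ N(35, 10), duration ~ N(20, 8), binary history ~ Bern(0.5)).

What the generator does *not* emulate: spatial autocorrelation of the
noise within a state (Σ_k is truly diagonal in the generator, as the model
assumes), scanner or site effects, heavy-tailed or skewed intensities
(pooled intensities are near-symmetric unimodal by construction,
\|skewness\| < 0.5), laterality structure, or any misspecification of the
logistic link. Passing recovery tests therefore demonstrate correctness of
the inference under the model's own assumptions, not robustness to their
violation on real images.

## Numerical choices

All densities are evaluated in log space; logistic terms use
log_expit/softplus and never overflow. The β update solves with a Cholesky
factor of the posterior precision and fails loudly if it is not positive
definite. Inverse-gamma draws use scale/Gamma(shape). Categorical draws use
a single uniform against the cumulative row. Degenerate diagnostics are
defined explicitly: a constant chain has Geweke z = 0; zero within-chain
variance gives PSRF 1; zero-variance vectors make chain-agreement
correlations NaN. Geweke's spectral density at zero uses a
Bartlett-windowed autocovariance sum (lag window ⌊10 log₁₀ m⌋); the PSRF
is the classic between/within estimate — both implemented directly because
the rank-normalized variants in modern diagnostic libraries are different
statistics. CSV round-trips use round-trip float parsing so a written
dataset reloads bit-identically.

## Known limitations

Single-site γ moves mix slowly when discriminatory and non-discriminatory
variances can trade off (acceptance rates of a few percent are typical);
the stuck-support mode is detectable by PSRF/chain-agreement and by
running chains from different initializations. The pseudo-likelihood
treatment of the intrinsic CAR joint is an approximation on connected
graphs (exact on edgeless ones). The outcome model assumes a correctly
specified logistic link with complete data; missing values are rejected,
not imputed. K is fixed within a fit; exploring K is delegated to
`select_k` rather than trans-dimensional moves over K.
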