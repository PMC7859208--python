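# Methods

This note documents the models, parameter choices and numerical conventions
behind `castesvm`, and what the synthetic data do and do not establish.

## The classifier

Caste is treated as a *numeric* response — worker = 0, queen = 1 — and
fitted with ε-insensitive support-vector regression rather than
classification. This is deliberate: the analysis needs a continuous caste
axis on which intermediate individuals can be placed, and regression
estimates may legitimately fall outside [0, 1] (a sample can look "more
queen-like than the average queen"). Probabilistic classifiers cannot
produce such values, and clipping would discard information, so estimates
are never clipped.

Kernels follow the standard definitions (radial
`exp(−γ‖x−y‖²)`, linear, sigmoid, polynomial). The quadratic program is
solved by libsvm (through scikit-learn); predictions are recomputed from the
stored dual expansion `f(x) = Σᵢ αᵢ k(sᵢ, x) + b`, which makes serialized
models self-contained and lets the test suite verify the solver against an
independent SLSQP solve of the SVR dual.

**ε (tube half-width).** ε = 0.1, the default of the classical SVM
implementations in this field. Its geometric consequence is visible in every
result: training estimates of the two castes hug the inner tube edges
(workers ≈ 0.100, queens ≈ 0.900 and above), because residuals inside the
tube are free and the solver prefers the flattest function. The spread of
queens *above* 0.9 comes from the flat-kernel (near-linear) operating
regime, where the fit cannot pin every sample exactly to the edge.

**γ and C.** The documented operating point is a radial kernel with
C = 2⁵ and γ = 10⁻⁶ for a 10,734-gene standardized transcriptome. γ sets
the kernel length scale relative to ‖x−y‖², which for standardized features
grows linearly with the number of genes; a fixed γ therefore changes
*regime* when the gene count changes. The default policy keeps
γ·(#genes) at the reference operating value (γ = 1.07×10⁻²/#genes, exactly
10⁻⁶ at 10,734 genes), preserving the mildly nonlinear regime at any
feature-space size. A literal γ and a refined grid search
(five log-spaced C in (2⁴, 2⁶) × five log-spaced γ in (10⁻⁷, 10⁻⁵),
iterated γ-major then C ascending, first minimum wins) are available in the
configuration.

**Cross-validation.** Threefold CV with randomly assigned, as-even-as-
possible bins (no caste stratification), repeated 20 times; the model's
error is the mean over repeats of the pooled held-out mean squared error.
Both MSE and √MSE are reported. Validation errors of this classifier are
conventionally quoted as "root mean squared" values that are numerically
MSEs (an error of 0.065 corresponding to estimates "within 25.5% of their
true values": 0.255² ≈ 0.065); comparisons in this package always use the
MSE. Fold assignment is drawn after seeding on the sorted sample-identifier
order, so CV results are invariant to the row order of the input matrix.

## Recursive feature elimination

Exactly one gene is dropped per iteration: (1) repeated-CV error of the
current gene set; (2) feature weights `w = αᵀS` from a model fitted on *all*
training samples (the linear-primal SVM-RFE heuristic, applied under any
kernel); (3) drop the gene with smallest |w|, ties broken by input gene
order; (4) refit. Elimination stops at 100 genes; the final set is also
CV-scored, and the selected model is the minimum-error iteration (ties go to
fewer genes), refitted on all samples. Each iteration draws its CV seed from
`SeedSequence([master_seed, iteration])`, so re-running a suffix of the
trace cannot shift the randomness of earlier iterations. An optional batch
mode (off by default) exists for very large matrices.

Because the optimum is selected by the same CV used during elimination, the
selected error is an optimistically biased estimate (no nested CV). The
procedure is reproduced as designed; the bias is simply documented here.

## Preprocessing

Genes are kept iff their count sum is strictly greater than 20 in at least
one experimental group; the rule is evaluated over the groups present (with
a warning if one is empty) and is idempotent. Counts are transformed to
`log2(count·10⁶/depth + 1)` (pseudocount configurable); features are then
standardized per gene with training-set statistics only, and zero-variance
genes are dropped and reported. What transformation feeds the SVM is a
genuinely open design point; log2-CPM + standardization was chosen because
weight-based elimination is only meaningful when features share a scale,
and raw or plain-CPM inputs remain available in the configuration.

## Downstream statistics

* Wilcoxon rank-sum: W is the Mann-Whitney U of the first sample (pairs
  with `x > y`, ties ½). Exact p for tie-free samples with
  `n_x·n_y ≤ 400`, otherwise a normal approximation with tie and continuity
  corrections; the regime used is always reported.
* Simple OLS with intercept; slope SE on n−2 degrees of freedom; two-sided
  t-test; Pearson r reported alongside. Residualization ("phenotype beyond
  age") regresses the estimate on the residuals of phenotype-on-age OLS.
  Zero-variance predictors are flagged, not fitted.
* Gene-set overlap: Jaccard `|A∩B|/|A∪B|` (0 for two empty sets) and the
  one-sided hypergeometric upper tail `P(X ≥ |A∩B|)` with the post-filter
  gene list as the default universe (configurable).
* Benjamini-Hochberg step-up with enforced monotonicity.
* Phenotypic queenness: maximum-likelihood logistic regression of caste on
  ovarian index and dominance, applied to all samples. Complete separation
  (noiseless phenotypes) is detected by fitted probabilities pinning to the
  labels and resolved with a minimal ridge (λ = 10⁻⁴) plus a warning. This
  is a simplification of the Bayesian logistic model used for the original
  phenotype score; the pipeline only needs a calibrated monotone score.

## DE stand-in

The differential-expression stage is explicitly a stand-in, not a
negative-binomial shrinkage GLM: per gene, a Welch test on log2-CPM against
the *interval null* |Δ| ≤ log2(1.5), using the minimum-effect construction
`p = min(1, 2·min(p_upper, p_lower))` with the two one-sided tests shifted
to the interval boundaries. At threshold 0 this reduces exactly to the
ordinary Welch test; raising the threshold can only reduce the flagged
count; swapping groups negates fold changes and preserves p-values. An
externally produced DE table (gene, log2fc, padj) can be dropped in for
real-data use.

## The synthetic data generator

Counts are negative binomial, `var = μ + φμ²`, with
`μ_gi = s_i · depth · p_g · 2^(β_g t_i + δ_g a_i)`: lognormal baseline
abundances `p_g`, lognormal library-size factors `s_i` (CV 0.25 around a
10⁶-read depth), latent caste state `t` (queens 1, control workers 0, QR
strictly intermediate), and a standardized age covariate `a`.

Defaults mirror the study design: 26 + 10 queens, 12 + 10 workers, 58 QR
individuals (24 day-3, 34 day-12), 500 genes with 50 caste-informative
genes at |log2FC| = 1.5 and 50 *disjoint* age genes at |log2FC| = 1 per SD
of age (random signs, fixed by seed). Dispersion φ = 0.1 (biological
CV ≈ 0.32, typical of bulk RNA-seq in outbred insects) is calibrated so the
generator meets its stated recoverability property: with |log2FC| ≥ 1 and
≥ 12 samples per caste, a per-gene Welch test recovers ≥ 70% of planted
genes at BH 0.05, while null simulations stay within the FDR bound.

Two structural choices matter for interpretation:

* **QR latent states** are Beta(2, 4) (mean ≈ ⅓, matching the observed
  intermediate group means) and are coupled to age through a Gaussian
  copula whose latent correlation is solved by quadrature + bisection so
  the realized Pearson cor(t, age) hits its target (default 0.48, the
  reported queenness-age correlation among post-removal individuals).
* **Queens' age covariate is decoupled from their chronological age.**
  Chronological ages follow the study design (overwintered foundresses
  ≈ 200 days; workers and QR individuals 3-30 days), but the covariate
  driving age-gene expression is standardized age among *young* individuals,
  and for queens it is drawn from that same young distribution — modelling
  post-diapause reset of maturation-tracking expression. This keeps planted
  age genes unconfounded with caste, which is precisely what makes "does
  the classifier track caste or age?" a well-posed question on simulated
  data. Phenotypes (ovarian index on a 0-1 scale, Elo-like dominance around
  1000 ± 500) are monotone functions of `t` plus Gaussian noise
  (SD 0.15 on the t scale by default).

What the simulator does *not* emulate: gene-gene correlation structure,
colony-level batch effects, GC/length biases, isoform-level variation, or
the stratified sampling of QR individuals (a quantile-strata option exists
but simple sampling is the default). Passing tests therefore demonstrate
that the *procedure* behaves as designed under its stated statistical
assumptions — recovery of planted structure, calibration of its tests,
determinism — not that real colonies satisfy those assumptions.

One caveat discovered by simulation: with the default (0.48) t-age coupling,
age-residualized queenness remains a strong predictor of classifier
estimates — correctly, because in that configuration the latent state has
substantial age-independent variation that the phenotypes capture. The
"age is the strongest determinant" pattern (age significant, residual
queenness not) emerges when the latent state is driven by age alone
(t-age correlation ≈ 0.95), which is how the corresponding property is
tested.

## Problem sizes and numerics

The shipped scenarios use 500-gene transcriptomes with elimination to 100
genes (≈ 400 iterations; 5 CV repeats per iteration in the seeded test
scenarios, 20 in the default configuration), chosen as the smallest sizes at
which planted-recovery and overlap statistics are stable across seeds.
libsvm is run at tolerance 10⁻⁶ (10⁻¹⁰ where tests compare against the QP
oracle at 10⁻⁵). Serialized models round-trip bit-exactly through JSON
(shortest-repr floats). Degenerate inputs: constant responses yield
all-zero dual coefficients and an intercept-only model; two-sample training
caps CV at 2 folds with a warning; constant genes are dropped at
standardization; an RFE stop size at or above the gene count is an error.

## Known limitations

* The selected CV error is optimistically biased (selection by the same CV).
* The DE stand-in has no dispersion shrinkage or size-factor model beyond
  CPM; it mirrors only the fold-change-threshold semantics.
* Held-out caste samples classify with group means slightly inside the
  labels (queens ≈ 0.88, workers ≈ 0.15 at the default scenario): the
  ε-tube places even training fits 0.1 inside the labels, and feature
  selection at n = 38 adds finite-sample attenuation on genuinely unseen
  samples. At transcriptome scale (thousands of informative dimensions)
  this attenuation shrinks, but it is a real property of the method at
  desk scale and is reported, not hidden.
* No nested CV, no multi-predictor models, no WGCNA/GO stages.
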