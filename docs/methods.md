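# Methods

This note documents the models, the numerical choices, and what the
synthetic-data studies do and do not establish.

## Graded response model (stage 1)

For item *j* with K<sub>j</sub> ordered categories, cumulative response
curves are logistic in a single latent trait θ with discrimination
a<sub>j</sub> > 0 and strictly increasing thresholds b<sub>j,1</sub> < … <
b<sub>j,K−1</sub>. The trait prior is standard normal, which fixes the
scale; all discriminations are free. We use the logistic link without the
historical 1.7 scaling constant.

Estimation is marginal maximum likelihood by EM: the E-step computes each
participant's posterior weights over a fixed 61-node Gauss–Hermite grid
(the default; EAP values agree with adaptive quadrature to < 1e−6 at 61
nodes), the M-step refits each item's parameters against expected
category-by-node counts using L-BFGS on an unconstrained parameterization
(log a; b₁; log threshold gaps), which enforces ordering by construction.
EM stops when the marginal log-likelihood improves by < 1e−6 (default cap
500 cycles; non-convergence is flagged, never silent). Missing item
responses drop out of that participant's likelihood factor. Participants
with every item missing receive a missing score.

Fit is assessed by two-way margins: observed vs model-expected bivariate
category counts for every item pair, integrated over the trait prior;
cells with (O−E)²/E > 4 are flagged (the classical rule of thumb — the
model names the diagnostic, the cutoff is convention). With three items a
single-factor model is just-identified for pairwise association, so the
diagnostic has power only against violations that four or more items (or
strong margin misfit) expose.

EAP scores are posterior means, standardized to sample mean 0, SD 1.
Posterior-mean scoring shrinks toward the prior mean: with the default
item banks the score–truth correlation is ≈ 0.79 (social) and lower for
the lifestyle trait. Consequently, structural coefficients estimated on
the scores are attenuated relative to coefficients on the true traits
(visible in the end-to-end pipeline outputs, e.g. a social→cognition
direct effect of ≈ 0.32 at a generating value of 0.364). This is a
property of every two-step scoring design, not an estimator defect; the
estimator-recovery studies therefore feed the structural stage the true
traits, and the pipeline run shows the attenuated two-step numbers.

## Structural model (stage 2)

The model is held in RAM form over observed + latent variables: directed
matrix A (loadings, regressions), symmetric S (residual variances and
covariances, exogenous moments), mean vector m, observed-row filter F.
Implied moments: Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, μ(θ) = F(I−A)⁻¹m.

Default pathway specification: latent small vessel disease, AD pathology,
neurodegeneration and cognition, measured as in the README; all four
regressed on the two trait scores, age (years), sex (woman = 1) and
APOE-ε4 (carrier = 1); cognition additionally on the three mediators;
free residual covariances among the mediators; free means, variances and
pairwise covariances among the five observed predictors, so their own
missingness is handled by FIML too. Mean structure on; latent intercepts
fixed to 0.

*Identification and orientation.* Marker-variable convention: the first
loading of each latent is fixed to 1, latent residual variances free. The
marker for AD pathology is log p-tau, not the Aβ42/40 ratio: p-tau rises
with pathology while the ratio falls, and anchoring on the ratio would
orient the latent toward *less* pathology and flip the sign of every AD
path relative to how such decompositions are conventionally reported
(APOE→AD positive, AD→cognition negative). The ratio then loads
negatively, as it should. The standardized solution is invariant to this
choice up to sign.

*Estimation.* The casewise multivariate-normal log-likelihood is summed
over missingness-pattern groups; its gradient is analytic (chain rule
through the RAM algebra), verified against finite differences to 1e−5.
Optimization is L-BFGS-B on a scale-free parameterization — each
parameter divided by its natural scale built from observed SDs (latents
inherit their marker's SD) — because raw-unit parameters span about six
orders of magnitude (Aβ-ratio variance ~1e−4, age variance ~75) and stall
a quasi-Newton method otherwise; the ML solution is equivariant, so this
changes conditioning only. Defaults: gradient tolerance 1e−6 on the
per-observation objective, up to 5000 iterations (iterations are ~1 ms;
the 88-parameter pathway model typically needs 500–1500), three jittered
restarts on non-convergence, variance parameters bounded at 1e−8 with a
warning when an estimate pins near the bound (Heywood case). Starting
values: observed means/covariances, marker-regression loadings, halved
variances, zero structural paths. A non-positive-definite implied
covariance during a line search is handled as a rejected step.

*Standard errors* are from the inverse observed information (numerical
Hessian of the analytic gradient, central differences). The standardized
solution multiplies each path by sd(source)/sd(target) under the implied
full covariance and converts covariances to correlations; delta-method SEs
propagate the raw estimate covariance through a numerically differentiated
standardization map. Both raw and standardized scales are reported.

*Saturated and baseline models.* The saturated model (free means and
covariances) is estimated under missingness by the EM algorithm for the
multivariate normal; with complete data it reduces to the sample moments
in one step. The baseline frees means and variances only (closed form per
variable). Fit indices from T = 2(llₛₐₜ − llₘₒdₑₗ): RMSEA =
√(max(T−df,0)/(df·n)) with noncentrality CI by root-finding on the
noncentral χ²; CFI = 1 − max(T−df,0)/max(T_b−df_b, T−df, 0); TLI from the
relative χ²/df ratios; SRMR as the RMS of residual moments between the
FIML-saturated and implied covariances on the correlation scale (the only
well-defined sample analogue under missingness). The RMSEA CI level is
configurable (default 90%). With df = 0 the χ²-based indices are reported
as undefined.

*Known approximation.* The two Fazekas severities (0–3 scales) enter as
continuous indicators under normal-theory ML, mirroring the source
analysis; a categorical-indicator (polychoric/WLSMV) treatment is out of
scope.

## Mediation effects

Indirect effect = product of the two constituent standardized paths;
SE² = b²V_aa + a²V_bb + 2abV_ab from the standardized estimate covariance.
Total = direct + Σ indirect with the gradient (1, b₁, a₁, …) against the
joint covariance; the decomposition identity holds exactly by
construction. p-values are two-sided normal (the delta method is known to
be slightly anticonservative for products near zero; empirical 95% CI
coverage of direct effects exceeds 90% at n = 2000 in the calibrated
simulation). `bootstrap_indirect_se` offers the refit parametric
bootstrap (simulate from the fitted moments, refit, recompute) and a
cheap Monte-Carlo propagation of the estimate distribution; at n = 500
and 1000 refit replicates the delta SE agrees within 10%. Mediator
"correlations" are residual correlations ψ_ij/√(ψ_ii ψ_jj), which are
scale-invariant.

## Synthetic cohort generator

What it emulates: the published category margins for every ordinal item
(thresholds solved by root-finding so the N(0,1)-marginal frequencies
match the printed frequencies); age ~ Normal(70.9, 8.7²) truncated to
[50, 95]; 61.9% women; 28.3% APOE-ε4 carriers; structural coefficients
defaulting to the published standardized direct effects with mediator
residual correlations at the published values and residual variances
solved so every latent has unit marginal variance; item-level missingness
at the published footnote rates (e.g. salary 317/2323) with the three
social-network components blanked jointly; and modality-panel missingness
(whole CSF panel, each PET) at the published acquisition complements, with
logistic probabilities in population-standardized age and sex
(`mar_strength`, default 0.5, intercept solved so the marginal rate is
exact) — missing at random by construction. One master seed spawns
per-stage substreams, so any stage can be varied without perturbing the
others; identical config + seed gives byte-identical tables.

Distributions the source does not state are ours and chosen once: trait
correlation 0.3; within-quartile leisure-count profile (smooth, unimodal);
SNI component endorsement rates (0.65/0.55/0.47, matching the printed
index mean); measurement loadings/intercepts/residual variances on
plausible clinical scales; a hypergeometric split of leisure activities
into physical vs other items (carried as `leisure_physical_count` so the
no-physical-leisure sensitivity variant can recompute the reduced score,
re-quartiled at sample quartiles). Fazekas severities are generated as
continuous values on the 0–3 scale, uncapped, so the linear measurement
model is exactly correct; real ratings are integers, which the analysis
side would treat as continuous anyway.

What passing tests therefore show: the estimators recover the generating
structure under the reference missingness geometry and effect sizes, with
calibrated test statistics and honest uncertainty. What they do not show:
robustness to distributional violations real data would add — integer
Fazekas ratings, floor/ceiling effects in cognitive tests, non-normal
biomarker residuals, missingness that is not MAR, or site effects. No
images, assay noise models or longitudinal visits are simulated.

## Problem sizes used in the checked studies

Structural recovery and CI coverage: 50 replicates at n = 2000 (complete
analysis-scale data, true traits as exposures). GRM recovery bias: 30
replicates at n = 5000 (the rare-category salary thresholds have
per-replicate SD ≈ 0.10, so ~30 replicates put the Monte Carlo noise of
the bias estimate well inside the 0.05 band). χ² calibration: 200
replicates of a compact one-factor model at n = 300. Bootstrap comparison:
1000 refit replicates of the compact mediation model at n = 500. The
acceptance script runs the full pipeline at the reference cohort size
n = 2323.
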