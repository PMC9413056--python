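# Methods

`atnreserve` implements a two-stage structural analysis used in cognitive
reserve research: (1) a *residual reserve index* is extracted from a
baseline episodic-memory composite, and (2) that index moderates every path
of a sequential amyloid → tau → neurodegeneration → cognition mediation
model with a latent-growth executive-function (EF) outcome. Because the
motivating cohort data (demographics, MRI volumes, CSF Aβ42/Aβ40, plasma
p-tau181, FDG SUVR, longitudinal cognitive composites) are access
restricted, the package ships a synthetic cohort generator with a fully
known structural ground truth; every estimator in the package is validated
by parameter recovery against that truth.

## Stage 1 — the decomposition model

Baseline memory `mem` is regressed on demographic and brain-integrity
predictors (age, sex, education, APOE ε4 count, TIV-adjusted hippocampal
and whole-brain volumes, log white-matter-hyperintensity volume, amyloid
ratio, p-tau181, FDG SUVR, all at baseline):

    mem_i = b0 + beta' x_i + MEMR_i + e_i,
    MEMR_i ~ N(0, psi),   e_i ~ N(0, theta),   theta fixed at 0.161.

`MEMR`, the residual reserve index, is the latent part of memory not
explained by the predictors; it is constrained to be uncorrelated with all
of them. The measurement-error variance `theta` is an *input* (an externally
derived reliability constant), not an estimate; the latent variance `psi` is
free, so the conditional model is saturated and the split of the residual
variance into `psi + theta` is identified only because theta is fixed.

**Estimation.** Full-information ML via the saturated joint moments of
(predictors, memory): EM under arbitrary missingness, then algebraic
extraction (`beta = Sxx^-1 sxy`, `psi = resid - theta` clipped at 0 with a
boundary warning). On complete data this equals OLS exactly, which the test
suite asserts at 1e-8. Standard errors are profile observed-information
(predictor moments held at their ML values). When zero-covariance
constraints among predictors are requested, the constrained saturated model
has no closed form and is maximized numerically over the free moment
entries; those constraints are the model's only degrees of freedom, so with
the default empty constraint list the model is saturated and no chi-square
fit statistics are defined (reported as absent rather than zero).

**Factor scores** use the regression method: the shrunken residual
`psi/(psi+theta) * (mem - b0 - x'beta)`; rows with missing predictors
substitute the conditional expectation of the linear predictor given the
observed predictors.

## Stage 2 — Bayesian plausible values

The same model is re-estimated by a Gibbs sampler so that the latent index
can be *imputed* (M plausible-value draws per subject, default 30) rather
than fixed at a point score, propagating factor-score indeterminacy into
downstream inference.

Sweep structure (all conjugate except theta):

1. saturated predictor moments `(mu_x, Sigma_x)` from their conjugate
   normal–inverse-Wishart (Jeffreys) posterior given the current imputed
   predictor matrix;
2. missing predictor cells from their **full** conditionals — the
   predictor-model conditional updated by the memory equation
   `y - MEMR = b0 + beta'x + e` as a rank-one Gaussian likelihood term.
   Conditioning on the outcome here is essential: imputing from the
   predictor model alone attenuates the coefficient posterior, which the
   posterior-predictive check detects as misfit once n is a few thousand;
3. per-subject latent values from
   `N(lambda * (y_i - b0 - x_i'beta), lambda * theta)`,
   `lambda = psi/(psi+theta)`;
4. coefficients from their conjugate normal (prior `N(0, 1e6)` per
   coordinate); `psi` from its conjugate inverse-gamma
   (prior `IG(0.001, 0.001)`);
5. `theta` by a random-walk Metropolis step targeting the likelihood times
   the highly informative prior `N(0.161, 0.00002)` truncated to positives
   (a normal prior on a variance, honored literally because the original
   analysis specifies it).

Chains start at the ML estimates (with small chain-specific jitter), 2
chains x 2000 sweeps by default, first half discarded.

**Diagnostics.**

* *PSRF* (Gelman–Rubin) per parameter on the second half of each chain;
  the convergence gate is PSRF < 1.1. Default-length runs on default
  synthetic data satisfy the gate (max ≈ 1.05).
* *PPP*: for each of ~100 retained draws, a replicate dataset with the
  observed missingness pattern is simulated from the draw's model-implied
  moments; the discrepancy is the likelihood-ratio distance between a
  dataset's saturated (EM) moments and the draw's implied moments, and the
  PPP is the fraction of draws whose replicate is at least as discrepant as
  the data. On correctly specified data the PPP concentrates between
  roughly 0.3 and 0.6 at any n we tested (up to 2351). Limitation: with
  diffuse coefficient priors and free `psi` the model is *saturated in
  first and second moments*, so this moment-based PPP cannot detect purely
  conditional-mean misspecification of the memory equation (e.g., memory
  unrelated to predictors): `psi` absorbs the residual variance and the
  implied moments still match. What it does detect is internal
  inconsistency of the posterior (see the imputation point above) and
  non-moment-representable structure.
* *ICC(2,k)*: reliability of the M plausible-value columns via the
  two-way random-effects, absolute-agreement, mean-of-k-ratings intraclass
  correlation, with the Shrout–Fleiss F-based interval stepped up by
  Spearman–Brown. Verified against an independent implementation
  (`pingouin`) to 1e-10.

The M saved vectors are taken at equally spaced post-burn-in sweeps,
alternating chains, to reduce autocorrelation (spacing is not dictated by
the source analysis; this is our choice).

## Stage 3 — moderated sequential mediation with a latent growth outcome

Variable roles: X = amyloid ratio (CSF Aβ42/Aβ40 at T0; *lower* = more
pathology), M1 = plasma p-tau181 (T1), M2 = FDG SUVR (T2; *lower* = more
neurodegeneration), W = residual reserve index (T0), outcome = EF composite
at visits T0–T7. The model follows the conditional-process tradition in
which a single moderator interacts with every path of a two-mediator
serial mediation:

    M1 = i1 + a1 X + g_tau W + a1w XW + e1
    M2 = i2 + a2 X + d21 M1 + g_fdg W + a2w XW + d21w M1*W + e2
    I  = i3 + c_I X + b1_I M1 + b2_I M2 + g_I W
            + cw_I XW + b1w_I M1*W + b2w_I M2*W + covariates + zeta_I
    S  =  (same regressors, slope coefficients)                + zeta_S
    EF_t = I + (t - 3) S + eps_t

The intercept is centred at the third annual visit (one year after the
neurodegeneration measurement); the slope is per year. Covariates (age
centred on 73.10 years, sex, education centred on 12 years) enter only the
growth-factor equations. Product terms are fixed regressors.

**Estimation.** The joint likelihood factorizes over the recursion, so the
mediator equations are ML linear regressions and the growth block maximizes
the marginal normal likelihood of each subject's observed EF values
(random intercept/slope integrated out) — full-information ML under
monotone dropout. The growth likelihood is profiled: for fixed variance
parameters (log-Cholesky of `Psi_eta`, log residual variance) the fixed
effects are GLS, leaving a 4-dimensional optimization with an analytic
gradient (envelope theorem). Three oracles validate this block: brute-force
maximization of the joint 8-variate normal likelihood (agreement ≤ 1e-6 on
complete balanced data), a random-intercept/slope mixed model fit by
`statsmodels.MixedLM` under dropout (log-likelihood agreement ≤ 1e-5), and
direct evaluation of the recursive conditional density.

**Fit statistics.** H1 is the unrestricted multivariate regression of
(M1, M2, EF0..EF7) on the exogenous columns (X, W, XW, covariates) with an
unstructured residual covariance, estimated via EM on the joint moments
under EF missingness; the baseline model has means and variances only.
Chi-square, RMSEA (with a 90% CI from noncentral chi-square inversion,
Steiger n−1 denominator), CFI and TLI follow the standard formulas; SRMR
compares the H1 residual covariance with the structural model's implied
residual covariance, with moderated paths evaluated at the sample mean of
W (a first-order treatment of the endogenous product terms; with moderated
paths on M1/M2 the H0 conditional mean is not strictly in H1's linear
span, so the chi-square is floored at zero and the comparison is
approximate in that regime).

## Effects and inference

Conditional indirect effects at moderator value w are products of
conditional paths: `B_AT = (a1 + a1w w)(b1 + b1w w)`,
`B_ATN = (a1 + a1w w)(d21 + d21w w)(b2 + b2w w)`,
`B_AN = (a2 + a2w w)(b2 + b2w w)`; the direct effect is `c + cw w`; the
total effect is their sum at every w (an identity of the recursive linear
system, asserted at 1e-10). The index of moderated mediation (IMM) is the
analytic derivative of a conditional indirect effect in w; when only one
path on a pathway is moderated it is constant and equals the familiar
product (`a2w * b2` for B_AN). When several paths of one pathway are
moderated the conditional effect is quadratic in w and a single IMM number
is not defined; the package reports the derivative at a stated w (default
0, the moderator mean) and the effect grid itself provides ±1 SD
contrasts.

Two inference tracks mirror the source analysis:

* **Rubin's rules** across the M plausible-value imputations: the model is
  fitted once per imputation; pooled variance `ubar + (1 + 1/M) b`;
  Barnard–Rubin small-sample degrees of freedom with complete-data df
  `n − 1`; symmetric t-based CIs.
* **Bias-corrected case bootstrap** (default B = 2000) with the per-subject
  *mean* plausible value as the moderator: subjects are resampled with
  replacement and all blocks refitted per resample; the percentile levels
  are shifted by twice the probit of the bootstrap distribution's position
  relative to the point estimate (half weight on ties, so z0 is finite at
  small B). With z0 = 0 the interval equals the percentile interval on the
  same draws, exactly.

The bootstrap refit is computed by a vectorized engine: a resample is a
vector of subject counts, every cross-product matrix entering the
likelihood is linear in those counts, and the 4-parameter profile
likelihood is maximized for all resamples simultaneously by a damped
Newton iteration with the analytic batched gradient. This is the identical
ML refit as looping over resamples (asserted to ~1e-8 in the tests); it
exists purely for speed.

## The synthetic cohort generator

The generator emulates the marginal structure of a large aging/AD research
cohort and embeds the full structural model as ground truth
(`TrueParams`). Default study conditions: 2,351 subjects of whom a random
subsample of 332 has complete amyloid/tau/FDG biomarkers (the mediation
analysis sample); monotone EF dropout with a per-visit hazard logistic in
the previous EF score and age (marginal ≈ 8%/visit); whole biomarker
families go missing together outside the complete subsample, mimicking
modality-level missingness.

Marginal moments (means/SDs of demographics, volumes, biomarkers, and the
APOE4 allele distribution) default to values typical of a large multisite
aging/AD observational cohort. Structural equations operate on
z-scored biomarkers; raw columns are affine in those z-scores. Default
path values are calibrations, not estimates from restricted data: the
amyloid→tau and amyloid→FDG paths are ±0.33 (one SD of amyloid moves tau
and neurodegeneration by about one-third SD), the amyloid×reserve
interaction on FDG is a2w = −0.25 — calibrated so that at n = 332 the
interaction is clearly detectable (z ≈ 3), matching a finding strong
enough to anchor an analysis at that sample size — and all other
interactions are zero. With `b2_I = 0.40`, `b2_S = 0.04` the implied
IMM_AN is −0.10 (intercept) and −0.01 (slope). Reserve variance
`psi = 0.35`; memory error variance `theta = 0.161` (the same constant the
estimator treats as known).

Two generator properties matter for interpretation:

* The T0 biomarker companions (p-tau181 and FDG at baseline, used in the
  decomposition) correlate 0.8 with the *linear* component of their
  analysis-time counterparts. Correlating with the full value would leak
  the amyloid×reserve product into the baseline predictors and make the
  decomposition's conditional mean nonlinear — contradicting the
  empirically well-fitting baseline model the analysis presumes.
* What the generator does **not** emulate: skewed assay distributions
  (biomarkers are Gaussian on the z-scale, so a few raw values can be
  implausibly small), visit-window jitter, non-monotone intermittent
  missingness, and any dependence of dropout on unobserved cognition
  (dropout is MAR via the previous *observed* EF score, which makes the
  FIML recovery results interpretable but says nothing about MNAR
  robustness). Passing recovery tests therefore demonstrate estimator
  correctness under the stated assumptions, not robustness to their
  violation in real cohort data.

## Numerical choices and problem sizes

* EM convergence: 1e-8 in log-likelihood units (1e-6 inside the
  posterior-predictive loop), max 500 iterations; chi-square floored at 0.
* Growth optimizer: L-BFGS-B on the 4 variance parameters, analytic
  gradient, log-Cholesky parameterization (the `Psi_eta` estimate cannot
  leave the PSD cone), up to 5 random restarts.
* RMSEA uses the n−1 denominator (flag for n); SRMR excludes mean
  residuals by default (flag to include).
* Bootstrap ties use the half-count convention in z0; resamples are
  subjects (cases), not residuals.
* The statistical test suite runs at deliberately chosen sizes: parameter
  recovery at 100 replicates of n = 332; bootstrap type-I error at 400
  replicates with B = 500; diagnostics calibration at 20 replicates of
  n = 400 with 800-sweep chains. The acceptance script runs the full
  default conditions (n = 2351, M = 30, B = 2000, 2000 sweeps).

## Known limitations

* A single shared EF residual variance is the default (per-visit variances
  are available via `ef_residual="per_time"`, without the vectorized
  bootstrap path).
* Binary/discrete predictors are treated as numeric in the Gibbs
  imputation conditionals; their sub-Gaussian moment fluctuations make the
  PPP mildly conservative rather than liberal.
* Product terms involving endogenous mediators are fixed regressors, as in
  the conditional-process tradition; no distributional treatment of the
  products.
* The pooled track and the bootstrap track answer slightly different
  questions (average over imputations vs. mean-score plug-in); both are
  reported, neither is "the" interval.
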