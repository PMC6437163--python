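# Methods

## Model and estimands

For variant *j*, let β_gx,j be its per-allele effect on the exposure (SD
units) with standard error se_gx,j, and β_gy,j its per-allele effect on the
outcome (log-OR for binary traits) with se_gy,j, both oriented to the
exposure-increasing allele. Under the instrumental-variable assumptions each
Wald ratio θ_j = β_gy,j / β_gx,j estimates the same causal effect θ (log-OR
per 1 SD of exposure). The estimators differ in which departures from those
assumptions they tolerate:

- **IVW** pools ratios with weights w_j = 1/se(θ_j)²; it is exact only when
  every instrument is valid. The fixed point estimate is algebraically
  identical to inverse-variance meta-analysis of the ratios and to WLS of
  β_gy on β_gx through the origin (asserted to 1e−10 in the tests).
- **MR-Egger** frees the intercept: under InSIDE (pleiotropic effects
  independent of instrument strength) the slope remains consistent and the
  intercept estimates the mean directional pleiotropic effect.
- **Weighted median** is consistent while >50% of total weight comes from
  valid instruments.
- **Mode-based estimate (MBE)** takes the argmax of a normal-kernel-smoothed,
  inverse-variance-weighted density of the θ_j; it is consistent when the
  largest homogeneous cluster of instruments is valid.
- **Correlated-instrument IVW** generalises IVW to instruments in LD via GLS
  with covariance Ω_ij = se_gy,i·se_gy,j·ρ_ij.

Heterogeneity of the ratios (Cochran's Q, with per-variant contributions) is
the operational signal of horizontal pleiotropy; I²GX = (Q_GX − (J−1))/Q_GX
measures how precisely the exposure effects are estimated and hence how much
regression dilution attenuates the Egger slope (values near 1: negligible).

## Numerical and inferential choices

- **Wald-ratio SEs.** First-order: se_gy/|β_gx| (NOME). Second-order adds the
  next Taylor term, sqrt(se_gy²/β_gx² + β_gy²·se_gx²/β_gx⁴); the
  "second-order" IVW/Egger modes use these. The second-order SE is validated
  against a Monte-Carlo ratio-sampling oracle in the tests.
- **Random-effects IVW** inflates the fixed SE by max(1, sqrt(Q/(J−1)))
  (multiplicative overdispersion, floored so random can never beat fixed);
  an additive DerSimonian–Laird variant is deliberately not offered.
- **Egger inference** uses t(J−2); with hundreds of instruments this is
  indistinguishable from normal, but it matters at small J where the residual
  scale is poorly estimated. The residual scale is likewise floored at 1.
- **Weighted median**: ratios sorted, standardized cumulative-weight midpoints
  s_j = (Σ_{k≤j} w_k − w_j/2)/Σw, linear interpolation at s = 0.5. SE = SD of
  the estimate over seeded parametric-bootstrap draws of (β_gx, β_gy).
- **MBE**: bandwidth = φ × 0.9·min(sd, 1.4826·MAD)·J^(−1/5) with φ = 1 by
  default; the mode is located on a 512-point grid and refined by bounded
  scalar minimisation to 1e−8. The grid spans the ratio median ± 5 MAD-based
  scale units: a mean ± 5·SD span collapses in resolution whenever a few
  low-precision instruments inflate the sample SD, and the mode always lives
  where the weight mass is. The SE is the scaled MAD over bootstrap draws of
  the ratio estimates with fixed weights, which is how the estimator is
  defined by its authors and is robust to bootstrap draws whose mode jumps
  between density bumps.
- **Bootstrap calibration (measured, not hidden).** Each parametric-bootstrap
  dataset carries the sampling noise twice (draws are centred on the already
  noisy estimates), which flattens the ratio density and inflates the
  weighted-median/MBE bootstrap SEs by ~12–16% relative to the true sampling
  SD in our null simulations. Under θ = 0 with 100 valid instruments the
  measured rejection rates at α = 0.05 are ≈0.046 (IVW), ≈0.046 (Egger),
  ≈0.028 (weighted median) and ≈0.022 (MBE): the latter two are conservative,
  in line with the MBE's published type-I-error behaviour. We report this
  rather than rescale the SEs, because the bootstrap definitions above are
  the field-standard ones.
- **GLS ridge**: if the Cholesky factorisation of Ω fails, 1e−8·diag(Ω) is
  added once; a second failure raises with the condition number.
- **MVMR** is a weighted (1/se_gy²) no-intercept regression of β_gy on
  [β_gx, β_gm…]; no intercept because harmonised orientation makes the origin
  meaningful. All-zero mediator columns are dropped with their coefficient
  pinned at 0 (the no-intercept design is otherwise rank-deficient);
  near-collinear trait effects raise an error naming the offending pair.
  SEs carry the same multiplicative overdispersion floor as univariable IVW.
- **Mediation decomposition** reports total and direct effects and the
  attenuation 100·(1 − θ_direct/θ_total) on the log-OR scale plus the
  (OR_total, OR_direct) pair; no indirect-effect point estimate is returned,
  because with a binary outcome the log-odds scale is non-collapsible and
  total − direct does not identify a well-defined indirect path.
- **Q-contribution filter**: thresholds are the upper-tail χ²₁ quantiles at
  5% / 1% / 0.19% (L1/L2/L3); contributions are computed once against the
  full-sample IVW estimate, not iteratively re-fit. The 0.19% mass is used
  literally.
- **Two-stage IV** (binary outcome): stage 1 OLS of standardized exposure on
  the standardized score + covariates; stage 2 logistic regression of disease
  on the stage-1 fitted values (+ covariates), with the control-function
  variant (default) adding the stage-1 residual as a regressor. The reported
  effect is the coefficient on the fitted exposure, log-OR per 1 SD.
  Stage-2 plug-in SEs ignore first-stage uncertainty, so a seeded
  nonparametric bootstrap over samples (default 200 replicates) is offered
  and the naive SE is always recorded alongside. First-stage F < 10 warns
  (never errors). Logistic fits are IRLS with deviance tolerance 1e−8, max 50
  iterations; standardized coefficients above 15 are treated as separation.
- **Three-stage mediation**: both first stages regress their phenotype on
  *both* genetic scores plus covariates (2SLS with two endogenous
  regressors). Regressing the mediator only on its own score would leave the
  exposure-score-driven part of the mediator unmodelled and push the mediated
  path into the "direct" coefficient — we verified on full-mediation
  simulations that the one-score variant is biased while the two-score
  variant is centred on zero. Fitted values whose partial correlation given
  covariates exceeds 0.99 raise a collinearity error.
- **Inverse-normal transform**: OLS residuals ranked (average ranks on ties),
  mapped through Φ⁻¹((r − 0.5)/n).
- **Power**: for an instrument set explaining r² of the exposure in an
  outcome study of n with case fraction K, the log-OR per SD has sampling
  variance ≈ 1/(n·K(1−K)·r²), giving non-centrality
  ncp = n·K(1−K)·r²·log(OR)²; power is the upper-tail mass of
  χ²₁(ncp) beyond the central critical value. At OR = 1 this returns α
  exactly; across a grid of (r², OR) the formula agrees with empirical IVW
  rejection rates from the two-sample generator within 0.03.

## Synthetic data: what it emulates and what it does not

**Two-sample generator.** MAF ~ U(0.1, 0.5); true exposure effects drawn
N(0, σ_gx) and then *significance-selected*: effects are redrawn until every
instrument's true F = (β_gx/se_gx)² clears 30, mirroring the fact that MR
instrument sets contain only genome-wide-significant variants — an
unconditioned normal draw would flood the set with sub-significant
instruments no practitioner would use. The selected truth is oriented to the
exposure-increasing allele (so "directional" pleiotropy means directional
after harmonisation); the written tables then randomly scramble
allele/strand representation so harmonisation does real work. Standard
errors follow the marginal-GWAS form se = 1/sqrt(2p(1−p)·n), scaled by
K(1−K) for binary outcomes analysed on the log-OR scale; exposure and
outcome noise are independent (no sample overlap). Pleiotropy models: none,
balanced (mean 0), directional (mean μ_α), and InSIDE-violating
(α_j = δ·β_gx,j + noise); a mediator adds β_gm = γ·β_gx + own effects and
contributes θ_m·β_gm to the outcome. A slow "exact" binary mode fits
per-variant logistic regressions on a simulated cohort and is used only to
cross-validate the fast log-OR-scale noise model.

The `height_cad_like` preset (J = 828, n_exposure = 700,000,
n_outcome = 184,000 with case fraction 0.33, θ = −0.17, σ_gx calibrated once
to 0.0254 so the selected instruments explain ≈30% of exposure variance) is
a *regime label*, not a claim about any real cohort.

**Cohort generator.** Genotypes Binomial(2, MAF); exposure = centred score +
confounder + normal noise with the score variance set to the target
heritability (default 0.3) and total variance ≈ 1; mediator = γ·exposure +
its own score + confounder + noise; outcome Bernoulli with logit linear in
exposure, mediator and confounder, the intercept solved by root-finding to
hit the target prevalence to 1e−4. Covariates (age, sex, batch, 5 PCs) are
generated independent of genotype, so they test interface plumbing, not
stratification correction.

**Not emulated:** real LD maps, population stratification, selection/collider
bias, assortative mating, sample overlap between the two GWAS, winner's-curse
bias in the instrument effects, and non-linear exposure–outcome
relationships. Passing tests therefore demonstrate internal statistical
correctness under the stated generating models, not robustness to these
real-data phenomena.

## Problem sizes

The statistical test-suite and `scripts/acceptance.py` use Monte-Carlo sizes
chosen to keep a single-CPU run to minutes while holding MC error well below
the tolerances checked: 2000 (script: 800) null-calibration replicates at
J = 100; 500 (200) recovery replicates at J = 828 with weighted-median
n_boot = 500 and MBE n_boot = 150 on a 256-point grid; 200 (150) directional
pleiotropy replicates; 500 (200) mediation-coverage replicates at
n = 6000 cohort samples; 30 (20) confounded-cohort replicates at n = 50,000;
2000 (800) replicates per power-grid point. At 500 replicates a coverage
proportion near 0.95 has MC SE ≈ 0.010; at 2000, a rejection rate near 0.05
has MC SE ≈ 0.005.

## Known limitations

- The weighted-median/MBE bootstrap conservatism quantified above.
- The control-function logistic estimator targets a conditional effect; with
  residual (unmodelled) confounder noise the estimate is attenuated by
  logistic non-collapsibility, ~2–3% at the simulated effect sizes — inside
  the 10% tolerance we test but visible at higher precision.
- MVMR treats mediator effect estimates as known (NOME across traits); with
  imprecise mediator GWAS the direct effect is diluted. The conditional-F
  diagnostic reports, but never gates.
- The simplified MR-PRESSO omits the distortion test; the Q-contribution
  filter plays the outlier-removal role.
- GSMR-style estimation here is the GLS IVW only; no HEIDI outlier step.
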