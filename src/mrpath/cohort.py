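"""Individual-level (cohort) analysis: QC, phenotype preprocessing, genetic
scores, observational regression, and score-based instrumental-variable
estimators for binary outcomes.

The IV machinery follows the two-stage logistic design: stage 1 regresses the
exposure on the genetic score (plus covariates) by OLS; stage 2 fits a
logistic model of disease on the stage-1 fitted values, optionally adding the
stage-1 residual as a regressor (the control-function variant, the default).
The coefficient on the fitted exposure is the causal log-OR per 1 SD of
exposure.  A three-stage extension instruments a mediator with its own score
and reports the exposure's direct effect conditional on the mediator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .estimators import MREstimate, Z95

__all__ = [
    "CohortTable",
    "GeneticScore",
    "StageFit",
    "qc_filter",
    "residual_inverse_normalise",
    "build_genetic_score",
    "observational_association",
    "two_stage_iv",
    "three_stage_mediation",
]


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass
class CohortTable:
    """Individual-level dosages, covariates, phenotypes and binary outcomes.

    ``samples``: one row per sample with sample_id, covariates, quantitative
    phenotypes and 0/1 outcome columns.  ``dosages``: samples x variants in
    [0, 2], oriented to the trait-increasing allele.  ``info_scores``: per
    variant imputation quality in [0, 1].  ``kinship_flag`` marks samples
    failing relatedness QC (kinship is an input, not estimated here).
    """

    samples: pd.DataFrame
    dosages: pd.DataFrame
    info_scores: pd.Series
    covariate_cols: list
    phenotype_cols: list
    outcome_cols: list
    kinship_flag: pd.Series | None = None
    variant_weights: pd.DataFrame | None = None
    exclusion_log: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicated sample_id")
        vals = self.dosages.to_numpy()
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for col in self.outcome_cols:
            if not set(pd.unique(self.samples[col])) <= {0, 1}:
                raise ValueError(f"outcome {col!r} must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class GeneticScore:
    """Per-sample allele-count score, optionally effect-size weighted.

    The weighted score sum_j beta_j dosage_j is rescaled by the mean effect
    size so its range matches the unweighted allele count.
    """

    kind: str
    values: pd.Series
    snps_used: int
    rescale_factor: float | None = None
    imputed_variants: list = field(default_factory=list)


@dataclass
class StageFit:
    stage: str
    params: pd.Series
    bse: pd.Series
    fitted: np.ndarray
    residuals: np.ndarray
    n: int
    converged: bool = True
    extras: dict = field(default_factory=dict)


def qc_filter(cohort: CohortTable, height_col: str | None = None,
              height_sd_limit: float = 5.0, kinship_threshold: float = 0.0884,
              info_threshold: float = 0.4) -> CohortTable:
    """Sample and variant QC.

    Removes samples flagged as related (the kinship flag is expected to encode
    kinship > ``kinship_threshold``) and samples whose phenotype lies more
    than ``height_sd_limit`` SDs from the mean; drops variants with
    imputation INFO below ``info_threshold`` table-wide.  Exclusion counts by
    reason land in ``exclusion_log``.
    """
    height_col = height_col or cohort.phenotype_cols[0]
    samples = cohort.samples
    log = {}

    related = (cohort.kinship_flag.astype(bool).to_numpy()
               if cohort.kinship_flag is not None
               else np.zeros(len(samples), dtype=bool))
    log["related"] = int(related.sum())

    h = samples[height_col].to_numpy(float)
    mu, sd = np.nanmean(h), np.nanstd(h)
    outlier = np.abs(h - mu) > height_sd_limit * sd if sd > 0 else np.zeros_like(related)
    log["height_outlier"] = int((outlier & ~related).sum())

    keep = ~(related | outlier)
    if not keep.any():
        raise ValueError("QC excluded every sample")

    bad_variants = cohort.info_scores[cohort.info_scores < info_threshold].index
    log["low_info_variants"] = len(bad_variants)

    weights = cohort.variant_weights
    if weights is not None and len(bad_variants):
        weights = weights[~weights["variant_id"].isin(bad_variants)].reset_index(drop=True)
    return CohortTable(
        samples[keep].reset_index(drop=True),
        cohort.dosages.loc[keep.nonzero()[0]].reset_index(drop=True)
            .drop(columns=list(bad_variants)),
        cohort.info_scores.drop(index=bad_variants),
        cohort.covariate_cols, cohort.phenotype_cols, cohort.outcome_cols,
        kinship_flag=None, variant_weights=weights, exclusion_log=log,
    )


def residual_inverse_normalise(cohort: CohortTable, phenotype: str,
                               covariates=None) -> pd.Series:
    """OLS-residualise a quantitative phenotype on covariates, then map ranks
    to standard-normal quantiles via r -> Phi^-1((r - 0.5)/n) (average ranks
    for ties).  Output has mean ~0 and SD ~1."""
    covariates = cohort.covariate_cols if covariates is None else covariates
    y = cohort.samples[phenotype].to_numpy(float)
    if np.nanstd(y) == 0:
        raise ValueError(f"phenotype {phenotype!r} is constant")
    X = sm.add_constant(cohort.samples[list(covariates)].to_numpy(float))
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    ranks = stats.rankdata(resid, method="average")
    z = stats.norm.ppf((ranks - 0.5) / len(ranks))
    return pd.Series(z, index=cohort.samples.index, name=f"{phenotype}_rint")


def build_genetic_score(cohort: CohortTable, weights: pd.Series | None = None,
                        variants=None) -> GeneticScore:
    """Allele-count genetic score over ``variants`` (default: all dosage
    columns), with dosages assumed oriented to the trait-increasing allele.

    Unweighted: sum of dosages.  Weighted: sum of beta_j * dosage_j divided by
    mean(beta), so the range matches the unweighted score.  Missing dosages
    are mean-imputed per variant (2 * EAF estimated from the cohort), logged.
    """
    variants = list(variants) if variants is not None else list(cohort.dosages.columns)
    G = cohort.dosages[variants].to_numpy(float).copy()
    imputed = []
    for k, v in enumerate(variants):
        col = G[:, k]
        nan = np.isnan(col)
        if nan.any():
            col[nan] = np.nanmean(col)
            imputed.append(v)
    if weights is None:
        vals = G.sum(axis=1)
        return GeneticScore("unweighted", pd.Series(vals, index=cohort.samples.index),
                            len(variants), imputed_variants=imputed)
    w = weights.reindex(variants)
    if w.isna().any():
        missing = list(w[w.isna()].index)
        raise ValueError(f"weights missing for variants {missing[:5]}")
    mean_beta = float(w.mean())
    vals = (G @ w.to_numpy(float)) / mean_beta
    return GeneticScore("weighted", pd.Series(vals, index=cohort.samples.index),
                        len(variants), rescale_factor=mean_beta,
                        imputed_variants=imputed)


def _design(cohort, cols, extra=None):
    parts = [np.ones(cohort.n_samples)]
    names = ["const"]
    if extra:
        for name, arr in extra.items():
            parts.append(np.asarray(arr, float))
            names.append(name)
    for c in cols:
        parts.append(cohort.samples[c].to_numpy(float))
        names.append(c)
    return np.column_stack(parts), names


def _fit_logistic(X, names, y, max_iter=50, tol=1e-8):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=max_iter, tol=tol)
    scale = np.std(X, axis=0)
    scale[scale == 0] = 1.0
    std_coef = np.abs(fit.params * scale)
    if np.any(std_coef[1:] > 15.0):
        raise RuntimeError("possible separation: diverging logistic coefficient")
    return fit


def observational_association(cohort: CohortTable, outcome: str, exposure: str,
                              covariates=None) -> StageFit:
    """Conventional logistic regression of a binary outcome on an exposure
    (plus covariates); the exposure is standardized internally so the OR is
    per 1 SD."""
    covariates = cohort.covariate_cols if covariates is None else covariates
    x = cohort.samples[exposure].to_numpy(float)
    if np.std(x) == 0:
        raise ValueError(f"exposure {exposure!r} is constant")
    xs = (x - x.mean()) / x.std()
    y = cohort.samples[outcome].to_numpy(float)
    X, names = _design(cohort, covariates, extra={exposure: xs})
    fit = _fit_logistic(X, names, y)
    params = pd.Series(fit.params, index=names)
    bse = pd.Series(fit.bse, index=names)
    b, s = params[exposure], bse[exposure]
    return StageFit(
        "observational", params, bse, fit.fittedvalues,
        y - fit.fittedvalues, cohort.n_samples, converged=fit.converged,
        extras={"OR": float(np.exp(b)),
                "OR_ci": (float(np.exp(b - Z95 * s)), float(np.exp(b + Z95 * s))),
                "pvalue": float(2 * stats.norm.sf(abs(b / s)))},
    )


def _first_stage(cohort, exposure, score, covariates):
    x = cohort.samples[exposure].to_numpy(float)
    sd_x = x.std()
    xs = (x - x.mean()) / sd_x
    sc = np.asarray(score.values, float)
    sc = (sc - sc.mean()) / sc.std()
    X, names = _design(cohort, covariates, extra={"score": sc})
    coef, _, _, _ = np.linalg.lstsq(X, xs, rcond=None)
    fitted = X @ coef
    resid = xs - fitted
    n, k = X.shape
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    f_stat = (coef[1] / bse[1]) ** 2
    fit = StageFit("first_stage", pd.Series(coef, index=names),
                   pd.Series(bse, index=names), fitted, resid, n,
                   extras={"f_statistic": float(f_stat), "sd_exposure": float(sd_x)})
    if f_stat < 10:
        warnings.warn(f"weak instrument: first-stage F = {f_stat:.2f}",
                      WeakInstrumentWarning, stacklevel=3)
    return fit


def two_stage_iv(cohort: CohortTable, outcome: str, exposure: str,
                 score: GeneticScore, covariates=None,
                 variant: str = "control_function",
                 n_boot: int = 200, seed=None):
    """Two-stage genetic-score IV estimate of the causal log-OR per 1 SD of
    exposure.

    ``variant="substitution"`` uses only the stage-1 fitted values in the
    logistic stage; ``"control_function"`` (default) adds the stage-1
    residual, absorbing confounding shared between exposure and outcome.
    Stage-2 naive SEs are always reported; if ``n_boot`` > 0 a nonparametric
    bootstrap over samples (seeded) replaces them, since the plug-in SE
    ignores first-stage uncertainty.
    """
    if variant not in ("substitution", "control_function"):
        raise ValueError(f"unknown variant {variant!r}")
    covariates = cohort.covariate_cols if covariates is None else covariates
    if n_boot and seed is None:
        raise ValueError("seed is required when n_boot > 0")
    y = cohort.samples[outcome].to_numpy(float)

    def point(c: CohortTable, sc_values):
        s1 = _first_stage_arrays(c, exposure, sc_values, covariates)
        extra = {"fitted_exposure": s1["fitted"]}
        if variant == "control_function":
            extra["stage1_residual"] = s1["resid"]
        X, names = _design(c, covariates, extra=extra)
        fit = _fit_logistic(X, names, c.samples[outcome].to_numpy(float))
        return s1, fit, names

    s1_arr, fit2, names = point(cohort, np.asarray(score.values, float))
    stage1 = _first_stage(cohort, exposure, score, covariates)
    params = pd.Series(fit2.params, index=names)
    bse = pd.Series(fit2.bse, index=names)
    beta = float(params["fitted_exposure"])
    naive_se = float(bse["fitted_exposure"])

    se = naive_se
    if n_boot:
        rng = np.random.default_rng(seed)
        n = cohort.n_samples
        boots = np.empty(n_boot)
        sc_values = np.asarray(score.values, float)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            cb = _reindex_cohort(cohort, idx)
            try:
                _, fb, nb = point(cb, sc_values[idx])
                boots[b] = fb.params[nb.index("fitted_exposure")]
            except RuntimeError:
                boots[b] = np.nan
        good = boots[~np.isnan(boots)]
        if len(good) >= max(20, n_boot // 2):
            se = float(np.std(good, ddof=1))

    p = float(2 * stats.norm.sf(abs(beta / se)))
    est = MREstimate(f"two_stage_{variant}", beta, se,
                     beta - Z95 * se, beta + Z95 * se, p, score.snps_used,
                     outcome_type="binary",
                     diagnostics={"naive_se": naive_se,
                                  "first_stage_f": stage1.extras["f_statistic"],
                                  "n_boot": n_boot, "seed": seed})
    stage2 = StageFit("second_stage", params, bse, fit2.fittedvalues,
                      y - fit2.fittedvalues, cohort.n_samples,
                      converged=fit2.converged)
    return stage1, stage2, est


def _first_stage_arrays(cohort, exposure, sc_values, covariates):
    x = cohort.samples[exposure].to_numpy(float)
    xs = (x - x.mean()) / x.std()
    sc = np.atleast_2d(np.asarray(sc_values, float).T).T
    sc = (sc - sc.mean(axis=0)) / sc.std(axis=0)
    extra = {f"score{k}": sc[:, k] for k in range(sc.shape[1])}
    X, _ = _design(cohort, covariates, extra=extra)
    coef, _, _, _ = np.linalg.lstsq(X, xs, rcond=None)
    fitted = X @ coef
    return {"fitted": fitted, "resid": xs - fitted}


def _reindex_cohort(cohort: CohortTable, idx) -> CohortTable:
    samples = cohort.samples.iloc[idx].reset_index(drop=True)
    samples = samples.assign(sample_id=[f"b{i}" for i in range(len(idx))])
    return CohortTable(samples, cohort.dosages.iloc[idx].reset_index(drop=True),
                       cohort.info_scores, cohort.covariate_cols,
                       cohort.phenotype_cols, cohort.outcome_cols)


def three_stage_mediation(cohort: CohortTable, outcome: str, exposure: str,
                          mediator: str, exposure_score: GeneticScore,
                          mediator_score: GeneticScore, covariates=None,
                          exposure_variants=None, mediator_variants=None) -> MREstimate:
    """Direct effect of the exposure on a binary outcome conditional on a
    mediator, both instrumented by their own genetic scores.

    The first stages regress exposure and mediator each on *both* scores
    (plus covariates) — the mediator inherits part of the exposure score's
    effect through the exposure->mediator path, and omitting the exposure
    score from its first stage would push that mediated signal into the
    exposure coefficient.  The final logistic stage regresses the outcome on
    both sets of fitted values plus covariates; the exposure-fitted-value
    coefficient is the direct log-OR per 1 SD of exposure.
    """
    covariates = cohort.covariate_cols if covariates is None else covariates
    if exposure_variants is not None and mediator_variants is not None:
        overlap = set(exposure_variants) & set(mediator_variants)
        if overlap:
            warnings.warn(f"exposure and mediator scores share variants: "
                          f"{sorted(overlap)[:5]}", UserWarning, stacklevel=2)
    instruments = np.column_stack([np.asarray(exposure_score.values, float),
                                   np.asarray(mediator_score.values, float)])
    fx = _first_stage_arrays(cohort, exposure, instruments, covariates)
    fm = _first_stage_arrays(cohort, mediator, instruments, covariates)
    # partial correlation given covariates: the fitted values always share
    # the covariate plane, only their instrument-driven parts must differ
    C, _ = _design(cohort, covariates)
    rx = fx["fitted"] - C @ np.linalg.lstsq(C, fx["fitted"], rcond=None)[0]
    rm = fm["fitted"] - C @ np.linalg.lstsq(C, fm["fitted"], rcond=None)[0]
    r = np.corrcoef(rx, rm)[0, 1]
    if abs(r) > 0.99:
        raise np.linalg.LinAlgError(
            f"collinear fitted values (correlation {r:.4f}); are the two "
            f"scores built from disjoint variants?")
    X, names = _design(cohort, covariates,
                       extra={"fitted_exposure": fx["fitted"],
                              "fitted_mediator": fm["fitted"]})
    y = cohort.samples[outcome].to_numpy(float)
    fit = _fit_logistic(X, names, y)
    params = pd.Series(fit.params, index=names)
    bse = pd.Series(fit.bse, index=names)
    b, s = float(params["fitted_exposure"]), float(bse["fitted_exposure"])
    p = float(2 * stats.norm.sf(abs(b / s)))
    return MREstimate("three_stage_direct", b, s, b - Z95 * s, b + Z95 * s, p,
                      exposure_score.snps_used, outcome_type="binary",
                      diagnostics={"mediator_beta": float(params["fitted_mediator"]),
                                   "mediator_se": float(bse["fitted_mediator"]),
                                   "fitted_correlation": float(r)})
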