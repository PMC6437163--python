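"""Synthetic data with known causal structure for every pipeline stage.

Two generators are provided:

* :func:`simulate_two_sample` — GWAS summary statistics for an exposure, an
  outcome and optionally a mediator, under the standard two-sample design:
  independent sampling noise in the two studies, per-variant standard errors
  1/sqrt(2 p (1-p) n) (scaled by K(1-K) for a binary outcome analysed on the
  log-odds scale), and a configurable horizontal-pleiotropy model.
* :func:`simulate_cohort` — individual-level genotype dosages, a polygenic
  exposure, a mediator on the causal path, a shared confounder, and a logistic
  binary outcome, for genetic-score instrumental-variable analysis.

Every dataset carries a :class:`SimulationTruth` recording the generating
parameters, so recovery can be tested, and every generator is a pure function
of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .cohort import CohortTable
from .summary_io import SummaryTable, LDInfo

__all__ = [
    "PleiotropyModel",
    "MediatorModel",
    "TwoSampleSimConfig",
    "CohortSimConfig",
    "SimulationTruth",
    "simulate_two_sample",
    "simulate_cohort",
    "simulate_ld_blocks",
    "PRESETS",
    "preset",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass
class PleiotropyModel:
    """Direct variant-outcome effects alpha_j.

    kind: "none" | "balanced" (mean-zero) | "directional" (mean mu) |
    "inside_violating" (alpha_j = delta * bx_j + noise, correlating pleiotropy
    with instrument strength and so breaking InSIDE).
    ``fraction_invalid`` restricts pleiotropy to a random subset of variants.
    """

    kind: str = "none"
    mu: float = 0.0
    sigma: float = 0.0
    delta: float = 0.0
    fraction_invalid: float = 1.0

    def draw(self, bx_true, rng):
        j = len(bx_true)
        alpha = np.zeros(j)
        if self.kind == "none":
            return alpha
        invalid = rng.random(j) < self.fraction_invalid
        if self.kind == "balanced":
            alpha[invalid] = rng.normal(0.0, self.sigma, invalid.sum())
        elif self.kind == "directional":
            alpha[invalid] = rng.normal(self.mu, self.sigma, invalid.sum())
        elif self.kind == "inside_violating":
            alpha[invalid] = (self.delta * bx_true[invalid]
                              + rng.normal(0.0, self.sigma, invalid.sum()))
        else:
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        return alpha


@dataclass
class MediatorModel:
    """Mediator on the causal path: bm_j = gamma * bx_j + own_j, with own
    genetic effects own_j ~ N(0, sigma_own) giving the mediator instruments
    of its own (needed for an identifiable MVMR design)."""

    label: str = "mediator"
    gamma: float = 0.0  # exposure -> mediator
    theta_mediator: float = 0.0  # mediator -> outcome
    sigma_own: float = 0.02
    n_mediator: int = 300_000


@dataclass
class TwoSampleSimConfig:
    n_snps: int = 100
    sigma_gx: float = 0.03  # SD of true per-allele exposure effects (SD units)
    fixed_beta_gx: list | None = None
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_exposure: int = 700_000
    n_outcome: int = 180_000
    theta: float = 0.0  # causal effect per 1 SD exposure
    min_instrument_f: float | None = 30.0  # significance selection in the exposure GWAS
    outcome_type: str = "binary"
    case_fraction: float = 0.33  # binary outcomes only
    pleiotropy: PleiotropyModel = field(default_factory=PleiotropyModel)
    mediator: MediatorModel | None = None
    scramble_orientation: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("maf bounds must satisfy 0 < low <= high <= 0.5")
        if self.sigma_gx < 0 or self.pleiotropy.sigma < 0:
            raise ValueError("scale parameters must be non-negative")
        if self.outcome_type == "binary" and not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must be in (0,1)")


@dataclass
class CohortSimConfig:
    n_samples: int = 20_000
    n_snps_exposure_score: int = 50
    n_snps_mediator_score: int = 50
    maf_low: float = 0.1
    maf_high: float = 0.5
    heritability_exposure: float = 0.3  # variance explained by the score
    heritability_mediator: float = 0.2  # mediator's own genetic variance
    confounder_exposure: float = 0.0
    confounder_mediator: float = 0.0
    confounder_outcome: float = 0.0
    gamma: float = 0.0  # exposure -> mediator (SD units)
    theta_exposure: float = 0.0  # log-OR per SD exposure
    theta_mediator: float = 0.0  # log-OR per SD mediator
    prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for h2 in (self.heritability_exposure, self.heritability_mediator):
            if not 0 <= h2 < 1:
                raise ValueError("heritability must lie in [0,1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0,1)")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class SimulationTruth:
    """Generating parameters attached to every synthetic dataset."""

    config: dict
    theta: float = 0.0
    alpha: np.ndarray | None = None  # per-variant pleiotropic effects
    beta_gx_true: np.ndarray | None = None
    realized_r2: float | None = None
    expected_attenuation_pct: float | None = None
    extras: dict = field(default_factory=dict)


def _se_marginal(maf, n, case_fraction=None):
    base = 2.0 * maf * (1.0 - maf) * n
    if case_fraction is not None:
        base = base * case_fraction * (1.0 - case_fraction)
    return 1.0 / np.sqrt(base)


def _as_table(rng, label, trait_type, ids, ea, oa, eaf, beta, se, n,
              scramble):
    beta = np.asarray(beta, float).copy()
    eaf = np.asarray(eaf, float).copy()
    ea = list(ea)
    oa = list(oa)
    if scramble:
        flip = rng.random(len(ids)) < 0.5
        for i in np.where(flip)[0]:
            ea[i], oa[i] = oa[i], ea[i]
            beta[i] = -beta[i]
            eaf[i] = 1.0 - eaf[i]
    z = np.abs(beta / se)
    p = np.clip(2 * stats.norm.sf(z), np.nextafter(0, 1), 1.0)
    df = pd.DataFrame({
        "variant_id": ids, "effect_allele": ea, "other_allele": oa,
        "eaf": eaf, "beta": beta, "se": se, "pvalue": p,
        "n": np.full(len(ids), n),
    })
    return SummaryTable(label, df, trait_type)


def simulate_two_sample(cfg: TwoSampleSimConfig, ld: LDInfo | None = None,
                        exact_binary: bool = False):
    """Generate (exposure, outcome[, mediator]) SummaryTables plus truth.

    True per-allele exposure effects bx_j ~ N(0, sigma_gx) (or a fixed list);
    pleiotropy alpha_j per the configured model; true outcome effects
    theta*bx_j + theta_m*bm_j + alpha_j.  Observed effects add independent
    normal noise with the marginal-GWAS standard errors; exposure and outcome
    noise are independent (the no-sample-overlap property).  ``ld`` draws the
    noise with the given within-block correlation, supporting the
    correlated-instrument estimator.  ``exact_binary`` fits per-variant
    logistic regressions on a simulated outcome cohort instead of the fast
    log-OR-scale normal model (slow; cross-validation only).
    """
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    ids = np.array([f"rs{100000 + i}" for i in range(j)], dtype=object)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), j)
    ea = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oa = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, j)

    se_gx = _se_marginal(maf, cfg.n_exposure)
    if cfg.fixed_beta_gx is not None:
        bx_true = np.asarray(cfg.fixed_beta_gx, float)
        if len(bx_true) != j:
            raise ValueError("fixed_beta_gx length must equal n_snps")
    else:
        bx_true = rng.normal(0.0, cfg.sigma_gx, j)
        if cfg.min_instrument_f is not None:
            # instrument sets in two-sample MR are significance-selected in
            # the exposure GWAS; redraw until every true F clears the bar
            floor = np.sqrt(cfg.min_instrument_f) * se_gx
            if np.any(floor > 6 * cfg.sigma_gx):
                raise ValueError("min_instrument_f unattainable at this sigma_gx")
            weak = np.abs(bx_true) < floor
            for _ in range(1000):
                if not weak.any():
                    break
                bx_true[weak] = rng.normal(0.0, cfg.sigma_gx, int(weak.sum()))
                weak = np.abs(bx_true) < floor
            else:
                raise ValueError("instrument-strength selection did not converge")
        # orient the generating truth to the exposure-increasing allele so a
        # directional pleiotropy model means what it says after harmonisation
        bx_true = np.abs(bx_true)
    alpha = cfg.pleiotropy.draw(bx_true, rng)

    med = cfg.mediator
    bm_true = None
    if med is not None:
        bm_true = med.gamma * bx_true + rng.normal(0.0, med.sigma_own, j)
    by_true = cfg.theta * bx_true + alpha
    if med is not None:
        by_true = by_true + med.theta_mediator * bm_true

    kf = cfg.case_fraction if cfg.outcome_type == "binary" else None
    se_gy = _se_marginal(maf, cfg.n_outcome, kf)

    if ld is not None:
        rho = ld.correlation_matrix(ids)
        chol = np.linalg.cholesky(rho)
        noise_x = chol @ rng.standard_normal(j)
        noise_y = chol @ rng.standard_normal(j)
    else:
        noise_x = rng.standard_normal(j)
        noise_y = rng.standard_normal(j)
    bx_obs = bx_true + se_gx * noise_x

    if exact_binary and cfg.outcome_type == "binary":
        by_obs, se_gy = _exact_binary_outcome(cfg, maf, by_true, rng)
    else:
        by_obs = by_true + se_gy * noise_y

    exposure = _as_table(rng, "exposure", "quantitative", ids, ea, oa, maf,
                         bx_obs, se_gx, cfg.n_exposure, cfg.scramble_orientation)
    outcome = _as_table(rng, "outcome", cfg.outcome_type, ids, ea, oa, maf,
                        by_obs, se_gy, cfg.n_outcome, cfg.scramble_orientation)
    mediator_table = None
    if med is not None:
        se_gm = _se_marginal(maf, med.n_mediator)
        bm_obs = bm_true + se_gm * rng.standard_normal(j)
        mediator_table = _as_table(rng, med.label, "quantitative", ids, ea, oa,
                                   maf, bm_obs, se_gm, med.n_mediator,
                                   cfg.scramble_orientation)

    realized_r2 = float(np.sum(2 * maf * (1 - maf) * bx_true**2))
    total = cfg.theta + (med.gamma * med.theta_mediator if med else 0.0)
    att = None
    if med is not None and abs(total) > 1e-12:
        att = 100.0 * (1.0 - cfg.theta / total)
    truth = SimulationTruth(
        config=asdict(cfg), theta=cfg.theta, alpha=alpha, beta_gx_true=bx_true,
        realized_r2=realized_r2, expected_attenuation_pct=att,
        extras={"beta_gm_true": bm_true, "total_effect": total},
    )
    if mediator_table is not None:
        return exposure, outcome, mediator_table, truth
    return exposure, outcome, truth


def _exact_binary_outcome(cfg, maf, by_true, rng):
    """Per-variant logistic fits on a simulated case-control cohort: the slow
    cross-check for the fast log-OR-scale noise model."""
    n = int(cfg.n_outcome)
    j = len(maf)
    k = cfg.case_fraction
    b0 = np.log(k / (1 - k))
    by_obs = np.empty(j)
    se = np.empty(j)
    import statsmodels.api as sm
    for v in range(j):
        g = rng.binomial(2, maf[v], n).astype(float)
        eta = b0 + by_true[v] * (g - 2 * maf[v])
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        fit = sm.GLM(y.astype(float), sm.add_constant(g),
                     family=sm.families.Binomial()).fit()
        by_obs[v] = fit.params[1]
        se[v] = fit.bse[1]
    return by_obs, se


def simulate_cohort(cfg: CohortSimConfig):
    """Individual-level cohort with the causal diagram
    exposure -> mediator -> outcome, a shared confounder, and genotype scores
    instrumenting exposure and mediator through disjoint variant sets.

    The exposure is standardized to SD ~1 so effects are per-SD; the logistic
    intercept is solved by root-finding so the realized outcome prevalence
    matches the target to 1e-4.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    jx, jm = cfg.n_snps_exposure_score, cfg.n_snps_mediator_score
    j = jx + jm
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, j)
    geno = rng.binomial(2, maf, size=(n, j)).astype(float)
    ids = [f"snpX{i}" for i in range(jx)] + [f"snpM{i}" for i in range(jm)]

    # per-allele effects scaled so the score explains the target heritability
    raw_bx = np.abs(rng.normal(1.0, 0.3, jx))
    var_unit = np.sum(2 * maf[:jx] * (1 - maf[:jx]) * raw_bx**2)
    bx = raw_bx * np.sqrt(cfg.heritability_exposure / var_unit)
    raw_bm = np.abs(rng.normal(1.0, 0.3, jm))
    var_unit_m = np.sum(2 * maf[jx:] * (1 - maf[jx:]) * raw_bm**2)
    bm = raw_bm * np.sqrt(cfg.heritability_mediator / var_unit_m)

    conf = rng.standard_normal(n)
    gscore_x = geno[:, :jx] @ bx
    env_var = max(1e-9, 1.0 - cfg.heritability_exposure - cfg.confounder_exposure**2)
    exposure = (gscore_x - gscore_x.mean()) + cfg.confounder_exposure * conf \
        + rng.normal(0.0, np.sqrt(env_var), n)

    gscore_m = geno[:, jx:] @ bm
    med_env = max(1e-9, 1.0 - cfg.heritability_mediator - cfg.confounder_mediator**2)
    mediator = cfg.gamma * exposure + (gscore_m - gscore_m.mean()) \
        + cfg.confounder_mediator * conf + rng.normal(0.0, np.sqrt(med_env), n)

    lin = cfg.theta_exposure * exposure + cfg.theta_mediator * mediator \
        + cfg.confounder_outcome * conf

    def prev_at(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + lin)))) - cfg.prevalence

    lo, hi = -30.0, 30.0
    if prev_at(lo) > 0 or prev_at(hi) < 0:
        raise ValueError("target prevalence unattainable for these effects")
    b0 = brentq(prev_at, lo, hi, xtol=1e-6)
    if abs(prev_at(b0)) > 1e-4:
        raise ValueError("prevalence root-finding failed")
    pr = 1.0 / (1.0 + np.exp(-(b0 + lin)))
    outcome = (rng.random(n) < pr).astype(int)

    age = rng.integers(40, 70, n).astype(float)
    sex = rng.integers(0, 2, n).astype(float)
    batch = rng.integers(0, 4, n).astype(float)
    pcs = rng.standard_normal((n, 5))
    samples = pd.DataFrame({
        "sample_id": [f"id{i:07d}" for i in range(n)],
        "age": age, "sex": sex, "batch": batch,
        **{f"pc{k + 1}": pcs[:, k] for k in range(5)},
        "exposure": exposure, "mediator": mediator, "outcome": outcome,
    })
    dosages = pd.DataFrame(geno, columns=ids)
    info = pd.Series(np.ones(j), index=ids, name="info")
    weights = pd.DataFrame({"variant_id": ids,
                            "beta": np.concatenate([bx, bm]),
                            "maf": maf,
                            "score": ["exposure"] * jx + ["mediator"] * jm})
    table = CohortTable(
        samples, dosages, info,
        covariate_cols=["age", "sex", "batch"] + [f"pc{k + 1}" for k in range(5)],
        phenotype_cols=["exposure", "mediator"],
        outcome_cols=["outcome"],
        variant_weights=weights,
    )
    total = cfg.theta_exposure + cfg.gamma * cfg.theta_mediator
    att = None
    if abs(total) > 1e-12:
        att = 100.0 * (1.0 - cfg.theta_exposure / total)
    r2 = float(np.corrcoef(gscore_x, exposure)[0, 1] ** 2)
    truth = SimulationTruth(
        config=asdict(cfg), theta=cfg.theta_exposure,
        realized_r2=r2, expected_attenuation_pct=att,
        extras={"intercept": float(b0), "total_effect": total,
                "beta_exposure_score": bx, "beta_mediator_score": bm},
    )
    return table, truth


def simulate_ld_blocks(n_blocks: int, block_size: int, rho: float,
                       seed: int = 0, ids=None) -> LDInfo:
    """Block-diagonal exchangeable LD: correlation ``rho`` within blocks of
    ``block_size`` variants, zero between blocks."""
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    if block_size > 1 and rho < -1.0 / (block_size - 1):
        raise ValueError("rho too negative for an exchangeable block (not PD)")
    j = n_blocks * block_size
    if ids is None:
        ids = [f"rs{100000 + i}" for i in range(j)]
    mat = np.eye(j)
    for b in range(n_blocks):
        s = slice(b * block_size, (b + 1) * block_size)
        block = np.full((block_size, block_size), rho)
        np.fill_diagonal(block, 1.0)
        mat[s, s] = block
    return LDInfo(matrix=pd.DataFrame(mat, index=ids, columns=ids))


def _height_cad_like():
    """Regime-realistic preset: labels only, not claims about any cohort."""
    return TwoSampleSimConfig(
        n_snps=828,
        sigma_gx=0.0254,  # instruments jointly explain ~30% of exposure variance
        n_exposure=700_000,
        n_outcome=184_000,
        case_fraction=0.33,
        theta=-0.17,
        outcome_type="binary",
    )


PRESETS = {"height_cad_like": _height_cad_like}


def preset(name: str, **overrides) -> TwoSampleSimConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    cfg = PRESETS[name]()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg
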