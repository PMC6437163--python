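"""Summary-statistic Mendelian randomisation estimators.

All estimators consume a :class:`~mrpath.summary_io.HarmonizedSet` whose
variant effects are oriented to the exposure-increasing allele, and return
causal effects per 1 SD of the exposure.  For a binary outcome the effect is
a log odds ratio; :func:`to_odds_ratio` converts to the OR scale.

Implemented methods
-------------------
wald_ratio           per-variant ratio estimate with first- or second-order
                     (delta-method) standard errors
ivw                  inverse-variance-weighted pooling of Wald ratios; fixed,
                     multiplicative random-effects, or second-order-weight modes
egger_regression     weighted regression with a free intercept; the intercept
                     tests directional pleiotropy, the slope is the causal
                     effect under the InSIDE assumption
weighted_median      consistent when >50% of weight comes from valid instruments
mode_based_estimate  mode of the smoothed Wald-ratio density; consistent when
                     the largest homogeneous instrument cluster is valid
ivw_correlated       generalised-least-squares IVW accounting for LD between
                     instruments
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .summary_io import HarmonizedSet, LDInfo

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "EggerEstimate",
    "wald_ratio",
    "wald_ratios",
    "f_statistic",
    "ivw",
    "egger_regression",
    "weighted_median",
    "mode_based_estimate",
    "ivw_correlated",
    "to_odds_ratio",
]

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    pass


class DegenerateInstrumentError(ValueError):
    pass


@dataclass
class RatioEstimate:
    variant_id: object
    theta: float
    se_theta: float
    weight_order: str = "first"

    def __post_init__(self):
        if self.se_theta <= 0:
            raise ValueError("se_theta must be positive")


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and provenance."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    heterogeneity: object | None = None
    outcome_type: str = "binary"
    sd_exposure_label: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class EggerEstimate:
    """MR-Egger fit: causal slope plus the directional-pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_ci: tuple
    intercept_pvalue: float
    i2_gx: float | None = None


def wald_ratio(beta_gx, se_gx, beta_gy, se_gy, weight_order="first",
               variant_id=None) -> RatioEstimate:
    """Per-variant causal estimate theta = beta_gy / beta_gx.

    First-order SE is se_gy/|beta_gx| (NOME assumption: the exposure effect is
    treated as known); second-order adds the next Taylor term,
    sqrt(se_gy^2/beta_gx^2 + beta_gy^2 se_gx^2 / beta_gx^4).
    """
    if beta_gx == 0:
        raise DegenerateInstrumentError("beta_gx = 0: Wald ratio undefined")
    theta = beta_gy / beta_gx
    if weight_order == "first":
        se = se_gy / abs(beta_gx)
    elif weight_order == "second":
        se = np.sqrt(se_gy**2 / beta_gx**2 + beta_gy**2 * se_gx**2 / beta_gx**4)
    else:
        raise ValueError(f"unknown weight_order {weight_order!r}")
    return RatioEstimate(variant_id, float(theta), float(se), weight_order)


def wald_ratios(h: HarmonizedSet, weight_order="first"):
    """Vectorised Wald ratios: returns (theta, se_theta) arrays."""
    if np.any(h.beta_gx == 0):
        raise DegenerateInstrumentError("beta_gx = 0 for some instrument")
    theta = h.beta_gy / h.beta_gx
    if weight_order == "first":
        se = h.se_gy / np.abs(h.beta_gx)
    elif weight_order == "second":
        se = np.sqrt(h.se_gy**2 / h.beta_gx**2
                     + h.beta_gy**2 * h.se_gx**2 / h.beta_gx**4)
    else:
        raise ValueError(f"unknown weight_order {weight_order!r}")
    return theta, se


def f_statistic(beta_gx, se_gx):
    """Instrument-strength F statistic, (beta/se)^2."""
    beta_gx = np.asarray(beta_gx, dtype=float)
    se_gx = np.asarray(se_gx, dtype=float)
    if np.any(se_gx <= 0):
        raise ValueError("se_gx must be positive")
    out = (beta_gx / se_gx) ** 2
    return float(out) if out.ndim == 0 else out


def _normal_estimate(method, beta, se, n_snps, outcome_type, **diag) -> MREstimate:
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    return MREstimate(method, float(beta), float(se),
                      float(beta - Z95 * se), float(beta + Z95 * se),
                      float(p), int(n_snps), outcome_type=outcome_type,
                      diagnostics=diag)


def ivw(h: HarmonizedSet, mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate: the fixed-effect meta-analysis of
    the per-variant Wald ratios (equivalently, origin-constrained WLS of
    beta_gy on beta_gx with weights 1/se_gy^2).

    ``mode="random"`` inflates the SE multiplicatively by
    max(1, sqrt(Q/(J-1))); ``mode="second_order"`` repeats the fixed analysis
    with second-order Wald-ratio weights.
    """
    if h.n_snps < 2:
        raise InsufficientInstrumentsError("IVW needs >= 2 instruments")
    if mode not in ("fixed", "random", "second_order"):
        raise ValueError(f"unknown ivw mode {mode!r}")
    order = "second" if mode == "second_order" else "first"
    theta, se_t = wald_ratios(h, order)
    w = 1.0 / se_t**2
    beta = np.sum(w * theta) / np.sum(w)
    se = np.sqrt(1.0 / np.sum(w))
    q = float(np.sum(w * (theta - beta) ** 2))
    scale = 1.0
    if mode == "random":
        scale = max(1.0, np.sqrt(q / (h.n_snps - 1)))
    est = _normal_estimate(f"ivw_{mode}" if mode != "second_order" else "ivw_2nd",
                           beta, se * scale, h.n_snps, h.outcome_type,
                           overdispersion_scale=scale)
    from .heterogeneity import cochran_q  # local import avoids a cycle
    est.heterogeneity = cochran_q(h, est, weight_order=order)
    return est


def egger_regression(h: HarmonizedSet, weight_order: str = "first",
                     constrain_intercept: bool = False) -> EggerEstimate:
    """MR-Egger: weighted regression beta_gy = alpha + theta * beta_gx.

    Weights are 1/se_gy^2 (first order) or the second-order Wald-ratio weights
    mapped back to the outcome scale, 1/(se_theta2^2 * beta_gx^2).  SEs use a
    multiplicative residual scale floored at 1 and t(J-2) inference, which
    matters at small instrument counts.  ``constrain_intercept`` is an
    internal check mode: with alpha fixed at 0 the slope equals IVW fixed.
    """
    j = h.n_snps
    if j < 3 and not constrain_intercept:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    if np.any(h.beta_gx < 0):
        raise ValueError("Egger requires orientation to the exposure-increasing allele")
    if not constrain_intercept and np.ptp(h.beta_gx) == 0:
        raise ValueError("constant exposure effects: Egger slope and intercept "
                         "are not separable")
    if weight_order == "first":
        w = 1.0 / h.se_gy**2
    elif weight_order == "second":
        _, se_t2 = wald_ratios(h, "second")
        w = 1.0 / (se_t2**2 * h.beta_gx**2)
    else:
        raise ValueError(f"unknown weight_order {weight_order!r}")

    sw = np.sqrt(w)
    if constrain_intercept:
        X = (sw * h.beta_gx)[:, None]
        dof = j - 1
    else:
        X = np.column_stack([sw, sw * h.beta_gx])
        dof = j - 2
    y = sw * h.beta_gy
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    scale = max(1.0, np.sqrt(rss / dof)) if dof > 0 else 1.0
    xtx_inv = np.linalg.inv(X.T @ X)
    ses = scale * np.sqrt(np.diag(xtx_inv))

    if constrain_intercept:
        slope, slope_se = coef[0], ses[0]
        alpha, alpha_se = 0.0, np.nan
    else:
        alpha, slope = coef
        alpha_se, slope_se = ses
    tq = stats.t.ppf(0.975, dof) if dof > 0 else np.nan
    slope_p = 2 * stats.t.sf(abs(slope / slope_se), dof) if dof > 0 else np.nan
    slope_est = MREstimate(
        "egger_slope", float(slope), float(slope_se),
        float(slope - tq * slope_se), float(slope + tq * slope_se),
        float(slope_p), j, outcome_type=h.outcome_type,
        diagnostics={"residual_scale": scale, "weight_order": weight_order},
    )
    from .heterogeneity import cochran_q, i2_gx
    if j >= 3 and not constrain_intercept:
        slope_est.heterogeneity = cochran_q(h, slope_est, weight_order=weight_order)
    if constrain_intercept:
        return EggerEstimate(slope_est, 0.0, np.nan, (np.nan, np.nan), np.nan)
    alpha_p = 2 * stats.t.sf(abs(alpha / alpha_se), dof)
    return EggerEstimate(
        slope_est, float(alpha), float(alpha_se),
        (float(alpha - tq * alpha_se), float(alpha + tq * alpha_se)),
        float(alpha_p), i2_gx=i2_gx(h),
    )


def _weighted_median_point(theta, w):
    order = np.argsort(theta)
    theta = theta[order]
    w = w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, theta))


def _boot_draws(h: HarmonizedSet, n_boot: int, rng):
    bx = h.beta_gx + rng.standard_normal((n_boot, h.n_snps)) * h.se_gx
    by = h.beta_gy + rng.standard_normal((n_boot, h.n_snps)) * h.se_gy
    return bx, by


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed=None) -> MREstimate:
    """Weighted median of the Wald ratios, inverse-variance weighted.

    The point estimate interpolates the ordered ratios at standardized
    cumulative weight 0.5; the SE is the SD of the estimate over ``n_boot``
    parametric bootstrap draws of (beta_gx, beta_gy) from their sampling
    distributions.
    """
    if h.n_snps < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    theta, se_t = wald_ratios(h, "first")
    w = 1.0 / se_t**2
    beta = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bx, by = _boot_draws(h, n_boot, rng)
    bt = by / bx
    bw = (np.abs(bx) / h.se_gy) ** 2  # 1/se(theta)^2 per draw
    order = np.argsort(bt, axis=1)
    bt_s = np.take_along_axis(bt, order, axis=1)
    bw_s = np.take_along_axis(bw, order, axis=1)
    cum = np.cumsum(bw_s, axis=1) - 0.5 * bw_s
    s = cum / np.sum(bw_s, axis=1, keepdims=True)
    boots = np.array([np.interp(0.5, s[i], bt_s[i]) for i in range(n_boot)])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        se = np.sqrt(1.0 / np.sum(w))  # degenerate: identical ratios
    return _normal_estimate("weighted_median", beta, se, h.n_snps,
                            h.outcome_type, n_boot=n_boot, seed=seed)


def _mbe_bandwidth(theta, phi):
    """phi times the modified-Silverman MAD-based default scale."""
    j = len(theta)
    mad = stats.median_abs_deviation(theta, scale="normal")
    sd = np.std(theta, ddof=1)
    s = 0.9 * min(sd, mad) * j ** (-1 / 5)
    if s == 0:
        s = 0.9 * max(sd, mad, 1e-12) * j ** (-1 / 5)
    return phi * s


def _mode_span(theta, bandwidth):
    # robust span: the sample SD of ratio estimates is dominated by
    # low-precision instruments, so centre on the median with a MAD scale
    centre = np.median(theta)
    scale = max(stats.median_abs_deviation(theta, scale="normal"), bandwidth)
    return centre, 5.0 * scale


def _mode_point(theta, w, bandwidth, grid_size):
    centre, half = _mode_span(theta, bandwidth)
    lo, hi = centre - half, centre + half
    grid = np.linspace(lo, hi, grid_size)
    dens = np.zeros(grid_size)
    wn = w / np.sum(w)
    for t, wt in zip(theta, wn):
        dens += wt * np.exp(-0.5 * ((grid - t) / bandwidth) ** 2)
    k = int(np.argmax(dens))

    def negdens(b):
        return -np.sum(wn * np.exp(-0.5 * ((b - theta) / bandwidth) ** 2))

    a = grid[max(k - 1, 0)]
    c = grid[min(k + 1, grid_size - 1)]
    from scipy.optimize import minimize_scalar
    opt = minimize_scalar(negdens, bounds=(a, c), method="bounded",
                          options={"xatol": 1e-8})
    return float(opt.x)


def _mode_points_batch(thetas, ws, bandwidths, grid_size):
    """Grid-argmax modes for a batch of bootstrap draws (no refinement)."""
    n, j = thetas.shape
    mu = np.median(thetas, axis=1)
    mad = 1.4826 * np.median(np.abs(thetas - mu[:, None]), axis=1)
    span = 5 * np.maximum(mad, bandwidths)
    frac = np.linspace(-1.0, 1.0, grid_size)
    grids = mu[:, None] + span[:, None] * frac[None, :]
    wn = ws / ws.sum(axis=1, keepdims=True)
    best = np.zeros(n)
    chunk = max(1, int(2_000_000 // (n * j)) or 1)
    dens = np.empty((n, grid_size))
    for start in range(0, grid_size, chunk):
        g = grids[:, start:start + chunk]  # (n, c)
        d = g[:, :, None] - thetas[:, None, :]  # (n, c, j)
        d = np.exp(-0.5 * (d / bandwidths[:, None, None]) ** 2)
        dens[:, start:start + chunk] = np.einsum("ncj,nj->nc", d, wn)
    idx = np.argmax(dens, axis=1)
    best = grids[np.arange(n), idx]
    return best


def mode_based_estimate(h: HarmonizedSet, phi: float = 1.0, weighted: bool = True,
                        n_boot: int = 1000, seed=None,
                        grid_size: int = 512) -> MREstimate:
    """Mode-based estimate: the argmax of a normal-kernel-smoothed density of
    the Wald ratios (inverse-variance weighted when ``weighted``).

    Bandwidth is ``phi`` times a MAD-based default scale of the ratios; the
    point estimate is located on a ``grid_size`` grid spanning mean +- 5 SD and
    refined to 1e-8.  The SE is a seeded parametric bootstrap as in
    :func:`weighted_median`.
    """
    if h.n_snps < 3:
        raise InsufficientInstrumentsError("MBE needs >= 3 instruments")
    if seed is None:
        raise ValueError("seed is required for the bootstrap")
    theta, se_t = wald_ratios(h, "first")
    w = 1.0 / se_t**2 if weighted else np.ones_like(theta)
    bandwidth = _mbe_bandwidth(theta, phi)
    beta = _mode_point(theta, w, bandwidth, grid_size)

    # parametric bootstrap of the ratio estimates with fixed weights; the SE
    # is the scaled MAD of the draws, robust to bootstrap mode jumps
    rng = np.random.default_rng(seed)
    bt = theta + rng.standard_normal((n_boot, h.n_snps)) * se_t
    bw = np.broadcast_to(w, bt.shape)
    bhs = np.array([_mbe_bandwidth(bt[i], phi) for i in range(n_boot)])
    boots = _mode_points_batch(bt, bw, bhs, grid_size)
    se = float(stats.median_abs_deviation(boots, scale="normal"))
    if se == 0:
        se = np.sqrt(1.0 / np.sum(w))
    return _normal_estimate("mbe", beta, se, h.n_snps, h.outcome_type,
                            bandwidth=float(bandwidth), phi=phi,
                            weighted=weighted, n_boot=n_boot, seed=seed)


def ivw_correlated(h: HarmonizedSet, ld: LDInfo) -> MREstimate:
    """Generalised-least-squares IVW for correlated instruments.

    With Omega_ij = se_gy_i se_gy_j rho_ij, the estimate is
    (bx' Omega^-1 by) / (bx' Omega^-1 bx) with SE sqrt(1/(bx' Omega^-1 bx)).
    Reduces to IVW fixed when rho is the identity.
    """
    if h.n_snps < 2:
        raise InsufficientInstrumentsError("correlated IVW needs >= 2 instruments")
    rho = ld.correlation_matrix(h.variant_ids)
    omega = np.outer(h.se_gy, h.se_gy) * rho
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        omega = omega + 1e-8 * np.diag(np.diag(omega))
        try:
            chol = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError:
            cond = np.linalg.cond(omega)
            raise np.linalg.LinAlgError(
                f"LD-adjusted covariance not positive definite "
                f"(condition number {cond:.3g})")
    bx = np.linalg.solve(chol, h.beta_gx)
    by = np.linalg.solve(chol, h.beta_gy)
    denom = bx @ bx
    beta = (bx @ by) / denom
    se = np.sqrt(1.0 / denom)
    return _normal_estimate("ivw_correlated", beta, se, h.n_snps, h.outcome_type)


def to_odds_ratio(e: MREstimate, sd_exposure_label: str | None = None) -> MREstimate:
    """Annotate a binary-outcome estimate with its OR-scale view.

    The estimate itself stays on the log-OR scale (``beta``); the OR and its
    CI are exposed through ``odds_ratio`` / ``or_ci`` and the diagnostics.
    """
    if e.outcome_type != "binary":
        raise ValueError("odds-ratio view requires a binary outcome")
    out = replace(e, sd_exposure_label=sd_exposure_label)
    out.diagnostics = dict(e.diagnostics, OR=out.odds_ratio,
                           OR_ci=out.or_ci, sd_exposure=sd_exposure_label)
    return out
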