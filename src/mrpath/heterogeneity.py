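"""Heterogeneity and pleiotropy diagnostics, and instrument-exclusion filters.

Cochran's Q over the per-variant Wald ratios signals horizontal pleiotropy;
I2GX quantifies regression dilution of the MR-Egger slope under violation of
the no-measurement-error (NOME) assumption.  Two sensitivity filters mirror a
common analysis battery: exclusion of instruments by their individual Q
contribution (at the upper 5% / 1% / 0.19% chi-square(1) thresholds, L1-L3),
and exclusion of instruments nominally associated with candidate mediator
traits.  A simplified MR-PRESSO global/outlier test is included (its
distortion test is not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import HarmonizedSet, SummaryTable

__all__ = [
    "HeterogeneityStats",
    "OutlierReport",
    "Q_LEVELS",
    "cochran_q",
    "i2_gx",
    "q_contribution_filter",
    "mediator_exclusion_filter",
    "presso_global_test",
    "funnel_data",
]

#: upper-tail chi-square(1) probabilities for the per-instrument Q thresholds
Q_LEVELS = {"L1": 0.05, "L2": 0.01, "L3": 0.0019}


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class HeterogeneityStats:
    Q: float
    df: int
    pvalue: float
    i2: float
    per_variant_q: np.ndarray

    def __post_init__(self):
        assert abs(float(np.sum(self.per_variant_q)) - self.Q) <= 1e-9 * max(1.0, self.Q)


@dataclass
class OutlierReport:
    excluded: pd.DataFrame  # columns variant_id, reason
    estimates_before: dict
    estimates_after: dict
    retained_log: list = field(default_factory=list)

    @property
    def excluded_ids(self):
        return list(self.excluded["variant_id"])


def _ratio_weights(h: HarmonizedSet, weight_order="first"):
    from .estimators import wald_ratios
    theta, se_t = wald_ratios(h, weight_order)
    return theta, 1.0 / se_t**2


def cochran_q(h: HarmonizedSet, reference, weight_order="first") -> HeterogeneityStats:
    """Cochran's Q of the Wald ratios about a reference causal estimate.

    ``reference`` is an MREstimate (or bare float); the Egger slope uses
    J-2 residual degrees of freedom, every other reference J-1.
    """
    if h.n_snps < 2:
        raise InsufficientInstrumentsError("Q needs >= 2 instruments")
    beta_ref = getattr(reference, "beta", reference)
    method = getattr(reference, "method", "")
    theta, w = _ratio_weights(h, weight_order)
    per = w * (theta - beta_ref) ** 2
    q = float(np.sum(per))
    df = h.n_snps - (2 if method == "egger_slope" else 1)
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityStats(q, df, p, i2, per)


def i2_gx(h: HarmonizedSet) -> float:
    """I2GX: heterogeneity of the variant-exposure effects relative to their
    standard errors; values near 1 mean NOME violation barely dilutes the
    Egger slope."""
    if h.n_snps < 2:
        raise InsufficientInstrumentsError("I2GX needs >= 2 instruments")
    v = 1.0 / h.se_gx**2
    bbar = np.sum(v * h.beta_gx) / np.sum(v)
    q_gx = float(np.sum(v * (h.beta_gx - bbar) ** 2))
    if q_gx == 0:
        return 0.0
    return max(0.0, (q_gx - (h.n_snps - 1)) / q_gx)


def _default_estimators():
    from .estimators import ivw
    return {"ivw_fixed": lambda h: ivw(h, "fixed"),
            "ivw_random": lambda h: ivw(h, "random")}


def _apply_estimators(h, estimators):
    return {name: fn(h) for name, fn in estimators.items()}


def q_contribution_filter(h: HarmonizedSet, level: str = "L1",
                          estimators=None) -> OutlierReport:
    """Exclude instruments whose individual Q contribution (against the IVW
    fixed estimate) exceeds the upper-tail chi-square(1) quantile for
    ``level`` in {L1: 5%, L2: 1%, L3: 0.19%}; re-estimate on the remainder."""
    if h.n_snps < 3:
        raise InsufficientInstrumentsError("Q filter needs >= 3 instruments")
    if level not in Q_LEVELS:
        raise ValueError(f"level must be one of {sorted(Q_LEVELS)}")
    from .estimators import ivw
    estimators = estimators or _default_estimators()
    ref = ivw(h, "fixed")
    het = cochran_q(h, ref)
    threshold = stats.chi2.isf(Q_LEVELS[level], 1)
    bad = het.per_variant_q > threshold
    if bad.all():
        raise ValueError("Q filter excluded every instrument")
    excluded = pd.DataFrame({
        "variant_id": h.variant_ids[bad],
        "reason": [f"q_level:{level}"] * int(bad.sum()),
    })
    before = _apply_estimators(h, estimators)
    after = _apply_estimators(h.subset(~bad), estimators)
    return OutlierReport(excluded, before, after)


def mediator_exclusion_filter(h: HarmonizedSet, mediator_tables,
                              p_threshold: float = 0.05,
                              estimators=None) -> OutlierReport:
    """Exclude instruments nominally associated (p < threshold, strict) with
    any supplied mediator trait; instruments missing from a mediator table are
    retained and logged."""
    estimators = estimators or _default_estimators()
    reasons = {}
    retained_log = []
    for table in mediator_tables:
        pmap = dict(zip(table.data["variant_id"], table.data["pvalue"]))
        for vid in h.variant_ids:
            if vid not in pmap:
                retained_log.append((vid, f"absent from {table.trait_label}"))
            elif pmap[vid] < p_threshold:
                reasons.setdefault(vid, []).append(table.trait_label)
    bad = np.array([v in reasons for v in h.variant_ids])
    excluded = pd.DataFrame({
        "variant_id": [v for v in h.variant_ids if v in reasons],
        "reason": [",".join(reasons[v]) for v in h.variant_ids if v in reasons],
    })
    before = _apply_estimators(h, estimators)
    if bad.all():
        raise ValueError("mediator filter excluded every instrument")
    after = _apply_estimators(h.subset(~bad), estimators)
    return OutlierReport(excluded, before, after, retained_log=retained_log)


def presso_global_test(h: HarmonizedSet, n_sim: int = 1000, seed=None):
    """Simplified MR-PRESSO: residual-sum-of-squares global pleiotropy test
    with leave-one-out IVW expectations and per-variant outlier p-values
    (Bonferroni-adjusted).  The distortion test is intentionally omitted.

    Returns ``(rss_observed, global_p, per_variant_outlier_p)``.
    """
    if h.n_snps < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)
    j = h.n_snps
    w = 1.0 / h.se_gy**2
    # leave-one-out IVW slopes via sufficient statistics
    sxy = w * h.beta_gx * h.beta_gy
    sxx = w * h.beta_gx**2
    theta_loo = (np.sum(sxy) - sxy) / (np.sum(sxx) - sxx)
    resid = h.beta_gy - theta_loo * h.beta_gx
    contrib_obs = w * resid**2
    rss_obs = float(np.sum(contrib_obs))

    sim_by = theta_loo[None, :] * h.beta_gx[None, :] \
        + rng.standard_normal((n_sim, j)) * h.se_gy[None, :]
    sim_resid = sim_by - theta_loo[None, :] * h.beta_gx[None, :]
    sim_contrib = w[None, :] * sim_resid**2
    sim_rss = np.sum(sim_contrib, axis=1)
    global_p = float((np.sum(sim_rss >= rss_obs) + 1) / (n_sim + 1))
    per_raw = (np.sum(sim_contrib >= contrib_obs[None, :], axis=0) + 1) / (n_sim + 1)
    per_adj = np.minimum(1.0, per_raw * j)
    return rss_obs, global_p, per_adj


def funnel_data(h: HarmonizedSet, estimates=None) -> pd.DataFrame:
    """Per-variant Wald ratio vs precision, for funnel plots.

    ``estimates`` (name -> MREstimate) are attached as ``df.attrs["reference_
    estimates"]`` and written as a sidecar metadata block by
    :func:`write_funnel`.
    """
    if h.n_snps < 1:
        raise InsufficientInstrumentsError("funnel needs >= 1 instrument")
    from .estimators import wald_ratios
    theta, se_t = wald_ratios(h, "first")
    df = pd.DataFrame({
        "variant_id": h.variant_ids,
        "theta": theta,
        "precision": 1.0 / se_t,
    })
    df.attrs["reference_estimates"] = {
        name: float(e.beta) for name, e in (estimates or {}).items()
    }
    return df


def write_funnel(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for name, beta in df.attrs.get("reference_estimates", {}).items():
            fh.write(f"# reference {name} {format(beta, '.12g')}\n")
        df.to_csv(fh, sep="\t", index=False)
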