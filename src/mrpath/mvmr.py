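"""Multivariable Mendelian randomisation and mediation decomposition.

MVMR regresses the variant-outcome effects jointly on the variant-exposure
and variant-mediator effects (no intercept, weights 1/se_gy^2); the exposure
coefficient is the *direct* effect of the exposure conditional on the
mediators.  Mediation is summarised as the attenuation of the total effect
after conditioning — the indirect effect itself is deliberately not returned,
since with a binary outcome the log-odds scale is non-collapsible and
total - direct does not estimate a well-defined indirect path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .estimators import MREstimate, Z95, InsufficientInstrumentsError
from .summary_io import HarmonizedSet

__all__ = [
    "MVMREstimate",
    "MediationSummary",
    "mvmr_ivw",
    "mediation_decomposition",
    "conditional_f_diagnostic",
]


@dataclass
class MVMREstimate:
    """Direct effect of the exposure conditional on mediator instruments."""

    exposure_beta: float
    exposure_se: float
    ci_low: float
    ci_high: float
    pvalue: float
    mediator_betas: dict  # label -> (beta, se)
    n_snps: int
    conditioning_traits: tuple
    instrument_hash: str = ""
    outcome_type: str = "binary"
    diagnostics: dict = field(default_factory=dict)

    # results-table compatibility
    @property
    def method(self):
        return "mvmr_ivw[" + ",".join(self.conditioning_traits) + "]"

    @property
    def beta(self):
        return self.exposure_beta

    @property
    def se(self):
        return self.exposure_se

    heterogeneity = None


@dataclass
class MediationSummary:
    total: MREstimate
    direct: MVMREstimate
    attenuation_pct: float
    or_shift: tuple  # (OR_total, OR_direct); NaN pair for quantitative outcomes


def mvmr_ivw(h: HarmonizedSet, mediators=None) -> MVMREstimate:
    """Multivariable IVW: weighted no-intercept regression of beta_gy on
    [beta_gx, beta_gm...], weights 1/se_gy^2; SEs carry a multiplicative
    overdispersion scale floored at 1.

    ``mediators`` selects a subset of the harmonized mediator columns by
    label (default: all).  With zero mediator columns this reduces exactly
    to univariable fixed-effect IVW.
    """
    labels = tuple(mediators if mediators is not None else h.mediators.keys())
    for lab in labels:
        if lab not in h.mediators:
            raise ValueError(f"mediator {lab!r} not present in harmonized set")
    k = 1 + len(labels)
    if h.n_snps < k + 1:
        raise InsufficientInstrumentsError(
            f"MVMR with {k} traits needs >= {k + 1} instruments")
    if not np.any(h.beta_gx != 0):
        raise ValueError("exposure effects are all zero")
    # an all-zero mediator column carries no information in the no-intercept
    # design: its coefficient is pinned at 0 and it is dropped from the fit
    active = [lab for lab in labels if np.any(h.mediators[lab][0] != 0)]
    X = np.column_stack([h.beta_gx] + [h.mediators[lab][0] for lab in active])
    ka = X.shape[1]
    w = 1.0 / h.se_gy**2
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = h.beta_gy * sw
    rank = np.linalg.matrix_rank(Xw)
    if rank < ka:
        corr = np.corrcoef(X, rowvar=False)
        names = ["exposure", *active]
        pairs = [(names[i], names[j])
                 for i in range(ka) for j in range(i + 1, ka)
                 if abs(corr[i, j]) > 0.999]
        raise np.linalg.LinAlgError(
            f"rank-deficient MVMR design; collinear trait pairs: {pairs}")
    coef, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ coef
    dof = h.n_snps - ka
    scale = max(1.0, np.sqrt(float(resid @ resid) / dof)) if dof > 0 else 1.0
    cov = np.linalg.inv(Xw.T @ Xw) * scale**2
    ses = np.sqrt(np.diag(cov))
    b, s = float(coef[0]), float(ses[0])
    p = 2 * stats.norm.sf(abs(b / s))
    med_out = {}
    for lab in labels:
        if lab in active:
            i = active.index(lab)
            med_out[lab] = (float(coef[i + 1]), float(ses[i + 1]))
        else:
            med_out[lab] = (0.0, float("nan"))
    return MVMREstimate(
        b, s, b - Z95 * s, b + Z95 * s, float(p),
        med_out,
        h.n_snps, labels, instrument_hash=h.instrument_hash(),
        outcome_type=h.outcome_type,
        diagnostics={"overdispersion_scale": scale},
    )


def mediation_decomposition(total: MREstimate, direct: MVMREstimate,
                            instrument_hash: str | None = None,
                            tolerance: float = 1e-8) -> MediationSummary:
    """Attenuation of the total effect after conditioning on mediators.

    attenuation_pct = 100 * (1 - beta_direct / beta_total) on the log-OR
    scale; the OR-scale pair (exp(total), exp(direct)) is reported alongside
    for binary outcomes.  Both estimates must come from the same harmonized
    instrument set (verified by hash when available).
    """
    h_total = total.diagnostics.get("instrument_hash") if total.diagnostics else None
    h_total = h_total or instrument_hash
    if h_total is not None and direct.instrument_hash \
            and h_total != direct.instrument_hash:
        raise ValueError("total and direct effects come from different instrument sets")
    if abs(total.beta) <= tolerance:
        att = float("nan")
    else:
        att = 100.0 * (1.0 - direct.exposure_beta / total.beta)
    if total.outcome_type == "binary":
        or_shift = (float(np.exp(total.beta)), float(np.exp(direct.exposure_beta)))
    else:
        or_shift = (float("nan"), float("nan"))
    return MediationSummary(total, direct, att, or_shift)


def conditional_f_diagnostic(h: HarmonizedSet) -> dict:
    """Conditional instrument strength per trait in the MVMR design.

    For each trait, its instrument effects are residualised (weighted by
    1/se_gy^2) on all the others'; the mean weighted F of the residual
    association is returned.  Reported as a weak-instrument diagnostic, never
    used as a gate.  With a single trait this is just the mean marginal F.
    """
    labels = ("exposure", *h.mediators.keys())
    cols = {"exposure": (h.beta_gx, h.se_gx)}
    cols.update(h.mediators)
    w = 1.0 / h.se_gy**2
    sw = np.sqrt(w)
    out = {}
    for lab in labels:
        b, se = cols[lab]
        others = [cols[o][0] for o in labels if o != lab]
        if others:
            Xw = np.column_stack(others) * sw[:, None]
            yw = b * sw
            coef, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            resid_w = yw - Xw @ coef
            resid = resid_w / sw
        else:
            resid = b
        out[lab] = float(np.mean((resid / se) ** 2))
    return out
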