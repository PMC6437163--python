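"""Orchestration of the full two-sample analysis flow.

``run_two_sample_pipeline`` executes harmonise -> LD-prune -> estimator
battery -> heterogeneity -> sensitivity filters -> mediation on any compliant
inputs, producing a :class:`RunReport` whose body is byte-identical across
reruns with the same config and seed (no timestamps in the report body).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import estimators as est
from . import heterogeneity as het
from .mvmr import mvmr_ivw, mediation_decomposition, conditional_f_diagnostic
from .summary_io import (HarmonizedSet, LDInfo, SummaryTable, harmonize,
                         ld_prune, write_results)
from .power import mr_power

__all__ = ["AnalysisConfig", "RunReport", "run_two_sample_pipeline",
           "run_bidirectional", "run_benchmark", "mr_power"]

DEFAULT_METHODS = ("ivw_fixed", "ivw_random", "ivw_2nd", "egger_slope",
                   "weighted_median", "mbe")


@dataclass
class AnalysisConfig:
    methods: tuple = DEFAULT_METHODS
    r2_threshold: float = 0.05
    palindromic_policy: str = "infer_by_eaf"
    q_levels: tuple = ()
    mediator_p_threshold: float = 0.05
    run_mediator_exclusion: bool = False
    run_mvmr: bool = True
    phi: float = 1.0
    n_boot: int = 1000
    seed: int = 0
    direction: str = "forward"
    allow_forward_instruments: bool = False
    sd_exposure_label: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    estimates: pd.DataFrame
    estimate_objects: dict
    harmonized: HarmonizedSet
    funnel: pd.DataFrame
    outlier_reports: dict
    mediation: dict
    stage_log: list
    manifest: dict
    direction: str = "forward"

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(self.estimate_objects.values(), out / "estimates.tsv")
        het.write_funnel(self.funnel, out / "funnel.tsv")
        rows = []
        for name, rep in self.outlier_reports.items():
            for _, r in rep.excluded.iterrows():
                rows.append({"filter": name, "variant_id": r["variant_id"],
                             "reason": r["reason"]})
        pd.DataFrame(rows, columns=["filter", "variant_id", "reason"]).to_csv(
            out / "exclusions.tsv", sep="\t", index=False)
        with open(out / "stage_log.txt", "w") as fh:
            fh.write("\n".join(self.stage_log) + "\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _estimate_row(e):
    h = getattr(e, "heterogeneity", None)
    return {
        "method": e.method, "n_snps": e.n_snps, "beta": e.beta, "se": e.se,
        "ci_low": getattr(e, "ci_low", np.nan),
        "ci_high": getattr(e, "ci_high", np.nan),
        "p": getattr(e, "pvalue", np.nan),
        "Q": h.Q if h else np.nan, "Q_p": h.pvalue if h else np.nan,
        "I2": h.i2 if h else np.nan,
    }


def _run_methods(h: HarmonizedSet, cfg: AnalysisConfig, seed_offset=0):
    out = {}
    seed = cfg.seed + seed_offset
    for m in cfg.methods:
        if m == "ivw_fixed":
            out[m] = est.ivw(h, "fixed")
        elif m == "ivw_random":
            out[m] = est.ivw(h, "random")
        elif m == "ivw_2nd":
            out[m] = est.ivw(h, "second_order")
        elif m == "egger_slope":
            egger = est.egger_regression(h)
            e = egger.slope
            e.diagnostics.update(intercept=egger.intercept,
                                 intercept_se=egger.intercept_se,
                                 intercept_ci=egger.intercept_ci,
                                 intercept_p=egger.intercept_pvalue,
                                 i2_gx=egger.i2_gx)
            out[m] = e
        elif m == "weighted_median":
            out[m] = est.weighted_median(h, n_boot=cfg.n_boot, seed=seed + 1)
        elif m == "mbe":
            out[m] = est.mode_based_estimate(h, phi=cfg.phi, n_boot=cfg.n_boot,
                                             seed=seed + 2)
        elif m == "wald":
            # single-instrument Wald only meaningful for J = 1 score-style input
            r = est.wald_ratio(h.beta_gx[0], h.se_gx[0], h.beta_gy[0],
                               h.se_gy[0], variant_id=h.variant_ids[0])
            out[m] = est.MREstimate("wald", r.theta, r.se_theta,
                                    r.theta - est.Z95 * r.se_theta,
                                    r.theta + est.Z95 * r.se_theta,
                                    float(2 * est.stats.norm.sf(abs(r.theta / r.se_theta))),
                                    1, outcome_type=h.outcome_type)
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def run_two_sample_pipeline(exposure: SummaryTable, outcome: SummaryTable,
                            mediators=None, ld: LDInfo | None = None,
                            ld_for_estimation: LDInfo | None = None,
                            cfg: AnalysisConfig | None = None) -> RunReport:
    """Execute the full summary-statistic analysis battery.

    ``ld`` is used for instrument pruning; ``ld_for_estimation`` additionally
    switches on the correlated-instrument IVW.  Mediator tables feed both the
    nominal-association exclusion filter and multivariable MR.
    """
    cfg = cfg or AnalysisConfig()
    mediators = list(mediators or [])
    log = []

    pruned = ld_prune(exposure, ld, cfg.r2_threshold)
    log.append(f"ld_prune: {len(exposure)} -> {len(pruned)} instruments "
               f"(r2 <= {cfg.r2_threshold})")
    h = harmonize(pruned, outcome, mediators,
                  palindromic_policy=cfg.palindromic_policy)
    dropped = (h.orientation_log["action"] == "dropped").sum()
    log.append(f"harmonize: {len(pruned)} -> {h.n_snps} instruments "
               f"({dropped} dropped)")

    ests = _run_methods(h, cfg)
    if ld_for_estimation is not None:
        ests["ivw_correlated"] = est.ivw_correlated(h, ld_for_estimation)
    log.append(f"estimators: {', '.join(ests)} on {h.n_snps} instruments")

    funnel = het.funnel_data(h, ests)
    outliers = {}
    for level in cfg.q_levels:
        rep = het.q_contribution_filter(h, level)
        outliers[f"q_{level}"] = rep
        log.append(f"q_contribution_filter {level}: excluded "
                   f"{len(rep.excluded)} of {h.n_snps}")
    if cfg.run_mediator_exclusion and mediators:
        rep = het.mediator_exclusion_filter(h, mediators,
                                            cfg.mediator_p_threshold)
        outliers["mediator_exclusion"] = rep
        log.append(f"mediator_exclusion_filter: excluded "
                   f"{len(rep.excluded)} of {h.n_snps} "
                   f"(p < {cfg.mediator_p_threshold})")

    mediation = {}
    if cfg.run_mvmr and h.mediators:
        total = ests.get("ivw_fixed") or est.ivw(h, "fixed")
        total.diagnostics["instrument_hash"] = h.instrument_hash()
        for label in h.mediators:
            direct = mvmr_ivw(h, mediators=[label])
            mediation[label] = mediation_decomposition(total, direct)
            log.append(f"mvmr[{label}]: direct beta {direct.exposure_beta:.4f} "
                       f"(attenuation {mediation[label].attenuation_pct:.1f}%)")
        mediation["conditional_F"] = conditional_f_diagnostic(h)

    rows = [_estimate_row(e) for e in ests.values()]
    for name, rep in outliers.items():
        for ename, e in rep.estimates_after.items():
            row = _estimate_row(e)
            row["method"] = f"{ename}|{name}"
            rows.append(row)
    for label, summ in mediation.items():
        if label == "conditional_F":
            continue
        row = _estimate_row(summ.direct)
        rows.append(row)
    table = pd.DataFrame(rows)

    manifest = {
        "config": asdict(cfg), "config_hash": cfg.config_hash(),
        "seed": cfg.seed, "direction": cfg.direction,
        "exposure": exposure.trait_label, "outcome": outcome.trait_label,
        "n_instruments": int(h.n_snps),
        "package": "mrpath", "version": _version(),
    }
    return RunReport(table, ests, h, funnel, outliers, mediation, log,
                     manifest, direction=cfg.direction)


def run_bidirectional(reverse_exposure: SummaryTable, reverse_outcome: SummaryTable,
                      forward_instrument_ids=None, ld: LDInfo | None = None,
                      cfg: AnalysisConfig | None = None) -> RunReport:
    """Reverse-direction analysis with the machinery of the forward run.

    ``reverse_exposure`` must carry its *own* genome-wide-significant, pruned
    instrument set; supplying the forward exposure's instruments is a common
    MR mistake and is rejected unless ``cfg.allow_forward_instruments``.
    """
    cfg = cfg or AnalysisConfig()
    if forward_instrument_ids is not None and not cfg.allow_forward_instruments:
        fwd = set(forward_instrument_ids)
        rev = set(reverse_exposure.data["variant_id"])
        frac = len(fwd & rev) / max(1, len(rev))
        if frac > 0.5:
            raise ValueError(
                "reverse exposure reuses the forward instrument set; supply "
                "instruments selected for the reverse exposure or set "
                "allow_forward_instruments=True")
    import dataclasses
    cfg = dataclasses.replace(cfg, direction="reverse")
    report = run_two_sample_pipeline(reverse_exposure, reverse_outcome,
                                     ld=ld, cfg=cfg)
    return report


def run_benchmark(scenarios: dict, replicates: int, seed: int,
                  methods=("ivw_fixed", "egger_slope", "weighted_median", "mbe"),
                  n_boot: int = 200, alpha: float = 0.05) -> pd.DataFrame:
    """Monte-Carlo estimator comparison over named two-sample scenarios.

    Returns a long-format table with bias, empirical SE, RMSE, 95% CI
    coverage and rejection rate per (scenario, estimator), plus Monte-Carlo
    SEs, reproducible from (scenarios, replicates, seed).
    """
    from .simulate import simulate_two_sample
    import dataclasses
    if replicates < 100:
        raise ValueError("replicates must be >= 100")
    rows = []
    for si, (name, base_cfg) in enumerate(sorted(scenarios.items())):
        res = {m: {"beta": [], "cover": [], "reject": []} for m in methods}
        theta = base_cfg.theta
        for r in range(replicates):
            cfg = dataclasses.replace(base_cfg, seed=seed + 7919 * si + r)
            sim = simulate_two_sample(cfg)
            exposure, outcome = sim[0], sim[1]
            h = harmonize(exposure, outcome)
            run_cfg = AnalysisConfig(methods=tuple(methods), n_boot=n_boot,
                                     seed=seed + 104729 * si + r)
            ests = _run_methods(h, run_cfg)
            for m, e in ests.items():
                res[m]["beta"].append(e.beta)
                res[m]["cover"].append(e.ci_low <= theta <= e.ci_high)
                res[m]["reject"].append(e.pvalue < alpha)
        for m in methods:
            b = np.array(res[m]["beta"])
            cov = np.mean(res[m]["cover"])
            rej = np.mean(res[m]["reject"])
            rows.append({
                "scenario": name, "estimator": m, "true_theta": theta,
                "replicates": replicates,
                "bias": float(np.mean(b) - theta),
                "bias_mc_se": float(np.std(b, ddof=1) / np.sqrt(replicates)),
                "empirical_se": float(np.std(b, ddof=1)),
                "rmse": float(np.sqrt(np.mean((b - theta) ** 2))),
                "coverage": float(cov),
                "coverage_mc_se": float(np.sqrt(cov * (1 - cov) / replicates)),
                "rejection_rate": float(rej),
            })
    return pd.DataFrame(rows)


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("mrpath")
    except Exception:
        return "unknown"
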