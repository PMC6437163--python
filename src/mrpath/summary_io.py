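"""Reading, validation, harmonisation and LD-pruning of GWAS summary statistics.

The canonical wire format is delimited text (tab or comma, sniffed) with a
header row and columns ``SNP, EA, OA, EAF, BETA, SE, P, N``.  Consortium
dialects (GIANT- or CARDIoGRAM-style headers) are handled through a
user-supplied ``column_map`` rather than hard-coded synonyms.

Harmonisation aligns every table to the exposure-increasing allele, which is
the orientation all downstream estimators assume (``beta_gx >= 0``).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VALID_ALLELES",
    "CANONICAL_COLUMNS",
    "SummaryTable",
    "HarmonizedSet",
    "LDInfo",
    "read_summary_stats",
    "harmonize",
    "ld_prune",
    "write_results",
    "read_results",
]

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})

#: canonical header -> internal field name
CANONICAL_COLUMNS = {
    "SNP": "variant_id",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pvalue",
    "N": "n",
}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue")


class SummaryStatsError(ValueError):
    """Raised for malformed or empty summary-statistic inputs."""


@dataclass
class SummaryTable:
    """Per-variant association records for a single trait.

    ``data`` holds columns ``variant_id, effect_allele, other_allele, eaf,
    beta, se, pvalue, n``; betas are per-allele effects in SD units for
    quantitative traits and log-odds-ratios for binary traits.
    """

    trait_label: str
    data: pd.DataFrame
    trait_type: str = "quantitative"
    n_dropped: int = 0
    drop_log: list = field(default_factory=list)

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.data["variant_id"].duplicated().any():
            dups = self.data["variant_id"][self.data["variant_id"].duplicated()]
            raise SummaryStatsError(
                f"duplicate variant_id in {self.trait_label!r}: {sorted(set(dups))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, variant_ids) -> "SummaryTable":
        keep = self.data[self.data["variant_id"].isin(set(variant_ids))]
        return SummaryTable(self.trait_label, keep.reset_index(drop=True), self.trait_type)


@dataclass
class HarmonizedSet:
    """Variant-matched effect estimates oriented to the exposure-increasing allele.

    Invariant: ``beta_gx >= 0`` for every instrument, with outcome (and any
    mediator) effects flipped in tandem when a variant is re-oriented.
    """

    variant_ids: np.ndarray
    beta_gx: np.ndarray
    se_gx: np.ndarray
    beta_gy: np.ndarray
    se_gy: np.ndarray
    mediators: dict = field(default_factory=dict)  # label -> (beta_gm, se_gm)
    orientation_log: pd.DataFrame | None = None
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    outcome_type: str = "binary"

    def __post_init__(self):
        n = len(self.variant_ids)
        for name in ("beta_gx", "se_gx", "beta_gy", "se_gy"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} has length {arr.shape}, expected {n}")
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if len(set(self.variant_ids)) != n:
            raise ValueError("duplicate variant in HarmonizedSet")
        if np.any(self.beta_gx < 0):
            raise ValueError("HarmonizedSet requires beta_gx >= 0 (orientation invariant)")
        if np.any(self.se_gx <= 0) or np.any(self.se_gy <= 0):
            raise ValueError("standard errors must be positive")
        for label, (bm, sm) in list(self.mediators.items()):
            bm = np.asarray(bm, dtype=float)
            sm = np.asarray(sm, dtype=float)
            if bm.shape != (n,) or sm.shape != (n,):
                raise ValueError(f"mediator {label!r} columns mis-sized")
            self.mediators[label] = (bm, sm)

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)

    def instrument_hash(self) -> str:
        """Stable hash of the instrument identifier set (order-insensitive)."""
        joined = "\x1f".join(sorted(map(str, self.variant_ids)))
        return hashlib.sha256(joined.encode()).hexdigest()[:16]

    def subset(self, mask) -> "HarmonizedSet":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            keep = set(mask.tolist())
            mask = np.array([v in keep for v in self.variant_ids])
        return HarmonizedSet(
            self.variant_ids[mask],
            self.beta_gx[mask],
            self.se_gx[mask],
            self.beta_gy[mask],
            self.se_gy[mask],
            {k: (b[mask], s[mask]) for k, (b, s) in self.mediators.items()},
            orientation_log=self.orientation_log,
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            outcome_type=self.outcome_type,
        )

    def swap_roles(self) -> "HarmonizedSet":
        """Exchange exposure and outcome columns (bidirectional analyses).

        The result is re-oriented so the new exposure effects are positive.
        """
        flip = np.where(self.beta_gy < 0, -1.0, 1.0)
        return HarmonizedSet(
            self.variant_ids,
            flip * self.beta_gy,
            self.se_gy,
            flip * self.beta_gx,
            self.se_gx,
            {k: (flip * b, s) for k, (b, s) in self.mediators.items()},
            exposure_label=self.outcome_label,
            outcome_label=self.exposure_label,
            outcome_type="quantitative",
        )


class LDInfo:
    """Pairwise linkage-disequilibrium information.

    Accepts either a pair list ``(id_a, id_b, r2)`` or a square signed
    correlation matrix keyed by variant id.  Pairs absent from the supplied
    information are treated as independent (r2 = 0).
    """

    def __init__(self, pairs=None, matrix: pd.DataFrame | None = None):
        self._r2 = {}
        self._rho = None
        if matrix is not None:
            matrix = matrix.astype(float)
            if list(matrix.index) != list(matrix.columns):
                raise ValueError("LD matrix must share row/column variant ids")
            vals = matrix.to_numpy()
            if not np.allclose(vals, vals.T, atol=1e-8):
                raise ValueError("LD matrix must be symmetric")
            if not np.allclose(np.diag(vals), 1.0, atol=1e-8):
                raise ValueError("LD matrix diagonal must be 1")
            self._rho = matrix
            ids = list(matrix.index)
            for i, a in enumerate(ids):
                for j in range(i + 1, len(ids)):
                    self._r2[frozenset((a, ids[j]))] = vals[i, j] ** 2
        if pairs is not None:
            for a, b, r2 in pairs:
                r2 = float(r2)
                if not 0.0 <= r2 <= 1.0:
                    raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
                self._r2[frozenset((a, b))] = r2

    @classmethod
    def identity(cls) -> "LDInfo":
        return cls(pairs=[])

    @classmethod
    def read(cls, path) -> "LDInfo":
        """Read a 3-column pair list (ID_A, ID_B, R2) or a square matrix."""
        df = pd.read_csv(path, sep=None, engine="python")
        cols = [c.upper() for c in df.columns]
        if cols[:3] == ["ID_A", "ID_B", "R2"]:
            return cls(pairs=df.itertuples(index=False))
        mat = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls(matrix=mat)

    def r2(self, a, b) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def correlation_matrix(self, ids) -> np.ndarray:
        """Signed correlation matrix for ``ids``; falls back to sqrt(r2) when
        only unsigned pair information is available."""
        ids = list(ids)
        if self._rho is not None and all(i in self._rho.index for i in ids):
            return self._rho.loc[ids, ids].to_numpy()
        n = len(ids)
        out = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = np.sqrt(self.r2(ids[i], ids[j]))
        return out


def read_summary_stats(path, column_map=None, trait_type="quantitative",
                       trait_label=None) -> SummaryTable:
    """Read a delimited summary-statistics file into a :class:`SummaryTable`.

    ``column_map`` maps file headers to canonical ones, e.g. ``{"A1": "EA"}``
    or directly to internal names; rows violating the per-variant invariants
    (se <= 0, p outside (0,1], eaf outside (0,1), invalid alleles) are dropped
    and counted in ``drop_log``.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "read"):
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(str(path), sep=None, engine="python", dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    # accept canonical headers (and our own internal field names) case-insensitively
    upper = {c: c.upper() for c in df.columns}
    df = df.rename(columns=upper)
    df = df.rename(columns=CANONICAL_COLUMNS)
    df = df.rename(columns={k.upper(): v for k, v in CANONICAL_COLUMNS.items()})
    df = df.rename(columns={v.upper(): v for v in CANONICAL_COLUMNS.values()})

    for fieldname in MANDATORY_FIELDS:
        if fieldname not in df.columns:
            raise SummaryStatsError(f"missing mandatory column for field {fieldname!r}")
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan

    df = df[["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pvalue", "n"]].copy()
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for col in ("eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    drop_log = []
    ok = pd.Series(True, index=df.index)

    def _flag(bad: pd.Series, reason: str):
        nonlocal ok
        bad = bad & ok
        if bad.any():
            drop_log.extend((vid, reason) for vid in df.loc[bad, "variant_id"])
            ok &= ~bad

    _flag(df["variant_id"].isna() | df["beta"].isna() | df["se"].isna() | df["pvalue"].isna(),
          "missing value")
    _flag(~df["effect_allele"].isin(VALID_ALLELES) | ~df["other_allele"].isin(VALID_ALLELES),
          "invalid allele")
    _flag(df["effect_allele"] == df["other_allele"], "identical alleles")
    _flag(df["se"] <= 0, "non-positive se")
    _flag((df["pvalue"] <= 0) | (df["pvalue"] > 1), "p out of (0,1]")
    _flag(df["eaf"].notna() & ((df["eaf"] <= 0) | (df["eaf"] >= 1)), "eaf out of (0,1)")
    _flag(df["n"].notna() & (df["n"] <= 0), "non-positive n")

    kept = df[ok].reset_index(drop=True)
    if kept.empty:
        raise SummaryStatsError(f"no valid rows left after filtering {path!r}")
    label = trait_label if trait_label is not None else str(path)
    return SummaryTable(label, kept, trait_type, n_dropped=len(drop_log), drop_log=drop_log)


def _allele_key(ea, oa):
    return (ea, oa)


def harmonize(exposure: SummaryTable, outcome: SummaryTable, mediators=None,
              palindromic_policy: str = "infer_by_eaf",
              eaf_ambiguity=(0.42, 0.58)) -> HarmonizedSet:
    """Match variants across tables and align everything to the
    exposure-increasing allele.

    For each shared variant the outcome (and mediator) record is expressed on
    the exposure's effect allele — swapped-allele records have their beta
    negated and eaf complemented — then, if the exposure beta is negative, the
    whole variant is re-oriented so ``beta_gx > 0``.  Palindromic (A/T, C/G)
    variants cannot be strand-checked from alleles alone and are handled per
    ``palindromic_policy``: ``"drop"`` removes them; ``"infer_by_eaf"`` keeps
    those whose allele frequency is far enough from 0.5 in both tables to
    identify the shared allele, dropping frequencies inside ``eaf_ambiguity``.
    """
    if palindromic_policy not in ("drop", "infer_by_eaf"):
        raise ValueError(f"unknown palindromic_policy {palindromic_policy!r}")
    mediators = list(mediators or [])

    tables = {"outcome": outcome, **{f"mediator:{m.trait_label}": m for m in mediators}}
    exp = exposure.data.set_index("variant_id")
    idx = {name: t.data.set_index("variant_id") for name, t in tables.items()}
    shared = [v for v in exp.index if all(v in d.index for d in idx.values())]
    if not shared:
        raise SummaryStatsError("no shared variants between exposure and outcome tables")

    log_rows = []
    kept_ids, bx, sx = [], [], []
    cols = {name: ([], []) for name in tables}

    for vid in shared:
        e = exp.loc[vid]
        ea, oa = e["effect_allele"], e["other_allele"]
        palindromic = frozenset((ea, oa)) in PALINDROMIC_PAIRS
        if palindromic and palindromic_policy == "drop":
            log_rows.append((vid, "dropped", "palindromic"))
            continue

        aligned = {}
        action, reason = "kept", ""
        for name, d in idx.items():
            r = d.loc[vid]
            key = _allele_key(r["effect_allele"], r["other_allele"])
            if key == (ea, oa):
                flip = 1.0
            elif key == (oa, ea):
                flip = -1.0
            else:
                aligned = None
                reason = f"allele mismatch vs {name}"
                break
            if palindromic:
                # both strands read the same; identify the shared allele by eaf
                e_eaf, r_eaf = e["eaf"], r["eaf"]
                if np.isnan(e_eaf) or np.isnan(r_eaf):
                    aligned = None
                    reason = "palindromic, eaf missing"
                    break
                lo, hi = eaf_ambiguity
                if lo <= e_eaf <= hi or lo <= r_eaf <= hi:
                    aligned = None
                    reason = "palindromic, ambiguous eaf"
                    break
                eff_freq = r_eaf if flip == 1.0 else 1.0 - r_eaf
                if (e_eaf < 0.5) != (eff_freq < 0.5):
                    # frequencies disagree: the file is on the other strand
                    flip = -flip
                    action = "flipped"
            aligned[name] = flip * r["beta"], r["se"]
            if flip == -1.0:
                action = "flipped"
        if aligned is None:
            log_rows.append((vid, "dropped", reason))
            continue

        orient = 1.0
        if e["beta"] < 0:
            orient = -1.0
            action = "reoriented" if action == "kept" else action + "+reoriented"
        kept_ids.append(vid)
        bx.append(orient * e["beta"])
        sx.append(e["se"])
        for name in tables:
            b, s = aligned[name]
            cols[name][0].append(orient * b)
            cols[name][1].append(s)
        log_rows.append((vid, action, ""))

    log = pd.DataFrame(log_rows, columns=["variant_id", "action", "reason"])
    if not kept_ids:
        raise SummaryStatsError("harmonisation left no usable variants")
    med_cols = {
        name.split(":", 1)[1]: (np.array(cols[name][0]), np.array(cols[name][1]))
        for name in tables if name.startswith("mediator:")
    }
    return HarmonizedSet(
        np.array(kept_ids, dtype=object),
        np.array(bx), np.array(sx),
        np.array(cols["outcome"][0]), np.array(cols["outcome"][1]),
        med_cols,
        orientation_log=log,
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        outcome_type=outcome.trait_type,
    )


def ld_prune(table: SummaryTable, ld: LDInfo | None = None,
             r2_threshold: float = 0.05) -> SummaryTable:
    """Greedy LD pruning: keep the most strongly associated variant per LD clump.

    Variants are visited in ascending p-value order (ties broken by larger
    |beta|/se, then lexicographic id, so the result is deterministic); a
    variant is accepted iff its r2 with every already-accepted variant is at
    or below ``r2_threshold``.  Pairs missing from ``ld`` count as independent.
    """
    if ld is None:
        ld = LDInfo.identity()
    df = table.data
    if df.empty:
        return SummaryTable(table.trait_label, df.copy(), table.trait_type)
    order = sorted(
        range(len(df)),
        key=lambda i: (df["pvalue"].iat[i],
                       -abs(df["beta"].iat[i] / df["se"].iat[i]),
                       str(df["variant_id"].iat[i])),
    )
    accepted = []
    for i in order:
        vid = df["variant_id"].iat[i]
        if all(ld.r2(vid, df["variant_id"].iat[j]) <= r2_threshold for j in accepted):
            accepted.append(i)
    out = df.iloc[accepted].reset_index(drop=True)
    return SummaryTable(table.trait_label, out, table.trait_type)


RESULT_COLUMNS = ["method", "n_snps", "beta", "se", "ci_low", "ci_high", "p",
                  "OR", "OR_ci_low", "OR_ci_high", "Q", "Q_p", "I2"]


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return format(float(x), ".12g")


def write_results(estimates, path) -> None:
    """Serialise estimates to delimited text, one row per method x analysis.

    Round-trips losslessly at 12 significant digits; undefined fields (e.g.
    heterogeneity with a single instrument) are written as empty strings.
    """
    rows = []
    for e in estimates:
        het = getattr(e, "heterogeneity", None)
        binary = getattr(e, "outcome_type", "binary") == "binary"
        rows.append({
            "method": e.method,
            "n_snps": e.n_snps,
            "beta": _fmt(e.beta),
            "se": _fmt(e.se),
            "ci_low": _fmt(e.ci_low),
            "ci_high": _fmt(e.ci_high),
            "p": _fmt(e.pvalue),
            "OR": _fmt(np.exp(e.beta)) if binary else "",
            "OR_ci_low": _fmt(np.exp(e.ci_low)) if binary else "",
            "OR_ci_high": _fmt(np.exp(e.ci_high)) if binary else "",
            "Q": _fmt(het.Q) if het is not None else "",
            "Q_p": _fmt(het.pvalue) if het is not None else "",
            "I2": _fmt(het.i2) if het is not None else "",
        })
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if isinstance(path, io.IOBase):
        out.to_csv(path, sep="\t", index=False)
    else:
        out.to_csv(str(path), sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in RESULT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    return df
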