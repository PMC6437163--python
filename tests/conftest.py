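import numpy as np
import pandas as pd
import pytest

from mrpath import HarmonizedSet, SummaryTable


def make_table(rows, label="trait", trait_type="quantitative"):
    df = pd.DataFrame(rows, columns=["variant_id", "effect_allele", "other_allele",
                                     "eaf", "beta", "se", "pvalue", "n"])
    return SummaryTable(label, df, trait_type)


@pytest.fixture
def tiny_tables():
    """Three shared variants, one with swapped alleles in the outcome file."""
    exposure = make_table([
        ("rs1", "A", "G", 0.3, 0.05, 0.005, 1e-20, 10000),
        ("rs2", "T", "C", 0.2, -0.04, 0.004, 1e-18, 10000),
        ("rs3", "G", "C", 0.6, 0.03, 0.006, 1e-8, 10000),
    ], label="exposure")
    outcome = make_table([
        ("rs1", "A", "G", 0.31, -0.02, 0.01, 0.05, 50000),
        ("rs2", "C", "T", 0.81, 0.015, 0.011, 0.2, 50000),  # swapped alleles
        ("rs3", "G", "C", 0.59, -0.01, 0.012, 0.4, 50000),
    ], label="outcome", trait_type="binary")
    return exposure, outcome


def make_harmonized(beta_gx, se_gx, beta_gy, se_gy, **kw):
    j = len(beta_gx)
    return HarmonizedSet(np.array([f"rs{i}" for i in range(j)], dtype=object),
                         np.asarray(beta_gx, float), np.asarray(se_gx, float),
                         np.asarray(beta_gy, float), np.asarray(se_gy, float),
                         **kw)


@pytest.fixture
def homogeneous_h():
    """20 instruments lying exactly on beta_gy = 0.5 * beta_gx."""
    rng = np.random.default_rng(7)
    bx = rng.uniform(0.02, 0.1, 20)
    return make_harmonized(bx, np.full(20, 0.003), 0.5 * bx, np.full(20, 0.01))


@pytest.fixture
def noisy_h():
    """50 instruments with sampling noise around a true ratio of -0.2."""
    rng = np.random.default_rng(11)
    bx_true = rng.uniform(0.02, 0.08, 50)
    se_gx = np.full(50, 0.002)
    se_gy = np.full(50, 0.008)
    bx = bx_true + rng.normal(0, se_gx)
    by = -0.2 * bx_true + rng.normal(0, se_gy)
    flip = np.sign(bx)
    return make_harmonized(flip * bx, se_gx, flip * by, se_gy)
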