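"""Non-centrality-parameter power calculation for binary-outcome MR.

For an instrument (or instrument set) explaining a fraction ``r2_gx`` of the
exposure variance, the Wald test of the causal log-OR b = log(OR) in an
outcome study of size n with case fraction K has approximate non-centrality

    ncp = n * K * (1 - K) * r2_gx * b**2,

because the sampling variance of the estimated log-OR per SD of exposure is
1 / (n K (1-K) r2_gx) for small effects.  Power is the upper-tail mass of the
non-central chi-square(1, ncp) beyond the central critical value at alpha.
At OR = 1 the ncp vanishes and power equals alpha exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mr_power"]


def mr_power(n_outcome: float, case_fraction: float, r2_gx: float,
             or_alternative: float, alpha: float = 0.05) -> float:
    if not 0 < r2_gx < 1:
        raise ValueError("r2_gx must lie in (0, 1)")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must lie in (0, 1)")
    if n_outcome <= 0:
        raise ValueError("n_outcome must be positive")
    if or_alternative <= 0:
        raise ValueError("or_alternative must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    b = np.log(or_alternative)
    ncp = n_outcome * case_fraction * (1 - case_fraction) * r2_gx * b**2
    crit = stats.chi2.isf(alpha, 1)
    if ncp == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, 1, ncp))
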