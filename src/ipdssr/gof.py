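"""Kolmogorov-Smirnov goodness of fit of the IPD to a plain sample.

The statistic is the one-sample KS distance sup |F_n - F(. ; alpha)| with the
shape parameter supplied by the caller (in practice the MLE).  The p-value
comes from the asymptotic Kolmogorov distribution of sqrt(n) D without
correcting for the estimated parameter — a deliberate, slightly
anti-conservative plug-in convention.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .distributions import IPDParams, ipd_cdf

__all__ = ["ks_test"]


def ks_test(data, params: "IPDParams | float") -> tuple[float, float]:
    """(D, p) for the fitted-IPD KS test; D in [0, 1]."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("data must be non-empty")
    res = stats.kstest(data, lambda x: ipd_cdf(x, params), mode="asymp")
    return float(res.statistic), float(res.pvalue)
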