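"""Shared Wald-test arithmetic.

p-values are two-sided standard-normal tail probabilities.  -log10(p) is
computed from the log survival function so that very large test statistics
(|z| > 38, where the p-value underflows a double) still yield an accurate
-log10(p).
"""
from __future__ import annotations

import numpy as np
from scipy import stats

_LN10 = np.log(10.0)


def p_two_sided(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal p-value for a Wald statistic z (never exactly 0)."""
    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    # guard against underflow to exactly 0: clamp to the smallest subnormal
    p = np.maximum(p, np.nextafter(0.0, 1.0))
    return p if p.ndim else float(p)


def neglog10p_two_sided(z: np.ndarray | float) -> np.ndarray | float:
    """-log10 of the two-sided normal p-value, accurate for extreme z."""
    z = np.asarray(z, dtype=float)
    out = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / _LN10
    return out if out.ndim else float(out)
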