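"""Small statistical helpers shared by several modules."""

from __future__ import annotations

import numpy as np
from scipy import stats

TINY_P = float(np.nextafter(0, 1))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return stats.false_discovery_control(p, method="bh")


def percentile_cutoff(values: np.ndarray, percentile: float) -> float:
    """Linear-interpolation percentile of ``values`` (numpy convention)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    return float(np.percentile(values, percentile))


def welch_t_p(mean1, var1, n1, mean2, var2, n2):
    """Two-sided Welch t-test p-value from summary statistics.

    Vectorised over the second sample; variances are *sample* variances
    (ddof=1).  Returns p = 1 where both variances vanish and the means agree,
    and the smallest positive float where they differ with zero variance.
    """
    mean2 = np.asarray(mean2, dtype=float)
    var1 = float(var1)
    var2 = np.asarray(var2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    se2 = var1 / n1 + var2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2**2 / (
            (var1 / n1) ** 2 / max(n1 - 1, 1) + (var2 / n2) ** 2 / np.maximum(n2 - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(se2 > 0, p, np.where(np.isclose(mean1, mean2), 1.0, TINY_P))
    return np.clip(p, TINY_P, 1.0)
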