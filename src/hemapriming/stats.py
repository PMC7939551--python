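"""Shared statistical primitives: Fisher's exact test wrapper, sample odds
ratios with the Haldane–Anscombe correction, Benjamini-Hochberg step-up, and
the four-level p-value binning used by every test battery.

The BH step-up is implemented in-package with plain p·n/rank arithmetic so the
adjusted values are bit-reproducible; it agrees with statsmodels' ``fdr_bh``
to floating-point noise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: p-value bins: [0, 0.01] -> 0, (0.01, 0.05] -> 1, (0.05, 0.1] -> 2, (0.1, 1] -> 3
LEVEL_EDGES = (0.01, 0.05, 0.1)


def significance_level(pval: float) -> int:
    """Map a p-value in [0, 1] to the four-level significance bin."""
    if not 0.0 <= pval <= 1.0:
        raise ValueError(f"p-value {pval} outside [0, 1]")
    for level, edge in enumerate(LEVEL_EDGES):
        if pval <= edge:
            return level
    return 3


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2×2 table of counts.

    Returns ``(sample_odds_ratio, pval)`` where the odds ratio is the
    unconditional ad/bc (inf when bc = 0 and ad > 0, nan for 0/0).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    num, den = a * d, b * c
    if den > 0:
        oratio = num / den
    elif num > 0:
        oratio = np.inf
    else:
        oratio = np.nan
    return float(oratio), float(p)


def haldane_odds_ratio(table) -> tuple[float, bool]:
    """Sample odds ratio with 0.5 added to every cell when any cell is zero.

    Returns ``(odds_ratio, corrected)``; the flag reports whether the
    Haldane–Anscombe correction was applied.
    """
    t = np.asarray(table, dtype=float)
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b, c, d = t.ravel()
    return float((a * d) / (b * c)), corrected


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} min(1, p_(j) * n / j) over the ascending order
    statistics, mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
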