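"""Elementary transforms used throughout: depth normalization with log1p,
minimum-cells gene filtering, count binarization and min-max standardization.
"""

from __future__ import annotations

import numpy as np

from .containers import CountMatrix, PeakMatrix


def normalize_lognorm(m: CountMatrix, scale: float = 10_000.0) -> CountMatrix:
    """Depth-normalize each cell to ``scale`` total counts and add a log1p layer.

    Adds two layers to a copy of ``m``: ``normalized`` (counts / cell total ×
    scale) and ``lognorm`` (log1p of normalized). Raw counts are untouched.

    Raises
    ------
    ValueError
        If any cell has zero total count (zero library size).
    """
    totals = m.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"zero library size for cell {m.cells[zero[0]]!r}")
    normalized = m.counts / totals[None, :] * scale
    layers = dict(m.layers)
    layers["normalized"] = normalized
    layers["lognorm"] = np.log1p(normalized)
    return CountMatrix(m.genes, m.cells, m.counts, layers)


def filter_genes_min_cells(m: CountMatrix, min_cells: int = 10) -> CountMatrix:
    """Drop genes expressed (count > 0) in fewer than ``min_cells`` cells.

    The boundary is strict: a gene expressed in exactly ``min_cells`` cells
    is kept. The cell set is unchanged.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    n_cells_expr = (m.counts > 0).sum(axis=1)
    keep = np.flatnonzero(n_cells_expr >= min_cells)
    return CountMatrix(
        [m.genes[i] for i in keep],
        m.cells,
        m.counts[keep],
        {k: v[keep] for k, v in m.layers.items()},
    )


def binarize(m):
    """Binarize a CountMatrix or PeakMatrix: value > 0 → 1, else 0. Idempotent."""
    if isinstance(m, CountMatrix):
        if (m.counts < 0).any():
            raise ValueError("cannot binarize negative values")
        return CountMatrix(m.genes, m.cells, (m.counts > 0).astype(np.int8), {})
    if isinstance(m, PeakMatrix):
        if (m.access < 0).any():
            raise ValueError("cannot binarize negative values")
        return PeakMatrix(m.peaks.copy(), m.cells, (m.access > 0).astype(np.int8))
    arr = np.asarray(m)
    if (arr < 0).any():
        raise ValueError("cannot binarize negative values")
    return (arr > 0).astype(np.int8)


def minmax_standardize(v) -> np.ndarray:
    """Scale a vector into [0, 1]: (x − min) / (max − min).

    A constant vector maps to all zeros (so heatmaps never see NaN).
    """
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("cannot min-max standardize an empty vector")
    lo = v.min()
    span = v.max() - lo
    if span == 0:
        return np.zeros_like(v)
    return (v - lo) / span
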