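"""Balanced-subsampling differential expression.

Two unequal cell groups are compared by repeatedly subsampling the larger
group to the size of the smaller one. Each repetition is summarized by the
median over genes of per-gene Welch t-test p-values; the repetition whose
median equals the median of the repetition medians (attained exactly for an
odd number of repetitions) provides the representative balanced subset. The
selected subset is then tested gene-by-gene with the two-sided Wilcoxon
rank-sum test, BH-adjusted, and filtered on the fraction of expressing cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .stats import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class SubsampleSelection:
    """Outcome of the median-of-medians subset selection."""

    rep_medians: np.ndarray
    selected_rep: int
    selected_cells: list[str]
    #: cells of the smaller group the selection is balanced against
    other_cells: list[str]

    @property
    def median_of_medians(self) -> float:
        return float(np.median(self.rep_medians))


def _welch_median_p(x: np.ndarray, y: np.ndarray) -> float:
    """Median over genes of two-sided Welch t-test p-values.

    Only genes expressed (value > 0) in at least one cell of the union are
    included; genes with zero variance in both groups contribute p = 1.
    """
    expressed = (x > 0).any(axis=1) | (y > 0).any(axis=1)
    if not expressed.any():
        return 1.0
    x, y = x[expressed], y[expressed]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.ttest_ind(x, y, axis=1, equal_var=False).pvalue
    degenerate = (x.std(axis=1) == 0) & (y.std(axis=1) == 0)
    p = np.where(degenerate | np.isnan(p), 1.0, p)
    return float(np.median(p))


def select_balanced_subset(
    expr: CountMatrix,
    group_a,
    group_b,
    n_reps: int = 1001,
    seed: int = 0,
) -> SubsampleSelection:
    """Pick a representative balanced subsample of the larger group.

    When the groups already have equal sizes no subsampling is performed:
    the selection uses every cell of ``group_b`` with a single repetition.
    Ties among repetitions attaining the median of medians are broken by the
    lowest repetition index.
    """
    group_a, group_b = list(group_a), list(group_b)
    if min(len(group_a), len(group_b)) < 3:
        raise ValueError("each group needs at least 3 cells for the t-test")
    if n_reps % 2 == 0:
        raise ValueError("n_reps must be odd so the median is attained")
    lognorm = expr.require_layer("lognorm")
    xa = lognorm[:, expr.cell_index(group_a)]
    xb = lognorm[:, expr.cell_index(group_b)]

    if len(group_a) == len(group_b):
        med = _welch_median_p(xa, xb)
        return SubsampleSelection(
            np.array([med]), 0, list(group_b), list(group_a)
        )

    if len(group_a) < len(group_b):
        small_ids, small_x = group_a, xa
        big_ids, big_x = group_b, xb
    else:
        small_ids, small_x = group_b, xb
        big_ids, big_x = group_a, xa

    rng = np.random.default_rng(seed)
    n_small, n_big = len(small_ids), len(big_ids)
    picks = np.empty((n_reps, n_small), dtype=int)
    medians = np.empty(n_reps)
    for r in range(n_reps):
        picks[r] = rng.choice(n_big, size=n_small, replace=False)
        medians[r] = _welch_median_p(big_x[:, picks[r]], small_x)
    target = np.median(medians)
    selected = int(np.flatnonzero(medians == target)[0])
    selected_cells = [big_ids[i] for i in picks[selected]]
    return SubsampleSelection(medians, selected, selected_cells, list(small_ids))


@dataclass
class DEResult:
    gene: str
    log2fc: float
    pval: float
    padj: float
    frac_in: float
    frac_out: float
    kept: bool


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene, r.log2fc, r.pval, r.padj, r.frac_in, r.frac_out, r.kept)
         for r in results],
        columns=["gene", "log2fc", "pval", "padj", "frac_in", "frac_out", "kept"],
    )


def wilcoxon_de(
    expr: CountMatrix,
    group_a,
    selected_cells,
    min_in_group_fraction: float = 0.3,
    max_out_group_fraction: float = 1.0,
    min_fold_change: float = 0.0,
) -> list[DEResult]:
    """Per-gene two-sided Wilcoxon rank-sum on a balanced pair of groups.

    p-values are BH-adjusted across all tested genes. The fold change is
    computed on expm1 of the group means of the lognorm layer with a +1
    pseudocount. A gene is ``kept`` when it is expressed in at least
    ``min_in_group_fraction`` of the cells of one of the two groups (and
    passes the out-fraction / fold-change screens, both no-ops at their
    defaults).
    """
    group_a, group_b = list(group_a), list(selected_cells)
    lognorm = expr.require_layer("lognorm")
    xa = lognorm[:, expr.cell_index(group_a)]
    xb = lognorm[:, expr.cell_index(group_b)]
    if xa.shape[0] == 0:
        warnings.warn("no genes to test", stacklevel=2)
        return []

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.mannwhitneyu(xa, xb, axis=1, alternative="two-sided").pvalue
    pooled_const = np.all(xa == xa[:, :1], axis=1) & np.all(
        xb == xa[:, :1], axis=1
    )
    p = np.where(pooled_const | np.isnan(p), 1.0, p)
    padj = bh_adjust(p)

    log2fc = np.log2(
        (np.expm1(xa.mean(axis=1)) + 1.0) / (np.expm1(xb.mean(axis=1)) + 1.0)
    )
    frac_in = (xa > 0).mean(axis=1)
    frac_out = (xb > 0).mean(axis=1)
    kept = (
        (np.maximum(frac_in, frac_out) >= min_in_group_fraction)
        & (np.minimum(frac_in, frac_out) <= max_out_group_fraction)
        & (np.abs(log2fc) >= min_fold_change)
    )
    return [
        DEResult(g, float(log2fc[i]), float(p[i]), float(padj[i]),
                 float(frac_in[i]), float(frac_out[i]), bool(kept[i]))
        for i, g in enumerate(expr.genes)
    ]


def balanced_de(
    expr: CountMatrix,
    group_a,
    group_b,
    n_reps: int = 1001,
    seed: int = 0,
    **filters,
) -> tuple[SubsampleSelection, list[DEResult]]:
    """Median-of-medians subset selection followed by Wilcoxon + BH."""
    sel = select_balanced_subset(expr, group_a, group_b, n_reps=n_reps, seed=seed)
    group_a = list(group_a)
    if set(sel.other_cells) == set(group_a):
        res = wilcoxon_de(expr, group_a, sel.selected_cells, **filters)
    else:  # group_a was the larger group: the selection subsampled it
        res = wilcoxon_de(expr, sel.selected_cells, sel.other_cells, **filters)
    return sel, res


def membrane_de(
    expr: CountMatrix,
    group_a,
    group_b,
    membrane_genes,
    n_reps: int = 1001,
    seed: int = 0,
    **filters,
) -> tuple[SubsampleSelection, list[DEResult]]:
    """Balanced DE restricted to a supplied membrane-protein gene list."""
    keep = [g for g in expr.genes if g in set(membrane_genes)]
    if not keep:
        raise ValueError("membrane gene list does not intersect the matrix genes")
    log.info("membrane DE on %d of %d genes", len(keep), len(expr.genes))
    return balanced_de(
        expr.subset_genes(keep), group_a, group_b, n_reps=n_reps, seed=seed,
        **filters,
    )
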