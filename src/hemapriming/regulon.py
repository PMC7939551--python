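"""Regulon target accessibility: promoter/enhancer peak assignment, per-cell
scoring, per-cluster summaries, k-means row ordering for heatmaps, and
binarized promoter co-accessibility between lineage marker sets.

Promoters are peaks overlapping TSS ± 3 kb. Enhancers are peaks overlapping
TSS ± 50 kb but not the ± 3 kb promoter core of the same gene, restricted to
peaks carrying a predicted binding site of the analyzed TF. All intervals
are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.cluster import KMeans

from .containers import CellTable, CountMatrix, GeneAnnotation, MotifHitTable, PeakMatrix, RegulonTable
from .preprocess import minmax_standardize
from .stats import fisher_exact_2x2, haldane_odds_ratio


def select_regulon_targets(
    reg: RegulonTable, tf: str, min_importance: float = 4.0
) -> list[str]:
    """Targets of ``tf`` with importance strictly greater than the threshold,
    ordered by descending importance (ties broken by target name)."""
    sub = reg.df[reg.df["tf"] == tf]
    if sub.empty:
        raise ValueError(f"TF {tf!r} absent from the regulon table")
    kept = sub[sub["importance"] > min_importance]
    if kept.empty:
        warnings.warn(
            f"no {tf} target exceeds importance {min_importance}", stacklevel=2
        )
    kept = kept.sort_values(
        ["importance", "target"], ascending=[False, True], kind="stable"
    )
    return list(kept["target"])


@dataclass
class RegionAssignment:
    gene_id: str
    region_kind: str  # promoter | enhancer
    peak_ids: list[str]


def assign_regions(
    genes: GeneAnnotation,
    peaks: PeakMatrix,
    motifs: MotifHitTable,
    tf: str,
    prom_bp: int = 3000,
    enh_bp: int = 50_000,
    gene_ids=None,
) -> list[RegionAssignment]:
    """Assign peaks to promoter and enhancer windows of each gene.

    A peak may serve several genes. Enhancer sets exclude any peak that
    intersects the promoter window of that same gene and keep only peaks
    with a motif hit for ``tf``.
    """
    trees: dict[str, IntervalTree] = {}
    for pid, row in peaks.peaks.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], pid
        )
    tf_peaks = motifs.peaks_for(tf)
    out: list[RegionAssignment] = []
    targets = genes.gene_ids if gene_ids is None else list(gene_ids)
    for g in targets:
        row = genes.df.loc[g]
        tss = int(row["tss"])
        tree = trees.get(row["chrom"], IntervalTree())
        prom_lo, prom_hi = max(0, tss - prom_bp), tss + prom_bp
        enh_lo, enh_hi = max(0, tss - enh_bp), tss + enh_bp
        prom = {iv.data for iv in tree.overlap(prom_lo, prom_hi)}
        wide = {iv.data for iv in tree.overlap(enh_lo, enh_hi)}
        enh = {p for p in (wide - prom) if p in tf_peaks}
        out.append(RegionAssignment(g, "promoter", sorted(prom)))
        out.append(RegionAssignment(g, "enhancer", sorted(enh)))
    return out


def _region_peak_index(
    peaks: PeakMatrix, assignments: list[RegionAssignment], kind: str
) -> dict[str, np.ndarray]:
    pos = {p: i for i, p in enumerate(peaks.peak_ids)}
    return {
        a.gene_id: np.array([pos[p] for p in a.peak_ids], dtype=int)
        for a in assignments
        if a.region_kind == kind
    }


def score_region_accessibility(
    peaks: PeakMatrix,
    assignments: list[RegionAssignment],
    cells: CellTable,
    kind: str = "promoter",
) -> pd.DataFrame:
    """Per-gene, per-cluster mean accessibility score (genes × clusters).

    Per cell: the number of open peaks in each gene's region is divided by
    the cell's total open peaks (depth normalization for a binary matrix),
    then min-max scaled across the gene set within that cell, and finally
    averaged per cluster. Scores therefore lie in [0, 1].
    """
    region = _region_peak_index(peaks, assignments, kind)
    gene_order = list(region)
    cell_ids = [c for c in peaks.cells if c in cells.df.index]
    cidx = peaks.cell_index(cell_ids)
    acc = peaks.access[:, cidx]
    depth = acc.sum(axis=0).astype(float)
    zero = depth == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero open peaks scored as 0",
            stacklevel=2,
        )
        depth[zero] = 1.0

    raw = np.vstack([
        acc[idx].sum(axis=0) if idx.size else np.zeros(len(cell_ids))
        for idx in region.values()
    ]) / depth[None, :]
    scaled = np.column_stack(
        [minmax_standardize(raw[:, j]) for j in range(raw.shape[1])]
    )
    scaled[:, zero] = 0.0

    clusters = cells.df.loc[cell_ids, "cluster"].to_numpy()
    table = {}
    for cl in pd.unique(clusters):
        table[cl] = scaled[:, clusters == cl].mean(axis=1)
    return pd.DataFrame(table, index=pd.Index(gene_order, name="gene"))


def expression_summary(
    expr: CountMatrix, cells: CellTable, gene_ids
) -> pd.DataFrame:
    """Per-cluster mean lognorm expression of a gene set, min-max scaled per
    gene across clusters (the paired heatmap panel for the score table)."""
    lognorm = expr.require_layer("lognorm")
    gidx = expr.gene_index(gene_ids)
    cell_ids = [c for c in expr.cells if c in cells.df.index]
    cidx = expr.cell_index(cell_ids)
    clusters = cells.df.loc[cell_ids, "cluster"].to_numpy()
    cols = {}
    for cl in pd.unique(clusters):
        cols[cl] = lognorm[np.ix_(gidx, cidx[clusters == cl])].mean(axis=1)
    df = pd.DataFrame(cols, index=pd.Index(list(gene_ids), name="gene"))
    return df.apply(lambda r: pd.Series(minmax_standardize(r), index=df.columns),
                    axis=1)


def kmeans_order(rows: pd.DataFrame, k: int = 5, seed: int = 0) -> list:
    """Row ordering for heatmaps: k-means with ``k`` centroids, groups sorted
    by descending centroid mean, original order kept within groups."""
    if k > len(rows):
        raise ValueError(f"k={k} exceeds the number of rows ({len(rows)})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(rows.to_numpy())
    means = km.cluster_centers_.mean(axis=1)
    order_of = {lab: rank for rank, lab in enumerate(np.argsort(-means, kind="stable"))}
    ranked = sorted(range(len(rows)), key=lambda i: (order_of[labels[i]], i))
    return [rows.index[i] for i in ranked]


@dataclass
class CoaccessResult:
    cluster: str
    lineage_pair: tuple[str, str]
    table: np.ndarray
    odds_ratio: float
    pval: float
    corrected: bool


def promoter_coaccessibility(
    peaks: PeakMatrix,
    assignments: list[RegionAssignment],
    cells: CellTable,
    lineage_sets: dict[str, list[str]],
    cluster: str,
) -> list[CoaccessResult]:
    """Association between binarized promoter accessibility of lineage
    marker sets within one cluster.

    Per cell and lineage the indicator is 1 when ANY marker promoter of that
    lineage has an open peak. Each lineage pair gives a 2×2 table over the
    cluster's cells, a two-sided Fisher exact p, and the sample odds ratio
    (Haldane–Anscombe 0.5 correction when any cell is zero, flagged;
    the exact p is computed on the uncorrected table).
    """
    if len(lineage_sets) < 2:
        raise ValueError("need at least two lineage sets")
    region = _region_peak_index(peaks, assignments, "promoter")
    cell_ids = [
        c for c in peaks.cells
        if c in cells.df.index and cells.df.loc[c, "cluster"] == cluster
    ]
    if not cell_ids:
        raise ValueError(f"cluster {cluster!r} has no cells in the peak matrix")
    cidx = peaks.cell_index(cell_ids)

    indicators = {}
    for name, gene_list in lineage_sets.items():
        idx = np.concatenate(
            [region.get(g, np.array([], dtype=int)) for g in gene_list]
        ) if gene_list else np.array([], dtype=int)
        if idx.size == 0:
            raise ValueError(f"lineage set {name!r} has no assigned promoter peaks")
        indicators[name] = (peaks.access[np.ix_(idx, cidx)].sum(axis=0) > 0)

    names = list(lineage_sets)
    out = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = indicators[names[i]], indicators[names[j]]
            table = np.array(
                [[(a & b).sum(), (a & ~b).sum()],
                 [(~a & b).sum(), (~a & ~b).sum()]],
                dtype=np.int64,
            )
            _, p = fisher_exact_2x2(table)
            oratio, corrected = haldane_odds_ratio(table)
            out.append(
                CoaccessResult(cluster, (names[i], names[j]), table,
                               oratio, p, corrected)
            )
    return out


def coaccess_frame(results: list[CoaccessResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.cluster, r.lineage_pair[0], r.lineage_pair[1],
             r.odds_ratio, r.pval, r.corrected)
            for r in results
        ],
        columns=["cluster", "lineage_a", "lineage_b", "odds_ratio", "pval",
                 "corrected"],
    )
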