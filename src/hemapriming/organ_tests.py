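"""Liver-vs-femur test batteries across cell types.

Three per-cluster batteries, each reported with a four-level significance
bin: (1) gate-normalized cluster composition — global χ² of homogeneity plus
per-cluster Fisher's exact tests on rescaled median compositions; (2)
expressed-genes-per-mapped-read distributions compared with KS and
Mann-Whitney-Wilcoxon on balanced subsamples (median p over repetitions);
(3) cell-cycle state (G2M/S pooled vs G1, G0 excluded) per-cluster Fisher.

Normalized (non-integer) abundances are turned back into counts by rescaling
each organ's vector to a fixed total and rounding half-to-even, so the
contingency tests are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellTable
from .stats import fisher_exact_2x2, significance_level

log = logging.getLogger(__name__)

ORGAN_PAIR = ("liver", "femur")


@dataclass
class TestOutcome:
    cluster: str
    test: str  # composition | gene_count_ks | gene_count_mww | cycle
    statistic: float
    pval: float
    level: int


def outcomes_frame(outcomes: list[TestOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.cluster, o.test, o.statistic, o.pval, o.level) for o in outcomes],
        columns=["cluster", "test", "statistic", "pval", "level"],
    )


@dataclass
class CompositionTable:
    """Gate-normalized cluster abundances per organ.

    ``per_gate`` holds one row per (gate, organ, cluster) with the abundance
    scaled so each gate-organ vector sums to 100; ``medians`` is the
    clusters × organs matrix of medians over gates; ``organ_totals`` are the
    true cell counts per organ within the matched gates.
    """

    per_gate: pd.DataFrame
    medians: pd.DataFrame
    organ_totals: dict[str, int]


def normalize_gate_composition(cells: CellTable) -> CompositionTable:
    """Normalize cluster abundances within each matched FACS gate.

    Only gates with cells from both organs are used. Within each
    (gate, organ), cluster cell counts are scaled to sum to 100; the
    per-cluster median over gates summarizes each organ.
    """
    df = cells.df[cells.df["organ"].isin(ORGAN_PAIR)]
    by_gate_organ = df.groupby(["gate", "organ"], observed=True).size().unstack(
        "organ", fill_value=0
    )
    matched = [
        g for g in by_gate_organ.index
        if all(o in by_gate_organ.columns and by_gate_organ.loc[g, o] > 0
               for o in ORGAN_PAIR)
    ]
    if not matched:
        raise ValueError("no FACS gate has cells from both liver and femur")
    df = df[df["gate"].isin(matched)]
    clusters = sorted(df["cluster"].unique())

    counts = (
        df.groupby(["gate", "organ", "cluster"], observed=True)
        .size()
        .reindex(
            pd.MultiIndex.from_product(
                [matched, ORGAN_PAIR, clusters],
                names=["gate", "organ", "cluster"],
            ),
            fill_value=0,
        )
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(["gate", "organ"])["n"].transform("sum")
    counts["abundance"] = counts["n"] / totals * 100.0

    medians = (
        counts.pivot_table(
            index="cluster", columns="organ", values="abundance",
            aggfunc="median",
        )
        .reindex(index=clusters, columns=list(ORGAN_PAIR))
    )
    organ_totals = {o: int((df["organ"] == o).sum()) for o in ORGAN_PAIR}
    return CompositionTable(counts, medians, organ_totals)


def _rescale_to_counts(vec: np.ndarray, total: int) -> np.ndarray:
    """Rescale a non-negative vector to sum ≈ total, rounding half-to-even."""
    s = vec.sum()
    if s == 0:
        raise ValueError("all-zero organ composition vector")
    return np.round(vec / s * total).astype(np.int64)


def composition_test(
    comp: CompositionTable,
) -> tuple[float, list[TestOutcome]]:
    """Global χ² of organ homogeneity plus per-cluster Fisher's exact tests.

    Each organ's median composition vector is rescaled to that organ's true
    matched-gate cell total and rounded; the χ² runs on the 2 × K table and
    each cluster is then tested cluster-vs-rest × liver-vs-femur.
    """
    clusters = list(comp.medians.index)
    if len(clusters) < 2:
        raise ValueError("composition test needs at least 2 clusters")
    mat = np.vstack(
        [
            _rescale_to_counts(
                comp.medians[o].to_numpy(dtype=float), comp.organ_totals[o]
            )
            for o in ORGAN_PAIR
        ]
    )
    keep = mat.sum(axis=0) > 0  # χ² is undefined for all-zero columns
    chi2, global_p, _, _ = stats.chi2_contingency(mat[:, keep])

    outcomes = []
    row_tot = mat.sum(axis=1)
    for j, cl in enumerate(clusters):
        table = [
            [mat[0, j], row_tot[0] - mat[0, j]],
            [mat[1, j], row_tot[1] - mat[1, j]],
        ]
        oratio, p = fisher_exact_2x2(table)
        outcomes.append(
            TestOutcome(cl, "composition", oratio, p, significance_level(p))
        )
    return float(global_p), outcomes


def _median_subsampled_p(
    small: np.ndarray,
    big: np.ndarray,
    testfun,
    n_reps: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Median (statistic, p) of ``testfun`` over balanced subsamples of big."""
    if small.size == big.size:
        res = testfun(small, big)
        return float(res.statistic), float(res.pvalue)
    stats_, ps = np.empty(n_reps), np.empty(n_reps)
    for r in range(n_reps):
        sub = rng.choice(big, size=small.size, replace=False)
        res = testfun(small, sub)
        stats_[r], ps[r] = res.statistic, res.pvalue
    return float(np.median(stats_)), float(np.median(ps))


def gene_count_test(
    cells: CellTable,
    n_reps: int = 1001,
    min_cells: int = 20,
    seed: int = 0,
) -> list[TestOutcome]:
    """KS and MWW on expressed-genes-per-mapped-read, per cluster.

    Each cell contributes n_genes / mapped_reads. The larger organ group is
    subsampled ``n_reps`` times to the smaller group's size and the median
    p over repetitions is reported (equal sizes skip subsampling). Clusters
    with fewer than ``min_cells`` cells in either organ are skipped.
    """
    df = cells.df[cells.df["organ"].isin(ORGAN_PAIR)]
    if (df["mapped_reads"] <= 0).any():
        raise ValueError("mapped_reads must be positive for all cells")
    rng = np.random.default_rng(seed)
    outcomes: list[TestOutcome] = []
    for cl, sub in df.groupby("cluster", observed=True, sort=True):
        vals = {
            o: (sub.loc[sub["organ"] == o, "n_genes"]
                / sub.loc[sub["organ"] == o, "mapped_reads"]).to_numpy()
            for o in ORGAN_PAIR
        }
        sizes = {o: v.size for o, v in vals.items()}
        if min(sizes.values()) < min_cells:
            log.info("cluster %s skipped (cells per organ %s < %d)",
                     cl, sizes, min_cells)
            continue
        small_o = min(ORGAN_PAIR, key=lambda o: (sizes[o], ORGAN_PAIR.index(o)))
        big_o = ORGAN_PAIR[1 - ORGAN_PAIR.index(small_o)]
        for name, fun in (
            ("gene_count_ks", stats.ks_2samp),
            ("gene_count_mww",
             lambda x, y: stats.mannwhitneyu(x, y, alternative="two-sided")),
        ):
            stat, p = _median_subsampled_p(
                vals[small_o], vals[big_o], fun, n_reps, rng
            )
            outcomes.append(TestOutcome(cl, name, stat, p, significance_level(p)))
    return outcomes


def cycle_test(cells: CellTable) -> list[TestOutcome]:
    """Per-cluster Fisher on cycling (G2M/S pooled) vs G1, liver vs femur.

    G0 cells are excluded. Each organ's (cycling, G1) pair is rescaled to a
    common total (the rounded mean of the two organ cell counts) before the
    exact test, so organs sorted at different depths are comparable.
    """
    df = cells.df[
        cells.df["organ"].isin(ORGAN_PAIR)
        & cells.df["cycle_phase"].isin(["G1", "S", "G2M"])
    ]
    outcomes: list[TestOutcome] = []
    for cl, sub in df.groupby("cluster", observed=True, sort=True):
        n_org = {o: (sub["organ"] == o).sum() for o in ORGAN_PAIR}
        if min(n_org.values()) == 0:
            log.info("cluster %s skipped (no cells in one organ)", cl)
            continue
        common = int(np.round(np.mean(list(n_org.values()))))
        table = []
        for o in ORGAN_PAIR:
            cyc = ((sub["organ"] == o)
                   & sub["cycle_phase"].isin(["S", "G2M"])).sum()
            cyc_scaled = int(np.round(cyc / n_org[o] * common))
            table.append([cyc_scaled, common - cyc_scaled])
        oratio, p = fisher_exact_2x2(table)
        outcomes.append(TestOutcome(cl, "cycle", oratio, p, significance_level(p)))
    return outcomes


def level_matrix(outcomes: list[TestOutcome]) -> pd.DataFrame:
    """Clusters × tests matrix of significance levels (heatmap analogue)."""
    frame = outcomes_frame(outcomes)
    return frame.pivot_table(
        index="cluster", columns="test", values="level", aggfunc="first"
    )
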