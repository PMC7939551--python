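"""Synthetic data with the statistical structure the pipeline assumes.

The RNA side draws genes × cells counts from a negative binomial with
cluster-specific marker up-shifts, assigns organ / FACS-gate / cell-cycle
labels, and derives per-cell mapped-read and expressed-gene counts. The ATAC
side draws binary peak states from cluster-dependent Bernoullis with peaks
placed in promoter (TSS ± 3 kb) and enhancer (TSS ± 50 kb, outside ± 3 kb)
windows, plants promoter co-accessibility through a shared latent Bernoulli,
and emits a simulated TF regulon whose target importances straddle the
selection threshold.

Everything is driven by a single integer seed through a splittable
``numpy.random.SeedSequence``, so identical configs give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import (
    CellTable,
    CountMatrix,
    GeneAnnotation,
    MotifHitTable,
    PeakMatrix,
    RegulonTable,
    peak_id,
)

_GENES_PER_CHROM = 25
_GENE_SPACING = 120_000
_FIRST_GENE_OFFSET = 60_000
_PROMOTER_PEAK_HALF = 500
_ENHANCER_PEAK_WIDTH = 400
_READS_PER_COUNT = 100.0


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    ``cells_per_cluster_per_organ`` is either a single int (every cluster in
    every organ) or a mapping ``{organ: int}`` / ``{organ: {cluster: int}}``;
    unequal organ entries encode planted composition differences. The
    entries are *expected* counts: each organ's cluster labels are drawn
    from a multinomial with these weights (total fixed at their sum), which
    is the sampling noise the composition tests assume. Set
    ``multinomial_composition=False`` to pin sizes exactly.

    ``cycle_fracs`` is the default (G1, S, G2M) simplex; per-(cluster, organ)
    overrides plant cell-cycle differences. ``organ_gene_count_shift`` is the
    fractional inflation of femur mapped-read counts, which depresses the
    femur expressed-genes-per-read ratio by the same relative amount.
    """

    n_clusters: int = 6
    cells_per_cluster_per_organ: int | dict = 100
    organs: tuple[str, ...] = ("liver", "femur")
    n_genes: int = 300
    nb_mean: float = 2.0
    nb_dispersion: float = 0.5
    marker_genes_per_cluster: int = 10
    marker_log2fc: float = 1.0
    organ_gene_count_shift: float = 0.0
    cycle_fracs: tuple[float, float, float] = (0.6, 0.25, 0.15)
    cycle_frac_overrides: dict = field(default_factory=dict)
    g0_frac: float = 0.0
    n_gates: int = 2
    # ATAC block
    n_atac_cells_per_cluster: int = 50
    n_ambiguous_atac_cells: int = 0
    n_background_peaks: int = 40
    promoter_open_prob: float = 0.3
    marker_promoter_open_prob: float = 0.8
    enhancer_open_prob: float = 0.2
    multinomial_composition: bool = True
    coaccess_rho: float = 0.0
    coaccess_pairs: tuple = ()
    regulon_n_targets: int = 20
    tf_name: str = "TF1"
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.promoter_open_prob,
            self.marker_promoter_open_prob,
            self.enhancer_open_prob,
            self.coaccess_rho,
            self.g0_frac,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for fr in [self.cycle_fracs, *self.cycle_frac_overrides.values()]:
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"cycle fractions {fr} do not sum to 1")
        if self.n_clusters < 1 or self.n_genes < 1:
            raise ValueError("need at least one cluster and one gene")
        if self.marker_genes_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("more marker genes requested than genes available")

    # ---------------------------------------------------------------- helpers

    @property
    def clusters(self) -> list[str]:
        return [f"C{k}" for k in range(self.n_clusters)]

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def marker_genes(self, cluster: str) -> list[str]:
        """Planted marker genes of ``cluster`` (empty when no effect planted)."""
        if self.marker_log2fc == 0 or self.marker_genes_per_cluster == 0:
            return []
        k = self.clusters.index(cluster)
        m = self.marker_genes_per_cluster
        return self.gene_names[k * m : (k + 1) * m]

    def n_cells(self, cluster: str, organ: str) -> int:
        table = self.cells_per_cluster_per_organ
        if isinstance(table, int):
            return table
        entry = table[organ]
        if isinstance(entry, int):
            return entry
        return entry[cluster]

    def _seeds(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "annotation": np.random.default_rng(children[0]),
            "rna": np.random.default_rng(children[1]),
            "atac": np.random.default_rng(children[2]),
        }


def small_fixture_config(seed: int = 0) -> SimConfig:
    """The packaged small fixture: 3 clusters, 200 cells, 2 organs."""
    return SimConfig(
        n_clusters=3,
        cells_per_cluster_per_organ={
            "liver": {"C0": 40, "C1": 30, "C2": 30},
            "femur": {"C0": 40, "C1": 30, "C2": 30},
        },
        n_genes=120,
        marker_genes_per_cluster=8,
        marker_log2fc=1.5,
        n_atac_cells_per_cluster=25,
        n_background_peaks=20,
        coaccess_rho=0.5,
        coaccess_pairs=(("G000", "G001"),),
        regulon_n_targets=15,
        seed=seed,
    )


# --------------------------------------------------------------- annotation


def make_gene_annotation(cfg: SimConfig) -> GeneAnnotation:
    """Non-overlapping gene bodies on synthetic chromosomes, both strands.

    Genes are spaced far enough apart that enhancer windows of one gene never
    reach the promoter window of another. TSS is body_start on '+' strands
    and body_end − 1 on '−' strands.
    """
    rng = cfg._seeds()["annotation"]
    lengths = rng.integers(2000, 6001, size=cfg.n_genes)
    rows = []
    for i, name in enumerate(cfg.gene_names):
        chrom = f"chr{i // _GENES_PER_CHROM + 1}"
        within = i % _GENES_PER_CHROM
        start = _FIRST_GENE_OFFSET + within * _GENE_SPACING
        end = start + int(lengths[i])
        if cfg.chrom_length is not None and end + 50_000 > cfg.chrom_length:
            raise ValueError(
                f"chromosome length {cfg.chrom_length} too short to place "
                f"gene {name} with its enhancer window"
            )
        strand = "+" if i % 2 == 0 else "-"
        tss = start if strand == "+" else end - 1
        rows.append((name, chrom, strand, start, end, tss))
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "body_start", "body_end", "tss"]
    ).set_index("gene_id")
    return GeneAnnotation(df)


# ---------------------------------------------------------------------- RNA


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB draws parametrized by mean and dispersion α (var = μ + α μ²)."""
    if dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


class SimRna(NamedTuple):
    cells: CellTable
    matrix: CountMatrix
    truth: pd.DataFrame


def simulate_rna(cfg: SimConfig) -> SimRna:
    """Draw the RNA cohort: counts, metadata labels and the truth table.

    Counts are NB(μ_g, α) per gene with marker genes up-shifted by
    ``marker_log2fc`` (log2 units) in their own cluster. Mapped reads are
    proportional to the cell total with lognormal noise; femur cells get an
    extra ``1 + organ_gene_count_shift`` factor. The truth table lists every
    planted effect (empty for a null config).
    """
    rng = cfg._seeds()["rna"]
    genes = cfg.gene_names
    clusters = cfg.clusters

    # gene base means: markers pinned at nb_mean, background lognormal around it
    base = np.exp(rng.normal(np.log(cfg.nb_mean), 0.8, size=cfg.n_genes))
    marker_rows: list[dict] = []
    marker_idx: dict[str, np.ndarray] = {}
    for k, cl in enumerate(clusters):
        mg = cfg.marker_genes(cl)
        idx = np.array([genes.index(g) for g in mg], dtype=int)
        marker_idx[cl] = idx
        base[idx] = cfg.nb_mean
        for g in mg:
            marker_rows.append(
                {"kind": "marker", "cluster": cl, "gene": g,
                 "value": cfg.marker_log2fc}
            )

    cell_ids, organ_lab, cluster_lab = [], [], []
    counts_blocks = []
    for organ in cfg.organs:
        weights = np.array(
            [cfg.n_cells(cl, organ) for cl in clusters], dtype=float
        )
        total = int(weights.sum())
        if total == 0:
            continue
        if cfg.multinomial_composition:
            sizes = rng.multinomial(total, weights / weights.sum())
        else:
            sizes = weights.astype(int)
        for k, cl in enumerate(clusters):
            n = int(sizes[k])
            if n == 0:
                continue
            mu = np.tile(base[:, None], (1, n))
            mu[marker_idx[cl], :] *= 2.0 ** cfg.marker_log2fc
            counts_blocks.append(_nb_draw(rng, mu, cfg.nb_dispersion))
            start = len(cell_ids)
            cell_ids += [f"{organ}_{cl}_{start + i}" for i in range(n)]
            organ_lab += [organ] * n
            cluster_lab += [cl] * n
    counts = np.concatenate(counts_blocks, axis=1)
    organ_lab = np.array(organ_lab)
    cluster_lab = np.array(cluster_lab)
    n_cells = len(cell_ids)

    # gates: organ-independent mixing over n_gates gates
    gates = np.array([f"gate{j + 1}" for j in range(cfg.n_gates)])
    gate_lab = gates[rng.integers(0, cfg.n_gates, size=n_cells)]

    # cell-cycle phases
    phase_lab = np.empty(n_cells, dtype=object)
    for cl in clusters:
        for organ in cfg.organs:
            mask = (cluster_lab == cl) & (organ_lab == organ)
            if not mask.any():
                continue
            fr = cfg.cycle_frac_overrides.get((cl, organ), cfg.cycle_fracs)
            probs = np.array([cfg.g0_frac] + [f * (1 - cfg.g0_frac) for f in fr])
            draws = rng.choice(4, size=mask.sum(), p=probs / probs.sum())
            phase_lab[mask] = np.array(["G0", "G1", "S", "G2M"])[draws]

    totals = counts.sum(axis=0)
    noise = np.exp(rng.normal(0.0, 0.1, size=n_cells))
    reads = totals * _READS_PER_COUNT * noise
    reads[organ_lab == "femur"] *= 1.0 + cfg.organ_gene_count_shift
    mapped_reads = np.maximum(1, np.round(reads)).astype(np.int64)
    n_genes_expr = (counts > 0).sum(axis=0)

    cells = CellTable(
        pd.DataFrame(
            {
                "organ": organ_lab,
                "gate": gate_lab,
                "cluster": cluster_lab,
                "cycle_phase": phase_lab,
                "mapped_reads": mapped_reads,
                "n_genes": n_genes_expr,
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )

    truth_rows = list(marker_rows)
    if cfg.organ_gene_count_shift != 0:
        truth_rows.append(
            {"kind": "gene_count_shift", "cluster": "*", "gene": "",
             "value": cfg.organ_gene_count_shift}
        )
    for (cl, organ), fr in cfg.cycle_frac_overrides.items():
        truth_rows.append(
            {"kind": "cycle_diff", "cluster": cl, "gene": organ,
             "value": 1.0 - fr[0]}
        )
    if not isinstance(cfg.cells_per_cluster_per_organ, int):
        for cl in clusters:
            ns = [cfg.n_cells(cl, o) for o in cfg.organs]
            if len(set(ns)) > 1:
                truth_rows.append(
                    {"kind": "composition", "cluster": cl, "gene": "",
                     "value": ns[0] / max(ns[1], 1)}
                )
    truth = pd.DataFrame(truth_rows, columns=["kind", "cluster", "gene", "value"])
    return SimRna(cells, CountMatrix(genes, cell_ids, counts), truth)


# --------------------------------------------------------------------- ATAC


def expected_coaccess_odds_ratio(rho: float, q: float) -> float:
    """Closed-form odds ratio of the shared-latent co-open model.

    Each of the two promoter states copies a shared Bernoulli(q) latent with
    probability ``rho`` and is an independent Bernoulli(q) otherwise.
    """
    p11 = q * (rho + (1 - rho) * q) ** 2 + (1 - q) * ((1 - rho) * q) ** 2
    p10 = q - p11
    p00 = 1 - 2 * q + p11
    return (p11 * p00) / (p10 * p10)


class SimAtac(NamedTuple):
    peaks: PeakMatrix
    motifs: MotifHitTable
    regulon: RegulonTable
    cells: CellTable
    truth: pd.DataFrame


def simulate_atac(cfg: SimConfig, genes: GeneAnnotation) -> SimAtac:
    """Draw the ATAC cohort: binary peaks, motif hits, regulon and truth.

    One promoter peak per gene (inside TSS ± 3 kb), one enhancer peak per
    gene (inside TSS ± 50 kb, outside ± 3 kb of every TSS) and background
    peaks on a gene-free chromosome. Marker-gene promoters open with
    ``marker_promoter_open_prob`` in their own cluster. For each configured
    gene pair the two promoter open-states share a latent Bernoulli with
    mixing weight ``coaccess_rho``. Ambiguous cells (uniform cluster
    mixtures) are appended when requested.
    """
    if len(genes) == 0:
        raise ValueError("gene annotation is empty")
    rng = cfg._seeds()["atac"]
    gdf = genes.df
    gene_names = genes.gene_ids

    peak_rows: list[tuple[str, int, int, str, str]] = []  # chrom,start,end,kind,gene
    for g, row in gdf.iterrows():
        tss = int(row["tss"])
        peak_rows.append(
            (row["chrom"], tss - _PROMOTER_PEAK_HALF, tss + _PROMOTER_PEAK_HALF,
             "promoter", g)
        )
        offset = int(rng.integers(8000, 45_000))
        sign = -1 if rng.random() < 0.5 else 1
        start = tss + sign * offset
        if start < 0:
            start = tss + offset
        peak_rows.append(
            (row["chrom"], start, start + _ENHANCER_PEAK_WIDTH, "enhancer", g)
        )
    for j in range(cfg.n_background_peaks):
        start = 10_000 + j * 5_000
        peak_rows.append(("chrBG", start, start + 300, "background", ""))

    peaks_df = pd.DataFrame(
        peak_rows, columns=["chrom", "start", "end", "kind", "gene"]
    )
    peaks_df.index = pd.Index(
        [peak_id(r.chrom, r.start, r.end) for r in peaks_df.itertuples()],
        name="peak_id",
    )
    n_peaks = len(peaks_df)
    prom_pos = {g: i for i, (g, k) in enumerate(zip(peaks_df["gene"], peaks_df["kind"]))
                if k == "promoter"}

    clusters = cfg.clusters
    cell_ids, cluster_lab = [], []
    for cl in clusters:
        cell_ids += [f"atac_{cl}_{i}" for i in range(cfg.n_atac_cells_per_cluster)]
        cluster_lab += [cl] * cfg.n_atac_cells_per_cluster
    cell_ids += [f"atac_ambiguous_{i}" for i in range(cfg.n_ambiguous_atac_cells)]
    cluster_lab += ["ambiguous"] * cfg.n_ambiguous_atac_cells
    cluster_lab = np.array(cluster_lab)
    n_cells = len(cell_ids)

    # per-peak per-cluster open probabilities
    prob = np.empty((n_peaks, n_cells))
    kind = peaks_df["kind"].to_numpy()
    pgene = peaks_df["gene"].to_numpy()
    base_p = np.where(
        kind == "promoter", cfg.promoter_open_prob,
        np.where(kind == "enhancer", cfg.enhancer_open_prob, 0.2),
    )
    marker_of = {}
    for cl in clusters:
        for g in cfg.marker_genes(cl):
            marker_of[g] = cl
    for j, cl in enumerate(cluster_lab):
        pj = base_p.copy()
        if cl == "ambiguous":
            # uniform mixture over clusters: average of the per-cluster profiles
            boost = np.isin(pgene, list(marker_of)) & (kind == "promoter")
            pj[boost] = (
                cfg.marker_promoter_open_prob
                + (cfg.n_clusters - 1) * cfg.promoter_open_prob
            ) / cfg.n_clusters
        else:
            for g, owner in marker_of.items():
                if owner == cl and g in prom_pos:
                    pj[prom_pos[g]] = cfg.marker_promoter_open_prob
        prob[:, j] = pj
    access = (rng.random((n_peaks, n_cells)) < prob).astype(np.int8)

    # planted promoter co-accessibility via a shared latent Bernoulli
    q = cfg.promoter_open_prob
    truth_rows = []
    for ga, gb in cfg.coaccess_pairs:
        ia, ib = prom_pos[ga], prom_pos[gb]
        z = rng.random(n_cells) < q
        for i in (ia, ib):
            copy = rng.random(n_cells) < cfg.coaccess_rho
            fresh = rng.random(n_cells) < q
            access[i] = np.where(copy, z, fresh).astype(np.int8)
        truth_rows.append(
            {"kind": "coaccess", "gene_a": ga, "gene_b": gb,
             "rho": cfg.coaccess_rho,
             "expected_or": expected_coaccess_odds_ratio(cfg.coaccess_rho, q)
             if cfg.coaccess_rho > 0 else 1.0}
        )

    # simulated regulon: importances straddle the selection threshold of 4
    targets = gene_names[: cfg.regulon_n_targets]
    importance = np.linspace(0.5, 8.0, len(targets))
    importance = rng.permutation(importance)
    regulon = RegulonTable(
        pd.DataFrame(
            {"tf": cfg.tf_name, "target": targets, "importance": importance}
        )
    )

    # motif hits: the TF hits every enhancer of its targets plus random decoys
    enh_mask = (kind == "enhancer") & np.isin(pgene, targets)
    decoy_mask = (kind == "enhancer") & ~np.isin(pgene, targets)
    decoys = np.flatnonzero(decoy_mask)
    decoys = decoys[rng.random(decoys.size) < 0.25]
    hit_idx = np.concatenate([np.flatnonzero(enh_mask), decoys])
    motifs = MotifHitTable(
        pd.DataFrame(
            {"peak_id": peaks_df.index[np.sort(hit_idx)], "tf": cfg.tf_name}
        )
    )

    open_counts = access.sum(axis=0)
    atac_cells = CellTable(
        pd.DataFrame(
            {
                "organ": "liver",
                "gate": "gate1",
                "cluster": cluster_lab,
                "cycle_phase": "G1",
                "mapped_reads": np.maximum(1, open_counts * 100),
                "n_genes": 0,
            },
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )
    truth = pd.DataFrame(
        truth_rows, columns=["kind", "gene_a", "gene_b", "rho", "expected_or"]
    )
    pm = PeakMatrix(peaks_df[["chrom", "start", "end"]].copy(), cell_ids, access)
    return SimAtac(pm, motifs, regulon, atac_cells, truth)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A config with no planted effects: identical organs in every respect."""
    base = SimConfig(
        marker_log2fc=0.0,
        organ_gene_count_shift=0.0,
        coaccess_rho=0.0,
        seed=seed,
    )
    return replace(base, **overrides)
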