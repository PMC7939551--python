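import numpy as np
import pandas as pd
import pytest

from conftest import make_cell_table
from hemapriming.containers import (
    GeneAnnotation,
    MotifHitTable,
    PeakMatrix,
    RegulonTable,
)
from hemapriming.regulon import (
    assign_regions,
    kmeans_order,
    promoter_coaccessibility,
    score_region_accessibility,
    select_regulon_targets,
)


def _annotation(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand",
                                     "body_start", "body_end", "tss"])
    return GeneAnnotation(df.set_index("gene_id"))


def _peaks(coords, cells, access):
    df = pd.DataFrame(coords, columns=["chrom", "start", "end"])
    return PeakMatrix(df, cells, np.asarray(access))


class TestSelectTargets:
    def test_strict_threshold_and_order(self):
        reg = RegulonTable(pd.DataFrame({
            "tf": ["T", "T", "T", "X"],
            "target": ["a", "b", "c", "d"],
            "importance": [4.5, 4.0, 7.0, 9.0],
        }))
        assert select_regulon_targets(reg, "T") == ["c", "a"]  # 4.0 dropped

    def test_absent_tf(self):
        reg = RegulonTable(pd.DataFrame(
            {"tf": ["T"], "target": ["a"], "importance": [5.0]}))
        with pytest.raises(ValueError):
            select_regulon_targets(reg, "Z")

    def test_empty_result_warns(self):
        reg = RegulonTable(pd.DataFrame(
            {"tf": ["T"], "target": ["a"], "importance": [1.0]}))
        with pytest.warns(UserWarning):
            assert select_regulon_targets(reg, "T") == []


class TestAssignRegions:
    def setup_method(self):
        self.genes = _annotation([("g", "chr1", "+", 10_000, 12_000, 10_000)])
        self.cells = ["c1"]

    def _assign(self, coords, motif_peaks=()):
        pm = _peaks(coords, self.cells, np.ones((len(coords), 1), dtype=int))
        motifs = MotifHitTable(pd.DataFrame(
            {"peak_id": list(motif_peaks), "tf": "T"}))
        return {(a.gene_id, a.region_kind): a.peak_ids
                for a in assign_regions(self.genes, pm, motifs, "T")}

    def test_promoter_overlap(self):
        out = self._assign([("chr1", 12_500, 12_700)])
        assert out[("g", "promoter")] == ["chr1:12500-12700"]

    def test_half_open_promoter_boundary(self):
        # promoter window is [7000, 13000): a peak starting at 13001 misses
        out = self._assign([("chr1", 13_001, 13_200)])
        assert out[("g", "promoter")] == []

    def test_enhancer_requires_motif(self):
        peak = ("chr1", 40_000, 40_200)
        with_hit = self._assign([peak], motif_peaks=["chr1:40000-40200"])
        without = self._assign([peak])
        assert with_hit[("g", "enhancer")] == ["chr1:40000-40200"]
        assert without[("g", "enhancer")] == []

    def test_promoter_and_enhancer_disjoint(self, small_genes, small_atac,
                                            small_cfg):
        assigns = assign_regions(small_genes, small_atac.peaks,
                                 small_atac.motifs, small_cfg.tf_name)
        by_gene = {}
        for a in assigns:
            by_gene.setdefault(a.gene_id, {})[a.region_kind] = set(a.peak_ids)
        for d in by_gene.values():
            assert not (d["promoter"] & d["enhancer"])


class TestScoring:
    def test_cluster_of_identical_cells(self):
        genes = _annotation([("g1", "chr1", "+", 10_000, 12_000, 10_000),
                             ("g2", "chr1", "+", 60_000, 62_000, 60_000)])
        coords = [("chr1", 9_800, 10_200), ("chr1", 59_800, 60_200)]
        access = np.array([[1, 1], [0, 0]])
        pm = _peaks(coords, ["c1", "c2"], access)
        cells = make_cell_table(
            [("c1", "liver", "g", "K", "G1", 10, 1),
             ("c2", "liver", "g", "K", "G1", 10, 1)])
        motifs = MotifHitTable(pd.DataFrame({"peak_id": [], "tf": []}))
        assigns = assign_regions(genes, pm, motifs, "T")
        scores = score_region_accessibility(pm, assigns, cells)
        # identical cells: cluster mean equals the single-cell score
        assert scores.loc["g1", "K"] == pytest.approx(1.0)
        assert scores.loc["g2", "K"] == pytest.approx(0.0)

    def test_scores_within_unit_interval(self, small_genes, small_atac,
                                         small_cfg):
        assigns = assign_regions(small_genes, small_atac.peaks,
                                 small_atac.motifs, small_cfg.tf_name)
        scores = score_region_accessibility(small_atac.peaks, assigns,
                                            small_atac.cells)
        vals = scores.to_numpy()
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_planted_cluster_scores_higher(self):
        """Markers with elevated promoter open-prob in their own cluster
        score higher there (Bernoulli mean contrast)."""
        from hemapriming.simulate import SimConfig, make_gene_annotation, simulate_atac
        cfg = SimConfig(n_clusters=2, n_atac_cells_per_cluster=200,
                        n_genes=40, marker_genes_per_cluster=8,
                        marker_log2fc=1.0, promoter_open_prob=0.2,
                        marker_promoter_open_prob=0.8, seed=3)
        genes = make_gene_annotation(cfg)
        atac = simulate_atac(cfg, genes)
        assigns = assign_regions(genes, atac.peaks, atac.motifs, cfg.tf_name,
                                 gene_ids=cfg.marker_genes("C0"))
        scores = score_region_accessibility(atac.peaks, assigns, atac.cells)
        assert (scores["C0"] > scores["C1"]).all()


class TestKmeansOrder:
    def test_k_equals_rows(self):
        rows = pd.DataFrame(np.eye(4) * [1, 2, 3, 4],
                            index=list("abcd"))
        order = kmeans_order(rows, k=4, seed=0)
        assert sorted(order) == list("abcd")

    def test_duplicate_rows_stay_together(self):
        data = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        rows = pd.DataFrame(data, index=list("abcd"))
        order = kmeans_order(rows, k=2, seed=0)
        assert {tuple(order[:2]), tuple(order[2:])} == {("a", "c"), ("b", "d")}

    def test_deterministic_and_k_too_large(self):
        rng = np.random.default_rng(0)
        rows = pd.DataFrame(rng.random((8, 3)))
        assert kmeans_order(rows, 3, seed=5) == kmeans_order(rows, 3, seed=5)
        with pytest.raises(ValueError):
            kmeans_order(rows, 9, seed=0)


class TestCoaccessibility:
    def _setup(self, access):
        genes = _annotation([("gA", "chr1", "+", 10_000, 12_000, 10_000),
                             ("gB", "chr1", "+", 130_000, 132_000, 130_000)])
        coords = [("chr1", 9_900, 10_100), ("chr1", 129_900, 130_100)]
        n = access.shape[1]
        pm = _peaks(coords, [f"c{i}" for i in range(n)], access)
        cells = make_cell_table(
            [(f"c{i}", "liver", "g", "K", "G1", 10, 1) for i in range(n)])
        motifs = MotifHitTable(pd.DataFrame({"peak_id": [], "tf": []}))
        assigns = assign_regions(genes, pm, motifs, "T")
        return pm, assigns, cells

    def test_known_table(self):
        # indicators forming [[3,1],[1,3]]
        a = [1, 1, 1, 1, 0, 0, 0, 0]
        b = [1, 1, 1, 0, 1, 0, 0, 0]
        pm, assigns, cells = self._setup(np.array([a, b]))
        res = promoter_coaccessibility(pm, assigns, cells,
                                       {"A": ["gA"], "B": ["gB"]}, "K")[0]
        assert res.pval == pytest.approx(34 / 70, abs=1e-12)
        assert res.odds_ratio == pytest.approx(9.0)
        assert not res.corrected

    def test_perfect_association_flagged(self):
        a = [1, 1, 1, 0, 0, 0]
        pm, assigns, cells = self._setup(np.array([a, a]))
        res = promoter_coaccessibility(pm, assigns, cells,
                                       {"A": ["gA"], "B": ["gB"]}, "K")[0]
        assert res.corrected and res.odds_ratio > 1

    def test_missing_promoter_peaks_named(self):
        pm, assigns, cells = self._setup(np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError, match="ghost"):
            promoter_coaccessibility(pm, assigns, cells,
                                     {"ghost": ["nope"], "B": ["gB"]}, "K")

    def test_single_lineage_rejected(self):
        pm, assigns, cells = self._setup(np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError):
            promoter_coaccessibility(pm, assigns, cells, {"A": ["gA"]}, "K")
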