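import numpy as np
import pytest

from conftest import make_cell_table
from hemapriming.organ_tests import (
    composition_test,
    cycle_test,
    gene_count_test,
    level_matrix,
    normalize_gate_composition,
)


def _cells_for_composition():
    rows = []
    i = 0
    # gate1 matched in both organs; gateX only in liver (must be dropped)
    for organ, gate, cluster, n in [
        ("liver", "gate1", "A", 3), ("liver", "gate1", "B", 7),
        ("femur", "gate1", "A", 5), ("femur", "gate1", "B", 5),
        ("liver", "gateX", "A", 4),
    ]:
        for _ in range(n):
            rows.append((f"c{i}", organ, gate, cluster, "G1", 1000, 100))
            i += 1
    return make_cell_table(rows)


class TestGateNormalization:
    def test_scaling_to_100(self):
        comp = normalize_gate_composition(_cells_for_composition())
        sub = comp.per_gate.query("gate == 'gate1' and organ == 'liver'")
        assert dict(zip(sub.cluster, sub.abundance)) == {"A": 30.0, "B": 70.0}

    def test_unmatched_gate_excluded(self):
        comp = normalize_gate_composition(_cells_for_composition())
        assert "gateX" not in set(comp.per_gate.gate)
        assert comp.organ_totals == {"liver": 10, "femur": 10}

    def test_median_over_two_gates(self):
        rows = []
        i = 0
        for organ, gate, cluster, n in [
            ("liver", "g1", "A", 3), ("liver", "g1", "B", 7),
            ("liver", "g2", "A", 5), ("liver", "g2", "B", 5),
            ("femur", "g1", "A", 1), ("femur", "g1", "B", 1),
            ("femur", "g2", "A", 1), ("femur", "g2", "B", 1),
        ]:
            for _ in range(n):
                rows.append((f"c{i}", organ, gate, cluster, "G1", 1000, 100))
                i += 1
        comp = normalize_gate_composition(make_cell_table(rows))
        assert comp.medians.loc["A", "liver"] == pytest.approx(40.0)

    def test_no_matched_gates_errors(self):
        rows = [("c0", "liver", "g1", "A", "G1", 10, 5),
                ("c1", "femur", "g2", "A", "G1", 10, 5)]
        with pytest.raises(ValueError, match="gate"):
            normalize_gate_composition(make_cell_table(rows))


class TestCompositionTest:
    def test_identical_compositions(self):
        rows = []
        i = 0
        for organ in ("liver", "femur"):
            for cluster, n in [("A", 30), ("B", 70)]:
                for _ in range(n):
                    rows.append((f"c{i}", organ, "g1", cluster, "G1", 10, 5))
                    i += 1
        comp = normalize_gate_composition(make_cell_table(rows))
        global_p, outcomes = composition_test(comp)
        assert global_p == pytest.approx(1.0)
        assert all(o.level == 3 for o in outcomes)
        assert all(o.pval == pytest.approx(1.0) for o in outcomes)

    def test_single_cluster_rejected(self):
        rows = [(f"c{i}", organ, "g1", "A", "G1", 10, 5)
                for i, organ in enumerate(["liver", "femur"])]
        comp = normalize_gate_composition(make_cell_table(rows))
        with pytest.raises(ValueError):
            composition_test(comp)


class TestGeneCountTest:
    def test_normalized_value(self):
        # 3000 expressed genes / 600000 mapped reads = 0.005 per cell
        assert 3000 / 600_000 == pytest.approx(0.005)

    def test_identical_samples_p_one(self):
        rows = []
        for i in range(25):
            rows.append((f"l{i}", "liver", "g1", "A", "G1", 1000, 100 + i))
            rows.append((f"f{i}", "femur", "g1", "A", "G1", 1000, 100 + i))
        out = gene_count_test(make_cell_table(rows), n_reps=11, seed=0)
        ks = [o for o in out if o.test == "gene_count_ks"][0]
        assert ks.statistic == 0.0 and ks.pval == pytest.approx(1.0)
        assert ks.level == 3

    def test_small_cluster_skipped(self):
        rows = [(f"l{i}", "liver", "g1", "A", "G1", 1000, 100) for i in range(19)]
        rows += [(f"f{i}", "femur", "g1", "A", "G1", 1000, 100) for i in range(30)]
        out = gene_count_test(make_cell_table(rows), n_reps=11, seed=0)
        assert out == []

    def test_invariant_to_organ_relabeling(self):
        """Swapping which organ is larger leaves equal-size tests unchanged."""
        rows = []
        rng = np.random.default_rng(0)
        ng = rng.integers(80, 140, size=60)
        for i in range(30):
            rows.append((f"l{i}", "liver", "g1", "A", "G1", 1000, int(ng[i])))
            rows.append((f"f{i}", "femur", "g1", "A", "G1", 1000, int(ng[30 + i])))
        swapped = [(c, {"liver": "femur", "femur": "liver"}[o], g, cl, p, m, n)
                   for (c, o, g, cl, p, m, n) in rows]
        out1 = gene_count_test(make_cell_table(rows), n_reps=11, seed=0)
        out2 = gene_count_test(make_cell_table(swapped), n_reps=11, seed=0)
        for a, b in zip(out1, out2):
            assert a.pval == pytest.approx(b.pval)


class TestCycleTest:
    def test_odds_ratio_arithmetic(self):
        rows = []
        i = 0
        for organ, cycling, g1 in [("liver", 48, 52), ("femur", 30, 70)]:
            for _ in range(cycling):
                rows.append((f"c{i}", organ, "g", "A", "S", 10, 5)); i += 1
            for _ in range(g1):
                rows.append((f"c{i}", organ, "g", "A", "G1", 10, 5)); i += 1
        out = cycle_test(make_cell_table(rows))
        assert out[0].statistic == pytest.approx((48 * 70) / (52 * 30), rel=1e-6)

    def test_identical_distributions(self):
        rows = []
        i = 0
        for organ in ("liver", "femur"):
            for ph, n in [("S", 40), ("G1", 60)]:
                for _ in range(n):
                    rows.append((f"c{i}", organ, "g", "A", ph, 10, 5)); i += 1
        out = cycle_test(make_cell_table(rows))
        assert out[0].pval == pytest.approx(1.0) and out[0].level == 3

    def test_g0_excluded_and_single_organ_skipped(self):
        rows = [(f"c{i}", "liver", "g", "A", "G0", 10, 5) for i in range(10)]
        rows += [(f"d{i}", "liver", "g", "B", "G1", 10, 5) for i in range(10)]
        rows += [(f"e{i}", "femur", "g", "B", "S", 10, 5) for i in range(10)]
        out = cycle_test(make_cell_table(rows))
        assert [o.cluster for o in out] == ["B"]


def test_level_matrix_shape():
    rows = []
    i = 0
    for organ in ("liver", "femur"):
        for cluster in ("A", "B"):
            for ph, n in [("S", 20), ("G1", 30)]:
                for _ in range(n):
                    rows.append((f"c{i}", organ, "g", cluster, ph, 1000, 100))
                    i += 1
    cells = make_cell_table(rows)
    comp = normalize_gate_composition(cells)
    _, outcomes = composition_test(comp)
    outcomes += gene_count_test(cells, n_reps=11, seed=0)
    outcomes += cycle_test(cells)
    mat = level_matrix(outcomes)
    assert set(mat.columns) == {"composition", "gene_count_ks",
                                "gene_count_mww", "cycle"}
    assert mat.isin([0, 1, 2, 3]).all().all()
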