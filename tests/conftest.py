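import numpy as np
import pandas as pd
import pytest

from hemapriming.containers import CellTable, CountMatrix
from hemapriming.simulate import (
    make_gene_annotation,
    simulate_atac,
    simulate_rna,
    small_fixture_config,
)


@pytest.fixture(scope="session")
def small_cfg():
    return small_fixture_config(seed=7)


@pytest.fixture(scope="session")
def small_genes(small_cfg):
    return make_gene_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_rna(small_cfg):
    return simulate_rna(small_cfg)


@pytest.fixture(scope="session")
def small_atac(small_cfg, small_genes):
    return simulate_atac(small_cfg, small_genes)


@pytest.fixture()
def tiny_matrix():
    counts = np.array(
        [[5, 0, 2],
         [5, 10, 0],
         [0, 0, 1]]
    )
    return CountMatrix(["g1", "g2", "g3"], ["c1", "c2", "c3"], counts)


def make_cell_table(rows):
    """rows: (cell_id, organ, gate, cluster, phase, mapped_reads, n_genes)"""
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "organ", "gate", "cluster", "cycle_phase",
                 "mapped_reads", "n_genes"],
    ).set_index("cell_id")
    return CellTable(df)
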