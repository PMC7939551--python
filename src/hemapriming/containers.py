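"""In-memory containers shared by every stage of the pipeline.

All genomic coordinates are 0-based half-open (BED convention); GTF-style
1-based inputs are converted at read time by :mod:`hemapriming.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANS = ("liver", "femur", "hip")
CYCLE_PHASES = ("G0", "G1", "S", "G2M")

CELL_COLUMNS = ["organ", "gate", "cluster", "cycle_phase", "mapped_reads", "n_genes"]


@dataclass
class CellTable:
    """Per-cell metadata: organ of origin, FACS gate, cluster label,
    cell-cycle phase, uniquely mapped read count and expressed-gene count.

    ``df`` is indexed by unique ``cell_id``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"CellTable missing columns: {missing}")
        if not self.df.index.is_unique:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValueError(f"duplicate cell_id: {dup!r}")
        bad = set(self.df["organ"]) - set(ORGANS)
        if bad:
            raise ValueError(f"unknown organ labels: {sorted(bad)}")
        bad = set(self.df["cycle_phase"]) - set(CYCLE_PHASES)
        if bad:
            raise ValueError(f"unknown cycle phases: {sorted(bad)}")
        if (self.df["mapped_reads"] < 0).any() or (self.df["n_genes"] < 0).any():
            raise ValueError("mapped_reads and n_genes must be non-negative")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, cell_ids) -> "CellTable":
        return CellTable(self.df.loc[list(cell_ids)].copy())


@dataclass
class CountMatrix:
    """Genes × cells raw counts plus optional derived layers.

    ``layers`` may hold ``"normalized"`` (depth-normalized to a fixed scale)
    and ``"lognorm"`` (log1p of normalized), both genes × cells floats.
    """

    genes: list[str]
    cells: list[str]
    counts: np.ndarray
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.cells = list(self.cells)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names not unique")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("cell names not unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("counts must be integer-valued")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValueError(f"layer {name!r} shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        return np.array([pos[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cells)}
        return np.array([pos[c] for c in cells], dtype=int)

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(
            [self.genes[i] for i in idx],
            self.cells,
            self.counts[idx],
            {k: v[idx] for k, v in self.layers.items()},
        )

    def require_layer(self, name: str) -> np.ndarray:
        if name not in self.layers:
            raise ValueError(
                f"layer {name!r} missing; run normalize_lognorm first"
            )
        return self.layers[name]


def peak_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass
class PeakMatrix:
    """Peaks × cells binary accessibility with BED-style peak coordinates.

    ``peaks`` has columns chrom, start, end (0-based half-open) and is
    indexed by the canonical ``chrom:start-end`` peak id.
    """

    peaks: pd.DataFrame
    cells: list[str]
    access: np.ndarray

    def __post_init__(self) -> None:
        self.cells = list(self.cells)
        self.access = np.asarray(self.access)
        for c in ("chrom", "start", "end"):
            if c not in self.peaks.columns:
                raise ValueError(f"peaks table missing column {c!r}")
        if self.peaks.index.name != "peak_id":
            self.peaks = self.peaks.copy()
            self.peaks.index = pd.Index(
                [peak_id(r.chrom, r.start, r.end) for r in self.peaks.itertuples()],
                name="peak_id",
            )
        if not self.peaks.index.is_unique:
            raise ValueError("peak ids not unique")
        if (self.peaks["start"] >= self.peaks["end"]).any():
            raise ValueError("peak start must be < end")
        if self.access.shape != (len(self.peaks), len(self.cells)):
            raise ValueError("access shape inconsistent with peaks/cells")
        vals = np.unique(self.access)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("access matrix must be strictly binary")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.peaks.index)

    def cell_index(self, cells) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cells)}
        return np.array([pos[c] for c in cells], dtype=int)


@dataclass
class GeneAnnotation:
    """Per-gene chromosome, strand, 0-based half-open body interval and TSS.

    TSS is body_start on the + strand and body_end − 1 on the − strand.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("chrom", "strand", "body_start", "body_end", "tss"):
            if c not in self.df.columns:
                raise ValueError(f"gene annotation missing column {c!r}")
        if not self.df.index.is_unique:
            raise ValueError("gene_id not unique")
        bad = set(self.df["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"bad strand values: {sorted(bad)}")
        if (self.df["body_start"] >= self.df["body_end"]).any():
            raise ValueError("body_start must be < body_end")
        inside = (self.df["tss"] >= self.df["body_start"]) & (
            self.df["tss"] < self.df["body_end"]
        )
        if not inside.all():
            raise ValueError("tss must lie inside the gene body")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RegulonTable:
    """(TF, target, importance) triples from upstream GRN inference."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("tf", "target", "importance"):
            if c not in self.df.columns:
                raise ValueError(f"regulon table missing column {c!r}")
        if self.df.duplicated(["tf", "target"]).any():
            raise ValueError("duplicate (tf, target) pairs")
        if (self.df["importance"] < 0).any():
            raise ValueError("importance must be >= 0")


@dataclass
class MotifHitTable:
    """Predicted TF binding sites: (peak_id, tf) pairs."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("peak_id", "tf"):
            if c not in self.df.columns:
                raise ValueError(f"motif table missing column {c!r}")

    def peaks_for(self, tf: str) -> set[str]:
        return set(self.df.loc[self.df["tf"] == tf, "peak_id"])
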