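"""Readers and writers for the plain-text formats the pipeline consumes.

Matrices travel as MatrixMarket triplets (``.mtx`` plus ``<stem>.genes.tsv`` /
``<stem>.cells.tsv`` name files) or dense TSV, auto-detected by extension.
Peaks use BED3+name; gene annotations a GTF-like TSV with 1-based inclusive
coordinates converted to 0-based half-open at read time. All writers are
deterministic: fixed column order, tab separator, '.' decimal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import (
    CELL_COLUMNS,
    CellTable,
    CountMatrix,
    GeneAnnotation,
    MotifHitTable,
    PeakMatrix,
    RegulonTable,
)

# ---------------------------------------------------------------- count matrix


def _names_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".genes.tsv"), stem.with_suffix(".cells.tsv")


def write_count_matrix(m: CountMatrix, path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(m.counts))
        gpath, cpath = _names_paths(path)
        gpath.write_text("".join(f"{g}\n" for g in m.genes))
        cpath.write_text("".join(f"{c}\n" for c in m.cells))
    elif path.suffix == ".tsv":
        df = pd.DataFrame(m.counts, index=m.genes, columns=m.cells)
        df.to_csv(path, sep="\t", index_label="gene")
    else:
        raise ValueError(f"unsupported matrix extension: {path.suffix!r}")


def read_count_matrix(path) -> CountMatrix:
    path = Path(path)
    if path.suffix == ".mtx":
        counts = np.asarray(spio.mmread(str(path)).todense())
        gpath, cpath = _names_paths(path)
        genes = gpath.read_text().splitlines()
        cells = cpath.read_text().splitlines()
        return CountMatrix(genes, cells, counts)
    if path.suffix == ".tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(list(df.index), list(df.columns), df.to_numpy())
    raise ValueError(f"unsupported matrix extension: {path.suffix!r}")


# ----------------------------------------------------------------- peak matrix


def write_peak_matrix(m: PeakMatrix, mtx_path, bed_path) -> None:
    mtx_path = Path(mtx_path)
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(m.access))
    _, cpath = _names_paths(mtx_path)
    cpath.write_text("".join(f"{c}\n" for c in m.cells))
    bed = m.peaks.reset_index()[["chrom", "start", "end", "peak_id"]]
    bed.to_csv(bed_path, sep="\t", header=False, index=False)


def read_peak_matrix(mtx_path, bed_path) -> PeakMatrix:
    mtx_path = Path(mtx_path)
    access = np.asarray(spio.mmread(str(mtx_path)).todense())
    _, cpath = _names_paths(mtx_path)
    cells = cpath.read_text().splitlines()
    peaks = read_peaks_bed(bed_path)
    return PeakMatrix(peaks, cells, access)


def read_peaks_bed(path) -> pd.DataFrame:
    peaks = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "peak_id"]
    )
    peaks = peaks.set_index("peak_id")
    return peaks


# ------------------------------------------------------------------ flat files


def write_cell_table(t: CellTable, path) -> None:
    t.df[CELL_COLUMNS].to_csv(path, sep="\t", index_label="cell_id")


def read_cell_table(path) -> CellTable:
    df = pd.read_csv(path, sep="\t", index_col="cell_id")
    return CellTable(df)


def write_gene_annotation(g: GeneAnnotation, path) -> None:
    """1-based inclusive gene coordinates (GTF-like TSV)."""
    out = g.df.copy()
    out["start"] = out["body_start"] + 1
    out["end"] = out["body_end"]
    out[["chrom", "strand", "start", "end"]].to_csv(
        path, sep="\t", index_label="gene_id"
    )


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df["body_start"] = df["start"] - 1
    df["body_end"] = df["end"]
    df["tss"] = np.where(df["strand"] == "+", df["body_start"], df["body_end"] - 1)
    return GeneAnnotation(df[["chrom", "strand", "body_start", "body_end", "tss"]])


def write_regulon_table(r: RegulonTable, path) -> None:
    r.df[["tf", "target", "importance"]].to_csv(path, sep="\t", index=False)


def read_regulon_table(path) -> RegulonTable:
    return RegulonTable(pd.read_csv(path, sep="\t"))


def write_motif_hits(m: MotifHitTable, path) -> None:
    m.df[["peak_id", "tf"]].to_csv(path, sep="\t", index=False)


def read_motif_hits(path) -> MotifHitTable:
    return MotifHitTable(pd.read_csv(path, sep="\t"))
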