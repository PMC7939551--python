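"""Gene-activity profiles from binary peak matrices and RNA→ATAC label
transfer with per-cell prediction scores and an unclassified threshold.

Gene activity sums binary peak states over gene body ± 3 kb (half-open,
clamped at the chromosome origin), depth-normalizes each cell to 10,000 and
applies log1p — the same convention as the RNA normalization, so the two
modalities are comparable.

The label-transfer backend is a centroid classifier: shared genes are
z-scored on the reference, query cells are Pearson-correlated with each
class centroid, and a softmax over scaled correlations gives a score
simplex. Cells whose top score falls below the threshold (default 0.40) are
reported as "unclassified". Anchor-based transfer could be swapped in behind
the same operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import CellTable, CountMatrix, GeneAnnotation, PeakMatrix

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class GeneActivityMatrix:
    """Genes × cells accessibility summaries with raw and lognorm layers."""

    genes: list[str]
    cells: list[str]
    activity: np.ndarray
    lognorm: np.ndarray

    def cell_index(self, cells) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cells)}
        return np.array([pos[c] for c in cells], dtype=int)


def gene_activity(
    peaks: PeakMatrix,
    genes: GeneAnnotation,
    flank_bp: int = 3000,
    scale: float = 10_000.0,
) -> GeneActivityMatrix:
    """Sum open peaks over gene body ± flank, depth-normalize and log1p.

    Windows are [body_start − flank, body_end + flank), clamped at 0. Genes
    on chromosomes absent from the peak set get activity 0 (logged). Cells
    with zero total activity get all-zero lognorm (logged, not an error).
    """
    trees: dict[str, IntervalTree] = {}
    for i, (_, row) in enumerate(peaks.peaks.iterrows()):
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], i
        )
    n_cells = len(peaks.cells)
    activity = np.zeros((len(genes), n_cells))
    for gi, (g, row) in enumerate(genes.df.iterrows()):
        tree = trees.get(row["chrom"])
        if tree is None:
            log.info("gene %s: chromosome %s absent from peaks; activity 0",
                     g, row["chrom"])
            continue
        lo = max(0, int(row["body_start"]) - flank_bp)
        hi = int(row["body_end"]) + flank_bp
        idx = [iv.data for iv in tree.overlap(lo, hi)]
        if idx:
            activity[gi] = peaks.access[idx].sum(axis=0)
    totals = activity.sum(axis=0)
    zero = totals == 0
    if zero.any():
        log.info("%d cell(s) with zero gene activity", int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    lognorm = np.log1p(activity / safe[None, :] * scale)
    return GeneActivityMatrix(genes.gene_ids, list(peaks.cells), activity, lognorm)


@dataclass
class LabelTransfer:
    cell_id: str
    label: str
    scores: dict[str, float]

    @property
    def max_score(self) -> float:
        return max(self.scores.values())


class CentroidLabelTransfer:
    """Minimal fit/predict classifier behind :func:`transfer_labels`.

    fit: store per-gene reference mean/sd and per-class centroids on the
    z-scored shared genes. predict: softmax(correlation / temperature).
    """

    def __init__(self, temperature: float = 0.2):
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.temperature = temperature

    def fit(self, ref_lognorm: np.ndarray, labels: np.ndarray):
        self.mean_ = ref_lognorm.mean(axis=1)
        sd = ref_lognorm.std(axis=1)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        z = (ref_lognorm - self.mean_[:, None]) / self.sd_[:, None]
        self.classes_ = sorted(set(labels))
        self.centroids_ = np.column_stack(
            [z[:, labels == cl].mean(axis=1) for cl in self.classes_]
        )
        return self

    def predict_proba(self, query_lognorm: np.ndarray) -> np.ndarray:
        z = (query_lognorm - self.mean_[:, None]) / self.sd_[:, None]

        def _corr(u: np.ndarray, v: np.ndarray) -> float:
            uc, vc = u - u.mean(), v - v.mean()
            den = np.linalg.norm(uc) * np.linalg.norm(vc)
            return float(uc @ vc / den) if den > 0 else 0.0

        n_query = z.shape[1]
        scores = np.empty((n_query, len(self.classes_)))
        for j in range(n_query):
            r = np.array([_corr(z[:, j], self.centroids_[:, k])
                          for k in range(len(self.classes_))])
            e = np.exp((r - r.max()) / self.temperature)
            scores[j] = e / e.sum()
        return scores


def transfer_labels(
    reference: CountMatrix,
    ref_cells: CellTable,
    query: GeneActivityMatrix,
    min_ref_cells: int = 20,
    threshold: float = 0.40,
    temperature: float = 0.2,
    seed: int = 0,
) -> list[LabelTransfer]:
    """Transfer reference cluster labels onto query cells.

    Classes are reference clusters with at least ``min_ref_cells`` cells.
    Each query cell gets a score simplex over classes; the argmax label is
    assigned when the top score reaches ``threshold``, otherwise the cell is
    "unclassified". The backend is deterministic; ``seed`` is accepted for
    interface symmetry with the other stages.
    """
    del seed
    labels_all = ref_cells.df.loc[
        [c for c in reference.cells if c in ref_cells.df.index], "cluster"
    ]
    sizes = labels_all.value_counts()
    classes = sorted(sizes[sizes >= min_ref_cells].index)
    if len(classes) < 2:
        raise ValueError(
            f"fewer than 2 reference clusters have >= {min_ref_cells} cells"
        )
    shared = [g for g in reference.genes if g in set(query.genes)]
    if not shared:
        raise ValueError("no shared genes between reference and query")
    log.info("label transfer: %d classes, %d shared genes", len(classes),
             len(shared))

    keep_cells = labels_all.index[labels_all.isin(classes)]
    lognorm = reference.require_layer("lognorm")
    ref = lognorm[np.ix_(reference.gene_index(shared),
                         reference.cell_index(keep_cells))]
    qpos = {g: i for i, g in enumerate(query.genes)}
    qx = query.lognorm[[qpos[g] for g in shared]]

    model = CentroidLabelTransfer(temperature=temperature).fit(
        ref, labels_all.loc[keep_cells].to_numpy()
    )
    proba = model.predict_proba(qx)
    out = []
    for j, cell in enumerate(query.cells):
        scores = dict(zip(model.classes_, proba[j].astype(float)))
        best = max(scores, key=scores.get)
        label = best if scores[best] >= threshold else UNCLASSIFIED
        out.append(LabelTransfer(cell, label, scores))
    return out


def transfer_frame(results: list[LabelTransfer]) -> pd.DataFrame:
    classes = sorted(results[0].scores) if results else []
    rows = [
        [r.cell_id, r.label, r.max_score] + [r.scores[c] for c in classes]
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "label", "max_score"] + classes
    )


def unclassified_fraction(results: list[LabelTransfer]) -> float:
    if not results:
        return 0.0
    return sum(r.label == UNCLASSIFIED for r in results) / len(results)
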