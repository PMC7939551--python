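"""End-to-end orchestration: simulate → DE → organ tests → regulon → transfer,
with a JSON run manifest (parameters, seed, checksums, per-stage outputs) and
a report generator that re-emits tables and static figures from a completed
manifest without recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .de import balanced_de, membrane_de, results_frame
from .integration import gene_activity, transfer_frame, transfer_labels
from .organ_tests import (
    composition_test,
    cycle_test,
    gene_count_test,
    level_matrix,
    normalize_gate_composition,
    outcomes_frame,
)
from .preprocess import filter_genes_min_cells, normalize_lognorm
from .regulon import (
    assign_regions,
    coaccess_frame,
    kmeans_order,
    promoter_coaccessibility,
    score_region_accessibility,
    select_regulon_targets,
)
from .simulate import SimConfig, make_gene_annotation, simulate_atac, simulate_rna, small_fixture_config

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input data violates a precondition (CLI exit code 3)."""


@dataclasses.dataclass
class PipelineConfig:
    """Full pipeline configuration; every block mirrors one stage's defaults."""

    outdir: str = "out"
    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=lambda: {"fixture": "small"})
    de: dict = dataclasses.field(default_factory=dict)
    organ_tests: dict = dataclasses.field(default_factory=dict)
    regulon: dict = dataclasses.field(default_factory=dict)
    transfer: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def sim_config_from_block(block: dict, seed: int) -> SimConfig:
    block = dict(block)
    if block.pop("fixture", None) == "small":
        return small_fixture_config(seed=seed)
    if "coaccess_pairs" in block:
        block["coaccess_pairs"] = tuple(tuple(p) for p in block["coaccess_pairs"])
    if "cycle_fracs" in block:
        block["cycle_fracs"] = tuple(block["cycle_fracs"])
    try:
        return SimConfig(seed=seed, **block)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage on one synthetic cohort and write the run manifest.

    Identical config + seed give byte-identical outputs. A stage failure
    aborts with a stage-tagged message; outputs written so far are renamed
    with a ``.partial`` suffix.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }
    written: list[Path] = []

    def emit(stage: str, name: str, writer) -> Path:
        sdir = outdir / stage
        sdir.mkdir(exist_ok=True)
        path = sdir / name
        writer(path)
        written.append(path)
        return path

    try:
        # ------------------------------------------------------ simulate
        stage = "simulate"
        scfg = sim_config_from_block(cfg.simulate, cfg.seed)
        genes = make_gene_annotation(scfg)
        rna = simulate_rna(scfg)
        atac = simulate_atac(scfg, genes)
        log.info("simulate: %d RNA cells, %d genes, %d peaks, %d ATAC cells",
                 len(rna.cells), scfg.n_genes, len(atac.peaks.peaks),
                 len(atac.cells))
        emit(stage, "cells.tsv", lambda p: io.write_cell_table(rna.cells, p))
        emit(stage, "rna.mtx", lambda p: io.write_count_matrix(rna.matrix, p))
        emit(stage, "genes.tsv", lambda p: io.write_gene_annotation(genes, p))
        emit(stage, "regulon.tsv",
             lambda p: io.write_regulon_table(atac.regulon, p))
        emit(stage, "motifs.tsv", lambda p: io.write_motif_hits(atac.motifs, p))
        emit(stage, "atac_cells.tsv",
             lambda p: io.write_cell_table(atac.cells, p))
        bed = outdir / stage / "peaks.bed"
        io.write_peak_matrix(atac.peaks, outdir / stage / "access.mtx", bed)
        written += [outdir / stage / "access.mtx", bed]
        emit(stage, "rna_truth.tsv",
             lambda p: rna.truth.to_csv(p, sep="\t", index=False))
        emit(stage, "atac_truth.tsv",
             lambda p: atac.truth.to_csv(p, sep="\t", index=False))
        manifest["stages"][stage] = {"n_cells": len(rna.cells)}

        # ------------------------------------------------------------ de
        stage = "de"
        matrix = filter_genes_min_cells(rna.matrix,
                                        cfg.de.get("min_cells_per_gene", 10))
        log.info("de: %d genes after min-cells filter", len(matrix.genes))
        matrix = normalize_lognorm(matrix)
        group_by = cfg.de.get("group_by", "cluster")
        groups = cfg.de.get("groups")
        if groups is None:
            groups = sorted(rna.cells.df[group_by].unique())[:2]
        if len(groups) != 2:
            raise ConfigError("de.groups must name exactly two groups")
        ga = list(rna.cells.df.index[rna.cells.df[group_by] == groups[0]])
        gb = list(rna.cells.df.index[rna.cells.df[group_by] == groups[1]])
        if not ga or not gb:
            raise DataError(f"empty DE group among {groups}")
        gene_list = cfg.de.get("gene_list")
        if gene_list:
            sel, res = membrane_de(matrix, ga, gb, gene_list,
                                   n_reps=cfg.de.get("reps", 1001),
                                   seed=cfg.seed)
        else:
            sel, res = balanced_de(matrix, ga, gb,
                                   n_reps=cfg.de.get("reps", 1001),
                                   seed=cfg.seed)
        de_frame = results_frame(res)
        emit(stage, "de.tsv",
             lambda p: de_frame.to_csv(p, sep="\t", index=False))
        manifest["stages"][stage] = {
            "groups": list(groups),
            "median_of_medians": sel.median_of_medians,
            "n_kept": int(de_frame["kept"].sum()),
        }

        # ----------------------------------------------------- organ tests
        stage = "organ_tests"
        comp = normalize_gate_composition(rna.cells)
        global_p, comp_out = composition_test(comp)
        gc_out = gene_count_test(
            rna.cells, n_reps=cfg.organ_tests.get("reps", 1001),
            min_cells=cfg.organ_tests.get("min_cells", 20), seed=cfg.seed,
        )
        cyc_out = cycle_test(rna.cells)
        outcomes = comp_out + gc_out + cyc_out
        frame = outcomes_frame(outcomes)
        emit(stage, "tests.tsv", lambda p: frame.to_csv(p, sep="\t", index=False))
        emit(stage, "levels.tsv",
             lambda p: level_matrix(outcomes).to_csv(p, sep="\t"))
        manifest["stages"][stage] = {"global_composition_p": global_p,
                                     "n_outcomes": len(outcomes)}

        # --------------------------------------------------------- regulon
        stage = "regulon"
        tf = cfg.regulon.get("tf", scfg.tf_name)
        targets = select_regulon_targets(
            atac.regulon, tf, cfg.regulon.get("min_importance", 4.0)
        )
        if not targets:
            raise DataError(f"no {tf} regulon targets above threshold")
        assignments = assign_regions(genes, atac.peaks, atac.motifs, tf,
                                     gene_ids=targets)
        scores = score_region_accessibility(atac.peaks, assignments, atac.cells)
        order = kmeans_order(scores, k=min(5, len(scores)), seed=cfg.seed)
        lineage_sets = cfg.regulon.get("lineage_sets")
        if lineage_sets is None and scfg.coaccess_pairs:
            ga_, gb_ = scfg.coaccess_pairs[0]
            lineage_sets = {"lineage_a": [ga_], "lineage_b": [gb_]}
        coacc = []
        if lineage_sets:
            all_assign = assign_regions(
                genes, atac.peaks, atac.motifs, tf,
                gene_ids=sorted({g for gl in lineage_sets.values() for g in gl}),
            )
            for cl in cfg.regulon.get("coaccess_clusters", scfg.clusters[:1]):
                coacc += promoter_coaccessibility(
                    atac.peaks, all_assign, atac.cells, lineage_sets, cl
                )
        assign_df = pd.DataFrame(
            [(a.gene_id, a.region_kind, ",".join(a.peak_ids))
             for a in assignments],
            columns=["gene", "region_kind", "peak_ids"],
        )
        emit(stage, "assignments.tsv",
             lambda p: assign_df.to_csv(p, sep="\t", index=False))
        emit(stage, "scores.tsv", lambda p: scores.to_csv(p, sep="\t"))
        emit(stage, "scores_ordered.tsv",
             lambda p: scores.loc[order].to_csv(p, sep="\t"))
        cdf = coaccess_frame(coacc)
        emit(stage, "coaccess.tsv", lambda p: cdf.to_csv(p, sep="\t", index=False))
        manifest["stages"][stage] = {"tf": tf, "n_targets": len(targets),
                                     "n_coaccess": len(coacc)}

        # -------------------------------------------------------- transfer
        stage = "transfer"
        activity = gene_activity(atac.peaks, genes)
        labels = transfer_labels(
            matrix, rna.cells, activity,
            min_ref_cells=cfg.transfer.get("min_ref_cells", 20),
            threshold=cfg.transfer.get("threshold", 0.40),
            seed=cfg.seed,
        )
        tdf = transfer_frame(labels)
        emit(stage, "labels.tsv", lambda p: tdf.to_csv(p, sep="\t", index=False))
        manifest["stages"][stage] = {
            "n_query": len(labels),
            "unclassified_fraction":
                float((tdf["label"] == "unclassified").mean()),
        }
    except (ConfigError, DataError):
        _mark_partial(written)
        raise
    except Exception as exc:
        _mark_partial(written)
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _mark_partial(written: list[Path]) -> None:
    for p in written:
        if p.exists():
            p.rename(p.with_suffix(p.suffix + ".partial"))


def report(manifest_path) -> list[Path]:
    """Emit tabular and graphical analogues of the published summary panels
    from a completed manifest. No recomputation; checksums are verified."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ConfigError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if "outputs" not in manifest:
        raise DataError("incomplete manifest: missing outputs block")
    outdir = manifest_path.parent
    for rel, digest in manifest["outputs"].items():
        path = outdir / rel
        if not path.exists() or _sha256(path) != digest:
            raise DataError(f"checksum mismatch for {rel}")

    rdir = outdir / "report"
    rdir.mkdir(exist_ok=True)
    produced: list[Path] = []

    def table(src: str, dst: str) -> pd.DataFrame:
        df = pd.read_csv(outdir / src, sep="\t")
        path = rdir / dst
        df.to_csv(path, sep="\t", index=False)
        produced.append(path)
        return df

    levels = table("organ_tests/levels.tsv", "test_levels.tsv")
    de = table("de/de.tsv", "de_table.tsv")
    coacc = table("regulon/coaccess.tsv", "coaccessibility.tsv")
    labels = table("transfer/labels.tsv", "label_transfer.tsv")

    # level heatmap
    fig, ax = plt.subplots(figsize=(6, 4))
    mat = levels.set_index("cluster")
    ax.imshow(mat.to_numpy(dtype=float), cmap="viridis_r", vmin=0, vmax=3,
              aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.set_title("significance levels by cluster and test")
    produced.append(_savefig(fig, rdir / "test_levels.png"))

    # volcano
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        ax.scatter(de["log2fc"], -np.log10(de["padj"].clip(lower=1e-300)),
                   s=8, c=np.where(de["kept"] & (de["padj"] < 0.05), "C3", "C7"))
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 adjusted p")
    produced.append(_savefig(fig, rdir / "de_volcano.png"))

    # co-accessibility bars
    fig, ax = plt.subplots(figsize=(5, 4))
    if len(coacc):
        names = coacc["lineage_a"] + "-" + coacc["lineage_b"] + "\n" + coacc[
            "cluster"]
        ax.bar(names, coacc["odds_ratio"], color="C0")
        ax.axhline(1.0, color="k", lw=0.8)
    ax.set_ylabel("odds ratio")
    produced.append(_savefig(fig, rdir / "coaccessibility.png"))

    # transfer composition
    fig, ax = plt.subplots(figsize=(5, 4))
    frac = labels["label"].value_counts(normalize=True).sort_index()
    ax.bar(frac.index, frac.to_numpy(), color="C2")
    ax.set_ylabel("fraction of query cells")
    ax.tick_params(axis="x", rotation=45)
    produced.append(_savefig(fig, rdir / "transfer_composition.png"))
    return produced


def _savefig(fig, path: Path) -> Path:
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
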