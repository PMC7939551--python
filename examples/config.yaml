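# Annotated pipeline configuration for `hemapriming run-all --config config.yaml`.
# CLI flags (--seed, --outdir) override the values here.

outdir: out          # all stage outputs and the run manifest land here
seed: 7              # single integer seed driving every random draw

# ---------------------------------------------------------------- simulate
# Either `fixture: small` (packaged 3-cluster, 200-cell cohort) or any
# SimConfig field. `cells_per_cluster_per_organ` entries are EXPECTED
# counts: cluster labels are drawn multinomially per organ.
simulate:
  fixture: small
  # n_clusters: 6
  # cells_per_cluster_per_organ: {liver: 100, femur: 100}
  # n_genes: 300
  # nb_mean: 2.0               # negative-binomial base mean per gene
  # nb_dispersion: 0.5         # var = mu + dispersion * mu^2
  # marker_genes_per_cluster: 10
  # marker_log2fc: 1.0         # 0 disables planted markers (null cohort)
  # organ_gene_count_shift: 0.0  # fractional femur mapped-read inflation
  # cycle_fracs: [0.6, 0.25, 0.15]   # (G1, S, G2M)
  # promoter_open_prob: 0.3
  # enhancer_open_prob: 0.2
  # coaccess_rho: 0.0          # shared-latent promoter co-open strength
  # coaccess_pairs: [[G000, G001]]

# ---------------------------------------------------------------------- de
de:
  reps: 1001          # balanced-subsampling repetitions (must be odd)
  # group_by: cluster
  # groups: [C0, C1]
  # gene_list: null    # optional membrane gene list (restricts tested genes)
  # min_cells_per_gene: 10

# --------------------------------------------------------------- organ tests
organ_tests:
  reps: 1001          # subsample repetitions for the gene-count KS/MWW tests
  min_cells: 20       # clusters below this per-organ count are skipped

# ------------------------------------------------------------------- regulon
regulon:
  min_importance: 4   # strictly-greater-than threshold on regulon targets
  # tf: TF1
  # lineage_sets: {ery: [G000], mk: [G001]}
  # coaccess_clusters: [C0]

# ------------------------------------------------------------------ transfer
transfer:
  threshold: 0.40     # prediction-score floor; below it -> "unclassified"
  min_ref_cells: 20   # reference clusters smaller than this are dropped
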