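# tamscape

Regional analysis of tumor-associated macrophages (TAMs) from single-cell and
bulk RNA-seq.

Glioblastoma tissue is not homogeneous: the hypoxic tumour core and the
invading periphery host macrophage populations that differ in origin
(bone-marrow-derived macrophages, BMDM, vs brain-resident microglia), in
activation state, and in how they mature.  `tamscape` packages the analysis
chain needed to dissect those differences from a gene × cell count matrix
with core/periphery labels:

* **Meta-gene scoring** — for a gene list *S* in a log-normalized,
  gene-centered matrix, the per-cell score is
  `mean_{g∈S} x_gc − mean_{g∉S} x_gc` (Tirosh-style module scoring).
* **Activation indices** — a signature-based surrogate for the macrophage
  polarization index (MPI, higher = more pro-inflammatory) and the
  activation-induced macrophage differentiation index (AMDI, higher = more
  mature), each a difference of meta-gene scores rescaled to [−50, 50];
  the sign quadrant of (AMDI, MPI) classifies cells into M0, M1
  pre-activation, M1-like and M2-like states.
* **Composition statistics** — core-vs-periphery 2×2 contingency tables per
  cell type / activation state with Yates-corrected chi-squared p-values,
  and exact/normal Mann–Whitney tests for ligand-density comparisons.
* **Ligand–receptor loop ranking** — a layered graph
  state → ligand → receptor → state with expression-fraction edge weights;
  a node's importance within a state is the summed weight of all 3-edge
  loops through it.
* **Ontogeny separability** — BMDM and microglia meta-gene scores per cell,
  a radial-kernel SVM (10-fold CV on a 70% split) predicting region from
  the two scores with held-out ROC/AUC, DeLong tests between states, and
  bulk validation with the five-structure anatomic vocabulary (leading
  edge / infiltrating tumour → periphery; cellular tumour / microvascular
  proliferation / pseudopalisading cells → core).
* **Principal-tree pseudotime** — Census-style relative counts,
  density-peak clustering of a 2-D embedding, ordering-gene selection by a
  negative-binomial GLM likelihood-ratio test, an alternating-optimization
  principal tree, and pseudotime measured as geodesic distance from a root
  placed at the terminal end of the lowest-mean-AMDI segment.
* **Branch analysis** — per-gene NB GLM LRT of a spline × branch
  interaction (BH q < 0.05 ⇒ branch-dependent), Ward clustering of
  smoothed expression curves, divergence scoring of cluster meta-genes
  between branch termini, hypergeometric over-representation, and bulk
  meta-gene correlation.
* **Synthetic data** — a seeded generator that emulates the study design
  (negative-binomial counts, core/periphery split, ontogeny mixing, a
  Y-shaped latent trajectory, state-dependent ligand/receptor panels,
  branch-specific pathway programs, Ivy-style bulk mixtures) with full
  ground truth for parameter-recovery testing.

## Worked example

Simulate a dataset and run the core-region pipeline:

```sh
tamscape simulate --config syn.yaml --out data/ --seed 4
tamscape run --config pipeline.yaml --region core
```

with `syn.yaml` containing e.g. `{n_cells_core: 500, n_cells_periphery: 250,
n_genes: 600}` and `pipeline.yaml` pointing at the generated
`matrix.mtx`, `signatures.gmt` and `pairs.tsv`.  The run prints a JSON
summary; on the seed-4 dataset above it ends with

```
"state_counts": {"M0": 134, "M1-like": 107, "M1-pre": 104, "M2-like": 127},
"trajectory": {
    "n_states": 3, "n_branch_points": 1,
    "amdi_pseudotime_r": 0.718, "amdi_pseudotime_p": 5.6e-76,
    "mpi_pseudotime_r": 0.303, "mpi_pseudotime_p": 1.9e-11
},
"branching": {"n_tested": 600, "n_branch_dependent": 45,
              "n_gene_clusters": 2, "divergent_clusters": [1, 2]}
```

Read: the fitted tree has one branch point and three segments; maturity
(AMDI) rises strongly along pseudotime (r = 0.72) and, in this core-like
wiring, polarization (MPI) rises with it (r = 0.30) — cells become more
pro-inflammatory as they mature.  45 genes change differently along the two
output branches and fall into two curve clusters, both of which diverge
strongly (≥ 1 pooled SD) between the branch termini.  Per-cell scores,
composition tables, pseudotime, tree edges and branch statistics are
written as TSV artifacts with the seed and a parameter hash in the header.

The same steps are available as library functions (`tamscape.scores`,
`tamscape.trajectory`, `tamscape.branching`, ...) for use on real matrices
read with `tamscape.read_counts` (MatrixMarket + sidecars, or dense TSV).

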