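"""End-to-end regional TAM analysis orchestration.

``run_regional_analysis`` wires the stages together for one region's cells:
QC filtering and normalization, MPI/AMDI activation scoring, composition
tables, ligand-receptor density and loop ranking, ontogeny scoring,
principal-tree pseudotime, and branch-point analysis.  Every artifact is a
TSV with a header comment carrying the seed and a parameter hash, plus a
JSON run summary; identical config + seed reproduce all outputs
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import composition_table
from .ingest import (
    CountMatrix,
    NormMatrix,
    filter_cells_depth_outliers,
    filter_genes_min_cells,
    lognormalize,
    read_counts,
    read_gmt,
    regress_out_label,
)
from .ligrec import (
    PairTable,
    build_graph,
    density_by_group,
    filter_panel,
    pair_receptors,
    per_cell_density,
    rank_nodes,
)
from .ontogeny import ontogeny_scores, region_separability
from .scores import GeneSignature, activation_scores
from . import branching as br
from . import trajectory as tj

logger = logging.getLogger("tamscape.pipeline")

SIGNATURE_KEYS = ("pol_pos", "pol_neg", "dif_pos", "dif_neg", "bmdm", "mg")


@dataclass
class PipelineConfig:
    counts: str
    signatures: str  # GMT with entries pol_pos/pol_neg/dif_pos/dif_neg/bmdm/mg
    out_dir: str
    counts_format: str = "mtx"
    pair_table: str | None = None
    ligands: list = field(default_factory=list)  # ligand panel gene ids
    bulk: str | None = None
    bulk_meta: str | None = None
    seed: int = 0
    min_cells_per_gene: int = 10
    depth_outlier_sd: float = 2.0
    min_expression_frac: float = 0.05
    dp_quantile: float = 0.95
    ordering_top_n: int = 1000
    latent_dim: int = 2
    n_centroids: int | None = None
    branch_q_threshold: float = 0.05
    ligrec_enabled: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for key in ("counts", "signatures"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config.{key}: {p} does not exist")
        if self.ligrec_enabled and self.pair_table is None:
            raise ValueError("ligrec stage enabled but no pair_table configured")
        for key in ("pair_table", "bulk", "bulk_meta"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config.{key}: {p} does not exist")

    def params_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "out_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, phash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tamscape {__version__} seed={seed} params={phash}\n")
        df.to_csv(fh, sep="\t", index=index)


def load_signatures(path) -> dict:
    sets = read_gmt(path)
    missing = [k for k in SIGNATURE_KEYS if k not in sets]
    if missing:
        raise ValueError(f"signature GMT lacks required entries: {missing}")
    return {name: GeneSignature(name, genes) for name, genes in sets.items()}


def branch_point_cells(model: tj.TrajectoryModel) -> list:
    """Downstream cell sets per branch point of an ordered tree.

    For each branch point, removing its node splits the tree; the component
    holding the root is upstream, and the two largest remaining components
    (by assigned cells) are the output branches A and B.  Returns one dict
    per branch point with the downstream cell indices and branch labels.
    """
    if model.pseudotime is None or model.root_node is None:
        raise ValueError("order the tree (order_pseudotime) before extracting branches")
    g = model.graph()
    out = []
    for b in model.branch_points:
        h = g.copy()
        h.remove_node(b)
        import networkx as nx

        comps = [c for c in nx.connected_components(h)]
        down = [c for c in comps if model.root_node not in c]
        if len(down) < 2:
            continue
        sizes = [
            int(np.isin(model.cell_assignment, list(c)).sum()) for c in down
        ]
        top2 = np.argsort(sizes)[::-1][:2]
        nodes_a, nodes_b = down[top2[0]], down[top2[1]]
        in_a = np.isin(model.cell_assignment, list(nodes_a))
        in_b = np.isin(model.cell_assignment, list(nodes_b))
        idx = np.where(in_a | in_b)[0]
        labels = np.where(in_a[idx], "A", "B").astype(object)
        out.append({"branch_point": b, "cell_idx": idx, "branch": labels})
    return out


def run_regional_analysis(
    cfg: PipelineConfig, region: str, counts: CountMatrix | None = None
) -> dict:
    """Execute the full stage chain for one region ('core', 'periphery' or 'all')."""
    t_start = time.time()
    cfg.validate()
    if region not in ("core", "periphery", "all"):
        raise ValueError("region must be 'core', 'periphery' or 'all'")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phash = cfg.params_hash()
    summary: dict = {
        "version": __version__, "seed": cfg.seed, "region": region,
        "params_hash": phash, "parameters": {k: v for k, v in cfg.__dict__.items()},
    }
    bundle: dict = {}
    stage = "ingest"
    try:
        cm = counts if counts is not None else read_counts(cfg.counts, cfg.counts_format)
        if region != "all":
            cm = cm.subset_cells(np.asarray(cm.cell_meta["region"]) == region)
            if cm.n_cells == 0:
                raise ValueError(f"no cells in region {region!r}")
        logger.info("ingest: %d genes x %d cells", cm.n_genes, cm.n_cells)
        cm = filter_cells_depth_outliers(cm, cfg.depth_outlier_sd)
        cm = filter_genes_min_cells(cm, cfg.min_cells_per_gene)
        nm = lognormalize(cm)
        nm = regress_out_label(nm, np.asarray(cm.cell_meta["tumor_id"]))
        sigs = load_signatures(cfg.signatures)
        bundle["counts"] = cm

        stage = "scores"
        prof = activation_scores(nm, sigs["pol_pos"], sigs["pol_neg"],
                                 sigs["dif_pos"], sigs["dif_neg"])
        onto = ontogeny_scores(nm, sigs["bmdm"], sigs["mg"])
        score_tab = pd.DataFrame(
            {"MPI": prof.mpi, "AMDI": prof.amdi, "state": prof.state,
             "bmdm_score": onto.bmdm_score, "mg_score": onto.mg_score},
            index=pd.Index(cm.cell_ids, name="cell_id"),
        )
        _write_tsv(score_tab, out_dir / f"scores_{region}.tsv", cfg.seed, phash)
        bundle["scores"] = score_tab

        stage = "composition"
        comp = composition_table(prof.state, np.asarray(cm.cell_meta["region"]),
                                 state_order=["M1-like", "M2-like", "M1-pre", "M0"])
        _write_tsv(comp, out_dir / f"composition_{region}.tsv", cfg.seed, phash)
        bundle["composition"] = comp
        summary["n_cells"] = int(cm.n_cells)
        summary["state_counts"] = comp["all_n"].to_dict()

        if cfg.ligrec_enabled and cfg.pair_table:
            stage = "ligrec"
            pairs = PairTable.read(cfg.pair_table)
            panel = cfg.ligands or sorted(set(pairs.pairs["ligand"]))
            ligands = filter_panel(cm, panel, cfg.min_expression_frac)
            receptors = pair_receptors(ligands, pairs, cm, cfg.min_expression_frac)
            if ligands and receptors:
                lig_density = per_cell_density(cm, ligands)
                rec_density = per_cell_density(cm, receptors)
                imm, mat = ("M0", "M1-pre"), ("M1-like", "M2-like")
                stats = []
                for name, dens in (("ligand", lig_density), ("receptor", rec_density)):
                    ma, mb, p = density_by_group(dens, prof.state, (imm, mat))
                    stats.append({"panel": name, "mean_immature": ma,
                                  "mean_mature": mb, "mw_p": p})
                dens_tab = pd.DataFrame(stats).set_index("panel")
                _write_tsv(dens_tab, out_dir / f"ligrec_density_{region}.tsv",
                           cfg.seed, phash)
                graph = build_graph(cm, prof.state, ligands, receptors, pairs)
                ranks = pd.concat(
                    [rank_nodes(graph, s) for s in graph.states], ignore_index=True
                )
                _write_tsv(ranks, out_dir / f"ligrec_importance_{region}.tsv",
                           cfg.seed, phash, index=False)
                bundle["ligrec"] = {"graph": graph, "ranks": ranks,
                                    "density": dens_tab}
            else:
                warnings.warn("empty ligand or receptor panel after filtering")

        if region == "all":
            stage = "ontogeny"
            roc = region_separability(
                onto, np.asarray(cm.cell_meta["region"]), prof.state, seed=cfg.seed
            )
            summary["ontogeny_auc"] = {s: r.auc for s, r in roc.items()}
            bundle["ontogeny_roc"] = roc

        stage = "trajectory"
        emb = tj.embed_2d(nm.values, seed=cfg.seed)
        dp = tj.density_peak_cluster(emb, quantile=cfg.dp_quantile)
        n_clusters = len(np.unique(dp.labels))
        summary["dp_clusters"] = int(n_clusters)
        if n_clusters < 2:
            raise ValueError("density-peak clustering found a single cluster; "
                             "lower dp_quantile")
        ordering = tj.select_ordering_genes(cm, dp.labels, cfg.ordering_top_n,
                                            cfg.min_expression_frac)
        idx = nm.gene_index(ordering)
        sub = NormMatrix(nm.values[idx], nm.gene_ids[idx], nm.cell_meta,
                         nm.transform_log)
        model = tj.fit_principal_tree(sub, latent_dim=cfg.latent_dim,
                                      n_centroids=cfg.n_centroids, seed=cfg.seed)
        tj.order_pseudotime(model, prof.amdi)
        pt_tab = pd.DataFrame(
            {"state": model.state, "pseudotime": model.pseudotime},
            index=pd.Index(cm.cell_ids, name="cell_id"),
        )
        _write_tsv(pt_tab, out_dir / f"pseudotime_{region}.tsv", cfg.seed, phash)
        edge_tab = pd.DataFrame(model.edges, columns=["node_a", "node_b"])
        _write_tsv(edge_tab, out_dir / f"tree_edges_{region}.tsv", cfg.seed, phash,
                   index=False)
        r_amdi, p_amdi = tj.correlate_score_pseudotime(model.pseudotime, prof.amdi)
        r_mpi, p_mpi = tj.correlate_score_pseudotime(model.pseudotime, prof.mpi)
        summary["trajectory"] = {
            "n_states": len(set(model.node_state.values())),
            "n_branch_points": len(model.branch_points),
            "amdi_pseudotime_r": r_amdi, "amdi_pseudotime_p": p_amdi,
            "mpi_pseudotime_r": r_mpi, "mpi_pseudotime_p": p_mpi,
        }
        bundle["trajectory"] = model

        stage = "branching"
        branches = branch_point_cells(model)
        if branches:
            info = branches[0]
            idx = info["cell_idx"]
            cmd = cm.subset_cells(idx)
            res = br.branch_dependence_test(
                cmd, model.pseudotime[idx], info["branch"],
                q_threshold=cfg.branch_q_threshold,
            )
            _write_tsv(res.table, out_dir / f"branch_test_{region}.tsv",
                       cfg.seed, phash)
            bundle["branch_test"] = res
            dep = res.branch_dependent_genes
            summary["branching"] = {"branch_point": int(info["branch_point"]),
                                    "n_tested": int(len(res.table)),
                                    "n_branch_dependent": int(len(dep))}
            if len(dep) >= 2:
                nmd = lognormalize(cmd)
                curves = br.smooth_curves(nmd, model.pseudotime[idx],
                                          info["branch"], dep)
                cc = br.cluster_branch_genes(curves)
                div = br.divergent_clusters(cc, nmd, model.pseudotime[idx],
                                            info["branch"])
                clu_tab = cc.labels.rename("cluster").to_frame()
                clu_tab.index.name = "gene"
                _write_tsv(clu_tab, out_dir / f"branch_clusters_{region}.tsv",
                           cfg.seed, phash)
                _write_tsv(div, out_dir / f"branch_divergence_{region}.tsv",
                           cfg.seed, phash)
                bundle["branch_clusters"] = cc
                bundle["branch_divergence"] = div
                summary["branching"]["n_gene_clusters"] = int(cc.n_clusters)
                summary["branching"]["divergent_clusters"] = [
                    int(i) for i in div.index[div["selected"]]
                ]
        else:
            summary["branching"] = {"n_branch_dependent": 0,
                                    "note": "no branch point recovered"}
    except Exception as exc:
        (out_dir / f"FAILED_{region}.txt").write_text(
            f"stage={stage}\nerror={exc!r}\n"
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary["runtime_s"] = round(time.time() - t_start, 2)
    with open(out_dir / f"summary_{region}.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    bundle["summary"] = summary
    return bundle


def run_table_stats(states, regions, state_order=None) -> pd.DataFrame:
    """Composition report with printed-precision percentages and chi-squared p.

    Accepts aligned per-cell state and region labels; single-region input
    yields a table with the p column blank.
    """
    regions = np.asarray(regions, dtype=object)
    tab = composition_table(states, regions, state_order)
    out = tab.copy()
    out["p_printed"] = [
        "" if not np.isfinite(p) else (f"{p:.3f}" if p >= 0.001 else "< 0.0001")
        for p in tab["p"]
    ]
    return out
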