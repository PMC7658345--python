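"""Pseudotime trajectory stage.

The stage mirrors the classic single-cell trajectory recipe: counts are
converted to relative transcript counts (Census-style mode scaling), a 2-D
embedding is clustered with density-peak clustering, ordering genes are
picked by a negative-binomial GLM likelihood-ratio test against the cluster
labels, a principal tree is fit by alternating optimization, tree segments
("states") and branch points are extracted, and pseudotime is the geodesic
distance along the tree from a root placed at the terminal end of the state
with the lowest mean maturity (AMDI) score.

The principal-tree objective is

    J = ||X - W Z||^2 + lambda * sum_i ||z_i - y_c(i)||^2
        + gamma * sum_{(k,l) in T} ||y_k - y_l||^2

with X the (features x cells) input, W an orthogonal-ish linear map to the
latent space, Z latent cell coordinates, Y centroids, c(.) hard assignments
and T a spanning tree over centroids.  Every update (W, Z, assignments, Y,
T=MST) is an exact coordinate-descent step, so J is monotone non-increasing;
this is asserted on every run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import gaussian_kde, nbinom, pearsonr
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .ingest import CountMatrix, NormMatrix


# ---------------------------------------------------------------------------
# Census-style relative counts
# ---------------------------------------------------------------------------

def census_normalize(m: CountMatrix, min_nonzero: int = 10) -> np.ndarray:
    """Convert counts to relative transcript counts by per-cell mode scaling.

    For each cell the log10 distribution of nonzero relative expression
    (count/total) is examined; the observed value with the highest kernel
    density is taken as the mode, and the cell is rescaled so that the modal
    relative expression maps to one transcript.  Cells with fewer than
    ``min_nonzero`` expressed genes fall back to scaling by the number of
    expressed genes (a uniform-profile mode proxy) with a warning.
    """
    dense = m.dense().astype(float)
    totals = dense.sum(axis=0)
    out = np.zeros_like(dense)
    fallback = 0
    for c in range(m.n_cells):
        col = dense[:, c]
        nz = col > 0
        if totals[c] == 0:
            continue
        rel = col / totals[c]
        vals = np.log10(rel[nz])
        if nz.sum() < min_nonzero or np.ptp(vals) == 0:
            fallback += 1
            out[:, c] = rel * nz.sum()
            continue
        kde = gaussian_kde(vals)
        uniq = np.unique(vals)
        mode_log = uniq[np.argmax(kde(uniq))]
        out[:, c] = rel / (10.0**mode_log)
    if fallback:
        warnings.warn(f"{fallback} cells used the depth-scaling fallback (<{min_nonzero} "
                      "expressed genes or a degenerate expression distribution)")
    return out


# ---------------------------------------------------------------------------
# Density-peak clustering (Rodriguez & Laio style)
# ---------------------------------------------------------------------------

@dataclass
class DensityPeakResult:
    density: np.ndarray  # local density P
    delta: np.ndarray  # distance to nearest higher-density point D
    peaks: np.ndarray  # boolean peak flags
    labels: np.ndarray  # integer cluster labels


def density_peak_cluster(
    points: np.ndarray, quantile: float = 0.95, bandwidth: float | None = None
) -> DensityPeakResult:
    """Cluster 2-D points by local density and separation.

    P(i) is a Gaussian kernel density; unless given, the bandwidth is a
    local scale, the median distance to the ceil(sqrt(n))-th nearest
    neighbor (a global pairwise-distance scale oversmooths well-separated
    groups).  D(i) is the distance to the nearest point with
    strictly higher density, with the global density maximum assigned the
    maximum pairwise distance.  Peaks are decision-graph outliers: points
    whose separation D and density-separation product P*D both reach their
    empirical ``quantile`` (thresholding P directly is brittle when equally
    dense groups compete for the top density ranks); every other point
    inherits the label
    of its nearest higher-density neighbor, traced in decreasing-density
    order.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n == 1:
        return DensityPeakResult(np.array([1.0]), np.array([0.0]),
                                 np.array([True]), np.array([0]))
    dist = squareform(pdist(pts))
    if dist.max() == 0:  # all points identical
        return DensityPeakResult(np.ones(n), np.zeros(n),
                                 np.eye(1, n, 0, dtype=bool).ravel(), np.zeros(n, int))
    if bandwidth is None:
        k = min(int(np.ceil(np.sqrt(n))), n - 1)
        knn_dist = np.sort(dist, axis=1)[:, k]
        bandwidth = float(np.median(knn_dist))
    if bandwidth <= 0:
        bandwidth = dist[dist > 0].min()
    kernel = np.exp(-(dist**2) / (2 * bandwidth**2))
    np.fill_diagonal(kernel, 0.0)
    density = kernel.sum(axis=1)
    order = np.argsort(-density, kind="stable")
    delta = np.empty(n)
    nearest_higher = np.full(n, -1)
    for rank, i in enumerate(order):
        if rank == 0:
            delta[i] = dist.max()
            continue
        higher = order[:rank]
        j = higher[np.argmin(dist[i, higher])]
        delta[i] = dist[i, j]
        nearest_higher[i] = j
    gamma = density * delta  # decision-graph outlier score
    g_thr = np.quantile(gamma, quantile)
    # a mode closer than ~2 kernel widths to a denser mode is not resolvable
    d_thr = max(np.quantile(delta, quantile), 2.0 * bandwidth)
    peaks = (gamma >= g_thr) & (delta >= d_thr)
    if not peaks.any():
        peaks[order[0]] = True
    labels = np.full(n, -1)
    next_label = 0
    for i in order:
        if peaks[i]:
            labels[i] = next_label
            next_label += 1
        else:
            labels[i] = labels[nearest_higher[i]]
    return DensityPeakResult(density, delta, peaks, labels)


def embed_2d(values: np.ndarray, method="pca", seed: int = 0, n_components: int = 2):
    """Commodity 2-D embedding of a genes x cells matrix (cells become rows).

    ``method`` may be 'pca' or any callable mapping a cells x genes array to
    a cells x 2 array; the embedding is a pluggable commodity step.
    """
    X = np.asarray(values, dtype=float).T
    if callable(method):
        return np.asarray(method(X), dtype=float)
    if method == "pca":
        return PCA(n_components=n_components, random_state=seed).fit_transform(X)
    raise ValueError(f"unknown embedding method {method!r}")


# ---------------------------------------------------------------------------
# Ordering-gene selection (dpFeature-style NB GLM LRT)
# ---------------------------------------------------------------------------

def _mom_dispersion(y: np.ndarray, floor: float = 1e-4) -> float:
    """Method-of-moments NB2 dispersion alpha in var = mu + alpha mu^2."""
    mu = y.mean()
    if mu <= 0:
        return floor
    v = y.var()
    return max((v - mu) / mu**2, floor)


def _nb_loglike(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    mu = np.maximum(mu, 1e-8)
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(nbinom.logpmf(y, r, p).sum())


def nb_lrt_groups(y: np.ndarray, groups: np.ndarray) -> tuple:
    """NB LRT of a per-group-mean model vs a single-mean model.

    For a group-indicator design with fixed dispersion the NB maximum
    likelihood estimate of each group mean is the group sample mean, so the
    likelihood ratio is available in closed form.  Returns (stat, p, df).
    """
    alpha = _mom_dispersion(y)
    uniq = np.unique(groups)
    mu_full = np.empty_like(y, dtype=float)
    for g in uniq:
        sel = groups == g
        mu_full[sel] = y[sel].mean()
    ll_full = _nb_loglike(y, mu_full, alpha)
    ll_null = _nb_loglike(y, np.full(len(y), y.mean()), alpha)
    stat = max(2 * (ll_full - ll_null), 0.0)
    df = len(uniq) - 1
    return stat, float(chi2_dist.sf(stat, df)), df


def select_ordering_genes(
    m: CountMatrix,
    clusters,
    top_n: int = 1000,
    min_frac: float = 0.05,
    min_cluster_cells: int = 3,
    return_table: bool = False,
):
    """Top genes separating density-peak clusters, by NB GLM likelihood ratio.

    Genes expressed in fewer than ``min_frac`` of cells are not tested.
    Clusters smaller than ``min_cluster_cells`` are merged into the cluster
    with the nearest mean profile.  Genes are ranked by ascending BH
    q-value (ties by p, then gene id) and the ``top_n`` best are returned.
    """
    clusters = np.asarray(clusters).copy()
    dense = m.dense()
    uniq, counts = np.unique(clusters, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two clusters")
    small = uniq[counts < min_cluster_cells]
    if small.size:
        centroids = {g: dense[:, clusters == g].mean(axis=1) for g in uniq}
        for g in small:
            others = [h for h in uniq if h not in small]
            if not others:
                raise ValueError("all clusters below the minimum size")
            nearest = min(others, key=lambda h: np.linalg.norm(centroids[g] - centroids[h]))
            warnings.warn(f"cluster {g} has <{min_cluster_cells} cells; merged into {nearest}")
            clusters[clusters == g] = nearest
    frac = np.asarray((m.counts > 0).sum(axis=1)).ravel() / m.n_cells
    testable = np.where(frac >= min_frac)[0]
    rows = []
    for gi in testable:
        y = np.asarray(dense[gi, :]).ravel()
        stat, p, _ = nb_lrt_groups(y, clusters)
        rows.append((m.gene_ids[gi], stat, p))
    tab = pd.DataFrame(rows, columns=["gene", "lrt_stat", "p"])
    tab["q"] = multipletests(tab["p"].values, method="fdr_bh")[1]
    tab = tab.sort_values(["q", "p", "gene"], kind="stable").reset_index(drop=True)
    if top_n > len(tab):
        warnings.warn(f"top_n={top_n} exceeds {len(tab)} testable genes; returning all")
    selected = list(tab["gene"].head(top_n))
    if return_table:
        return selected, tab
    return selected


# ---------------------------------------------------------------------------
# Principal tree
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryModel:
    centroids: np.ndarray  # K x d latent centroids
    edges: list  # (k, l) undirected spanning-tree edges
    cell_assignment: np.ndarray  # per-cell centroid index
    cell_coords: np.ndarray  # per-cell latent coordinates (n x d)
    state: np.ndarray | None = None  # per-cell segment label
    node_state: dict = field(default_factory=dict)  # centroid -> segment label
    branch_points: list = field(default_factory=list)
    pseudotime: np.ndarray | None = None
    root_node: int | None = None
    objective_trace: list = field(default_factory=list)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.centroids)))
        for k, l in self.edges:
            g.add_edge(k, l, weight=float(np.linalg.norm(self.centroids[k] - self.centroids[l])))
        return g


def _mst_edges(Y: np.ndarray) -> list:
    d2 = squareform(pdist(Y)) ** 2
    mst = minimum_spanning_tree(d2).tocoo()
    return [(int(i), int(j)) for i, j in zip(mst.row, mst.col)]


def _tree_objective(Xt, W, Z, Y, assign, edges, lam, gamma):
    recon = np.linalg.norm(Xt - W @ Z) ** 2
    attach = lam * np.linalg.norm(Z - Y[:, assign]) ** 2
    tree = gamma * sum(np.linalg.norm(Y[:, k] - Y[:, l]) ** 2 for k, l in edges)
    return recon + attach + tree


def fit_principal_tree(
    m,
    latent_dim: int = 2,
    n_centroids: int | None = None,
    seed: int = 0,
    lam: float = 1.0,
    gamma: float = 800.0,
    max_iter: int = 100,
    tol: float = 1e-5,
    prune_min_cells_frac: float = 0.1,
) -> TrajectoryModel:
    """Fit a latent spanning tree to expression data by alternating optimization.

    ``m`` is a NormMatrix (or genes x cells array) restricted to the
    ordering genes.  The number of centroids defaults to
    ``max(50, n_cells // 20)`` capped at ``n_cells``.  After convergence,
    leaf branches supported by fewer than ``prune_min_cells_frac`` of cells
    are collapsed so reported branch points reflect populated paths.
    """
    values = m.values if isinstance(m, NormMatrix) else np.asarray(m, dtype=float)
    n_cells = values.shape[1]
    if n_centroids is None:
        n_centroids = max(50, n_cells // 20)
    n_centroids = min(n_centroids, n_cells)
    if n_centroids < 3:
        raise ValueError("need at least 3 centroids")
    if n_cells < n_centroids:
        raise ValueError("need at least as many cells as centroids")
    Xt = values - values.mean(axis=1, keepdims=True)  # features x cells, centered
    pca = PCA(n_components=min(latent_dim, min(Xt.shape) - 1), random_state=seed)
    Z = pca.fit_transform(Xt.T).T  # d x cells
    if Z.shape[0] < latent_dim:  # degenerate feature space: pad with zeros
        Z = np.vstack([Z, np.zeros((latent_dim - Z.shape[0], n_cells))])
    W = np.linalg.lstsq(Z.T, Xt.T, rcond=None)[0].T  # features x d
    km = KMeans(n_clusters=n_centroids, random_state=seed, n_init=3).fit(Z.T)
    Y = km.cluster_centers_.T  # d x K
    assign = km.labels_.copy()
    edges = _mst_edges(Y.T)
    trace = [_tree_objective(Xt, W, Z, Y, assign, edges, lam, gamma)]
    d = Z.shape[0]
    converged = False
    for _ in range(max_iter):
        # W step: least squares of centered data on latent coordinates
        G = Z @ Z.T + 1e-9 * np.eye(d)
        W = np.linalg.solve(G, Z @ Xt.T).T
        # Z step: ridge toward the assigned centroid
        A = W.T @ W + lam * np.eye(d)
        Z = np.linalg.solve(A, W.T @ Xt + lam * Y[:, assign])
        # assignment step
        d2 = ((Z.T[:, None, :] - Y.T[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        # Y step: Laplacian-regularized weighted means
        K = Y.shape[1]
        counts = np.bincount(assign, minlength=K).astype(float)
        adj = np.zeros((K, K))
        for k, l in edges:
            adj[k, l] = adj[l, k] = 1.0
        lap = np.diag(adj.sum(axis=1)) - adj
        S = np.zeros((d, K))
        np.add.at(S.T, assign, Z.T)
        M = lam * np.diag(counts) + gamma * lap + 1e-9 * np.eye(K)
        Y = np.linalg.solve(M, lam * S.T).T
        # tree step: MST over centroids
        edges = _mst_edges(Y.T)
        trace.append(_tree_objective(Xt, W, Z, Y, assign, edges, lam, gamma))
        if trace[-1] > trace[-2] + 1e-6 * max(1.0, abs(trace[-2])):
            raise AssertionError("principal-tree objective increased")
        if trace[-2] - trace[-1] < tol * max(1.0, abs(trace[-2])):
            converged = True
            break
    if not converged:
        warnings.warn("principal tree did not converge in "
                      f"{max_iter} iterations; returning best fit")
    model = TrajectoryModel(Y.T.copy(), edges, assign.copy(), Z.T.copy(),
                            objective_trace=trace)
    model = _prune_spurs(model, max(1, int(prune_min_cells_frac * n_cells)))
    assign_states(model)
    return model


def _prune_spurs(model: TrajectoryModel, min_cells: int) -> TrajectoryModel:
    """Collapse leaf branches whose exclusive centroids hold < min_cells cells."""
    g = model.graph()
    assign = model.cell_assignment.copy()
    changed = True
    while changed and g.number_of_nodes() > 2:
        changed = False
        counts = np.bincount(assign, minlength=len(model.centroids))
        for leaf in [n for n in g.nodes if g.degree[n] == 1]:
            path = [leaf]
            cur = leaf
            prev = None
            while True:
                nbrs = [x for x in g.neighbors(cur) if x != prev]
                if len(nbrs) != 1 or g.degree[cur] >= 3:
                    break
                prev, cur = cur, nbrs[0]
                if g.degree[cur] == 2:
                    path.append(cur)
                else:
                    break
            if counts[path].sum() < min_cells and g.number_of_nodes() - len(path) >= 2:
                g.remove_nodes_from(path)
                changed = True
                break
    keep = sorted(g.nodes)
    remap = {old: new for new, old in enumerate(keep)}
    centroids = model.centroids[keep]
    edges = [(remap[k], remap[l]) for k, l in g.edges]
    # reassign every cell to its nearest surviving centroid
    d2 = ((model.cell_coords[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    return TrajectoryModel(centroids, edges, assign, model.cell_coords,
                           objective_trace=model.objective_trace)


def assign_states(t: TrajectoryModel) -> TrajectoryModel:
    """Decompose the tree into maximal segments between nodes of degree != 2.

    Segments ("states", the paper's "lines") are maximal paths whose
    interior nodes all have degree 2; a tree with one degree-3 node yields
    3 states, two cascaded branch points yield 5.  Cells inherit the state
    of their assigned centroid; branch-point centroids are attributed to
    the first segment that contains them (deterministic order).
    """
    g = t.graph()
    anchors = [n for n in g.nodes if g.degree[n] != 2]
    if not anchors:  # cycle-free ⇒ only when the tree is a single node/edge chain
        anchors = [min(g.nodes)]
    segments = []
    seen_edges = set()
    for a in sorted(anchors):
        for nb in sorted(g.neighbors(a)):
            if (a, nb) in seen_edges or (nb, a) in seen_edges:
                continue
            path = [a, nb]
            seen_edges.add((a, nb))
            while g.degree[path[-1]] == 2:
                nxt = [x for x in g.neighbors(path[-1]) if x != path[-2]][0]
                seen_edges.add((path[-1], nxt))
                path.append(nxt)
            segments.append(path)
    if not segments:  # single-node tree
        segments = [[min(g.nodes)]]
    node_state: dict = {}
    for si, path in enumerate(segments):
        for n in path:
            node_state.setdefault(n, f"state_{si + 1}")
    t.node_state = node_state
    t.state = np.array([node_state[k] for k in t.cell_assignment], dtype=object)
    t.branch_points = sorted(n for n in g.nodes if g.degree[n] >= 3)
    return t


def order_pseudotime(t: TrajectoryModel, amdi) -> np.ndarray:
    """Root the tree at the terminal end of the lowest-mean-AMDI state.

    Pseudotime is the geodesic distance along the tree (latent-space edge
    lengths) from the root node to each cell's assigned tree position;
    cells at the root have pseudotime 0.
    """
    amdi = np.asarray(amdi, dtype=float)
    if t.state is None:
        assign_states(t)
    if len(amdi) != len(t.cell_assignment):
        raise ValueError("AMDI must be available for all cells")
    means = pd.Series(amdi).groupby(t.state).mean()
    lowest = means.min()
    tied = sorted(means.index[means == lowest])
    if len(tied) > 1:
        warnings.warn(f"mean-AMDI tie between states {tied}; using {tied[0]}")
    root_state = tied[0]
    g = t.graph()
    state_nodes = [n for n, s in t.node_state.items() if s == root_state]
    leaf_candidates = [n for n in state_nodes if g.degree[n] == 1] or state_nodes
    if len(leaf_candidates) > 1:
        # pick the end from which AMDI increases along the state
        best, best_corr = None, -np.inf
        for cand in sorted(leaf_candidates):
            dist = nx.single_source_dijkstra_path_length(g, cand, weight="weight")
            in_state = np.isin(t.cell_assignment, state_nodes)
            dvals = np.array([dist[k] for k in t.cell_assignment[in_state]])
            avals = amdi[in_state]
            if dvals.std() == 0 or avals.std() == 0:
                corr = 0.0
            else:
                corr = float(np.corrcoef(dvals, avals)[0, 1])
            if corr > best_corr:
                best, best_corr = cand, corr
        root = best
    else:
        root = leaf_candidates[0]
    dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    # refine beyond centroid quantization: project each cell onto the edges
    # incident to its centroid and measure the geodesic to that point
    pt = np.empty(len(t.cell_assignment), dtype=float)
    for i, k in enumerate(t.cell_assignment):
        z = t.cell_coords[i]
        best_d, best_pt = np.inf, dist[k]
        for l in g.neighbors(k):
            seg = t.centroids[l] - t.centroids[k]
            e2 = float(seg @ seg)
            if e2 == 0:
                continue
            s_raw = float((z - t.centroids[k]) @ seg / e2)
            # extrapolate past terminal centroids so end cells stay ordered
            hi = s_raw if (s_raw > 1.0 and g.degree[l] == 1) else 1.0
            lo = s_raw if (s_raw < 0.0 and g.degree[k] == 1) else 0.0
            s = float(np.clip(s_raw, lo, hi))
            proj = t.centroids[k] + s * seg
            perp = float(np.linalg.norm(z - proj))
            e = np.sqrt(e2)
            along = dist[k] + s * e if dist[l] > dist[k] else dist[k] - s * e
            if perp < best_d:
                best_d, best_pt = perp, along
        pt[i] = best_pt
    if pt.min() < 0:  # cells extrapolated before the root centroid start at 0
        pt = pt - pt.min()
    t.pseudotime = pt
    t.root_node = int(root)
    return t.pseudotime


def correlate_score_pseudotime(pseudotime, score) -> tuple:
    """Pearson correlation (r, two-sided p) between pseudotime and a score."""
    pt = np.asarray(pseudotime, dtype=float)
    sc = np.asarray(score, dtype=float)
    if len(pt) != len(sc) or len(pt) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if pt.std() == 0 or sc.std() == 0:
        raise ValueError("zero variance input")
    r, p = pearsonr(pt, sc)
    return float(r), float(p)
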