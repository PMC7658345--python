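"""Branch-point analysis of principal-tree trajectories.

Given the cells downstream of one branch point (two output states A and B,
each with its pseudotime), the branch test asks, per gene, whether the
expression-vs-pseudotime curve differs between the branches: a negative
binomial GLM with a natural cubic spline of pseudotime (df = 3) interacting
with the branch label is compared against the spline-only model by a
likelihood-ratio test (chi-squared, df = 4), with Benjamini-Hochberg control
across genes.  Branch-dependent genes (q < 0.05) are smoothed on a common
0-100 pseudotime grid per branch, clustered hierarchically (Ward linkage on
1 - Pearson correlation of the concatenated curves), and clusters whose
meta-gene diverges strongly between the terminal cells of the two branches
(>= 1 pooled SD) are flagged as candidate regulatory programs, which can be
annotated by hypergeometric over-representation against user gene sets and
validated by meta-gene correlation in bulk samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import hypergeom, pearsonr
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .ingest import CountMatrix, NormMatrix
from .ontogeny import map_ivy_regions, normalize_bulk
from .scores import GeneSignature, MetaGeneScore, metagene_score
from .trajectory import _mom_dispersion


# ---------------------------------------------------------------------------
# Natural cubic spline basis (R ns()-style, truncated-power construction)
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int = 3, knots: np.ndarray | None = None):
    """Natural cubic spline basis with `df` columns (no intercept column).

    Boundary knots at min/max of x, interior knots at quantiles.  Returns
    (basis matrix n x df, knots) so the same knots can be reused on a grid.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        n_interior = df - 1
        qs = np.linspace(0, 1, n_interior + 2)
        knots = np.quantile(x, qs)
        knots = np.unique(knots)
        if len(knots) < 2:
            knots = np.array([x.min(), x.max() + 1e-9])
    K = len(knots)

    def trunc3(v, xi):
        return np.clip(v - xi, 0, None) ** 3

    def d(v, k):
        return (trunc3(v, knots[k]) - trunc3(v, knots[-1])) / (knots[-1] - knots[k])

    cols = [x]
    for k in range(K - 2):
        cols.append(d(x, k) - d(x, K - 2))
    basis = np.column_stack(cols[:df]) if len(cols) >= df else np.column_stack(cols)
    return basis, knots


# ---------------------------------------------------------------------------
# Branch-dependence LRT
# ---------------------------------------------------------------------------

@dataclass
class BranchTestResult:
    table: pd.DataFrame  # index gene; columns lrt_stat, p, q, branch_dependent

    @property
    def branch_dependent_genes(self) -> list:
        return list(self.table.index[self.table["branch_dependent"]])


def _fit_nb_glm_ll(y: np.ndarray, X: np.ndarray, alpha: float) -> float:
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-4))
    try:
        res = sm.GLM(y, X, family=fam).fit(maxiter=50, tol=1e-8)
        return float(res.llf)
    except Exception:
        return -np.inf


def _residual_dispersion(y: np.ndarray, X: np.ndarray, floor: float = 1e-4) -> float:
    """NB2 dispersion from Pearson residuals of a Poisson fit of the full model.

    Estimating alpha from the marginal moments attributes the modelled signal
    to noise and is conservative; the residual-based estimate is the standard
    quasi-likelihood moment estimator.
    """
    try:
        mu = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=50).mu
    except Exception:
        return _mom_dispersion(y, floor)
    mu = np.maximum(mu, 1e-8)
    num = ((y - mu) ** 2 - mu).sum()
    den = (mu**2).sum()
    return max(num / den, floor) if den > 0 else floor


def branch_dependence_test(
    m: CountMatrix,
    pseudotime,
    branch,
    q_threshold: float = 0.05,
    min_cells_expressed: int = 10,
    spline_df: int = 3,
) -> BranchTestResult:
    """Per-gene NB LRT of spline x branch interaction vs spline-only.

    ``branch`` holds labels {A, B} (any two values) for the cells
    downstream of one branch point; genes expressed in fewer than
    ``min_cells_expressed`` of those cells are excluded rather than tested.
    """
    pt = np.asarray(pseudotime, dtype=float)
    br = np.asarray(branch, dtype=object)
    labels = pd.unique(br)
    if len(labels) != 2:
        raise ValueError(f"branch must have exactly two labels, got {list(labels)}")
    if min((br == labels[0]).sum(), (br == labels[1]).sum()) < 20:
        warnings.warn("a branch has fewer than 20 cells; the LRT may be unstable")
    span = np.ptp(pt)
    pts = (pt - pt.min()) / (span if span > 0 else 1.0)
    basis, _ = natural_spline_basis(pts, df=spline_df)
    ind = (br == labels[1]).astype(float)
    X_null = np.column_stack([np.ones(len(pt)), basis])
    X_full = np.column_stack([X_null, ind, basis * ind[:, None]])
    df_diff = X_full.shape[1] - X_null.shape[1]
    dense = m.dense()
    rows = []
    for gi, gene in enumerate(m.gene_ids):
        y = np.asarray(dense[gi, :], dtype=float).ravel()
        if (y > 0).sum() < min_cells_expressed:
            continue
        alpha = _residual_dispersion(y, X_full)
        ll_full = _fit_nb_glm_ll(y, X_full, alpha)
        ll_null = _fit_nb_glm_ll(y, X_null, alpha)
        if not np.isfinite(ll_full) or not np.isfinite(ll_null):
            stat, p = 0.0, 1.0
        else:
            stat = max(2 * (ll_full - ll_null), 0.0)
            p = float(chi2_dist.sf(stat, df_diff))
        rows.append((gene, stat, p))
    if not rows:
        raise ValueError("no gene passes the expression filter")
    tab = pd.DataFrame(rows, columns=["gene", "lrt_stat", "p"]).set_index("gene")
    tab["q"] = multipletests(tab["p"].values, method="fdr_bh")[1]
    tab["branch_dependent"] = tab["q"] < q_threshold
    return BranchTestResult(tab)


# ---------------------------------------------------------------------------
# Curve smoothing and clustering
# ---------------------------------------------------------------------------

@dataclass
class GeneCurveCluster:
    curves: dict  # branch label -> DataFrame (genes x grid), standardized rows
    labels: pd.Series  # gene -> cluster id (1-based)
    n_clusters: int
    grid: np.ndarray


def smooth_curves(
    m, pseudotime, branch, genes, grid_n: int = 100, spline_df: int = 3
) -> dict:
    """Natural-spline mean curves per branch on a pseudotime grid scaled 0-100.

    ``m`` is a NormMatrix (log-scale values are sensible input) or an
    aligned genes x cells array with a gene index.  Within each branch,
    pseudotime is rescaled to [0, 100] and a df-3 natural spline is fit per
    gene by least squares; returned rows are standardized (mean 0, SD 1
    across the concatenated branch grids; constant genes become zero rows).
    """
    if isinstance(m, NormMatrix):
        vals, gene_ids = m.values, m.gene_ids
    else:
        vals, gene_ids = np.asarray(m, dtype=float), None
    if gene_ids is not None:
        lookup = {g: i for i, g in enumerate(gene_ids)}
        idx = [lookup[g] for g in genes]
        vals = vals[idx, :]
    pt = np.asarray(pseudotime, dtype=float)
    br = np.asarray(branch, dtype=object)
    grid = np.linspace(0.0, 100.0, grid_n)
    raw = {}
    for lab in pd.unique(br):
        sel = br == lab
        p = pt[sel]
        span = np.ptp(p)
        p100 = (p - p.min()) / (span if span > 0 else 1.0) * 100.0
        basis, knots = natural_spline_basis(p100, df=spline_df)
        X = np.column_stack([np.ones(sel.sum()), basis])
        gbasis, _ = natural_spline_basis(grid, df=spline_df, knots=knots)
        Xg = np.column_stack([np.ones(grid_n), gbasis])
        coef, *_ = np.linalg.lstsq(X, vals[:, sel].T, rcond=None)
        raw[lab] = pd.DataFrame((Xg @ coef).T, index=list(genes), columns=grid)
    concat = np.hstack([raw[lab].values for lab in raw])
    mu = concat.mean(axis=1, keepdims=True)
    sd = concat.std(axis=1, keepdims=True)
    # constant genes (up to float noise in the spline solve) become zero rows
    flat = sd.ravel() <= 1e-8 * np.maximum(1.0, np.abs(mu.ravel()))
    sd[flat] = np.inf
    out = {}
    for lab in raw:
        out[lab] = pd.DataFrame(
            (raw[lab].values - mu) / sd, index=list(genes), columns=grid
        )
    return out


def cluster_branch_genes(curves: dict, k: int | str = "auto") -> GeneCurveCluster:
    """Ward clustering of smoothed gene curves on correlation distance.

    Distance between genes is 1 - Pearson correlation of their concatenated
    per-branch curves.  With ``k='auto'`` the cluster count maximizes the
    mean silhouette over k in 2..10; identical curves force k = 1.
    """
    branches = list(curves)
    genes = list(curves[branches[0]].index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to cluster")
    mat = np.hstack([curves[b].values for b in branches])
    grid = curves[branches[0]].columns.values.astype(float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    if dist.max() == 0:
        warnings.warn("all curves identical; forcing a single cluster")
        labels = pd.Series(1, index=genes)
        return GeneCurveCluster(curves, labels, 1, grid)
    if isinstance(k, int) and k > len(genes):
        raise ValueError(f"k={k} exceeds the {len(genes)} genes available")
    Zl = linkage(squareform(dist, checks=False), method="ward")
    if k == "auto":
        best_k, best_sil = 2, -np.inf
        for kk in range(2, min(10, len(genes) - 1) + 1):
            lab = fcluster(Zl, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            sil = silhouette_score(dist, lab, metric="precomputed")
            if sil > best_sil:
                best_k, best_sil = kk, sil
        k = best_k
    labels = pd.Series(fcluster(Zl, k, criterion="maxclust"), index=genes)
    return GeneCurveCluster(curves, labels, int(labels.nunique()), grid)


# ---------------------------------------------------------------------------
# Divergent clusters, pathway correlation, enrichment, bulk validation
# ---------------------------------------------------------------------------

def _terminal_mask(pt: np.ndarray, sel: np.ndarray, frac: float, min_cells: int = 5):
    idx = np.where(sel)[0]
    n_term = max(1, int(np.ceil(frac * idx.size)))
    if n_term < min_cells:
        warnings.warn("branch has fewer than 5 terminal cells; using all its cells")
        return idx
    order = idx[np.argsort(pt[idx])]
    return order[-n_term:]


def divergent_clusters(
    cc: GeneCurveCluster,
    m: NormMatrix,
    pseudotime,
    branch,
    terminal_frac: float = 0.1,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Clusters whose meta-gene separates the two branches' terminal cells.

    For each gene cluster, the cluster meta-gene is evaluated in the top
    ``terminal_frac`` of cells by pseudotime on each branch; the divergence
    score is |mean_A - mean_B| / pooled SD, and clusters scoring at least
    ``threshold`` are selected.
    """
    pt = np.asarray(pseudotime, dtype=float)
    br = np.asarray(branch, dtype=object)
    labs = pd.unique(br)
    if len(labs) != 2:
        raise ValueError("need exactly two branches")
    term_a = _terminal_mask(pt, br == labs[0], terminal_frac)
    term_b = _terminal_mask(pt, br == labs[1], terminal_frac)
    rows = []
    for cid in sorted(cc.labels.unique()):
        genes = list(cc.labels.index[cc.labels == cid])
        sig = GeneSignature(f"cluster_{cid}", genes)
        score = metagene_score(m, sig).values
        sa, sb = score[term_a], score[term_b]
        na, nb = len(sa), len(sb)
        pooled_var = (
            ((na - 1) * sa.var(ddof=1) + (nb - 1) * sb.var(ddof=1)) / (na + nb - 2)
            if na > 1 and nb > 1
            else 0.0
        )
        gap = abs(sa.mean() - sb.mean())
        if pooled_var > 0:
            div = gap / np.sqrt(pooled_var)
        else:
            div = 0.0 if gap == 0 else np.inf
        rows.append({"cluster": cid, "n_genes": len(genes),
                     "mean_A": sa.mean(), "mean_B": sb.mean(), "divergence": div,
                     "selected": div >= threshold})
    return pd.DataFrame(rows).set_index("cluster")


def pathway_correlation(mg_cluster: MetaGeneScore, mg_pathway: MetaGeneScore) -> tuple:
    """Pearson (r, p) between a cluster meta-gene and a pathway meta-gene."""
    x, y = np.asarray(mg_cluster.values), np.asarray(mg_pathway.values)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned scores of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance meta-gene")
    r, p = pearsonr(x, y)
    return float(r), float(p)


def overrepresentation(genes, collection: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of `genes` in each set.

    p = P(overlap >= observed) drawing |genes| from the universe; sets with
    no member in the universe are skipped.  BH correction across sets.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = [g for g in dict.fromkeys(genes) if g in uni]
    if set(genes) - uni:
        raise ValueError("cluster genes must be contained in the universe")
    N, n = len(universe), len(query)
    rows = []
    skipped = []
    for name, members in collection.items():
        K = len(uni.intersection(members))
        if K == 0:
            skipped.append(name)
            continue
        k = len(set(query).intersection(members))
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "set_size": K, "overlap": k, "p": p})
    if skipped:
        warnings.warn(f"{len(skipped)} gene sets have no gene in the universe; skipped")
    if not rows:
        return pd.DataFrame(columns=["set", "set_size", "overlap", "p", "q"]).set_index("set")
    tab = pd.DataFrame(rows).set_index("set")
    tab["q"] = multipletests(tab["p"].values, method="fdr_bh")[1]
    return tab.sort_values("p")


def bulk_correlation(
    bulk: pd.DataFrame,
    structure_labels,
    cluster_sig: GeneSignature,
    pathway_sig: GeneSignature,
    region: str,
    normalized: bool = False,
) -> tuple:
    """Pearson (r, p) between two meta-genes across one region's bulk samples."""
    vals = bulk if normalized else normalize_bulk(bulk)
    regions = map_ivy_regions(structure_labels)
    sel = regions == region
    if sel.sum() < 3:
        raise ValueError(f"fewer than 3 bulk samples in region {region!r}")
    sub = vals.loc[:, sel]
    nm = NormMatrix(sub.values, vals.index.values,
                    pd.DataFrame(index=sub.columns), ["lognorm"], 1e6)
    a = metagene_score(nm, cluster_sig).values
    b = metagene_score(nm, pathway_sig).values
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance meta-gene in bulk samples")
    r, p = pearsonr(a, b)
    return float(r), float(p)
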