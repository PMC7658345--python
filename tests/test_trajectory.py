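import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from tamscape import trajectory as tj
from tamscape.ingest import NormMatrix, lognormalize
from tamscape.trajectory import TrajectoryModel

from conftest import make_counts


def brute_force_density_delta(points, bandwidth):
    """O(n^2) double-loop oracle for density-peak P and D."""
    pts = np.asarray(points, float)
    n = len(pts)
    dist = squareform(pdist(pts))
    P = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                P[i] += np.exp(-dist[i, j] ** 2 / (2 * bandwidth**2))
    order = np.argsort(-P, kind="stable")
    D = np.zeros(n)
    for rank, i in enumerate(order):
        if rank == 0:
            D[i] = dist.max()
        else:
            D[i] = min(dist[i, j] for j in order[:rank])
    return P, D


class TestCensus:
    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        profile = rng.integers(0, 10, size=30)
        profile[profile.sum() == 0] = 1
        counts = np.column_stack([profile, profile * 3])
        out = tj.census_normalize(make_counts(counts))
        np.testing.assert_allclose(out[:, 0], out[:, 1], atol=1e-8)

    def test_modal_gene_maps_to_one(self):
        # 80% of expressed genes share one relative-expression value
        counts = np.concatenate([np.full(40, 5), np.array([1, 2, 8, 20, 50,
                                                           3, 7, 11, 13, 17])])
        out = tj.census_normalize(make_counts(counts.reshape(-1, 1)))
        np.testing.assert_allclose(out[:40, 0], 1.0, atol=1e-9)

    def test_sparse_cell_falls_back_with_warning(self):
        counts = np.zeros((20, 2), dtype=int)
        counts[0, 0] = 7
        counts[:, 1] = 1
        with pytest.warns(UserWarning, match="fallback"):
            out = tj.census_normalize(make_counts(counts))
        assert out[0, 0] == pytest.approx(1.0)  # rel=1 scaled by 1 nonzero gene


class TestDensityPeak:
    @pytest.mark.parametrize("seed", range(6))
    def test_p_and_d_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        pts = rng.normal(size=(n, 2))
        bw = 0.5
        res = tj.density_peak_cluster(pts, bandwidth=bw)
        P, D = brute_force_density_delta(pts, bw)
        np.testing.assert_allclose(res.density, P, atol=1e-12)
        np.testing.assert_allclose(res.delta, D, atol=1e-12)

    def test_oracle_at_two_hundred_points(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(200, 2))
        res = tj.density_peak_cluster(pts, bandwidth=0.3)
        P, D = brute_force_density_delta(pts, 0.3)
        np.testing.assert_allclose(res.density, P, atol=1e-10)
        np.testing.assert_allclose(res.delta, D, atol=1e-10)

    def test_two_separated_blobs_give_two_clusters(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pts = np.vstack([rng.normal(0, 1, (100, 2)),
                             rng.normal([10, 0], 1, (100, 2))])
            res = tj.density_peak_cluster(pts)
            hits += len(np.unique(res.labels)) == 2
        assert hits >= 0.95 * 50

    def test_single_point_single_cluster(self):
        res = tj.density_peak_cluster(np.array([[0.0, 0.0]]))
        assert res.labels.tolist() == [0] and res.peaks.all()

    def test_identical_points_single_cluster(self):
        res = tj.density_peak_cluster(np.zeros((5, 2)))
        assert len(np.unique(res.labels)) == 1

    def test_every_label_traces_to_a_peak(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(80, 2))
        res = tj.density_peak_cluster(pts)
        peak_labels = set(res.labels[res.peaks])
        assert set(res.labels) == peak_labels


class TestOrderingGenes:
    def _null_counts(self, rng, n_genes, n_cells):
        mu = 2.0
        return rng.negative_binomial(2, 2 / (2 + mu), size=(n_genes, n_cells))

    def test_null_rejection_controlled(self):
        rng = np.random.default_rng(0)
        n_cells = 200
        counts = self._null_counts(rng, 800, n_cells)
        clusters = rng.integers(0, 3, n_cells)
        cm = make_counts(counts)
        _, tab = tj.select_ordering_genes(cm, clusters, top_n=800, min_frac=0.0,
                                          return_table=True)
        frac = (tab["q"] < 0.05).mean()
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(tab))

    def test_separated_gene_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = self._null_counts(rng, 50, 200)
            # gene 0 has a 4-fold mean difference between clusters
            clusters = np.repeat([0, 1], 100)
            mu = np.where(clusters == 0, 1.0, 4.0)
            counts[0] = rng.negative_binomial(2, 2 / (2 + mu))
            cm = make_counts(counts)
            genes = tj.select_ordering_genes(cm, clusters, top_n=5, min_frac=0.0)
            hits += "g0" in genes
        assert hits >= 0.95 * 20

    def test_top_n_larger_than_gene_count_warns(self):
        rng = np.random.default_rng(1)
        cm = make_counts(self._null_counts(rng, 10, 60))
        with pytest.warns(UserWarning, match="returning all"):
            genes = tj.select_ordering_genes(cm, rng.integers(0, 2, 60),
                                             top_n=50, min_frac=0.0)
        assert len(genes) == 10

    def test_tiny_cluster_merged(self):
        rng = np.random.default_rng(2)
        cm = make_counts(self._null_counts(rng, 10, 50))
        clusters = np.zeros(50, int)
        clusters[25:] = 1
        clusters[0] = 2  # singleton cluster
        with pytest.warns(UserWarning, match="merged"):
            tj.select_ordering_genes(cm, clusters, top_n=5, min_frac=0.0)


class TestPrincipalTree:
    def test_noiseless_line_recovers_path_and_order(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 1, 200)
        X = np.outer(rng.normal(size=30), t)
        model = tj.fit_principal_tree(X, seed=0)
        assert model.branch_points == []
        pt = tj.order_pseudotime(model, t)
        assert spearmanr(pt, t).statistic >= 0.99

    def test_objective_monotone_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 150))
        model = tj.fit_principal_tree(X, n_centroids=10, seed=1)
        trace = np.asarray(model.objective_trace)
        assert (np.diff(trace) <= 1e-6 * np.maximum(1.0, np.abs(trace[:-1]))).all()

    def test_three_cells_three_centroids_path(self):
        X = np.array([[0.0, 1, 2], [0, 1, 2]])
        model = tj.fit_principal_tree(X, n_centroids=3, seed=0,
                                      prune_min_cells_frac=0.0)
        assert len(model.edges) == 2 and model.branch_points == []

    def test_too_few_centroids_is_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            tj.fit_principal_tree(np.ones((5, 10)), n_centroids=2)


def path_model(n_nodes, coords=None):
    centroids = coords if coords is not None else np.column_stack(
        [np.arange(n_nodes, dtype=float), np.zeros(n_nodes)]
    )
    edges = [(i, i + 1) for i in range(n_nodes - 1)]
    assign = np.arange(n_nodes)
    return TrajectoryModel(centroids, edges, assign, centroids.copy())


class TestStates:
    def test_path_tree_single_state(self):
        m = tj.assign_states(path_model(5))
        assert len(set(m.node_state.values())) == 1
        assert m.branch_points == []

    def test_single_y_three_states_one_branch(self):
        centroids = np.array([[0, 0], [1, 0], [2, 1], [2, -1]], dtype=float)
        m = TrajectoryModel(centroids, [(0, 1), (1, 2), (1, 3)],
                            np.arange(4), centroids.copy())
        tj.assign_states(m)
        assert len(set(m.node_state.values())) == 3
        assert m.branch_points == [1]

    def test_cascaded_ys_five_states_two_branches(self):
        # trunk -> branch -> one arm branches again: 5 lines, 2 branch points
        centroids = np.array(
            [[0, 0], [1, 0], [2, 1], [2, -1], [3, 2], [3, 0]], dtype=float
        )
        edges = [(0, 1), (1, 2), (1, 3), (2, 4), (2, 5)]
        m = TrajectoryModel(centroids, edges, np.arange(6), centroids.copy())
        tj.assign_states(m)
        assert len(set(m.node_state.values())) == 5
        assert sorted(m.branch_points) == [1, 2]


class TestPseudotime:
    def test_path_rooted_at_low_amdi_end(self):
        m = tj.assign_states(path_model(6))
        amdi = np.arange(6, dtype=float)  # increases left to right
        pt = tj.order_pseudotime(m, amdi)
        assert m.root_node == 0
        assert pt[0] == 0.0
        assert (np.diff(pt) > 0).all()

    def test_root_cell_pseudotime_zero(self):
        m = tj.assign_states(path_model(4))
        pt = tj.order_pseudotime(m, np.array([0.0, 1, 2, 3]))
        assert pt.min() == 0.0 and pt[0] == 0.0

    def test_invariant_to_uniform_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 120))
        m1 = tj.fit_principal_tree(X, n_centroids=8, seed=3)
        amdi = rng.normal(size=120)
        pt1 = tj.order_pseudotime(m1, amdi)
        m2 = TrajectoryModel(m1.centroids * 7.0, list(m1.edges),
                             m1.cell_assignment.copy(), m1.cell_coords * 7.0)
        tj.assign_states(m2)
        pt2 = tj.order_pseudotime(m2, amdi)
        assert spearmanr(pt1, pt2).statistic == pytest.approx(1.0)

    def test_recovers_planted_latent_time(self, syn_small, syn_small_norm,
                                          syn_signatures):
        _, cm, truth = syn_small
        core = np.asarray(cm.cell_meta["region"]) == "core"
        cmc = cm.subset_cells(core)
        nm = lognormalize(cmc)
        emb = tj.embed_2d(nm.values, seed=0)
        dp = tj.density_peak_cluster(emb)
        genes = tj.select_ordering_genes(cmc, dp.labels, top_n=200)
        idx = nm.gene_index(genes)
        sub = NormMatrix(nm.values[idx], nm.gene_ids[idx], nm.cell_meta,
                         nm.transform_log)
        model = tj.fit_principal_tree(sub, seed=0)
        from tamscape.scores import activation_scores

        s = syn_signatures
        prof = activation_scores(nm, s["pol_pos"], s["pol_neg"],
                                 s["dif_pos"], s["dif_neg"])
        pt = tj.order_pseudotime(model, prof.amdi)
        assert spearmanr(pt, truth.latent_time[core]).statistic >= 0.8


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        pt = np.linspace(0, 5, 20)
        assert tj.correlate_score_pseudotime(pt, pt)[0] == pytest.approx(1.0)
        assert tj.correlate_score_pseudotime(pt, -pt)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = tj.correlate_score_pseudotime(x, y)
        r_ref, p_ref = pearsonr(x, y)
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            tj.correlate_score_pseudotime(np.ones(5), np.arange(5.0))


class TestRegionalPolarizationWiring:
    def _mpi_pseudotime_r(self, seed, wiring):
        from tamscape.scores import activation_scores
        from tamscape.syndata import SynthConfig, default_signatures, generate_single_cell
        from tamscape.ingest import (
            filter_cells_depth_outliers,
            filter_genes_min_cells,
        )

        cfg = SynthConfig(n_cells_core=700, n_cells_periphery=300, n_genes=600,
                          seed=seed, polarization_wiring=wiring)
        cm, truth = generate_single_cell(cfg)
        core = np.asarray(cm.cell_meta["region"]) == "core"
        cmc = cm.subset_cells(core)
        cm2 = filter_genes_min_cells(filter_cells_depth_outliers(cmc))
        nm = lognormalize(cm2)
        emb = tj.embed_2d(nm.values, seed=seed)
        dp = tj.density_peak_cluster(emb)
        genes = tj.select_ordering_genes(cm2, dp.labels, top_n=200)
        idx = nm.gene_index(genes)
        sub = NormMatrix(nm.values[idx], nm.gene_ids[idx], nm.cell_meta,
                         nm.transform_log)
        model = tj.fit_principal_tree(sub, seed=seed)
        sigs = default_signatures(truth)
        prof = activation_scores(nm, sigs["pol_pos"], sigs["pol_neg"],
                                 sigs["dif_pos"], sigs["dif_neg"])
        pt = tj.order_pseudotime(model, prof.amdi)
        return tj.correlate_score_pseudotime(pt, prof.mpi)[0]

    def test_polarization_sign_follows_regional_wiring(self):
        # core-like wiring: cells grow more pro-inflammatory as they mature;
        # periphery-like wiring: the polarization trend reverses
        pos = [self._mpi_pseudotime_r(seed, +1) for seed in range(10)]
        neg = [self._mpi_pseudotime_r(seed, -1) for seed in range(10)]
        assert np.mean([r > 0 for r in pos]) >= 0.9
        assert np.mean([r < 0 for r in neg]) >= 0.9
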