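import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom
from sklearn.metrics import adjusted_rand_score

from tamscape import branching as br
from tamscape.ingest import lognormalize
from tamscape.scores import GeneSignature, MetaGeneScore, metagene_score
from tamscape.syndata import generate_bulk

from conftest import make_counts, make_norm


def nb_counts(rng, mu, alpha=0.5):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mu)))


class TestBranchDependenceTest:
    def test_null_rejection_controlled(self):
        rng = np.random.default_rng(0)
        n_cells, n_genes = 240, 400
        pt = rng.uniform(0, 1, n_cells)
        branch = np.where(rng.random(n_cells) < 0.5, "A", "B")
        counts = nb_counts(rng, np.full((n_genes, n_cells), 2.0))
        res = br.branch_dependence_test(make_counts(counts), pt, branch)
        frac = res.table["branch_dependent"].mean()
        assert frac <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(res.table))

    def test_branch_specific_gene_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 150
            pt = np.concatenate([rng.uniform(0, 1, n), rng.uniform(0, 1, n)])
            branch = np.array(["A"] * n + ["B"] * n, dtype=object)
            counts = nb_counts(rng, np.full((30, 2 * n), 5.0), alpha=0.25)
            # genes 0-4 double along pseudotime on branch A, flat on B
            mu0 = np.where(branch == "A", 5.0 * 2**pt, 5.0)
            for g in range(5):
                counts[g] = nb_counts(rng, mu0, alpha=0.25)
            res = br.branch_dependence_test(make_counts(counts), pt, branch)
            hits += bool(res.table.loc["g0", "branch_dependent"])
        assert hits >= 9

    def test_all_zero_gene_excluded(self):
        rng = np.random.default_rng(1)
        counts = nb_counts(rng, np.full((5, 60), 2.0))
        counts[2] = 0
        pt = rng.uniform(0, 1, 60)
        branch = np.where(np.arange(60) < 30, "A", "B")
        res = br.branch_dependence_test(make_counts(counts), pt, branch)
        assert "g2" not in res.table.index

    def test_bh_q_values_monotone_in_p(self):
        rng = np.random.default_rng(2)
        counts = nb_counts(rng, np.full((50, 80), 2.0))
        pt = rng.uniform(0, 1, 80)
        branch = np.where(np.arange(80) < 40, "A", "B")
        res = br.branch_dependence_test(make_counts(counts), pt, branch)
        tab = res.table.sort_values("p")
        assert (np.diff(tab["q"].values) >= -1e-12).all()
        assert (tab["q"].values >= tab["p"].values - 1e-12).all()


class TestSmoothCurves:
    def test_linear_gene_recovered(self):
        rng = np.random.default_rng(0)
        n = 200
        pt = rng.uniform(0, 1, n)
        branch = np.full(n, "A", dtype=object)
        vals = np.vstack([2.0 + 3.0 * pt + rng.normal(0, 0.01, n)])
        curves = br.smooth_curves(make_norm(vals), pt, branch, ["g0"], grid_n=50)
        grid = curves["A"].columns.values.astype(float)
        assert grid[0] == 0.0 and grid[-1] == 100.0
        # the standardized curve of a linear gene is the standardized line
        expected = (grid - grid.mean()) / grid.std()
        interior = slice(5, 45)
        np.testing.assert_allclose(
            curves["A"].values[0, interior], expected[interior], rtol=0.05, atol=0.05
        )

    def test_constant_gene_standardizes_to_zero(self):
        rng = np.random.default_rng(1)
        n = 100
        pt = rng.uniform(0, 1, n)
        branch = np.where(np.arange(n) < 50, "A", "B")
        vals = np.full((1, n), 4.0)
        curves = br.smooth_curves(make_norm(vals), pt, branch, ["g0"])
        for b in curves:
            np.testing.assert_allclose(curves[b].values, 0.0, atol=1e-9)


def archetype_curves(rng, n_genes=50, noise=0.2, grid_n=60):
    grid = np.linspace(0, 100, grid_n)
    rise = grid / 100.0
    a_genes = [f"a{i}" for i in range(n_genes)]
    b_genes = [f"b{i}" for i in range(n_genes)]
    genes = a_genes + b_genes
    curve_a = np.vstack([
        np.concatenate([rise, np.zeros(grid_n)]) + rng.normal(0, noise, 2 * grid_n)
        for _ in range(n_genes)
    ])
    curve_b = np.vstack([
        np.concatenate([np.zeros(grid_n), rise]) + rng.normal(0, noise, 2 * grid_n)
        for _ in range(n_genes)
    ])
    mat = np.vstack([curve_a, curve_b])
    mat = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
    curves = {
        "A": pd.DataFrame(mat[:, :grid_n], index=genes, columns=grid),
        "B": pd.DataFrame(mat[:, grid_n:], index=genes, columns=grid),
    }
    truth = np.array([0] * n_genes + [1] * n_genes)
    return curves, truth


class TestClusterBranchGenes:
    def test_two_archetypes_recovered(self):
        rng = np.random.default_rng(0)
        curves, truth = archetype_curves(rng)
        cc = br.cluster_branch_genes(curves, k=2)
        assert adjusted_rand_score(truth, cc.labels.values) >= 0.9

    def test_auto_k_picks_two_for_two_archetypes(self):
        rng = np.random.default_rng(1)
        curves, truth = archetype_curves(rng, noise=0.1)
        cc = br.cluster_branch_genes(curves, k="auto")
        assert cc.n_clusters == 2

    def test_identical_curves_forced_single_cluster(self):
        grid = np.linspace(0, 100, 20)
        row = np.sin(grid / 20)
        curves = {"A": pd.DataFrame([row] * 4, index=list("wxyz"), columns=grid)}
        with pytest.warns(UserWarning, match="single cluster"):
            cc = br.cluster_branch_genes(curves)
        assert cc.n_clusters == 1

    def test_k_equals_n_genes_gives_singletons(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(0, 100, 30)
        curves = {"A": pd.DataFrame(rng.normal(size=(5, 30)),
                                    index=[f"g{i}" for i in range(5)], columns=grid)}
        cc = br.cluster_branch_genes(curves, k=5)
        assert cc.n_clusters == 5

    def test_k_above_n_genes_is_error(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(0, 100, 10)
        curves = {"A": pd.DataFrame(rng.normal(size=(3, 10)),
                                    index=list("abc"), columns=grid)}
        with pytest.raises(ValueError, match="exceeds"):
            br.cluster_branch_genes(curves, k=4)


class TestDivergence:
    def _setup(self, rng, divergent=True):
        n = 200
        pt = np.concatenate([rng.uniform(0, 1, n), rng.uniform(0, 1, n)])
        branch = np.array(["A"] * n + ["B"] * n, dtype=object)
        base = np.full((20, 2 * n), 2.0)
        if divergent:
            base[:5] *= np.where(branch == "A", 4.0**pt, 1.0)  # A-only program
        counts = nb_counts(rng, base)
        nm = lognormalize(make_counts(counts))
        labels = pd.Series([1] * 5 + [2] * 15, index=[f"g{i}" for i in range(20)])
        cc = br.GeneCurveCluster({}, labels, 2, np.linspace(0, 100, 10))
        return cc, nm, pt, branch

    def test_planted_program_cluster_selected(self):
        hits = 0
        for seed in range(10):
            cc, nm, pt, branch = self._setup(np.random.default_rng(seed))
            div = br.divergent_clusters(cc, nm, pt, branch)
            hits += bool(div.loc[1, "selected"])
        assert hits >= 9

    def test_branch_independent_cluster_not_selected(self):
        low = 0
        for seed in range(10):
            cc, nm, pt, branch = self._setup(np.random.default_rng(seed),
                                             divergent=False)
            div = br.divergent_clusters(cc, nm, pt, branch)
            low += not div.loc[2, "selected"]
        assert low >= 9

    def test_identical_branches_zero_divergence(self):
        rng = np.random.default_rng(0)
        n = 100
        pt = np.concatenate([np.linspace(0, 1, n)] * 2)
        vals = rng.normal(size=(20, 2 * n))
        vals[:, n:] = vals[:, :n]  # branch B mirrors branch A exactly
        branch = np.array(["A"] * n + ["B"] * n, dtype=object)
        labels = pd.Series(1, index=[f"g{i}" for i in range(10)])
        cc = br.GeneCurveCluster({}, labels, 1, np.linspace(0, 100, 10))
        div = br.divergent_clusters(cc, make_norm(vals), pt, branch)
        assert div.loc[1, "divergence"] == pytest.approx(0.0, abs=1e-12)


class TestPathwayCorrelation:
    def test_identity_r_one(self):
        s = MetaGeneScore(np.arange(10, dtype=float), "x", 5)
        r, p = br.pathway_correlation(s, s)
        assert r == pytest.approx(1.0)

    def test_independent_scores_near_zero(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            a = MetaGeneScore(rng.normal(size=500), "a", 5)
            b = MetaGeneScore(rng.normal(size=500), "b", 5)
            r, _ = br.pathway_correlation(a, b)
            hits += abs(r) < 0.15
        assert hits >= 0.95 * 30

    def test_planted_overlap_correlates(self, syn_small, syn_small_norm,
                                        syn_signatures):
        _, _, truth = syn_small
        nm = syn_small_norm
        mg = metagene_score(nm, syn_signatures["pathway1"])
        half = GeneSignature("half", syn_signatures["pathway1"].genes[:20])
        r, _ = br.pathway_correlation(metagene_score(nm, half), mg)
        assert r > 0.5


class TestOverrepresentation:
    def test_maximal_overlap_matches_closed_form(self):
        universe = [f"g{i}" for i in range(100)]
        cluster = universe[:10]
        collection = {"set": cluster}
        tab = br.overrepresentation(cluster, collection, universe)
        expected = hypergeom.sf(9, 100, 10, 10) + 0  # = pmf(10) alone
        assert tab.loc["set", "p"] == pytest.approx(expected)
        assert tab.loc["set", "p"] == pytest.approx(1 / 17310309456440)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        tab = br.overrepresentation(universe[:5], {"s": universe[10:]}, universe)
        assert tab.loc["s", "p"] == pytest.approx(1.0)

    def test_set_equal_to_universe_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        tab = br.overrepresentation(universe[:5], {"s": universe}, universe)
        assert tab.loc["s", "p"] == pytest.approx(1.0)

    def test_cluster_outside_universe_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            br.overrepresentation(["x"], {"s": ["a"]}, ["a", "b"])


class TestBulkCorrelation:
    def test_identical_signatures_r_one(self, syn_small, syn_signatures):
        cfg, cm, truth = syn_small
        bulk, labels = generate_bulk(cfg, cm, truth, 3)
        sig = syn_signatures["pathway1"]
        r, _ = br.bulk_correlation(bulk, labels.values, sig, sig, "core")
        assert r == pytest.approx(1.0)

    def test_too_few_samples_is_error(self, syn_small, syn_signatures):
        cfg, cm, truth = syn_small
        bulk, labels = generate_bulk(cfg, cm, truth, 1)
        sig = syn_signatures["pathway1"]
        with pytest.raises(ValueError, match="fewer than 3"):
            br.bulk_correlation(bulk, labels.values, sig, sig, "periphery")
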