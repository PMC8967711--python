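"""Normalization, HVG selection, PCA, BBKNN graph and class merging."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import neurotax as nt
from neurotax._utils import as_dense
from neurotax.embedding import build_bbknn_graph, cluster_and_merge, leiden_clusters


def _adata_from_counts(X, batches=None):
    n, m = X.shape
    a = ad.AnnData(
        X=np.asarray(X, dtype=np.int32),
        obs=pd.DataFrame(
            {"batch": batches if batches is not None else ["b0"] * n},
            index=[f"c{i}" for i in range(n)],
        ),
        var=pd.DataFrame(index=[f"g{j}" for j in range(m)]),
    )
    a.layers["spliced"] = np.asarray(X, dtype=np.int32)
    return a


class TestNormalize:
    def test_proportional_cells_identical_after_depth_norm(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 20, size=30)
        X = np.vstack([base, base * 3, rng.integers(0, 20, size=30)])
        a = nt.normalize(_adata_from_counts(X))
        norm = a.layers["spliced_norm"]
        assert np.allclose(norm[0], norm[1], rtol=1e-6)

    def test_constant_gene_scaled_to_zero(self):
        # equal per-cell totals, so the constant gene stays constant after
        # depth normalization and hits the variance guard
        X = np.ones((10, 5), dtype=int)
        X[:, 0] = 5
        X[:, 1] = np.arange(10)
        X[:, 2] = 9 - np.arange(10)
        a = nt.normalize(_adata_from_counts(X))
        assert np.allclose(a.layers["scaled"][:, 0], 0.0)

    def test_scaled_columns_standardized(self, normalized_small):
        a = normalized_small["macaque"]
        scaled = as_dense(a.layers["scaled"]).astype(np.float64)
        logn = as_dense(a.layers["lognorm"])
        varying = logn.std(axis=0) > 1e-8
        # clipping (+/- 10) legitimately shifts the moments of extreme genes
        unclipped = np.abs(scaled).max(axis=0) < 10.0
        cols = varying & unclipped
        assert np.abs(scaled[:, cols].mean(axis=0)).max() < 1e-8
        assert np.abs(scaled[:, cols].var(axis=0) - 1.0).max() < 1e-6

    def test_all_zero_cells_dropped_with_warning(self):
        X = np.ones((4, 6), dtype=int)
        X[2] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            a = nt.normalize(_adata_from_counts(X))
        assert a.n_obs == 3


class TestSelectHVG:
    def test_single_sample_relaxed_with_warning(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2.0, size=(50, 40))
        a = nt.normalize(_adata_from_counts(X))
        with pytest.warns(UserWarning, match="sample"):
            hvg = nt.select_hvg(a, n_hvg=10)
        assert 0 < len(hvg) <= 10

    def test_zero_variance_gene_never_selected(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(2.0, size=(60, 30))
        X[:, 0] = 5  # constant gene
        batches = ["b0"] * 30 + ["b1"] * 30
        a = nt.normalize(_adata_from_counts(X, batches))
        with pytest.warns(UserWarning):
            hvg = nt.select_hvg(a, n_hvg=1000)
        assert "g0" not in hvg

    def test_matches_direct_dispersion_oracle(self, normalized_small):
        """Final list equals an independent recomputation of the rule."""
        a = normalized_small["mouse"]
        n_hvg = 100
        hvg = nt.select_hvg(a, n_hvg=n_hvg)

        logn = as_dense(a.layers["lognorm"])
        samples = a.obs["batch"].astype(str)
        zs, variable = [], np.zeros(a.n_vars, int)
        for s in pd.unique(samples):
            sub = logn[(samples == s).to_numpy()]
            mean, var = sub.mean(axis=0), sub.var(axis=0)
            disp = np.where(mean > 1e-12, var / np.where(mean > 1e-12, mean, 1), 0.0)
            ranks = pd.Series(mean).rank(method="first").to_numpy()
            bins = np.ceil(ranks / (len(mean) / 20)).astype(int)
            z = np.zeros_like(disp)
            for b in np.unique(bins):
                m_ = bins == b
                sd = disp[m_].std()
                z[m_] = (disp[m_] - disp[m_].mean()) / sd if sd > 1e-12 else 0.0
            zs.append(z)
            variable += (z > 0.5).astype(int)
        zm = np.mean(zs, axis=0)
        eligible = (variable >= 2) & (logn.var(axis=0) > 0)
        order = np.where(eligible)[0][np.argsort(-zm[eligible], kind="stable")]
        expected = [a.var_names[i] for i in order[:n_hvg]]
        assert hvg == expected

    def test_high_dispersion_programme_genes_recovered(
        self, normalized_small, small_data
    ):
        """Planted programme genes that rank among the top raw dispersions
        are recovered in the HVG list at 10x their count."""
        _, _, truth = small_data
        a = normalized_small["macaque"]
        logn = as_dense(a.layers["lognorm"])
        mean, var = logn.mean(axis=0), logn.var(axis=0)
        disp = np.where(mean > 1e-12, var / np.where(mean > 1e-12, mean, 1), 0.0)
        top = set(np.asarray(a.var_names)[np.argsort(-disp)[:150]])
        planted = {
            g
            for g, grp in truth.genes["group"].items()
            if grp.startswith(("marker", "specific", "tf", "cycling", "maturation"))
        }
        targets = top & planted
        with pytest.warns(UserWarning):
            hvg = set(nt.select_hvg(a, n_hvg=10 * len(targets)))
        assert np.mean([g in hvg for g in targets]) >= 0.95


class TestPCA:
    def test_explained_variance_non_increasing(self, demo_state):
        _, state = demo_state
        ev = state["processed"]["macaque"]["adata"].uns["pca"]["explained_variance"]
        assert np.all(np.diff(ev) <= 1e-9)


class TestBBKNN:
    @staticmethod
    def _brute_force(pcs, batches, k):
        edges = set()
        batches = np.asarray(batches)
        for i in range(len(pcs)):
            for b in np.unique(batches):
                members = [
                    j for j in range(len(pcs)) if batches[j] == b and j != i
                ]
                d = [(np.linalg.norm(pcs[i] - pcs[j]), j) for j in members]
                for _, j in sorted(d)[:k]:
                    edges.add((i, j))
        return edges

    @pytest.mark.parametrize("n,k,n_batches,seed", [(50, 3, 2, 0), (120, 4, 3, 1), (200, 3, 2, 2)])
    def test_equals_brute_force(self, n, k, n_batches, seed):
        rng = np.random.default_rng(seed)
        pcs = rng.normal(size=(n, 5))
        batches = rng.integers(0, n_batches, n).astype(str)
        graph = build_bbknn_graph(pcs, batches, k=k)
        got = set(zip(*graph.distances.nonzero()))
        assert got == self._brute_force(pcs, batches, k)

    def test_edge_counts_two_batches(self):
        rng = np.random.default_rng(3)
        pcs = rng.normal(size=(80, 4))
        batches = np.array(["a"] * 40 + ["b"] * 40)
        graph = build_bbknn_graph(pcs, batches, k=3)
        out_degree = np.diff(graph.distances.indptr)
        assert (out_degree == 6).all()

    def test_single_batch_is_plain_knn(self):
        rng = np.random.default_rng(4)
        pcs = rng.normal(size=(30, 3))
        graph = build_bbknn_graph(pcs, ["b"] * 30, k=5)
        assert (np.diff(graph.distances.indptr) == 5).all()

    def test_no_self_edges(self):
        rng = np.random.default_rng(5)
        pcs = rng.normal(size=(40, 3))
        graph = build_bbknn_graph(pcs, ["a"] * 20 + ["b"] * 20, k=2)
        assert graph.distances.diagonal().sum() == 0

    def test_small_batch_warns_and_uses_all(self):
        rng = np.random.default_rng(6)
        pcs = rng.normal(size=(23, 3))
        batches = ["a"] * 20 + ["b"] * 3
        with pytest.warns(UserWarning, match="cells"):
            graph = build_bbknn_graph(pcs, batches, k=4)
        # edges into the 3-cell batch: at most 3 per query (2 for its members)
        into_b = graph.distances[:, 20:].getnnz(axis=1)
        assert into_b[:20].max() == 3 and into_b[20:].max() == 2


class TestClusterAndMerge:
    @pytest.fixture(scope="class")
    def clustered(self, normalized_small):
        a = normalized_small["mouse"]
        with pytest.warns(UserWarning):
            hvg = nt.select_hvg(a, n_hvg=12000)
        a = nt.run_pca(a, hvg, n_pcs=50, seed=0)
        graph = build_bbknn_graph(a.obsm["X_pca"], a.obs["batch"], k=3)
        return a, graph, hvg

    def test_merge_distance_zero_keeps_fine_clusters(self, clustered):
        a, graph, hvg = clustered
        asn = cluster_and_merge(graph, a, hvg, resolution=2.0, merge_distance=0.0, seed=0)
        assert asn.classes.nunique() == asn.fine.nunique()

    def test_merge_distance_two_gives_single_class(self, clustered):
        a, graph, hvg = clustered
        asn = cluster_and_merge(graph, a, hvg, resolution=2.0, merge_distance=2.0, seed=0)
        assert asn.classes.nunique() == 1

    def test_each_fine_cluster_maps_to_one_class(self, clustered):
        a, graph, hvg = clustered
        asn = cluster_and_merge(graph, a, hvg, resolution=2.0, seed=0)
        mapping = pd.DataFrame({"fine": asn.fine, "cls": asn.classes})
        assert (mapping.groupby("fine")["cls"].nunique() == 1).all()

    def test_dendrogram_heights_bounded_and_monotone(self, clustered):
        a, graph, hvg = clustered
        asn = cluster_and_merge(graph, a, hvg, resolution=2.0, seed=0)
        Z = asn.linkage_matrix
        assert Z is not None
        h = Z[:, 2]
        assert (h >= 0).all() and (h <= 2 + 1e-9).all()
        assert (np.diff(h) >= -1e-9).all()  # complete linkage is monotone

    def test_reproducible_under_fixed_seed(self, clustered):
        a, graph, hvg = clustered
        l1 = leiden_clusters(graph, resolution=5.0, seed=42)
        l2 = leiden_clusters(graph, resolution=5.0, seed=42)
        assert l1.equals(l2)

    def test_explicit_cluster_map_overrides(self, clustered):
        a, graph, hvg = clustered
        base = cluster_and_merge(graph, a, hvg, resolution=2.0, seed=0)
        manual = {c: "LUMP" for c in base.fine.unique()}
        asn = cluster_and_merge(
            graph, a, hvg, resolution=2.0, seed=0, cluster_to_class=manual
        )
        assert set(asn.classes) == {"LUMP"}
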