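"""Normalization, HVG selection, PCA, batch-balanced kNN and Leiden classes.

The processing order mirrors standard practice for droplet scRNA-seq:
depth normalization to a common target sum, log1p, per-gene z-scaling,
dispersion-based highly-variable-gene selection computed per sequencing
sample (a gene must be variable in more than one sample to survive, which
acts as a light batch filter), PCA on the scaled HVG matrix, a
batch-balanced k-nearest-neighbour graph (k nearest cells *per batch* by
Euclidean distance in PC space), Leiden clustering at high resolution, and
finally merging of the fine clusters into classes.  The default merge uses
trajectory continuity (classes are connected components of the thresholded
cluster-level graph, since differentiation stages of one class are densely
linked while distinct classes are not); a complete-linkage dendrogram of
the Pearson-correlation distance between cluster mean-expression vectors is
always computed, and an explicit ``merge_distance`` cuts that dendrogram
instead.  Both stand in for the manual, marker-guided curation of real
datasets: an externally supplied cluster-to-class map takes precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._utils import ConfigurationError, as_dense, logger


@dataclass(frozen=True)
class EmbeddingConfig:
    n_hvg: int = 12000
    n_pcs: int = 100
    neighbors_per_batch: int = 3  # 12 when merging developmental and adult data
    leiden_resolution: float = 10.0
    merge_distance: float | None = None  # None: trajectory-continuity merge
    scale_clip: float | None = 10.0
    hvg_z_cutoff: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not (self.n_hvg >= self.n_pcs >= 2):
            raise ConfigurationError("need n_hvg >= n_pcs >= 2")
        if self.neighbors_per_batch < 1:
            raise ConfigurationError("neighbors_per_batch must be >= 1")
        if self.leiden_resolution <= 0:
            raise ConfigurationError("leiden_resolution must be positive")


@dataclass
class NeighborGraph:
    """Directed batch-balanced kNN graph over cells.

    ``distances`` holds the directed edges (entry [i, j] is the Euclidean PC
    distance of the edge i -> j); ``connectivities`` is the symmetrized
    unweighted adjacency used for clustering and as the random-walk support.
    """

    distances: sp.csr_matrix
    connectivities: sp.csr_matrix
    batches: pd.Series
    k_per_batch: int

    @property
    def n_cells(self) -> int:
        return self.distances.shape[0]

    def out_neighbors(self, i: int) -> np.ndarray:
        return self.distances.indices[self.distances.indptr[i] : self.distances.indptr[i + 1]]


@dataclass
class ClassAssignment:
    """Fine Leiden clusters plus their merge into initial classes."""

    fine: pd.Series  # per-cell fine cluster id (int)
    classes: pd.Series  # per-cell merged class label (str)
    class_means: pd.DataFrame  # class x HVG mean expression
    linkage_matrix: np.ndarray | None
    cluster_to_class: dict[int, str]

    def validate(self) -> None:
        mapped = self.fine.map(self.cluster_to_class)
        if not (mapped == self.classes).all():
            raise ConfigurationError("each fine cluster must map to exactly one class")


def normalize(dataset: ad.AnnData, target_sum: float | None = None,
              scale_clip: float | None = 10.0) -> ad.AnnData:
    """Depth-normalize, log-transform and per-gene standardize the counts.

    The spliced and unspliced layers are each depth-normalized to the median
    per-cell total of that layer (kept un-logged for velocity estimation);
    ``layers['lognorm']`` holds log1p of the normalized spliced matrix and
    ``layers['scaled']`` its per-gene z-scores (clipped at ``scale_clip``).
    Raw counts remain in ``layers['spliced']`` / ``layers['unspliced']``.
    All-zero cells are dropped with a warning before scaling.
    """
    X = as_dense(dataset.layers.get("spliced", dataset.X)).astype(np.float64)
    totals = X.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(f"removing {int((~nonzero).sum())} all-zero cells", stacklevel=2)
        dataset = dataset[nonzero].copy()
        X = X[nonzero]
        totals = totals[nonzero]

    adata = dataset.copy()
    target = float(target_sum) if target_sum else float(np.median(totals))
    norm = X / totals[:, None] * target
    adata.layers["spliced_norm"] = norm.astype(np.float32)

    if "unspliced" in adata.layers:
        U = as_dense(adata.layers["unspliced"]).astype(np.float64)
        u_tot = U.sum(axis=1)
        u_target = float(np.median(u_tot[u_tot > 0])) if (u_tot > 0).any() else 1.0
        adata.layers["unspliced_norm"] = (
            U / np.where(u_tot > 0, u_tot, 1.0)[:, None] * u_target
        ).astype(np.float32)

    logn = np.log1p(norm)
    adata.layers["lognorm"] = logn.astype(np.float32)

    mean = logn.mean(axis=0)
    std = logn.std(axis=0)
    std_safe = np.where(std > 1e-12, std, 1.0)  # constant genes scale to zero
    scaled = (logn - mean) / std_safe
    if scale_clip is not None:
        np.clip(scaled, -scale_clip, scale_clip, out=scaled)
    adata.layers["scaled"] = scaled  # float64: downstream asserts exact moments
    adata.uns["normalize"] = {"target_sum": target, "scale_clip": scale_clip}
    return adata


def select_hvg(
    dataset: ad.AnnData,
    n_hvg: int = 12000,
    sample_key: str = "batch",
    z_cutoff: float = 0.5,
    n_bins: int = 20,
    min_samples_variable: int = 2,
) -> list[str]:
    """Dispersion-based HVG selection with a multi-sample variability rule.

    Per sample: per-gene mean and dispersion (variance/mean) of the
    log-normalized data; genes are binned by mean into ``n_bins`` equal-count
    bins and dispersions z-scored within bins.  A gene counts as variable in
    a sample when its z-scored dispersion exceeds ``z_cutoff``; the final
    list is the top ``n_hvg`` genes by mean z-scored dispersion among genes
    variable in at least ``min_samples_variable`` samples.
    """
    logn = as_dense(dataset.layers["lognorm"])
    samples = (
        dataset.obs[sample_key].astype(str)
        if sample_key in dataset.obs
        else pd.Series("all", index=dataset.obs_names)
    )
    unique = list(pd.unique(samples))
    if len(unique) < min_samples_variable:
        warnings.warn(
            f"only {len(unique)} sample(s); relaxing the multi-sample "
            "variability rule to the available samples",
            stacklevel=2,
        )
        min_samples_variable = len(unique)

    z_all, variable_counts = [], np.zeros(dataset.n_vars, dtype=int)
    for s in unique:
        sub = logn[(samples == s).to_numpy()]
        mean = sub.mean(axis=0)
        var = sub.var(axis=0)
        disp = np.where(mean > 1e-12, var / np.where(mean > 1e-12, mean, 1.0), 0.0)
        z = _bin_zscore(mean, disp, n_bins)
        z_all.append(z)
        variable_counts += (z > z_cutoff).astype(int)
    z_mean = np.mean(z_all, axis=0)

    eligible = variable_counts >= min_samples_variable
    eligible &= np.asarray(logn.var(axis=0) > 0)  # never a zero-variance gene
    candidates = np.where(eligible)[0]
    if len(candidates) < n_hvg:
        warnings.warn(
            f"only {len(candidates)} genes eligible for n_hvg={n_hvg}; returning all",
            stacklevel=2,
        )
    order = candidates[np.argsort(-z_mean[candidates], kind="stable")]
    chosen = order[:n_hvg]
    return [dataset.var_names[i] for i in chosen]


def _bin_zscore(mean: np.ndarray, disp: np.ndarray, n_bins: int) -> np.ndarray:
    """Z-score dispersions within equal-count bins of the gene mean."""
    ranks = pd.Series(mean).rank(method="first").to_numpy()
    bins = np.ceil(ranks / (len(mean) / n_bins)).astype(int)
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        idx = bins == b
        mu, sd = disp[idx].mean(), disp[idx].std()
        z[idx] = (disp[idx] - mu) / sd if sd > 1e-12 else 0.0
    return z


def run_pca(
    dataset: ad.AnnData, hvg: list[str], n_pcs: int = 100, seed: int = 0
) -> ad.AnnData:
    """Seeded randomized PCA on the scaled HVG matrix.

    Stores coordinates in ``obsm['X_pca']``, loadings in ``uns['pca']``
    (components x HVGs) together with the HVG list and explained variance.
    """
    scaled = as_dense(dataset.layers["scaled"])
    gidx = [dataset.var_names.get_loc(g) for g in hvg]
    M = scaled[:, gidx]
    n_comp = int(min(n_pcs, M.shape[0] - 1, M.shape[1]))
    if n_comp < n_pcs:
        logger.info("reducing n_pcs from %d to %d for matrix shape %s", n_pcs, n_comp, M.shape)
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    coords = pca.fit_transform(M)
    dataset.obsm["X_pca"] = coords.astype(np.float32)
    dataset.uns["pca"] = {
        "components": pca.components_.astype(np.float32),
        "explained_variance": pca.explained_variance_.astype(np.float64),
        "hvg": list(hvg),
    }
    return dataset


def build_bbknn_graph(
    pcs: np.ndarray, batches: pd.Series | np.ndarray, k: int = 3
) -> NeighborGraph:
    """Batch-balanced kNN: for every cell, its k nearest cells in each batch.

    Distances are Euclidean in PC space; self-edges are excluded; a batch
    with fewer than k other cells contributes all it has (with a warning).
    The union over batches forms the directed graph; the symmetrized,
    binarized adjacency is kept for clustering.
    """
    pcs = np.asarray(pcs, dtype=np.float64)
    batches = pd.Series(np.asarray(batches).astype(str))
    n = pcs.shape[0]
    rows, cols, vals = [], [], []
    for b in pd.unique(batches):
        members = np.where((batches == b).to_numpy())[0]
        nn = NearestNeighbors(n_neighbors=min(k + 1, len(members)), algorithm="auto")
        nn.fit(pcs[members])
        dist, idx = nn.kneighbors(pcs)  # queries: all cells
        for i in range(n):
            targets = members[idx[i]]
            keep = targets != i
            t = targets[keep][:k]
            d = dist[i][keep][:k]
            if len(t) < k and len(members) - (i in set(members)) < k:
                pass  # small batch: take all available (warned once below)
            rows.extend([i] * len(t))
            cols.extend(t)
            vals.extend(d)
        if len(members) <= k:
            warnings.warn(
                f"batch {b!r} has only {len(members)} cells (< k+1={k + 1}); using all",
                stacklevel=2,
            )
    distances = sp.csr_matrix(
        (np.asarray(vals, dtype=np.float64), (rows, cols)), shape=(n, n)
    )
    adj = distances.copy()
    adj.data[:] = 1.0
    conn = adj.maximum(adj.T)
    return NeighborGraph(
        distances=distances, connectivities=conn.tocsr(), batches=batches, k_per_batch=k
    )


def leiden_clusters(
    graph: NeighborGraph, resolution: float = 10.0, seed: int = 0
) -> pd.Series:
    """Leiden community detection on the symmetrized graph."""
    conn = sp.triu(graph.connectivities, k=0).tocoo()
    g = igraph.Graph(
        n=graph.n_cells, edges=list(zip(conn.row.tolist(), conn.col.tolist()))
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return pd.Series(np.asarray(part.membership, dtype=int))


def cluster_and_merge(
    graph: NeighborGraph,
    dataset: ad.AnnData,
    hvg: list[str],
    resolution: float = 10.0,
    merge_distance: float | None = None,
    seed: int = 0,
    cluster_to_class: dict[int, str] | None = None,
) -> ClassAssignment:
    """Fine Leiden clusters merged into classes by correlation dendrogram.

    Cluster mean expression (scaled, over HVGs) is hierarchically clustered
    with complete linkage of the Pearson-correlation distance (1 - r);
    cutting the dendrogram at ``merge_distance`` yields the merged classes.
    With ``merge_distance=None`` the cut is placed automatically in the
    largest *relative* gap between consecutive merge heights (the class
    structure announces itself as a multiplicative jump from within-class to
    between-class merge heights, robust to how many classes there are).  An
    explicit ``cluster_to_class`` map overrides the automatic cut,
    supporting manually curated class assignments.
    """
    fine = leiden_clusters(graph, resolution=resolution, seed=seed)
    fine.index = dataset.obs_names
    min_connectivity = 0.1

    # reassign disconnected singleton clusters to the closest cluster;
    # cluster means use the scaled expression so the dominant maturation-
    # stage programmes (shared across classes) do not swamp class identity
    degree = np.asarray(graph.connectivities.sum(axis=1)).ravel()
    scaled = as_dense(dataset.layers["scaled"])
    gidx = [dataset.var_names.get_loc(g) for g in hvg]
    E = scaled[:, gidx]
    sizes = fine.value_counts()
    singletons = [c for c in sizes.index[sizes == 1]]
    if singletons:
        big = [c for c in sizes.index if sizes[c] > 1]
        means = {c: E[(fine == c).to_numpy()].mean(axis=0) for c in big}
        for c in singletons:
            i = np.where((fine == c).to_numpy())[0][0]
            if degree[i] > 0 and big:
                best = max(big, key=lambda cc: _pearson(E[i], means[cc]))
                logger.info("reassigning singleton cluster %s to %s", c, best)
                fine.iloc[i] = best
        fine = fine.map({c: r for r, c in enumerate(sorted(fine.unique()))})

    clusters = sorted(fine.unique())
    mean_expr = np.vstack([E[(fine == c).to_numpy()].mean(axis=0) for c in clusters])

    Z = None
    if cluster_to_class is None:
        if len(clusters) == 1:
            cluster_to_class = {clusters[0]: "C1"}
        else:
            corr = np.corrcoef(mean_expr)
            corr = np.nan_to_num(corr, nan=0.0)
            D = np.clip(1.0 - corr, 0.0, 2.0)
            np.fill_diagonal(D, 0.0)
            Z = linkage(squareform(D, checks=False), method="complete")
            if merge_distance is not None:
                flat = fcluster(Z, t=merge_distance, criterion="distance")
            else:
                # default: trajectory-continuity merging.  Differentiation is
                # continuous, so stage-subclusters of one class are densely
                # linked in the kNN graph while distinct classes are not;
                # classes are the connected components of the cluster-level
                # graph after thresholding normalized connectivity.
                flat = _connectivity_components(
                    graph, fine, clusters, min_connectivity
                )
            cluster_to_class = {c: f"C{fl}" for c, fl in zip(clusters, flat)}

    classes = fine.map(cluster_to_class).astype(str)
    class_means = (
        pd.DataFrame(mean_expr, index=[cluster_to_class[c] for c in clusters], columns=hvg)
        .groupby(level=0)
        .mean()
    )
    assignment = ClassAssignment(
        fine=fine,
        classes=classes,
        class_means=class_means,
        linkage_matrix=Z,
        cluster_to_class=cluster_to_class,
    )
    assignment.validate()
    return assignment


def _connectivity_components(
    graph: NeighborGraph,
    fine: pd.Series,
    clusters: list,
    min_connectivity: float = 0.1,
) -> np.ndarray:
    """Merge fine clusters into the components of their connectivity graph.

    The weight between clusters i and j is the number of kNN edges linking
    them, normalized by sqrt(n_i * n_j); pairs at or above
    ``min_connectivity`` are linked and classes are the resulting connected
    components (labelled 1..K in cluster order).
    """
    from scipy.sparse.csgraph import connected_components

    labels = fine.to_numpy()
    k = len(clusters)
    idx = {c: i for i, c in enumerate(clusters)}
    memb = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), [idx[c] for c in labels])),
        shape=(len(labels), k),
    )
    A = graph.connectivities.maximum(graph.connectivities.T)
    E = (memb.T @ A @ memb).toarray()
    sizes = np.asarray(memb.sum(axis=0)).ravel()
    norm = E / np.sqrt(np.outer(sizes, sizes))
    np.fill_diagonal(norm, 0.0)
    # a link must also hold its own against the endpoints' strongest links:
    # spurious bridges (a couple of forced batch-balanced edges between
    # otherwise unrelated clusters) are weak relative to the true
    # consecutive-stage links of both endpoints
    top = norm.max(axis=1)
    rel_floor = 0.5 * np.minimum.outer(top, top)
    adj = sp.csr_matrix((norm >= min_connectivity) & (norm >= rel_floor))
    _, comp = connected_components(adj, directed=False)
    # relabel components to consecutive ids in cluster order
    remap = {}
    out = np.empty(k, dtype=int)
    for i, c in enumerate(comp):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[i] = remap[c]
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def embed_and_cluster(
    dataset: ad.AnnData,
    config: EmbeddingConfig | None = None,
    cluster_to_class: dict[int, str] | None = None,
) -> tuple[ad.AnnData, NeighborGraph, ClassAssignment]:
    """Convenience pipeline: normalize -> HVG -> PCA -> BBKNN -> classes."""
    config = config or EmbeddingConfig()
    config.validate()
    adata = normalize(dataset, scale_clip=config.scale_clip)
    hvg = select_hvg(adata, n_hvg=config.n_hvg, z_cutoff=config.hvg_z_cutoff)
    adata = run_pca(adata, hvg, n_pcs=config.n_pcs, seed=config.seed)
    graph = build_bbknn_graph(
        adata.obsm["X_pca"],
        adata.obs["batch"] if "batch" in adata.obs else pd.Series("all", index=adata.obs_names),
        k=config.neighbors_per_batch,
    )
    assignment = cluster_and_merge(
        graph,
        adata,
        hvg,
        resolution=config.leiden_resolution,
        merge_distance=config.merge_distance,
        seed=config.seed,
        cluster_to_class=cluster_to_class,
    )
    adata.obs["leiden"] = assignment.fine.to_numpy()
    adata.obs["initial_class"] = assignment.classes.to_numpy()
    return adata, graph, assignment
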