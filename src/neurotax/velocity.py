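"""Steady-state RNA velocity, diffusion latent time and new-born calling.

RNA velocity rests on the two-state transcription model: unspliced
pre-mRNA u is produced at rate alpha, spliced at rate beta*u, degraded at
rate gamma*s, so at steady state u = (gamma/beta) * s.  The steady-state
estimator fits, per gene, the slope gamma_hat of u against s through the
origin using only cells in the extreme quantiles of s (where the
steady-state assumption is most defensible); the velocity of a cell is the
residual v = u - gamma_hat * s, positive while a gene is being induced and
negative while it is being repressed.

Latent time is a per-cell coordinate in [0, 1]: the diffusion distance
from a root set of progenitor-like cells on the neighbour graph,
min-normalized and rescaled.  Roots default to the cells with the highest
mean expression of cycling/progenitor markers.  "New-born" neurons are the
cells of each class strictly below that class's median latent time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh

from ._utils import ConfigurationError, as_dense, logger
from .embedding import NeighborGraph

DEFAULT_PROGENITOR_MARKERS = ("MKI67", "TOP2A", "CCNB1", "CDK1", "AURKA")


@dataclass
class VelocityField:
    gamma_hat: pd.Series  # per-gene slope estimate (>= 0)
    velocity: np.ndarray  # cells x genes, u - gamma_hat * s
    latent_time: pd.Series | None = None
    roots: np.ndarray | None = None
    degenerate_genes: list = field(default_factory=list)


@dataclass
class NewbornPartition:
    newborn: pd.Series  # per-cell boolean
    thresholds: pd.Series  # per-class 0.5-quantile of latent time


def estimate_velocity(
    dataset: ad.AnnData,
    quantile_frac: float = 0.05,
    spliced_layer: str = "spliced_norm",
    unspliced_layer: str = "unspliced_norm",
) -> VelocityField:
    """Per-gene steady-state gamma and per-cell velocity.

    ``gamma_hat`` is the zero-intercept least-squares slope of u on s over
    cells in the top and bottom ``quantile_frac`` of s for that gene.
    Genes with all-zero unspliced signal get gamma_hat = 0, velocity 0,
    and are flagged in ``degenerate_genes``.
    """
    if not 0 < quantile_frac <= 0.5:
        raise ConfigurationError("quantile_frac must lie in (0, 0.5]")
    S = as_dense(dataset.layers[spliced_layer]).astype(np.float64)
    U = as_dense(dataset.layers[unspliced_layer]).astype(np.float64)
    if S.shape != U.shape:
        raise ConfigurationError("spliced and unspliced matrices must share dimensions")
    n, m = S.shape

    lo = np.quantile(S, quantile_frac, axis=0)
    hi = np.quantile(S, 1.0 - quantile_frac, axis=0)
    extreme = (S <= lo[None, :]) | (S >= hi[None, :])

    Sx = np.where(extreme, S, 0.0)
    Ux = np.where(extreme, U, 0.0)
    num = (Ux * Sx).sum(axis=0)
    den = (Sx * Sx).sum(axis=0)
    gamma = np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 0.0)
    gamma = np.clip(gamma, 0.0, None)

    degenerate = [dataset.var_names[j] for j in np.where(U.sum(axis=0) == 0)[0]]
    gamma[np.asarray(U.sum(axis=0) == 0)] = 0.0

    velocity = U - gamma[None, :] * S
    velocity[:, np.asarray(U.sum(axis=0) == 0)] = 0.0
    if degenerate:
        logger.info("%d genes with all-zero unspliced counts flagged", len(degenerate))
    return VelocityField(
        gamma_hat=pd.Series(gamma, index=dataset.var_names),
        velocity=velocity.astype(np.float32),
        degenerate_genes=degenerate,
    )


def score_progenitor_roots(
    dataset: ad.AnnData,
    markers: tuple[str, ...] = DEFAULT_PROGENITOR_MARKERS,
    n_roots: int | None = None,
    layer: str = "lognorm",
) -> np.ndarray:
    """Indices of the cells scoring highest on cycling/progenitor markers.

    By default the root set is 2% of cells (at least 30): with several
    branches in one dataset every branch should contribute its youngest
    cells to the root set, since the progenitor programme is shared.
    """
    if n_roots is None:
        n_roots = max(30, int(0.02 * dataset.n_obs))
    present = [g for g in markers if g in dataset.var_names]
    if not present:
        # fall back on case-insensitive match (mouse-style capitalisation)
        lower = {g.lower(): g for g in dataset.var_names}
        present = [lower[g.lower()] for g in markers if g.lower() in lower]
    if not present:
        raise ConfigurationError(
            f"none of the progenitor markers {markers} found; supply roots explicitly"
        )
    expr = as_dense(dataset.layers[layer])[:, [dataset.var_names.get_loc(g) for g in present]]
    score = expr.mean(axis=1)
    return np.argsort(-score, kind="stable")[:n_roots]


def compute_latent_time(
    graph: NeighborGraph,
    pcs: np.ndarray,
    roots: np.ndarray,
    n_comps: int = 15,
) -> pd.Series:
    """Diffusion-distance latent time from a root set, rescaled to [0, 1].

    An adaptive Gaussian kernel on the symmetrized graph (bandwidth: each
    cell's distance to its k-th neighbour, making the result invariant to a
    global rescaling of PC coordinates) defines a diffusion operator; cells
    are embedded in diffusion components scaled by lambda/(1-lambda) and the
    latent time of a cell is its Euclidean diffusion distance to the nearest
    root, min-shifted and max-normalized.  Cells in components unreachable
    from the roots get time 1.0 with a warning.
    """
    roots = np.asarray(roots, dtype=int)
    if roots.size == 0:
        raise ConfigurationError(
            "empty root set: supply root cells or enable automatic progenitor scoring"
        )
    n = graph.n_cells
    pcs = np.asarray(pcs, dtype=np.float64)

    conn = graph.connectivities.maximum(graph.connectivities.T).tocoo()
    d2 = ((pcs[conn.row] - pcs[conn.col]) ** 2).sum(axis=1)
    # adaptive bandwidth: distance to the farthest stored neighbour
    dist_sym = graph.distances.maximum(graph.distances.T).tocsr()
    sigma = np.zeros(n)
    for i in range(n):
        row = dist_sym.data[dist_sym.indptr[i] : dist_sym.indptr[i + 1]]
        sigma[i] = row.max() if row.size else 1.0
    sigma = np.where(sigma > 1e-12, sigma, 1.0)
    w = np.exp(-d2 / (sigma[conn.row] * sigma[conn.col]))
    W = sp.csr_matrix((w, (conn.row, conn.col)), shape=(n, n))

    n_cc, labels = connected_components(W, directed=False)
    reachable = np.isin(labels, np.unique(labels[roots]))
    if not reachable.all():
        warnings.warn(
            f"{int((~reachable).sum())} cells unreachable from roots; assigned time 1.0",
            stacklevel=2,
        )

    deg = np.asarray(W.sum(axis=1)).ravel()
    deg = np.where(deg > 1e-12, deg, 1.0)
    Dinv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    M = Dinv_sqrt @ W @ Dinv_sqrt
    k = int(min(n_comps + 1, n - 1))
    v0 = np.full(n, 1.0 / np.sqrt(n))  # deterministic Lanczos start
    vals, vecs = eigsh(M, k=k, which="LA", v0=v0)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    # drop the trivial stationary component(s); scale the rest
    keep = (vals < 1.0 - 1e-9) & (vals > 1e-9)
    vals, vecs = vals[keep], vecs[:, keep]
    psi = vecs / np.sqrt(deg)[:, None]
    coords = psi * (vals / (1.0 - vals))[None, :]

    diff = coords[:, None, :] - coords[None, roots, :]
    dist_to_roots = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
    t = dist_to_roots - dist_to_roots[reachable].min()
    span = t[reachable].max()
    t = t / span if span > 1e-12 else np.zeros_like(t)
    t = np.clip(t, 0.0, 1.0)
    t[~reachable] = 1.0
    return pd.Series(t, name="latent_time")


def classify_newborn(
    times: pd.Series, classes: pd.Series, quantile: float = 0.5
) -> NewbornPartition:
    """Flag cells strictly below their class's latent-time quantile.

    The threshold is the empirical quantile with the linear-interpolation
    convention; classes of size 1 are never flagged (warned).
    """
    times = pd.Series(np.asarray(times, dtype=float), index=classes.index)
    flags = pd.Series(False, index=classes.index)
    thresholds = {}
    for cls, idx in classes.groupby(classes).groups.items():
        t = times.loc[idx]
        if len(t) == 1:
            warnings.warn(f"class {cls!r} has a single cell; not flagged", stacklevel=2)
            thresholds[cls] = float(t.iloc[0])
            continue
        thr = float(np.quantile(t.to_numpy(), quantile))
        thresholds[cls] = thr
        flags.loc[idx] = (t < thr).to_numpy()
    return NewbornPartition(newborn=flags, thresholds=pd.Series(thresholds))
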