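"""Markov-chain fate mapping: kernels, absorption probabilities, summaries.

Developmental and terminal (adult) cells are joined in one nearest-neighbour
graph.  A row-stochastic transition matrix mixes, with equal weight by
default, a connectivity kernel (row-normalized symmetrized adjacency) and a
velocity kernel (per cell, a softmax over its out-neighbours of the cosine
between the displacement in PC space and the cell's velocity vector
projected into PC space).  Terminal cells are absorbing states grouped by
terminal class; the absorption probability of each transient cell into each
terminal class comes from sparse solves of (I - Q) X = R, the fundamental
matrix system of the absorbing chain.

Summaries follow the study design: classes are subsampled to at most 1,000
cells to blunt compositional bias, the 100 transient cells most strongly
absorbed into each terminal class are tabulated by their initial class
(the Sankey edge table), and an initial-class x terminal-class mean
absorption matrix is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ._utils import ConfigurationError, logger
from .embedding import NeighborGraph
from .velocity import VelocityField


@dataclass
class TransitionKernel:
    matrix: sp.csr_matrix  # combined row-stochastic kernel
    connectivity: sp.csr_matrix
    velocity: sp.csr_matrix
    weight: float

    def validate(self) -> None:
        rowsum = np.asarray(self.matrix.sum(axis=1)).ravel()
        if np.abs(rowsum - 1.0).max() > 1e-9:
            raise ConfigurationError("transition kernel rows must sum to 1")
        if self.matrix.data.min() < -1e-12:
            raise ConfigurationError("transition kernel entries must be >= 0")


@dataclass
class FateResult:
    absorption: pd.DataFrame  # transient cells x terminal classes
    terminal_classes: list
    unreachable: pd.Index  # transient cells with no path to any absorbing state
    sankey: pd.DataFrame | None = None
    mean_absorption: pd.DataFrame | None = None
    subsampled_counts: pd.Series | None = None


def build_kernels(
    graph: NeighborGraph,
    field: VelocityField,
    pcs: np.ndarray,
    pca_components: np.ndarray,
    hvg_indices: np.ndarray,
    weight: float = 0.5,
    sigma: float | None = None,
) -> TransitionKernel:
    """Equally weighted (by default) connectivity and velocity kernels.

    ``pca_components`` (n_pcs x n_hvg) projects gene-space velocities of the
    HVG subset into PC space so displacement and velocity live in one space.
    ``sigma`` is the softmax temperature; by default each row self-tunes to
    the median |cosine| of that row.  Cells with zero velocity fall back to
    their connectivity row.
    """
    if not 0 <= weight <= 1:
        raise ConfigurationError("mixture weight must lie in [0, 1]")
    n = graph.n_cells
    pcs = np.asarray(pcs, dtype=np.float64)

    conn = graph.connectivities.maximum(graph.connectivities.T).tocsr().astype(np.float64)
    conn_rowsum = np.asarray(conn.sum(axis=1)).ravel()
    conn_rowsum = np.where(conn_rowsum > 0, conn_rowsum, 1.0)
    connectivity = sp.diags(1.0 / conn_rowsum) @ conn

    v_pc = np.asarray(field.velocity, dtype=np.float64)[:, hvg_indices] @ np.asarray(
        pca_components, dtype=np.float64
    ).T

    rows, cols, vals = [], [], []
    fallback = 0
    indptr, indices = connectivity.indptr, connectivity.indices
    for i in range(n):
        nbrs = indices[indptr[i] : indptr[i + 1]]
        nbrs = nbrs[nbrs != i]
        if nbrs.size == 0:
            rows.append(i)
            cols.append(i)
            vals.append(1.0)
            continue
        vi = v_pc[i]
        norm_v = np.linalg.norm(vi)
        if norm_v < 1e-12:
            fallback += 1
            row = connectivity[i, nbrs].toarray().ravel()
            row = row / row.sum()
            rows.extend([i] * nbrs.size)
            cols.extend(nbrs)
            vals.extend(row)
            continue
        delta = pcs[nbrs] - pcs[i]
        dn = np.linalg.norm(delta, axis=1)
        cos = (delta @ vi) / (np.where(dn > 1e-12, dn, 1.0) * norm_v)
        s = sigma if sigma is not None else max(np.median(np.abs(cos)), 1e-8)
        logits = cos / s
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        rows.extend([i] * nbrs.size)
        cols.extend(nbrs)
        vals.extend(p)
    velocity_kernel = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    if fallback:
        logger.info("%d zero-velocity cells fell back to the connectivity row", fallback)

    combined = (weight * connectivity + (1.0 - weight) * velocity_kernel).tocsr()
    rowsum = np.asarray(combined.sum(axis=1)).ravel()
    rowsum = np.where(rowsum > 0, rowsum, 1.0)
    combined = (sp.diags(1.0 / rowsum) @ combined).tocsr()
    kernel = TransitionKernel(
        matrix=combined,
        connectivity=connectivity.tocsr(),
        velocity=velocity_kernel,
        weight=weight,
    )
    kernel.validate()
    return kernel


def compute_absorption(
    kernel: TransitionKernel | sp.spmatrix,
    terminal_labels: pd.Series,
) -> FateResult:
    """Absorption probabilities of transient cells into terminal classes.

    ``terminal_labels`` holds the terminal class per cell, with NaN/None/""
    marking transient cells.  Terminal rows are replaced by self-loops.
    With Q the transient submatrix and R the transient-to-class block
    (columns pre-aggregated by class), the absorption matrix solves
    (I - Q) X = R via a single sparse LU factorization.  Transient cells
    whose probability mass cannot reach any absorbing state are flagged in
    ``unreachable`` and carry NaN rows.
    """
    P = kernel.matrix if isinstance(kernel, TransitionKernel) else sp.csr_matrix(kernel)
    labels = pd.Series(terminal_labels)
    is_terminal = labels.notna() & (labels.astype(object) != "")
    if not is_terminal.any():
        raise ConfigurationError("at least one absorbing (terminal) class is required")

    t_idx = np.where(~is_terminal.to_numpy())[0]
    a_idx = np.where(is_terminal.to_numpy())[0]
    classes = sorted(pd.unique(labels.iloc[a_idx]))
    class_of_absorbing = labels.iloc[a_idx]

    P = P.tocsr()
    # transient states in a closed communicating class can never be
    # absorbed; identify them by BFS from the absorbing states over the
    # reversed support graph and exclude them from the linear system (a
    # singular (I - Q) otherwise)
    support = (P > 0).astype(np.int8).tocsr()
    can_reach = np.zeros(P.shape[0], dtype=bool)
    can_reach[a_idx] = True
    while True:
        new = (support @ can_reach.astype(np.int8)) > 0
        new &= ~can_reach
        if not new.any():
            break
        can_reach |= new

    reachable_t = np.array([can_reach[i] for i in t_idx])
    solve_idx = t_idx[reachable_t]
    Q = P[solve_idx][:, solve_idx].tocsc()
    Rfull = P[solve_idx][:, a_idx].tocsr()
    # aggregate absorbing columns by terminal class
    agg = sp.csr_matrix(
        (
            np.ones(len(a_idx)),
            (np.arange(len(a_idx)), [classes.index(c) for c in class_of_absorbing]),
        ),
        shape=(len(a_idx), len(classes)),
    )
    R = (Rfull @ agg).toarray()

    X = np.full((len(t_idx), len(classes)), np.nan)
    if len(solve_idx):
        I = sp.identity(len(solve_idx), format="csc")
        lu = splu((I - Q).tocsc())
        sol = np.column_stack([lu.solve(R[:, k]) for k in range(len(classes))])
        X[reachable_t] = np.clip(sol, 0.0, None)
    unreachable_mask = ~reachable_t

    index = labels.index[~is_terminal.to_numpy()]
    absorption = pd.DataFrame(X, index=index, columns=classes)
    unreachable = index[unreachable_mask]
    if len(unreachable):
        logger.warning("%d transient cells cannot reach any terminal class", len(unreachable))
    return FateResult(absorption=absorption, terminal_classes=classes, unreachable=unreachable)


def summarize_fates(
    result: FateResult,
    initial_classes: pd.Series,
    cap: int = 1000,
    top_n: int = 100,
    seed: int = 0,
) -> FateResult:
    """Sankey edge table and mean-absorption matrix over subsampled cells.

    Each initial class is subsampled (uniformly, seeded) to at most ``cap``
    cells.  For every terminal class, the ``top_n`` subsampled transient
    cells by absorption probability (ties broken by cell identifier) are
    tabulated by initial class; the mean absorption matrix averages over
    all subsampled cells of each initial class.
    """
    if cap < top_n:
        raise ConfigurationError("subsample cap must be >= top_n")
    rng = np.random.default_rng(seed)
    ab = result.absorption.dropna()
    classes = pd.Series(initial_classes).reindex(ab.index)

    chosen = []
    counts = {}
    for cls, idx in classes.groupby(classes).groups.items():
        idx = pd.Index(sorted(idx))
        if len(idx) > cap:
            sel = rng.choice(len(idx), size=cap, replace=False)
            idx = idx[np.sort(sel)]
        counts[cls] = len(idx)
        chosen.append(idx)
    pool = ab.loc[pd.Index(np.concatenate([list(c) for c in chosen]))]
    pool_classes = classes.loc[pool.index]

    edges = []
    for terminal in result.terminal_classes:
        ranked = pool[terminal].sort_index().sort_values(ascending=False, kind="stable")
        take = min(top_n, len(ranked))
        if take < top_n:
            logger.info("terminal class %s: only %d candidates (< %d)", terminal, take, top_n)
        top = ranked.index[:take]
        tab = pool_classes.loc[top].value_counts()
        for source, w in tab.items():
            edges.append({"source_class": source, "target_class": terminal, "weight": int(w)})
    sankey = pd.DataFrame(edges, columns=["source_class", "target_class", "weight"])

    mean_ab = pool.groupby(pool_classes).mean()
    mean_ab.index.name = "initial_class"
    result.sankey = sankey
    result.mean_absorption = mean_ab
    result.subsampled_counts = pd.Series(counts, name="subsampled")
    return result


def monte_carlo_absorption(
    P: np.ndarray,
    terminal_labels: pd.Series | list,
    start_states: list[int] | None = None,
    n_walks: int = 200_000,
    max_steps: int = 5_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random-walk oracle for absorption probabilities (small dense chains).

    Runs ``n_walks`` independent walks from each requested start state and
    returns the empirical absorption frequencies per terminal class plus
    their binomial standard errors.  Steps are vectorized over walkers
    (inverse-CDF sampling against the cumulative transition rows), so a
    100-state chain with 200,000 walks finishes in seconds.  Intended for
    validating the linear-algebra solver on fixtures, not for production.
    """
    rng = np.random.default_rng(seed)
    P = np.asarray(P, dtype=np.float64)
    labels = pd.Series(terminal_labels)
    is_terminal = (labels.notna() & (labels.astype(object) != "")).to_numpy()
    t_idx = np.where(~is_terminal)[0]
    if start_states is None:
        start_states = list(t_idx)
    classes = sorted(pd.unique(labels[is_terminal]))
    class_code = np.full(len(labels), -1)
    for k, c in enumerate(classes):
        class_code[(labels == c).to_numpy()] = k

    cdf = P.cumsum(axis=1)
    hits = np.zeros((len(start_states), len(classes)), dtype=np.int64)
    for si, start in enumerate(start_states):
        state = np.full(n_walks, start, dtype=np.int64)
        active = np.ones(n_walks, dtype=bool)
        for _ in range(max_steps):
            act = np.where(active)[0]
            if act.size == 0:
                break
            cur = state[act]
            u = rng.random(act.size)
            nxt = (u[:, None] > cdf[cur]).sum(axis=1)
            nxt = np.minimum(nxt, P.shape[0] - 1)
            state[act] = nxt
            absorbed = is_terminal[nxt]
            if absorbed.any():
                codes = class_code[nxt[absorbed]]
                np.add.at(hits[si], codes, 1)
                active[act[absorbed]] = False
        # walks still active after max_steps are dropped (counted nowhere)
    freq = hits / n_walks
    se = np.sqrt(np.clip(freq * (1 - freq), 1e-12, None) / n_walks)
    idx = labels.index[np.asarray(start_states)]
    return (
        pd.DataFrame(freq, index=idx, columns=classes),
        pd.DataFrame(se, index=idx, columns=classes),
    )
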