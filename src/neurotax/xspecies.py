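"""Cross-species class homology via mutual nearest neighbours and correlation.

Two species are merged in the space of one-to-one orthologues that are
highly variable in *both* species; expression is scaled within species
before concatenation so species-level shifts do not dominate.  Homology is
assessed at single-cell resolution by mutual nearest neighbours — a cross-
species pair (a, b) such that b is among a's k nearest cells of the other
species and vice versa — and at class resolution by Pearson correlation of
class mean-expression vectors over the shared variable orthologues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._utils import ConfigurationError, as_dense, logger


@dataclass
class HomologyTable:
    mnn_counts: pd.DataFrame  # classes of species A x classes of species B
    correlation: pd.DataFrame  # same shape, Pearson r of class means
    cell_counts: dict
    n_pairs: int


def validate_orthologues(orth: pd.DataFrame) -> pd.DataFrame:
    """Enforce the one-to-one constraint on an orthologue table."""
    if orth["geneA"].duplicated().any() or orth["geneB"].duplicated().any():
        dupA = orth.loc[orth["geneA"].duplicated(), "geneA"].tolist()[:5]
        dupB = orth.loc[orth["geneB"].duplicated(), "geneB"].tolist()[:5]
        raise ConfigurationError(
            f"orthologue map must be one-to-one; repeated entries e.g. {dupA + dupB}"
        )
    return orth


def merge_species(
    dsA: ad.AnnData,
    dsB: ad.AnnData,
    orthologues: pd.DataFrame,
    hvgA: list[str],
    hvgB: list[str],
    layer: str = "scaled",
) -> ad.AnnData:
    """Stack two within-species-scaled datasets over shared variable orthologues.

    The merged gene space is the set of orthologue pairs whose members are
    highly variable in their respective species; merged genes are named by
    the species-A symbol.  Each cell records its species of origin.
    """
    orthologues = validate_orthologues(orthologues)
    setA, setB = set(hvgA), set(hvgB)
    pairs = orthologues[
        orthologues["geneA"].isin(setA) & orthologues["geneB"].isin(setB)
    ]
    pairs = pairs[
        pairs["geneA"].isin(dsA.var_names) & pairs["geneB"].isin(dsB.var_names)
    ]
    if pairs.empty:
        raise ConfigurationError(
            "no orthologue pair is variable in both species; nothing to merge"
        )
    logger.info("merging on %d shared variable orthologues", len(pairs))

    XA = as_dense(dsA.layers[layer])[:, [dsA.var_names.get_loc(g) for g in pairs["geneA"]]]
    XB = as_dense(dsB.layers[layer])[:, [dsB.var_names.get_loc(g) for g in pairs["geneB"]]]
    X = np.vstack([XA, XB]).astype(np.float32)
    obs = pd.concat([dsA.obs.assign(_species_slot="A"), dsB.obs.assign(_species_slot="B")])
    obs.index = list(dsA.obs_names) + list(dsB.obs_names)
    var = pd.DataFrame(
        {"geneB": pairs["geneB"].to_numpy()}, index=pd.Index(pairs["geneA"], name="gene")
    )
    merged = ad.AnnData(X=X, obs=obs, var=var)
    merged.uns["n_shared_variable_orthologues"] = int(len(pairs))
    return merged


def find_mnn_pairs(
    merged: ad.AnnData, k: int = 25, n_pcs: int = 50, seed: int = 0
) -> set[tuple[str, str]]:
    """Mutual nearest cross-species neighbour pairs in merged PC space.

    (a, b) is a pair iff b is among a's k nearest cells *of the other
    species* and a is among b's (Euclidean PC distance).  Mutuality is
    enforced on cross-species neighbour lists only.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    slot = merged.obs["_species_slot"].to_numpy()
    idxA = np.where(slot == "A")[0]
    idxB = np.where(slot == "B")[0]
    if "X_pca" in merged.obsm:
        pcs = np.asarray(merged.obsm["X_pca"], dtype=np.float64)
    else:
        n_comp = int(min(n_pcs, merged.n_obs - 1, merged.n_vars))
        pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
        pcs = pca.fit_transform(as_dense(merged.X))
        merged.obsm["X_pca"] = pcs.astype(np.float32)

    kA = min(k, len(idxB))
    kB = min(k, len(idxA))
    if kA < k or kB < k:
        warnings.warn(f"a species has fewer than k={k} cells; using all", stacklevel=2)

    nnB = NearestNeighbors(n_neighbors=kA).fit(pcs[idxB])
    _, a_to_b = nnB.kneighbors(pcs[idxA])
    nnA = NearestNeighbors(n_neighbors=kB).fit(pcs[idxA])
    _, b_to_a = nnA.kneighbors(pcs[idxB])

    neigh_of_a = [set(idxB[row]) for row in a_to_b]
    neigh_of_b = [set(idxA[row]) for row in b_to_a]
    pos_in_B = {g: i for i, g in enumerate(idxB)}
    pairs = set()
    names = merged.obs_names
    for ai, a in enumerate(idxA):
        for b in neigh_of_a[ai]:
            if a in neigh_of_b[pos_in_B[b]]:
                pairs.add((names[a], names[b]))
    logger.info("found %d MNN pairs", len(pairs))
    return pairs


def class_homology(
    pairs: set[tuple[str, str]],
    classesA: pd.Series,
    classesB: pd.Series,
    merged: ad.AnnData,
) -> HomologyTable:
    """Per class-pair MNN counts and Pearson correlation of class means."""
    clsA = sorted(pd.unique(classesA))
    clsB = sorted(pd.unique(classesB))
    counts = pd.DataFrame(0, index=clsA, columns=clsB)
    for a, b in pairs:
        ca = classesA.get(a)
        cb = classesB.get(b)
        if ca is not None and cb is not None:
            counts.loc[ca, cb] += 1

    X = as_dense(merged.X)
    names = pd.Index(merged.obs_names)
    corr = pd.DataFrame(np.nan, index=clsA, columns=clsB)
    meansA, meansB = {}, {}
    for ca in clsA:
        members = names.get_indexer(classesA.index[classesA == ca])
        members = members[members >= 0]
        meansA[ca] = X[members].mean(axis=0) if len(members) else None
    for cb in clsB:
        members = names.get_indexer(classesB.index[classesB == cb])
        members = members[members >= 0]
        meansB[cb] = X[members].mean(axis=0) if len(members) else None
    for ca in clsA:
        for cb in clsB:
            if meansA[ca] is None or meansB[cb] is None:
                logger.info("class with zero cells in merged data: %s/%s", ca, cb)
                corr.loc[ca, cb] = 0.0
                continue
            a, b = meansA[ca], meansB[cb]
            a = a - a.mean()
            b = b - b.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            r = float(a @ b / denom) if denom > 0 else 0.0
            corr.loc[ca, cb] = float(np.clip(r, -1.0, 1.0))

    return HomologyTable(
        mnn_counts=counts,
        correlation=corr.astype(float),
        cell_counts={
            "A": classesA.value_counts().to_dict(),
            "B": classesB.value_counts().to_dict(),
        },
        n_pairs=len(pairs),
    )
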