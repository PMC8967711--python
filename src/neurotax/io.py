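"""Reading and writing MTX + TSV dataset bundles.

A dataset bundle is a directory holding, for one species:

    spliced.mtx         cell x gene spliced counts (MatrixMarket)
    unspliced.mtx       cell x gene unspliced counts
    genes.tsv           one gene per line with annotation columns
    barcodes.tsv        one cell identifier per line
    cell_metadata.tsv   per-cell metadata (species, batch, region, age, ...)

and optionally ``truth.tsv`` (synthetic ground truth) and
``orthologues.tsv`` (two-column one-to-one orthologue table).  The in-memory
carrier is :class:`anndata.AnnData` with the spliced counts in ``X`` and
both count layers under ``layers['spliced']`` / ``layers['unspliced']``.
"""

from __future__ import annotations

import os
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_bundle(adata: ad.AnnData, outdir: str | os.PathLike) -> Path:
    """Write an ExpressionDataset as an MTX + TSV bundle. Returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spliced = sp.csr_matrix(adata.layers["spliced"])
    unspliced = sp.csr_matrix(adata.layers["unspliced"])
    scipy.io.mmwrite(str(outdir / "spliced.mtx"), spliced)
    scipy.io.mmwrite(str(outdir / "unspliced.mtx"), unspliced)
    adata.var.reset_index().rename(columns={"index": "gene"}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False
    )
    adata.obs.reset_index().rename(columns={"index": "barcode"}).to_csv(
        outdir / "cell_metadata.tsv", sep="\t", index=False
    )
    return outdir


def read_bundle(indir: str | os.PathLike) -> ad.AnnData:
    """Read an MTX + TSV bundle back into an AnnData ExpressionDataset."""
    indir = Path(indir)
    spliced = sp.csr_matrix(scipy.io.mmread(str(indir / "spliced.mtx")))
    unspliced = sp.csr_matrix(scipy.io.mmread(str(indir / "unspliced.mtx")))
    genes = pd.read_csv(indir / "genes.tsv", sep="\t").set_index("gene")
    obs = pd.read_csv(indir / "cell_metadata.tsv", sep="\t").set_index("barcode")
    obs.index = obs.index.astype(str)
    genes.index = genes.index.astype(str)
    adata = ad.AnnData(X=spliced.copy(), obs=obs, var=genes)
    adata.layers["spliced"] = spliced
    adata.layers["unspliced"] = unspliced
    return adata


def write_orthologues(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table[["geneA", "geneB"]].to_csv(path, sep="\t", index=False)


def read_orthologues(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if list(table.columns[:2]) != ["geneA", "geneB"]:
        raise ValueError("orthologue table must have columns geneA, geneB")
    return table


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def _render(node, parent_height) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = _render(node.left, node.dist)
        right = _render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _render(tree, tree.dist) + ";"
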