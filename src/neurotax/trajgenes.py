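"""Latent-time regression screen for trajectory genes.

For each class, every gene's depth-normalized log expression is regressed
on latent time by ordinary least squares; the two-tailed P value of the
slope (t distribution, n - 2 df) is corrected for multiple testing across
the genes of that class with the Holm–Šidák step-down procedure.  Genes
with q < alpha are called "activated" (positive slope) or "inactivated"
(negative slope); gene sets are compared between classes with the Jaccard
index |A ∩ B| / |A ∪ B|.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ConfigurationError, as_dense, logger


def holm_sidak(pvalues) -> np.ndarray:
    """Holm–Šidák step-down adjusted q values.

    With the p values sorted ascending, the j-th (1-based) adjusted value is
    the running maximum of 1 - (1 - p_(j))**(m - j + 1), clipped to 1 and
    mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("p values must be a 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ConfigurationError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = 1.0 - np.power(1.0 - p[order], m - np.arange(m))
    adj = np.maximum.accumulate(adj)
    q = np.empty(m)
    q[order] = np.clip(adj, 0.0, 1.0)
    return q


def regress_on_latent_time(
    dataset: ad.AnnData,
    times: pd.Series,
    classes: pd.Series,
    alpha: float = 0.05,
    layer: str = "lognorm",
    correction_family: str = "per_class",
) -> pd.DataFrame:
    """OLS of expression on latent time, per class and gene.

    Returns a tidy table with columns class, gene, slope, intercept, pvalue,
    qvalue, direction (activated / inactivated / null).  Classes with fewer
    than 3 cells or zero latent-time variance are skipped with a warning.
    Constant genes get slope 0 and the conservative convention P = 1.
    ``correction_family`` is ``per_class`` (default) or ``global``.
    """
    if correction_family not in ("per_class", "global"):
        raise ConfigurationError("correction_family must be 'per_class' or 'global'")
    X = as_dense(dataset.layers[layer] if layer in dataset.layers else dataset.X)
    times = pd.Series(np.asarray(times, dtype=float), index=classes.index)

    frames = []
    for cls, idx in classes.groupby(classes).groups.items():
        rows = dataset.obs_names.get_indexer(idx)
        rows = rows[rows >= 0]
        n = len(rows)
        if n < 3:
            warnings.warn(f"class {cls!r} has n={n} < 3 cells; skipped", stacklevel=2)
            continue
        x = times.loc[idx].to_numpy()
        if x.var() == 0:
            warnings.warn(f"class {cls!r} has zero latent-time variance; skipped", stacklevel=2)
            continue
        Y = X[rows]
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = (xc @ Y) / sxx
        intercept = Y.mean(axis=0) - slope * x.mean()
        resid = Y - (x[:, None] * slope[None, :] + intercept[None, :])
        sse = (resid**2).sum(axis=0)
        dof = n - 2
        sigma2 = sse / dof
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, slope / np.where(se > 0, se, 1.0), 0.0)
        pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
        constant = Y.var(axis=0) == 0
        slope = np.where(constant, 0.0, slope)
        pval = np.where(constant, 1.0, np.clip(pval, 0.0, 1.0))
        frames.append(
            pd.DataFrame(
                {
                    "class": cls,
                    "gene": dataset.var_names,
                    "slope": slope,
                    "intercept": intercept,
                    "pvalue": pval,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["class", "gene", "slope", "intercept", "pvalue", "qvalue", "direction"]
        )
    table = pd.concat(frames, ignore_index=True)

    if correction_family == "per_class":
        table["qvalue"] = table.groupby("class")["pvalue"].transform(
            lambda p: holm_sidak(p.to_numpy())
        )
    else:
        table["qvalue"] = holm_sidak(table["pvalue"].to_numpy())

    table["direction"] = "null"
    sig = table["qvalue"] < alpha
    table.loc[sig & (table["slope"] > 0), "direction"] = "activated"
    table.loc[sig & (table["slope"] < 0), "direction"] = "inactivated"
    logger.info(
        "trajectory screen: %d activated, %d inactivated calls",
        int((table["direction"] == "activated").sum()),
        int((table["direction"] == "inactivated").sum()),
    )
    return table


def jaccard_sets(setA, setB) -> float:
    """|A ∩ B| / |A ∪ B|, with 0 for two empty sets."""
    A, B = set(setA), set(setB)
    union = A | B
    if not union:
        return 0.0
    return len(A & B) / len(union)


def jaccard_matrix(table: pd.DataFrame, direction: str = "activated") -> pd.DataFrame:
    """Class x class Jaccard indices of the given direction's gene sets."""
    sets = {
        cls: set(sub.loc[sub["direction"] == direction, "gene"])
        for cls, sub in table.groupby("class")
    }
    classes = sorted(sets)
    out = pd.DataFrame(
        [[jaccard_sets(sets[a], sets[b]) for b in classes] for a in classes],
        index=classes,
        columns=classes,
    )
    return out
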