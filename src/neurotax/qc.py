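"""Droplet-level QC threshold filters and the inhibitory-cluster selection rule.

Droplets are removed when fewer than 800 genes are detected, or more than
40% of spliced reads are ribosomal, or more than 15% mitochondrial (strict
inequalities: a cell at exactly 800 detected genes or exactly the fraction
caps is retained).  When an upstream per-droplet cell probability is
present, droplets at or below 0.99 are removed as probable ambient RNA.

At the cluster level, a cluster is dropped as non-inhibitory (glia,
excitatory lineage) when its mean normalized expression falls strictly
below the dataset-wide mean for two or more of the canonical interneuron
markers (GAD1, GAD2, DLX1, DLX2, DLX5, DLX6 by default); batches from
ganglionic-eminence dissections can be exempted, since those dissections
are expected to be overwhelmingly inhibitory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from ._utils import ConfigurationError, as_dense, logger


@dataclass(frozen=True)
class QCThresholds:
    min_genes_detected: int = 800
    max_ribosomal_fraction: float = 0.40
    max_mitochondrial_fraction: float = 0.15
    min_cell_probability: float = 0.99

    def validate(self) -> None:
        if self.min_genes_detected < 0:
            raise ConfigurationError("min_genes_detected must be >= 0")
        for name in (
            "max_ribosomal_fraction",
            "max_mitochondrial_fraction",
            "min_cell_probability",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class InhibitorySelectionRule:
    marker_genes: tuple[str, ...] = ("GAD1", "GAD2", "DLX1", "DLX2", "DLX5", "DLX6")
    min_failing_genes_to_remove: int = 2
    exempt_batches: frozenset = field(default_factory=frozenset)

    def validate(self) -> None:
        if not self.marker_genes:
            raise ConfigurationError("marker gene list must be non-empty")
        if self.min_failing_genes_to_remove < 1:
            raise ConfigurationError("min_failing_genes_to_remove must be >= 1")


def qc_metrics(dataset: ad.AnnData) -> pd.DataFrame:
    """Per-cell detected genes and mito/ribo fractions on the spliced matrix."""
    for col in ("is_mito", "is_ribo"):
        if col not in dataset.var:
            raise ConfigurationError(
                f"gene annotation column '{col}' is required for QC; annotate "
                "mitochondrial and ribosomal genes in .var first"
            )
    X = as_dense(dataset.layers.get("spliced", dataset.X))
    total = X.sum(axis=1)
    safe_total = np.where(total > 0, total, 1)
    return pd.DataFrame(
        {
            "detected_genes": (X > 0).sum(axis=1),
            "ribo_fraction": X[:, dataset.var["is_ribo"].to_numpy().astype(bool)].sum(axis=1)
            / safe_total,
            "mito_fraction": X[:, dataset.var["is_mito"].to_numpy().astype(bool)].sum(axis=1)
            / safe_total,
            "total_counts": total,
        },
        index=dataset.obs_names,
    )


def filter_cells(
    dataset: ad.AnnData, thresholds: QCThresholds | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the droplet threshold filters.

    Returns the filtered dataset (gene set unchanged) and a per-cell report
    with pass/fail and comma-joined reason codes among
    ``min_genes``, ``max_ribo``, ``max_mito``, ``cell_probability``.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    metrics = qc_metrics(dataset)

    fail = {
        "min_genes": metrics["detected_genes"] < thresholds.min_genes_detected,
        "max_ribo": metrics["ribo_fraction"] > thresholds.max_ribosomal_fraction,
        "max_mito": metrics["mito_fraction"] > thresholds.max_mitochondrial_fraction,
    }
    if "cell_probability" in dataset.obs:
        fail["cell_probability"] = (
            dataset.obs["cell_probability"].to_numpy() <= thresholds.min_cell_probability
        )

    report = metrics.copy()
    any_fail = np.zeros(dataset.n_obs, dtype=bool)
    reasons = [[] for _ in range(dataset.n_obs)]
    for code, mask in fail.items():
        mask = np.asarray(mask)
        any_fail |= mask
        for i in np.where(mask)[0]:
            reasons[i].append(code)
    report["pass"] = ~any_fail
    report["reasons"] = [",".join(r) for r in reasons]

    kept = dataset[~any_fail].copy()
    if kept.n_obs == 0:
        warnings.warn("QC removed every cell", stacklevel=2)
    logger.info("QC: kept %d / %d cells", kept.n_obs, dataset.n_obs)
    return kept, report


def select_inhibitory_clusters(
    dataset: ad.AnnData,
    cluster_labels: pd.Series,
    rule: InhibitorySelectionRule | None = None,
    normalized_layer: str = "lognorm",
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Drop clusters whose marker expression marks them as non-inhibitory.

    A cluster is removed when, over its cells in non-exempt batches, the
    mean normalized expression is strictly below the dataset-wide mean for
    at least ``min_failing_genes_to_remove`` of the marker genes.  Cells of
    removed clusters that sit in exempt (ganglionic-eminence) batches are
    retained.  Returns the reduced dataset and a per-cluster decision log
    with the per-gene comparisons.
    """
    rule = rule or InhibitorySelectionRule()
    rule.validate()
    missing = [g for g in rule.marker_genes if g not in dataset.var_names]
    if missing:
        raise ConfigurationError(f"marker genes absent from dataset: {missing}")

    layer = dataset.layers[normalized_layer] if normalized_layer in dataset.layers else dataset.X
    gidx = [dataset.var_names.get_loc(g) for g in rule.marker_genes]
    expr = as_dense(layer)[:, gidx]
    global_mean = expr.mean(axis=0)

    labels = pd.Series(np.asarray(cluster_labels), index=dataset.obs_names)
    in_exempt = dataset.obs["batch"].isin(rule.exempt_batches).to_numpy() \
        if "batch" in dataset.obs else np.zeros(dataset.n_obs, dtype=bool)

    records = []
    drop_cell = np.zeros(dataset.n_obs, dtype=bool)
    for cluster in labels.unique():
        members = (labels == cluster).to_numpy()
        eligible = members & ~in_exempt
        if not eligible.any():
            records.append({"cluster": cluster, "n_failing": 0, "removed": False,
                            **{f"mean_{g}": np.nan for g in rule.marker_genes}})
            continue
        cmeans = expr[eligible].mean(axis=0)
        failing = cmeans < global_mean
        removed = int(failing.sum()) >= rule.min_failing_genes_to_remove
        if removed:
            drop_cell |= eligible
        records.append(
            {
                "cluster": cluster,
                "n_failing": int(failing.sum()),
                "removed": removed,
                **{f"mean_{g}": cmeans[k] for k, g in enumerate(rule.marker_genes)},
            }
        )
    log = pd.DataFrame(records)
    log["global_means"] = [",".join(f"{m:.4g}" for m in global_mean)] * len(log)
    kept = dataset[~drop_cell].copy()
    logger.info(
        "inhibitory selection: removed %d clusters (%d cells)",
        int(log["removed"].sum()),
        int(drop_cell.sum()),
    )
    return kept, log
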