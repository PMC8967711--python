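"""End-to-end orchestration with a run manifest.

Stages run in the fixed order simulate -> qc -> cluster -> velocity ->
fate -> xspecies -> trajgenes.  A selected subset only controls which
outputs are written; any upstream stage a selected stage depends on is
still computed.  Every output file is checksummed into the manifest, and
all randomness flows from one root seed through named per-stage substreams
so a stage re-run in isolation reproduces its draws.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from . import qc as nqc
from ._utils import ConfigurationError, derive_seed, logger
from .embedding import EmbeddingConfig, embed_and_cluster
from .fatemap import build_kernels, compute_absorption, summarize_fates
from .synthetic import KineticParams, TrajectoryDesign, generate_dataset
from .trajgenes import jaccard_matrix, regress_on_latent_time
from .velocity import (
    classify_newborn,
    compute_latent_time,
    estimate_velocity,
    score_progenitor_roots,
)
from .xspecies import class_homology, find_mnn_pairs, merge_species

STAGES = ("simulate", "qc", "cluster", "velocity", "fate", "xspecies", "trajgenes")


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "design": {},
        "kinetics": {},
        "qc": {},
        "inhibitory": {},
        "embedding": {},
        "velocity": {"quantile_frac": 0.05, "n_roots": None, "roots": None},
        "fate": {"weight": 0.5, "cap": 1000, "top_n": 100},
        "xspecies": {"k": 25},
        "trajgenes": {"alpha": 0.05},
        "cluster_map": {"path": None},
        "stages": list(STAGES),
    }


def _validate_config(config: dict) -> dict:
    cfg = default_config()
    for key, value in config.items():
        if key not in cfg:
            raise ConfigurationError(f"unknown config key: {key}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config key {key} must be a mapping")
            cfg[key] = {**cfg[key], **value}
        else:
            cfg[key] = value
    unknown = [s for s in cfg["stages"] if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages: {unknown}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the selected stages and return the manifest (also written to disk)."""
    cfg = _validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = list(cfg["stages"])
    needed_upto = max(STAGES.index(s) for s in selected)
    root_seed = int(cfg["seed"])

    manifest: dict = {
        "config": cfg,
        "root_seed": root_seed,
        "stage_seeds": {s: derive_seed(root_seed, s) for s in STAGES},
        "stages": {},
        "outputs": {},
    }

    state: dict = {}
    for stage in STAGES[: needed_upto + 1]:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](cfg, state, outdir / stage, stage in selected)
        except Exception:
            manifest["stages"][stage] = {"status": "failed"}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            logger.error("stage %r failed", stage)
            raise
        elapsed = time.perf_counter() - t0
        manifest["stages"][stage] = {
            "status": "ok",
            "written": stage in selected,
            "seconds": round(elapsed, 3),
        }
        for path in outputs:
            manifest["outputs"][str(path.relative_to(outdir))] = _sha256(path)
        logger.info("stage %s done in %.1fs", stage, elapsed)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(cfg, state, stagedir: Path, write: bool) -> list[Path]:
    seed = derive_seed(cfg["seed"], "simulate")
    design = replace(TrajectoryDesign(**cfg["design"]), seed=seed)
    kinetics = KineticParams(**cfg["kinetics"])
    datasets, truth = generate_dataset(design, kinetics)
    state.update(design=design, datasets=datasets, truth=truth)
    outputs: list[Path] = []
    if write:
        for species, adata in datasets.items():
            bundle = nio.write_bundle(adata, stagedir / species)
            outputs.extend(sorted(bundle.iterdir()))
            outputs.append(
                _write_tsv(truth.cells[species], stagedir / species / "truth.tsv")
            )
        orth_path = stagedir / "orthologues.tsv"
        stagedir.mkdir(parents=True, exist_ok=True)
        nio.write_orthologues(truth.orthologues, orth_path)
        outputs.append(orth_path)
    return outputs


def _stage_qc(cfg, state, stagedir: Path, write: bool) -> list[Path]:
    thresholds = nqc.QCThresholds(
        min_genes_detected=cfg["qc"].get("min_genes", 800),
        max_ribosomal_fraction=cfg["qc"].get("max_ribo", 0.40),
        max_mitochondrial_fraction=cfg["qc"].get("max_mito", 0.15),
    )
    outputs = []
    state["filtered"] = {}
    for species, adata in state["datasets"].items():
        kept, report = nqc.filter_cells(adata, thresholds)
        state["filtered"][species] = kept
        if write:
            outputs.append(_write_tsv(report, stagedir / f"{species}_qc_report.tsv"))
    return outputs


def _marker_names(dataset, markers: tuple[str, ...]) -> tuple[str, ...]:
    """Resolve marker symbols against a dataset, tolerating capitalisation."""
    lower = {g.lower(): g for g in dataset.var_names}
    return tuple(lower.get(m.lower(), m) for m in markers)


def _stage_cluster(cfg, state, stagedir: Path, write: bool) -> list[Path]:
    emb_cfg = EmbeddingConfig(
        **{**cfg["embedding"], "seed": derive_seed(cfg["seed"], "cluster")}
    )
    rule_cfg = cfg["inhibitory"]
    outputs = []
    state["processed"] = {}
    for species, adata in state["filtered"].items():
        processed, graph, assignment = embed_and_cluster(adata, emb_cfg)
        rule = nqc.InhibitorySelectionRule(
            marker_genes=_marker_names(
                processed, tuple(rule_cfg.get("markers", nqc.InhibitorySelectionRule().marker_genes))
            ),
            min_failing_genes_to_remove=rule_cfg.get("min_failing", 2),
            exempt_batches=frozenset(rule_cfg.get("exempt_batches", ())),
        )
        inhibitory, log = nqc.select_inhibitory_clusters(
            processed, assignment.fine, rule
        )
        # repeat embedding and clustering on the final inhibitory dataset
        class_map_path = cfg["cluster_map"].get("path")
        cluster_to_class = None
        if class_map_path:
            cm = pd.read_csv(class_map_path, sep="\t")
            cluster_to_class = dict(zip(cm.iloc[:, 0].astype(int), cm.iloc[:, 1].astype(str)))
        processed2, graph2, assignment2 = embed_and_cluster(
            inhibitory, emb_cfg, cluster_to_class=cluster_to_class
        )
        state["processed"][species] = {
            "adata": processed2,
            "graph": graph2,
            "assignment": assignment2,
            "selection_log": log,
        }
        if write:
            outputs.append(
                _write_tsv(
                    pd.DataFrame(
                        {
                            "leiden": assignment2.fine,
                            "initial_class": assignment2.classes,
                        }
                    ),
                    stagedir / f"{species}_classes.tsv",
                )
            )
            outputs.append(_write_tsv(log, stagedir / f"{species}_inhibitory_rule.tsv", index=False))
            if assignment2.linkage_matrix is not None:
                newick = nio.linkage_to_newick(
                    assignment2.linkage_matrix,
                    [str(c) for c in sorted(assignment2.fine.unique())],
                )
                path = stagedir / f"{species}_dendrogram.nwk"
                path.write_text(newick)
                outputs.append(path)
    return outputs


def _stage_velocity(cfg, state, stagedir: Path, write: bool) -> list[Path]:
    outputs = []
    for species, prod in state["processed"].items():
        adata, graph = prod["adata"], prod["graph"]
        field = estimate_velocity(adata, quantile_frac=cfg["velocity"]["quantile_frac"])
        explicit = cfg["velocity"].get("roots")
        if explicit:
            roots = np.asarray(adata.obs_names.get_indexer(explicit))
            roots = roots[roots >= 0]
        else:
            roots = score_progenitor_roots(adata, n_roots=cfg["velocity"]["n_roots"])
        field.latent_time = compute_latent_time(graph, adata.obsm["X_pca"], roots)
        field.latent_time.index = adata.obs_names
        field.roots = roots
        newborn = classify_newborn(field.latent_time, prod["assignment"].classes)
        prod["field"] = field
        prod["newborn"] = newborn
        adata.obs["latent_time"] = field.latent_time.to_numpy()
        adata.obs["newborn"] = newborn.newborn.to_numpy()
        if write:
            outputs.append(
                _write_tsv(
                    pd.DataFrame(
                        {"latent_time": field.latent_time, "newborn": newborn.newborn}
                    ),
                    stagedir / f"{species}_latent_time.tsv",
                )
            )
            outputs.append(
                _write_tsv(
                    field.gamma_hat.to_frame("gamma_hat"),
                    stagedir / f"{species}_gamma.tsv",
                )
            )
    return outputs


def _stage_fate(cfg, state, stagedir: Path, write: bool) -> list[Path]:
    outputs = []
    seed = derive_seed(cfg["seed"], "fate")
    for species, prod in state["processed"].items():
        adata, graph, field = prod["adata"], prod["graph"], prod["field"]
        hvg = adata.uns["pca"]["hvg"]
        hvg_idx = np.asarray([adata.var_names.get_loc(g) for g in hvg])
        kernel = build_kernels(
            graph,
            field,
            adata.obsm["X_pca"],
            adata.uns["pca"]["components"],
            hvg_idx,
            weight=cfg["fate"]["weight"],
        )
        terminal = pd.Series(
            np.where(
                adata.obs["is_terminal"].to_numpy(), adata.obs["terminal_class"], ""
            ),
            index=adata.obs_names,
        )
        result = compute_absorption(kernel, terminal)
        result = summarize_fates(
            result,
            prod["assignment"].classes,
            cap=cfg["fate"]["cap"],
            top_n=cfg["fate"]["top_n"],
            seed=seed,
        )
        prod["fate"] = result
        if write:
            outputs.append(_write_tsv(result.absorption, stagedir / f"{species}_absorption.tsv"))
            outputs.append(
                _write_tsv(result.sankey, stagedir / f"{species}_sankey.tsv", index=False)
            )
            outputs.append(
                _write_tsv(result.mean_absorption, stagedir / f"{species}_mean_absorption.tsv")
            )
    return outputs


def _stage_xspecies(cfg, state, stagedir: Path, write: bool) -> list[Path]:
    design = state["design"]
    if not design.cross_species:
        return []
    spA, spB = design.species
    prodA, prodB = state["processed"][spA], state["processed"][spB]
    merged = merge_species(
        prodA["adata"],
        prodB["adata"],
        state["truth"].orthologues,
        prodA["adata"].uns["pca"]["hvg"],
        prodB["adata"].uns["pca"]["hvg"],
    )
    pairs = find_mnn_pairs(
        merged, k=cfg["xspecies"]["k"], seed=derive_seed(cfg["seed"], "xspecies")
    )
    table = class_homology(
        pairs, prodA["assignment"].classes, prodB["assignment"].classes, merged
    )
    state["homology"] = table
    outputs = []
    if write:
        sankey = table.mnn_counts.reset_index().melt(
            id_vars="index", var_name="class_B", value_name="weight"
        )
        sankey.columns = ["class_A", "class_B", "weight"]
        outputs.append(_write_tsv(sankey, stagedir / "mnn_sankey.tsv", index=False))
        outputs.append(_write_tsv(table.mnn_counts, stagedir / "mnn_counts.tsv"))
        outputs.append(_write_tsv(table.correlation, stagedir / "class_correlation.tsv"))
    return outputs


def _stage_trajgenes(cfg, state, stagedir: Path, write: bool) -> list[Path]:
    outputs = []
    for species, prod in state["processed"].items():
        adata = prod["adata"]
        table = regress_on_latent_time(
            adata,
            prod["field"].latent_time,
            prod["assignment"].classes,
            alpha=cfg["trajgenes"]["alpha"],
        )
        prod["trajgenes"] = table
        if write:
            outputs.append(
                _write_tsv(table, stagedir / f"{species}_trajectory_genes.tsv", index=False)
            )
            for direction in ("activated", "inactivated"):
                outputs.append(
                    _write_tsv(
                        jaccard_matrix(table, direction),
                        stagedir / f"{species}_jaccard_{direction}.tsv",
                    )
                )
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "velocity": _stage_velocity,
    "fate": _stage_fate,
    "xspecies": _stage_xspecies,
    "trajgenes": _stage_trajgenes,
}
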