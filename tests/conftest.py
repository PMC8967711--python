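"""Shared fixtures: small generated datasets and processed pipeline state.

Everything is generated programmatically; the demo-scale state (used by the
acceptance-style recovery tests) is built once per session.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import neurotax as nt
from neurotax.pipeline import STAGES, _STAGE_FUNCS, _validate_config

warnings.filterwarnings("ignore", category=UserWarning)

DEMO_SEED = 0  # the bundled demo configuration's documented seed


@pytest.fixture(scope="session")
def small_design():
    return nt.TrajectoryDesign(cells_per_branch=120, seed=11)


@pytest.fixture(scope="session")
def small_data(small_design):
    datasets, truth = nt.generate_dataset(small_design)
    return small_design, datasets, truth


@pytest.fixture(scope="session")
def demo_state(tmp_path_factory):
    """Full pipeline state on the demo-scale dataset (~5,000 cells)."""
    cfg = _validate_config({"seed": DEMO_SEED, "design": {"cells_per_branch": 450}})
    state: dict = {}
    out = tmp_path_factory.mktemp("demo")
    for stage in STAGES:
        _STAGE_FUNCS[stage](cfg, state, out / stage, False)
    return cfg, state


@pytest.fixture(scope="session")
def normalized_small(small_data):
    _, datasets, _ = small_data
    return {sp: nt.normalize(a) for sp, a in datasets.items()}


def truth_classes(truth, species, adata) -> pd.Series:
    """Ground-truth class labels aligned to a dataset's cells."""
    return truth.cells[species].loc[adata.obs_names, "class"]


def make_counts_adata(X, is_mito=None, is_ribo=None, obs=None):
    """Tiny AnnData with spliced counts and mito/ribo annotation."""
    import anndata as ad

    X = np.asarray(X)
    n, m = X.shape
    var = pd.DataFrame(
        {
            "is_mito": np.zeros(m, bool) if is_mito is None else np.asarray(is_mito),
            "is_ribo": np.zeros(m, bool) if is_ribo is None else np.asarray(is_ribo),
        },
        index=[f"g{j}" for j in range(m)],
    )
    obs = obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(n)])
    a = ad.AnnData(X=X.astype(np.int32), obs=obs, var=var)
    a.layers["spliced"] = X.astype(np.int32)
    a.layers["unspliced"] = np.zeros_like(X, dtype=np.int32)
    return a
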