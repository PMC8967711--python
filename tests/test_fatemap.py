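"""Transition kernels, absorption probabilities and fate summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import neurotax as nt
from neurotax import ConfigurationError
from neurotax.embedding import build_bbknn_graph
from neurotax.fatemap import (
    build_kernels,
    compute_absorption,
    monte_carlo_absorption,
    summarize_fates,
)
from neurotax.velocity import VelocityField


def _random_chain(rng, n_states, n_classes, absorb_mass=0.25):
    """Row-stochastic chain whose last `n_classes` states are absorbing."""
    n_trans = n_states - n_classes
    P = np.zeros((n_states, n_states))
    for i in range(n_trans):
        row = rng.random(n_states)
        row[n_trans:] *= absorb_mass * n_states / n_classes / n_trans
        P[i] = row / row.sum()
    for j in range(n_trans, n_states):
        P[j, j] = 1.0
    labels = pd.Series(
        [None] * n_trans + [f"T{j % n_classes}" for j in range(n_classes)]
    )
    return P, labels


def _toy_field_and_graph(n=40, seed=0):
    rng = np.random.default_rng(seed)
    pcs = rng.normal(size=(n, 4))
    graph = build_bbknn_graph(pcs, ["b"] * n, k=4)
    velocity = rng.normal(size=(n, 6)).astype(np.float32)
    field = VelocityField(
        gamma_hat=pd.Series(np.ones(6)), velocity=velocity
    )
    components = rng.normal(size=(4, 6))
    return graph, field, pcs, components, np.arange(6)


class TestBuildKernels:
    def test_weight_one_equals_connectivity(self):
        graph, field, pcs, comp, hidx = _toy_field_and_graph()
        kernel = build_kernels(graph, field, pcs, comp, hidx, weight=1.0)
        assert np.allclose(
            kernel.matrix.toarray(), kernel.connectivity.toarray(), atol=1e-12
        )

    def test_rows_sum_to_one(self):
        graph, field, pcs, comp, hidx = _toy_field_and_graph(n=30, seed=1)
        for w in (0.0, 0.3, 0.5, 1.0):
            kernel = build_kernels(graph, field, pcs, comp, hidx, weight=w)
            rowsum = np.asarray(kernel.matrix.sum(axis=1)).ravel()
            assert np.abs(rowsum - 1.0).max() < 1e-12

    def test_softmax_limit_concentrates_on_aligned_neighbour(self):
        """With sigma -> 0, the velocity row puts ~all mass on the neighbour
        the velocity vector points at."""
        graph, field, pcs, comp, hidx = _toy_field_and_graph(n=25, seed=2)
        i = 0
        nbrs = np.unique(
            graph.connectivities.maximum(graph.connectivities.T)[i].indices
        )
        nbrs = nbrs[nbrs != i]
        target = nbrs[0]
        # velocity in PC space pointing exactly at `target`
        direction_pc = pcs[target] - pcs[i]
        v_gene, *_ = np.linalg.lstsq(comp.T[hidx].T, direction_pc, rcond=None)
        field.velocity[i, :] = v_gene.astype(np.float32)
        kernel = build_kernels(graph, field, pcs, comp, hidx, weight=0.0, sigma=1e-4)
        row = kernel.matrix[i].toarray().ravel()
        assert row[target] > 0.999

    def test_zero_velocity_rows_fall_back_to_connectivity(self):
        graph, field, pcs, comp, hidx = _toy_field_and_graph(n=30, seed=3)
        field.velocity[:] = 0.0
        kernel = build_kernels(graph, field, pcs, comp, hidx, weight=0.0)
        assert np.allclose(
            kernel.matrix.toarray(), kernel.connectivity.toarray(), atol=1e-12
        )

    def test_mixture_weight_monotone_convergence(self):
        graph, field, pcs, comp, hidx = _toy_field_and_graph(n=30, seed=4)
        conn = build_kernels(graph, field, pcs, comp, hidx, weight=1.0).matrix.toarray()
        gaps = []
        for w in (0.5, 0.9, 0.99):
            K = build_kernels(graph, field, pcs, comp, hidx, weight=w).matrix.toarray()
            gaps.append(np.abs(K - conn).max())
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.01

    def test_invalid_weight_rejected(self):
        graph, field, pcs, comp, hidx = _toy_field_and_graph()
        with pytest.raises(ConfigurationError):
            build_kernels(graph, field, pcs, comp, hidx, weight=1.5)


class TestComputeAbsorption:
    def test_single_transient_closed_form(self):
        """P(self)=0.5, P(A)=0.3, P(B)=0.2 -> absorption 0.6 / 0.4 exactly."""
        P = np.array([[0.5, 0.3, 0.2], [0, 1, 0], [0, 0, 1]])
        labels = pd.Series([None, "A", "B"])
        res = compute_absorption(sp.csr_matrix(P), labels)
        assert res.absorption.loc[0, "A"] == pytest.approx(0.6, abs=1e-10)
        assert res.absorption.loc[0, "B"] == pytest.approx(0.4, abs=1e-10)

    def test_edges_only_to_one_class(self):
        P = np.array([[0.0, 1.0, 0.0], [0, 1, 0], [0, 0, 1]])
        labels = pd.Series([None, "A", "B"])
        res = compute_absorption(sp.csr_matrix(P), labels)
        assert res.absorption.loc[0, "A"] == pytest.approx(1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        P, labels = _random_chain(rng, 40, 3)
        res = compute_absorption(sp.csr_matrix(P), labels)
        assert np.allclose(res.absorption.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_monte_carlo_oracle(self):
        """50-state random chain: solver within 3 SE of 200k-walk oracle."""
        rng = np.random.default_rng(6)
        P, labels = _random_chain(rng, 50, 3)
        res = compute_absorption(sp.csr_matrix(P), labels)
        starts = [0, 7, 21]
        freq, se = monte_carlo_absorption(P, labels, start_states=starts, seed=9)
        for s in starts:
            diff = (res.absorption.loc[s] - freq.loc[s]).abs()
            assert (diff <= 3 * se.loc[s] + 1e-9).all()

    def test_unreachable_cells_flagged(self):
        # state 1 loops to itself and state 0 only; never reaches A
        P = np.array(
            [
                [0.5, 0.5, 0.0, 0.0],
                [0.5, 0.5, 0.0, 0.0],
                [0.1, 0.0, 0.4, 0.5],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        labels = pd.Series([None, None, None, "A"])
        res = compute_absorption(sp.csr_matrix(P), labels)
        assert {0, 1} <= set(res.unreachable)
        assert 2 not in set(res.unreachable)

    def test_no_absorbing_state_rejected(self):
        P = np.eye(3)
        with pytest.raises(ConfigurationError):
            compute_absorption(sp.csr_matrix(P), pd.Series([None, None, None]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(10)
        P, labels = _random_chain(rng, 20, 2)
        res = compute_absorption(sp.csr_matrix(P), labels)
        perm = rng.permutation(20)
        Pp = P[np.ix_(perm, perm)]
        labp = labels.iloc[perm].reset_index(drop=True)
        resp = compute_absorption(sp.csr_matrix(Pp), labp)
        for new_pos, old in enumerate(perm):
            if labels[old] is None:
                got = resp.absorption.loc[new_pos]
                want = res.absorption.loc[old]
                assert np.allclose(got.to_numpy(), want.to_numpy(), atol=1e-9)


class TestSummarizeFates:
    @staticmethod
    def _separated_result(n_per_class=150):
        """Two initial classes, X absorbed into T fully and Y not at all."""
        idx = [f"x{i}" for i in range(n_per_class)] + [
            f"y{i}" for i in range(n_per_class)
        ]
        ab = pd.DataFrame(
            {
                "T": [1.0] * n_per_class + [0.0] * n_per_class,
                "U": [0.0] * n_per_class + [1.0] * n_per_class,
            },
            index=idx,
        )
        res = nt.FateResult(
            absorption=ab, terminal_classes=["T", "U"], unreachable=pd.Index([])
        )
        classes = pd.Series(
            ["X"] * n_per_class + ["Y"] * n_per_class, index=idx
        )
        return res, classes

    def test_separation_case(self):
        res, classes = self._separated_result()
        out = summarize_fates(res, classes, cap=1000, top_n=100, seed=0)
        sankey = out.sankey.set_index(["source_class", "target_class"])["weight"]
        assert sankey.get(("X", "T"), 0) == 100
        assert sankey.get(("Y", "T"), 0) == 0

    def test_sankey_column_sums(self):
        res, classes = self._separated_result()
        out = summarize_fates(res, classes, cap=1000, top_n=100, seed=0)
        sums = out.sankey.groupby("target_class")["weight"].sum()
        assert (sums == 100).all()

    def test_cap_larger_than_class_uses_all(self):
        res, classes = self._separated_result(n_per_class=70)
        out = summarize_fates(res, classes, cap=10_000, top_n=50, seed=0)
        assert out.subsampled_counts["X"] == 70

    def test_subsampling_caps_class_size(self):
        res, classes = self._separated_result(n_per_class=300)
        out = summarize_fates(res, classes, cap=200, top_n=100, seed=1)
        assert (out.subsampled_counts <= 200).all()

    def test_cap_below_top_n_rejected(self):
        res, classes = self._separated_result()
        with pytest.raises(ConfigurationError):
            summarize_fates(res, classes, cap=50, top_n=100, seed=0)

    def test_mean_absorption_rows(self):
        res, classes = self._separated_result()
        out = summarize_fates(res, classes, cap=1000, top_n=100, seed=0)
        assert out.mean_absorption.loc["X", "T"] == pytest.approx(1.0)
        assert out.mean_absorption.loc["Y", "T"] == pytest.approx(0.0)

    def test_fate_recovery_on_synthetic_data(self, demo_state):
        """>=90 of each terminal class's top-100 cells carry the true
        precursor class (checked in the acceptance suite as well)."""
        _, state = demo_state
        truth = state["truth"]
        for sp, prod in state["processed"].items():
            tc = truth.cells[sp].loc[prod["adata"].obs_names]
            ab = prod["fate"].absorption.dropna()
            for term in prod["fate"].terminal_classes:
                ranked = ab[term].sort_index().sort_values(
                    ascending=False, kind="stable"
                )
                top = ranked.index[:100]
                assert (tc.loc[top, "terminal_class"] == term).sum() >= 90
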