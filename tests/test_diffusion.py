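"""Transition-matrix construction and heat-equation solvers.

The dense Taylor-series oracle is the independent ground truth throughout;
the closed form for the single-edge graph, H_t = ((1+e^{-2t})/2,
(1-e^{-2t})/2) from h0 = (1, 0), was verified analytically (L has
eigenvalues 0 and 2 with eigenvectors (1,1) and (1,-1)).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netheat import (
    ConvergenceError,
    DiffusionConfig,
    PPINetwork,
    SeedSet,
    ValidationError,
    column_normalize,
    diffuse,
    expm_series_oracle,
    initial_heat,
    iterate_until_converged,
)

from conftest import random_network, random_seed_heat


class TestColumnNormalize:
    def test_single_edge_independent_of_weight(self, two_node):
        tm = column_normalize(two_node)
        np.testing.assert_allclose(tm.matrix.toarray(), [[0, 1], [1, 0]])

    def test_star_weights(self, star):
        tm = column_normalize(star)
        i = tm.node_index
        col_c = tm.matrix.toarray()[:, i["c"]]
        expect = np.zeros(3)
        expect[i["x"]] = 300 / 1200
        expect[i["y"]] = 900 / 1200
        np.testing.assert_allclose(col_c, expect)
        # leaves put all weight on the center
        assert tm.matrix.toarray()[i["c"], i["x"]] == 1.0
        assert tm.matrix.toarray()[i["c"], i["y"]] == 1.0

    def test_isolated_node_gets_self_loop(self):
        net = PPINetwork.from_edges([("a", "b", 500)], extra_nodes=["z"])
        tm = column_normalize(net)
        col_z = tm.matrix.toarray()[:, tm.node_index["z"]]
        expect = np.zeros(3)
        expect[tm.node_index["z"]] = 1.0
        np.testing.assert_allclose(col_z, expect)

    @pytest.mark.parametrize("n,seed", [(30, 0), (120, 1), (57, 2)])
    def test_columns_sum_to_one(self, n, seed):
        tm = column_normalize(random_network(n, seed))
        np.testing.assert_allclose(
            np.asarray(tm.matrix.sum(axis=0)).ravel(), 1.0, atol=1e-12
        )


class TestInitialHeat:
    def test_uniform_share(self):
        net = random_network(10, 3)
        seeds = SeedSet(members=[f"n{i}" for i in range(4)])
        tm = column_normalize(net)
        h0 = initial_heat(seeds, tm.node_index)
        assert sorted(h0) == [0.0] * 6 + [0.25] * 4
        assert h0.sum() == 1.0

    def test_thirty_seven_seeds(self):
        net = random_network(60, 4)
        seeds = SeedSet(members=[f"n{i}" for i in range(37)])
        tm = column_normalize(net)
        h0 = initial_heat(seeds, tm.node_index)
        np.testing.assert_allclose(h0[h0 > 0], 1.0 / 37)

    def test_single_seed_unit_vector(self, two_node):
        tm = column_normalize(two_node)
        h0 = initial_heat(SeedSet(members=["b"]), tm.node_index)
        np.testing.assert_array_equal(h0, [0.0, 1.0])

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValidationError):
            SeedSet(members=[])


class TestDiffuse:
    def test_t_zero_is_identity(self, star):
        tm = column_normalize(star)
        h0 = initial_heat(SeedSet(members=["c"]), tm.node_index)
        np.testing.assert_array_equal(diffuse(tm, h0, DiffusionConfig(t=0)), h0)

    @pytest.mark.parametrize("t", [0.0, 0.1, 0.5, 2.0])
    def test_two_node_closed_form(self, two_node, t):
        tm = column_normalize(two_node)
        h0 = initial_heat(SeedSet(members=[tm.nodes[0]]), tm.node_index)
        expect = np.array([(1 + np.exp(-2 * t)) / 2, (1 - np.exp(-2 * t)) / 2])
        np.testing.assert_allclose(diffuse(tm, h0, DiffusionConfig(t=t)), expect, atol=1e-10)

    def test_path_graph_matches_series_oracle(self, path3):
        tm = column_normalize(path3)
        h0 = initial_heat(SeedSet(members=["a"]), tm.node_index)
        got = diffuse(tm, h0, DiffusionConfig(t=0.5))
        want = expm_series_oracle(tm, h0, 0.5, n_terms=40)
        np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_spectral_agrees_with_expm(self, seed):
        tm, h0 = random_seed_heat(random_network(50, seed), 5, seed)
        he = diffuse(tm, h0, DiffusionConfig(t=0.7))
        hs = diffuse(tm, h0, DiffusionConfig(t=0.7, mode="spectral"))
        np.testing.assert_allclose(he, hs, atol=1e-8)

    def test_misaligned_heat_rejected(self, star):
        tm = column_normalize(star)
        with pytest.raises(ValidationError):
            diffuse(tm, np.zeros(5), DiffusionConfig())


class TestSeriesOracle:
    def test_t_zero(self, path3):
        tm = column_normalize(path3)
        h0 = initial_heat(SeedSet(members=["b"]), tm.node_index)
        np.testing.assert_array_equal(expm_series_oracle(tm, h0, 0.0, 30), h0)

    def test_one_term_is_euler_step(self, star):
        tm = column_normalize(star)
        h0 = initial_heat(SeedSet(members=["c"]), tm.node_index)
        t = 0.01
        L = tm.laplacian().toarray()
        np.testing.assert_allclose(
            expm_series_oracle(tm, h0, t, n_terms=1), h0 - t * (L @ h0), atol=1e-15
        )


class TestIterateUntilConverged:
    def test_stationary_input_returns_immediately(self):
        # uniform heat on a regular connected graph is the fixed point
        net = PPINetwork.from_edges(
            [("a", "b", 500), ("b", "c", 500), ("c", "d", 500), ("d", "a", 500)]
        )
        tm = column_normalize(net)
        h0 = np.full(4, 0.25)
        h, t_stop = iterate_until_converged(tm, h0, step=0.5, eps=1e-9)
        np.testing.assert_allclose(h, h0, atol=1e-9)
        assert t_stop == 0.5

    def test_two_node_converges_to_half(self, two_node):
        tm = column_normalize(two_node)
        h0 = initial_heat(SeedSet(members=[tm.nodes[0]]), tm.node_index)
        h, _ = iterate_until_converged(tm, h0, step=0.5, eps=1e-8)
        np.testing.assert_allclose(h, [0.5, 0.5], atol=1e-6)

    def test_huge_eps_stops_after_first_step(self, two_node):
        tm = column_normalize(two_node)
        h0 = initial_heat(SeedSet(members=[tm.nodes[0]]), tm.node_index)
        _, t_stop = iterate_until_converged(tm, h0, step=0.1, eps=10.0)
        assert t_stop == 0.1

    def test_step_cap_raises(self, two_node):
        tm = column_normalize(two_node)
        h0 = initial_heat(SeedSet(members=[tm.nodes[0]]), tm.node_index)
        with pytest.raises(ConvergenceError):
            iterate_until_converged(tm, h0, step=1e-6, eps=1e-15, max_steps=10)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    n=st.integers(5, 60),
    seed=st.integers(0, 10_000),
    t=st.sampled_from([0.0, 0.05, 0.5, 2.0, 10.0]),
)
def test_conservation_and_nonnegativity(n, seed, t):
    """Total heat is invariant in t and no entry ever goes negative."""
    net = random_network(n, seed)
    tm, h0 = random_seed_heat(net, max(1, n // 5), seed)
    h = diffuse(tm, h0, DiffusionConfig(t=t))
    assert abs(h.sum() - h0.sum()) < 1e-9
    assert (h >= 0).all()


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_permutation_equivariance(seed):
    """Relabeling nodes permutes the heat vector identically."""
    rng = np.random.default_rng(seed)
    net = random_network(25, seed)
    tm, h0 = random_seed_heat(net, 4, seed)
    h = diffuse(tm, h0, DiffusionConfig(t=0.5))

    perm = rng.permutation(len(tm.nodes))
    relabel = {tm.nodes[i]: f"m{perm[i]}" for i in range(len(tm.nodes))}
    edges = [
        (relabel[a], relabel[b], d["score"]) for a, b, d in net.graph.edges(data=True)
    ]
    net2 = PPINetwork.from_edges(edges, extra_nodes=[relabel[x] for x in tm.nodes])
    tm2 = column_normalize(net2)
    h0_2 = np.zeros_like(h0)
    for old, new in relabel.items():
        h0_2[tm2.node_index[new]] = h0[tm.node_index[old]]
    h2 = diffuse(tm2, h0_2, DiffusionConfig(t=0.5))
    for old, new in relabel.items():
        assert h2[tm2.node_index[new]] == pytest.approx(h[tm.node_index[old]], abs=1e-12)


def test_monotone_spread_from_seed(path3):
    """For small t, heat on a seed neighbor grows from zero at rate (A'h0)_i."""
    tm = column_normalize(path3)
    h0 = initial_heat(SeedSet(members=["a"]), tm.node_index)
    prev = 0.0
    for t in [0.0, 0.01, 0.05, 0.1]:
        hb = diffuse(tm, h0, DiffusionConfig(t=t))[tm.node_index["b"]]
        assert hb >= prev
        prev = hb
    t = 1e-6
    hb = diffuse(tm, h0, DiffusionConfig(t=t))[tm.node_index["b"]]
    rate = (tm.matrix @ h0)[tm.node_index["b"]]
    assert hb == pytest.approx(t * rate, rel=1e-4)
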