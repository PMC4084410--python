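"""Reservation-based SOM: distance, schedules, training, dominance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from examine.hypergraph import (
    AnnotationSet,
    Interaction,
    MembershipMatrix,
    Node,
    build_module,
    encode,
)
from examine.rsom import (
    Layout,
    NeuronGrid,
    TrainingSchedule,
    cosine_distance,
    grid_side,
    init_grid,
    retrain,
    set_dominance,
    train,
    train_epoch,
)

from conftest import TEST_ITERATIONS, random_module


def small_matrix(seed: int, n_items: int = 8, m: int = 12) -> MembershipMatrix:
    rng = np.random.default_rng(seed)
    values = (rng.random((n_items, m)) < 0.3).astype(float)
    return MembershipMatrix(
        node_ids=[f"n{i}" for i in range(n_items)],
        component_keys=[("set", str(j)) for j in range(m)],
        values=values,
        weights=np.ones(m),
    )


class TestCosineDistance:
    def test_self_distance_zero(self, fig2_matrix):
        for nid in fig2_matrix.node_ids:
            assert cosine_distance(fig2_matrix.vector(nid),
                                   fig2_matrix.vector(nid)) == 0.0

    def test_orthogonal_printed_vectors(self, fig2_matrix):
        v5, v6 = fig2_matrix.vector("Nr3c2"), fig2_matrix.vector("Plcb4")
        assert v5 @ v6 == 0.0
        assert cosine_distance(v5, v6) == pytest.approx(0.5, abs=1e-15)

    def test_antiparallel_is_one(self):
        v = np.array([1.0, 2.0, 0.5])
        assert cosine_distance(v, -v) == pytest.approx(1.0, abs=1e-12)

    def test_zero_vector_conventions(self):
        z = np.zeros(3)
        assert cosine_distance(z, z) == 0.0
        assert cosine_distance(z, np.ones(3)) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cosine_distance(np.ones(2), np.ones(3))

    def test_against_high_precision_oracle(self):
        """1000 random pairs agree with an arbitrary-precision evaluation."""
        import mpmath

        mpmath.mp.dps = 50
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            q = rng.normal(size=n)
            p = rng.normal(size=n)
            got = cosine_distance(q, p)
            qm = [mpmath.mpf(x) for x in q]
            pm = [mpmath.mpf(x) for x in p]
            dot = mpmath.fsum(a * b for a, b in zip(qm, pm))
            nq = mpmath.sqrt(mpmath.fsum(a * a for a in qm))
            np_ = mpmath.sqrt(mpmath.fsum(b * b for b in pm))
            expected = float(mpmath.acos(dot / (nq * np_)) / mpmath.pi)
            assert got == pytest.approx(expected, abs=1e-12)
            assert 0.0 <= got <= 1.0
            assert cosine_distance(p, q) == got


class TestSchedule:
    @pytest.mark.parametrize("c,iterations", [(0.5, 100), (0.01, 7), (0.9, 1)])
    def test_endpoints(self, c, iterations):
        s = TrainingSchedule(c=c, iterations=iterations, seed=0)
        assert s.alpha(0) == c
        assert s.alpha(iterations) == 0.0
        assert s.radius(0, 20) == 20
        assert s.radius(iterations, 20) == 0

    def test_monotone(self):
        s = TrainingSchedule(c=0.5, iterations=50, seed=0)
        alphas = [s.alpha(i) for i in range(51)]
        radii = [s.radius(i, 16) for i in range(51)]
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))
        assert all(a >= b for a, b in zip(radii, radii[1:]))

    def test_default_iteration_count(self):
        assert TrainingSchedule.for_items(17, seed=0).iterations == math.ceil(1e6 / 17)

    def test_grid_side_policy(self):
        assert grid_side(17) == 34
        assert grid_side(40) == 64  # capped
        assert grid_side(17, mode="cells") == math.ceil(math.sqrt(34))


class TestInitGrid:
    def test_deterministic(self):
        w = np.array([1.0, 2.0, 0.5])
        a = init_grid(8, 3, w, np.random.default_rng(5))
        b = init_grid(8, 3, w, np.random.default_rng(5))
        np.testing.assert_array_equal(a.values, b.values)

    def test_range_respects_weights(self):
        w = np.array([1.0, 3.0, 0.0])
        g = init_grid(16, 3, w, np.random.default_rng(0))
        for i in range(3):
            assert g.values[:, :, i].min() >= 0.0
            assert g.values[:, :, i].max() <= w[i]

    def test_uniform_moments(self):
        """Component means match w_i/2 within 3 standard errors on 64x64."""
        w = np.array([1.0, 2.0])
        g = init_grid(64, 2, w, np.random.default_rng(7))
        n = 64 * 64
        for i in range(2):
            se = (w[i] / math.sqrt(12.0)) / math.sqrt(n)
            assert abs(g.values[:, :, i].mean() - w[i] / 2) < 3 * se


class TestTrainEpoch:
    def test_zero_alpha_leaves_values_but_reserves(self):
        mat = small_matrix(0)
        g = init_grid(5, mat.dimension, mat.weights, np.random.default_rng(1))
        out = train_epoch(g, mat, alpha=0.0, radius=2, rng=np.random.default_rng(2))
        np.testing.assert_array_equal(out.values, g.values)
        assert len(out.reservations) == 8
        assert len(set(out.reservations.values())) == 8

    def test_full_overwrite_single_item(self):
        mat = small_matrix(3, n_items=1)
        g = init_grid(4, mat.dimension, mat.weights, np.random.default_rng(1))
        out = train_epoch(g, mat, alpha=1.0, radius=0, rng=np.random.default_rng(2))
        (cell,) = out.reservations.values()
        np.testing.assert_allclose(out.values[cell[1], cell[0]], mat.values[0])

    def test_identical_items_get_distinct_cells(self):
        """Two equal vectors trickle outwards into separate reservations."""
        values = np.ones((2, 4))
        mat = MembershipMatrix(
            node_ids=["a", "b"],
            component_keys=[("set", str(i)) for i in range(4)],
            values=values, weights=np.ones(4),
        )
        g = init_grid(3, 4, np.ones(4), np.random.default_rng(0))
        out = train_epoch(g, mat, alpha=0.3, radius=1, rng=np.random.default_rng(1))
        cells = list(out.reservations.values())
        assert cells[0] != cells[1]

    def test_too_many_items_rejected(self):
        mat = small_matrix(0, n_items=8)
        g = init_grid(2, mat.dimension, mat.weights, np.random.default_rng(0))
        with pytest.raises(ValueError, match="exceed"):
            train_epoch(g, mat, 0.1, 1, np.random.default_rng(0))


class TestTrain:
    def test_deterministic(self):
        mat = small_matrix(1)
        s = TrainingSchedule(c=0.5, iterations=300, seed=9)
        l1, g1 = train(mat, s)
        l2, g2 = train(mat, s)
        assert l1.positions == l2.positions
        np.testing.assert_array_equal(g1.values, g2.values)

    def test_zero_member_set_invariance(self, fig2):
        """An appended empty active set cannot change cosine distances."""
        s = TrainingSchedule(c=0.5, iterations=TEST_ITERATIONS, seed=11)
        base, _ = train(encode(fig2), s)
        extra = build_module(
            fig2.nodes, fig2.interactions,
            fig2.sets + [AnnotationSet(id="empty", members=frozenset())],
            active=fig2.active + ["empty"],
        )
        with_empty, _ = train(encode(extra), s)
        assert base.positions == with_empty.positions

    def test_convexity_of_neuron_values(self):
        """Convex updates keep every component within [0, w_max]."""
        mat = small_matrix(2)
        mat.values[mat.values > 0] = 2.5  # non-unit weights
        _, grid = train(mat, TrainingSchedule(c=0.9, iterations=400, seed=3))
        assert grid.values.min() >= 0.0
        assert grid.values.max() <= 2.5 + 1e-9

    @pytest.mark.parametrize("seed", range(4))
    def test_injective_layouts(self, seed):
        m = random_module(seed)
        layout, _ = train(
            encode(m), TrainingSchedule(c=0.5, iterations=500, seed=seed)
        )
        assert len(set(layout.positions.values())) == len(m.nodes)

    def test_warm_start_preserves_layout(self):
        """Retraining an unchanged module relocates nodes only locally."""
        m = random_module(17, n_nodes=17)
        mat = encode(m)
        cold, grid = train(
            mat, TrainingSchedule(c=0.5, iterations=TEST_ITERATIONS, seed=5)
        )
        warm, _ = retrain(mat, grid, seed=6, iterations=TEST_ITERATIONS)
        drift = np.mean([
            math.hypot(cold.positions[n][0] - warm.positions[n][0],
                       cold.positions[n][1] - warm.positions[n][1])
            for n in cold.positions
        ])
        # regression bound: well below the ~10-20 cell drift of independent
        # cold starts on an N=34 grid
        assert drift <= 0.15 * cold.side

    def test_warm_start_across_dimension_change(self, fig2):
        mat = encode(fig2)
        _, grid = train(mat, TrainingSchedule(c=0.5, iterations=500, seed=2))
        smaller = build_module(fig2.nodes, fig2.interactions, fig2.sets,
                               active=["glioma"])
        layout, g2 = retrain(encode(smaller), grid, seed=3, iterations=500)
        assert g2.dimension == 8
        assert len(set(layout.positions.values())) == 6

    def test_item_overflow_rejected(self):
        mat = small_matrix(0, n_items=8)
        with pytest.raises(ValueError, match="exceed"):
            train(mat, TrainingSchedule(c=0.5, iterations=10, seed=0), side=2)


class TestSetDominance:
    def test_weight_one_is_identity(self, fig2):
        np.testing.assert_array_equal(
            encode(set_dominance(fig2, "ltp", 1.0)).values, encode(fig2).values
        )

    def test_unknown_set(self, fig2):
        with pytest.raises(KeyError):
            set_dominance(fig2, "nope", 2.0)

    def test_zero_weight_matches_network_only_distances(self, fig2):
        """Weight 0 removes the set's influence on cosine distances."""
        stripped = set_dominance(
            set_dominance(set_dominance(fig2, "glioma", 0.0), "ltp", 0.0),
            "gnrh", 0.0,
        )
        s = TrainingSchedule(c=0.5, iterations=TEST_ITERATIONS, seed=21)
        lay_zero, _ = train(encode(stripped), s)
        network_only = build_module(fig2.nodes, fig2.interactions, fig2.sets,
                                    active=[])
        # zero-weight set components are all-zero in items and neurons, so
        # every cosine distance — and hence the layout — matches the
        # network-only embedding exactly
        assert not encode(stripped).values[:, 7:].any()
        lay_net, _ = train(encode(network_only), s)
        assert lay_zero.positions == lay_net.positions


@settings(derandomize=True, max_examples=15, deadline=None)
@given(
    n_items=st.integers(min_value=1, max_value=10),
    m=st.integers(min_value=1, max_value=8),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_epoch_reservation_bijection(n_items, m, seed):
    """Property: every epoch yields an injective item -> cell map."""
    rng = np.random.default_rng(seed)
    values = (rng.random((n_items, m)) < 0.4).astype(float)
    mat = MembershipMatrix(
        node_ids=[f"n{i}" for i in range(n_items)],
        component_keys=[("set", str(j)) for j in range(m)],
        values=values, weights=np.ones(m),
    )
    side = max(4, grid_side(n_items, cap=8))
    g = init_grid(side, m, np.ones(m), np.random.default_rng(seed + 1))
    out = train_epoch(g, mat, alpha=0.4, radius=2, rng=rng)
    assert len(out.reservations) == n_items
    assert len(set(out.reservations.values())) == n_items
    assert out.values.min() >= 0.0 and out.values.max() <= 1.0 + 1e-12
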