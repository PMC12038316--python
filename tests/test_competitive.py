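"""The competitive layer: activation, lateral inhibition, the sparseness
measure and threshold-setting, and the associative / trace learning rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import scenenet as sn
from scenenet.competitive import _dog_kernel
from scenenet.topology import ConnectivityMap


def small_connectivity(rng, n_source=16, n_targets=4, n_conn=5):
    idx = np.stack([rng.choice(n_source, n_conn, replace=False)
                    for _ in range(n_targets)])
    w = np.stack([sn.init_weights(n_conn, rng) for _ in range(n_targets)])
    return ConnectivityMap((n_source,), (n_targets, 1), idx, w)


class TestActivate:
    def test_zero_input_zero_activation(self, rng):
        conn = small_connectivity(rng)
        h = sn.activate(np.zeros(16), conn)
        assert not h.any()

    def test_single_afferent_identity(self):
        conn = ConnectivityMap((4,), (1, 1), np.array([[2]]), np.array([[1.0]]))
        h = sn.activate(np.array([0.0, 0.0, 0.7, 0.0]), conn)
        assert h[0, 0] == pytest.approx(0.7)

    def test_matches_brute_force_loop(self, rng):
        conn = small_connectivity(rng)
        x = rng.random(16)
        h = sn.activate(x, conn)
        for t in range(4):
            expected = sum(conn.weights[t, k] * x[conn.indices[t, k]]
                           for k in range(5))
            assert h.ravel()[t] == pytest.approx(expected)

    def test_dimension_mismatch(self, rng):
        conn = small_connectivity(rng)
        with pytest.raises(ValueError):
            sn.activate(np.zeros(17), conn)


class TestLateralInhibition:
    def test_filter_sums_to_zero(self):
        assert abs(_dog_kernel(0.2, 1.5).sum()) < 1e-10

    def test_uniform_map_suppressed(self):
        out = sn.lateral_inhibit(np.full((32, 32), 3.0))
        assert np.abs(out).max() < 1e-9

    def test_impulse_response_is_the_kernel(self):
        h = np.zeros((33, 33))
        h[16, 16] = 1.0
        out = sn.lateral_inhibit(h)
        k = _dog_kernel(0.2, 1.5)
        hw = k.shape[0] // 2
        np.testing.assert_allclose(
            out[16 - hw : 16 + hw + 1, 16 - hw : 16 + hw + 1], k, atol=1e-12
        )
        assert out[16, 16] > 0 and out[16, 16 + 2] < 0  # centre +, surround -

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            sn.lateral_inhibit(np.zeros((8, 8)), 1.5, 0.2)


class TestSparseness:
    @pytest.mark.parametrize(
        "y, expected",
        [
            ([1, 1, 0, 0], 0.5),       # binary: k/n
            ([1, 1, 1, 1], 1.0),       # all equal
            ([3, 1, 0, 0], 0.4),       # graded
            ([0, 0, 0], 0.0),          # defined as 0 for silence
        ],
    )
    def test_closed_forms(self, y, expected):
        assert sn.sparseness(np.array(y, dtype=float)) == pytest.approx(expected)

    @given(
        y=hnp.arrays(np.float64, 16,
                     elements=st.floats(0, 100, allow_nan=False)),
        c=st.floats(0.01, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_and_bounds(self, y, c):
        a = sn.sparseness(y)
        assert 0.0 <= a <= 1.0 + 1e-12
        if y.any():
            assert sn.sparseness(c * y) == pytest.approx(a, rel=1e-9)


class TestSetSparseness:
    def test_worked_example(self):
        y, theta = sn.set_sparseness(np.array([2.0, 1.0, 1.0, 1.0]), 0.25)
        assert theta == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(y, [1.0, 0.0, 0.0, 0.0], atol=1e-6)
        assert sn.sparseness(y) == pytest.approx(0.25, abs=1e-3)

    def test_identity_case_accepts_zero_threshold(self, rng):
        h = rng.random((8, 8))
        target = sn.sparseness(np.maximum(h, 0.0))
        y, theta = sn.set_sparseness(h, target)
        # a threshold at (or within tolerance of) zero is accepted
        assert theta <= h.min() + 0.01
        assert sn.sparseness(y) == pytest.approx(target, abs=1e-3)

    @pytest.mark.parametrize("target", [0.1, 0.12, 0.08])
    def test_table_targets_on_seeded_maps(self, target):
        rng = np.random.default_rng(42)
        for _ in range(100):
            h = rng.standard_normal((32, 32))
            y, _ = sn.set_sparseness(h, target)
            assert abs(sn.sparseness(y) - target) <= 1e-3

    def test_constant_map_degenerate(self, caplog):
        y, theta = sn.set_sparseness(np.full((4, 4), 2.0), 0.1)
        assert not y.any()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_target(self, bad):
        with pytest.raises(ValueError):
            sn.set_sparseness(np.ones((2, 2)), bad)


class TestLearningRules:
    def test_silent_neuron_weights_bitwise_unchanged(self, rng):
        conn = small_connectivity(rng)
        before = conn.weights.copy()
        y = np.array([0.0, 1.0, 0.0, 2.0])
        sn.hebb_update(conn, rng.random(16), y, alpha=0.5)
        np.testing.assert_array_equal(conn.weights[0], before[0])
        np.testing.assert_array_equal(conn.weights[2], before[2])
        assert not np.array_equal(conn.weights[1], before[1])

    def test_update_direction_matches_rule(self):
        # dw_j = alpha * y * x_j before renormalisation
        conn = ConnectivityMap((3,), (1, 1), np.array([[0, 1, 2]]),
                               np.array([[0.6, 0.0, 0.8]]))
        x = np.array([1.0, 0.0, 1.0])
        sn.hebb_update(conn, x, np.array([2.0]), alpha=0.5)
        raw = np.array([0.6, 0.0, 0.8]) + 0.5 * 2.0 * x
        np.testing.assert_allclose(conn.weights[0], raw / np.linalg.norm(raw))

    def test_weight_norms_unit_after_updates(self, rng):
        conn = small_connectivity(rng)
        for _ in range(5):
            sn.hebb_update(conn, rng.random(16), rng.random(4), alpha=1.0)
        np.testing.assert_allclose(np.linalg.norm(conn.weights, axis=1), 1.0,
                                   atol=1e-12)

    def test_trace_examples(self):
        np.testing.assert_array_equal(
            sn.trace_step(np.zeros(3), np.array([1.0, 2.0, 3.0]), 0.0),
            [1.0, 2.0, 3.0],
        )
        assert sn.trace_step(np.zeros(1), np.ones(1), 0.8)[0] == pytest.approx(0.2)

    def test_trace_converges_geometrically_to_constant_rate(self):
        tr = np.zeros(1)
        for _ in range(200):
            tr = sn.trace_step(tr, np.ones(1), 0.8)
        assert tr[0] == pytest.approx(1.0, abs=1e-12)

    def test_trace_recursion_matches_closed_form(self, rng):
        # ybar^tau = (1-eta) sum_k eta^k y^(tau-k) + eta^tau ybar^0
        eta = 0.8
        ys = rng.random((100, 6))
        tr = rng.random(6)
        tr0 = tr.copy()
        for y in ys:
            tr = sn.trace_step(tr, y, eta)
        tau = len(ys)
        closed = eta**tau * tr0
        for k in range(tau):
            closed += (1 - eta) * eta**k * ys[tau - 1 - k]
        np.testing.assert_allclose(tr, closed, atol=1e-12)

    def test_eta_zero_trace_update_bitwise_equals_hebb(self, rng):
        conn_a = small_connectivity(np.random.default_rng(7))
        conn_b = small_connectivity(np.random.default_rng(7))
        x, y = rng.random(16), rng.random(4)
        trace = sn.trace_step(np.zeros(4), y, eta=0.0)
        sn.hebb_update(conn_a, x, y, alpha=0.3)
        sn.trace_update(conn_b, x, trace, alpha=0.3)
        np.testing.assert_array_equal(conn_a.weights, conn_b.weights)

    def test_invalid_eta(self):
        with pytest.raises(ValueError):
            sn.trace_step(np.zeros(2), np.zeros(2), 1.0)
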