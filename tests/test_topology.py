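"""Topological connectivity: kernel calibration, afferent sampling,
frequency allocation, weight initialisation, neuron distances."""

import numpy as np
import pytest

import scenenet as sn
from scenenet.topology import (
    CONTAINMENT_Z,
    LayerConfig,
    aligned_position,
    build_layer_connectivity,
    build_v1_connectivity,
    connection_probabilities,
    distance_matrix,
)

LAYER2_CFG = LayerConfig(32, 32, n_connections=40, radius=1.7, sparseness=0.12)


class TestContainmentCalibration:
    def test_analytic_mass_within_radius_is_067(self):
        # 2-D radial Gaussian: P(r <= R) with sigma = R / z equals 0.67
        assert abs(1.0 - np.exp(-(CONTAINMENT_Z**2) / 2.0) - 0.67) < 1e-12

    def test_empirical_kernel_containment(self, rng):
        # i.i.d. draws from the connection-probability kernel of an
        # interior neuron: ~67% fall within one radius
        radius = 1.7
        hits = total = 0
        for t in range(250):
            pos = (8 + t % 16, 8 + (t * 7) % 16)
            idx = sn.sample_afferents(pos, (32, 32), 40, radius, rng, replace=True)
            d = np.array([sn.neuron_distance(pos, i, (32, 32)) for i in idx])
            hits += int((d <= radius).sum())
            total += len(d)
        assert total == 10_000
        assert abs(hits / total - 0.67) <= 0.03

    def test_degenerate_radius_collapses_to_aligned_cells(self, rng):
        idx = sn.sample_afferents((10, 10), (32, 32), 4, 0.05, rng)
        d = [sn.neuron_distance((10, 10), i, (32, 32)) for i in idx]
        assert max(d) <= np.sqrt(2) + 1e-9  # nearest cells only (widened kernel)


class TestAfferentSampling:
    def test_layer2_neuron_gets_exactly_40_unique_afferents(self, rng):
        conn = build_layer_connectivity((32, 32), LAYER2_CFG, rng)
        assert conn.n_connections == 40
        for t in (0, 500, 1023):
            assert len(set(conn.indices[t])) == 40

    def test_reproducible_from_seed(self):
        a = build_layer_connectivity((32, 32), LAYER2_CFG, np.random.default_rng(5))
        b = build_layer_connectivity((32, 32), LAYER2_CFG, np.random.default_rng(5))
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_no_systematic_alignment_drift(self, rng):
        conn = build_layer_connectivity((32, 32), LAYER2_CFG, rng)
        biases = []
        for t in range(conn.n_targets):
            pos = divmod(t, 32)
            if not (8 <= pos[0] < 24 and 8 <= pos[1] < 24):
                continue  # interior only: edge truncation biases inward
            rows, cols = np.divmod(conn.indices[t], 32)
            biases.append([rows.mean() - pos[0], cols.mean() - pos[1]])
        bias = np.abs(np.mean(biases, axis=0))
        assert np.all(bias < 0.5)

    def test_oversubscribed_request_rejected(self, rng):
        with pytest.raises(ValueError):
            sn.sample_afferents((0, 0), (4, 4), 17, 1.0, rng)

    def test_kernel_probabilities_normalised(self):
        p = connection_probabilities((10.0, 10.0), (32, 32), 1.7)
        assert abs(p.sum() - 1.0) < 1e-12
        assert p.max() == p[10, 10]


class TestFrequencyAllocation:
    @pytest.mark.parametrize(
        "n, ratio, expected",
        [
            (54, 2.0, (29, 14, 7, 4)),
            (54, 1.0, (14, 14, 13, 13)),
        ],
    )
    def test_largest_remainder_apportionment(self, n, ratio, expected):
        counts = sn.allocate_by_frequency(n, 4, ratio)
        assert tuple(counts) == expected

    @pytest.mark.parametrize("n", [4, 13, 54, 101])
    def test_counts_sum_conserved(self, n):
        assert sn.allocate_by_frequency(n).sum() == n

    def test_too_few_connections_rejected(self):
        with pytest.raises(ValueError):
            sn.allocate_by_frequency(3, 4)

    def test_v1_connectivity_band_counts(self, rng):
        l1 = LayerConfig(32, 32, n_connections=54, radius=1.0, sparseness=0.1)
        conn = build_v1_connectivity((256, 256, 32), l1, rng)
        chan = conn.indices[0] % 32
        band = chan // 8
        assert tuple(np.bincount(band, minlength=4)) == (29, 14, 7, 4)
        assert len(set(conn.indices[0])) == 54


class TestWeightsAndDistances:
    def test_init_weights_unit_norm_positive(self, rng):
        w = sn.init_weights(40, rng)
        assert abs(np.linalg.norm(w) - 1.0) < 1e-12
        assert np.all(w > 0)

    def test_init_weights_seeded(self):
        a = sn.init_weights(10, np.random.default_rng(3))
        b = sn.init_weights(10, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_distance_examples(self):
        assert sn.neuron_distance((0, 0), (0, 0), (32, 32)) == 0.0
        assert sn.neuron_distance((0, 0), (3, 4), (32, 32)) == 5.0

    def test_distance_symmetry(self, rng):
        for _ in range(20):
            i, j = rng.integers(0, 1024, 2)
            assert sn.neuron_distance(int(i), int(j), (32, 32)) == pytest.approx(
                sn.neuron_distance(int(j), int(i), (32, 32))
            )

    def test_distance_out_of_range(self):
        with pytest.raises(IndexError):
            sn.neuron_distance(1024, 0, (32, 32))

    def test_distance_matrix_matches_pairwise(self):
        D = distance_matrix((4, 4))
        assert D[0, 5] == pytest.approx(np.sqrt(2))
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_aligned_position_scaling(self):
        # a 32-neuron layer aligned onto the 256-px V1 grid
        assert aligned_position((0, 0), (32, 32), (256, 256)) == (3.5, 3.5)
        assert aligned_position((31, 31), (32, 32), (256, 256)) == (251.5, 251.5)


def test_connectivity_csv_export(tmp_path, rng):
    from scenenet.topology import save_connectivity_csv

    conn = build_layer_connectivity((32, 32), LAYER2_CFG, rng)
    path = tmp_path / "conn.csv"
    save_connectivity_csv(conn, path)
    table = np.loadtxt(path, delimiter=",")
    assert table.shape == (1024 * 40, 3)
    np.testing.assert_array_equal(table[:40, 1], conn.indices[0])
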