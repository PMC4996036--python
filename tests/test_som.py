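"""Hexagonal grid geometry, BMU search, training, and determinism."""

import numpy as np
import pytest

from somtopo import som, synthetic


class TestGrid:
    @pytest.mark.parametrize(
        "units,shape",
        [(320, (20, 16)), (285, (19, 15)), (340, (20, 17)),
         (100, (10, 10)), (1, (1, 1)), (12, (4, 3))],
    )
    def test_near_square_factorization(self, units, shape):
        assert som.near_square_shape(units) == shape

    def test_prime_falls_back_to_single_column(self):
        with pytest.warns(UserWarning, match="prime"):
            assert som.near_square_shape(7) == (7, 1)

    def test_single_node_has_no_neighbors(self):
        coords, neighbors = som.build_grid(1)
        assert coords.shape == (1, 2)
        assert neighbors == [[]]

    def test_interior_nodes_have_six_unit_neighbors(self):
        # brute-force distance enumeration on the 20x16 lattice
        coords, neighbors = som.build_grid(320)
        rows, cols = 20, 16
        for i in range(320):
            r, c = divmod(i, cols)
            if 1 <= r <= rows - 2 and 1 <= c <= cols - 2:
                assert len(neighbors[i]) == 6
                d = np.linalg.norm(coords[neighbors[i]] - coords[i], axis=1)
                np.testing.assert_allclose(d, 1.0, atol=1e-9)

    def test_lattice_unit_spacing_within_rows(self):
        coords, _ = som.build_grid(12)
        # consecutive nodes in one row are exactly one unit apart
        np.testing.assert_allclose(
            np.diff(coords[:3, 0]), 1.0, atol=1e-12
        )


class TestInitCodebook:
    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(100, 5))
        a = som.init_codebook(data, 10, seed=3)
        b = som.init_codebook(data, 10, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_full_sampling_is_permutation(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(8, 3))
        cb = som.init_codebook(data, 8, seed=0)
        # every data row appears exactly once
        matched = sorted(
            int(np.flatnonzero((data == row).all(axis=1))[0]) for row in cb
        )
        assert matched == list(range(8))

    def test_different_seeds_differ(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(100, 5))
        a = som.init_codebook(data, 10, seed=0)
        b = som.init_codebook(data, 10, seed=1)
        assert not np.array_equal(a, b)

    def test_too_few_genes_fails(self):
        with pytest.raises(ValueError, match="map units"):
            som.init_codebook(np.zeros((3, 2)), 5, seed=0)


class TestAssignBmu:
    def test_exact_row_match(self):
        rng = np.random.default_rng(0)
        cb = rng.normal(size=(10, 4))
        assert som.assign_bmu(cb[4], cb) == 5  # 1-based

    def test_tie_broken_by_lowest_node_id(self):
        cb = np.array([[1.0], [-1.0], [1.0]])
        assert som.assign_bmu(np.array([0.0]), cb) == 1

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(7)
        cb = rng.normal(size=(50, 6))
        for _ in range(200):
            x = rng.normal(size=6)
            brute = 1 + int(
                np.argmin([np.sum((x - w) ** 2) for w in cb])
            )
            assert som.assign_bmu(x, cb) == brute

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="features"):
            som.assign_bmu(np.zeros(3), np.zeros((4, 5)))


class TestTrain:
    def test_zero_steps_identity_when_codebook_is_data(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(12, 4))
        model = som.train(
            data,
            som.SomConfig(map_units=12, total_steps=0, seed=0),
            initial_codebook=data,
        )
        assert som.quantization_error(model.codebook, data) == 0.0
        np.testing.assert_array_equal(model.assignment, np.arange(1, 13))

    def test_seed_determinism(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(200, 6))
        a = som.train(data, som.SomConfig(map_units=16, seed=9))
        b = som.train(data, som.SomConfig(map_units=16, seed=9))
        np.testing.assert_array_equal(a.codebook, b.codebook)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(300, 5))
        model = som.train(data, som.SomConfig(map_units=25, seed=0))
        assert model.node_sizes().sum() == 300
        assert set(model.assignment) <= set(range(1, 26))

    def test_separated_blobs_use_disjoint_connected_regions(self):
        rng = np.random.default_rng(8)
        blob_a = rng.normal(0.0, 0.3, size=(80, 5))
        blob_b = rng.normal(6.0, 0.3, size=(80, 5))
        data = np.vstack([blob_a, blob_b])
        model = som.train(data, som.SomConfig(map_units=4, seed=1))
        nodes_a = set(model.assignment[:80])
        nodes_b = set(model.assignment[80:])
        assert nodes_a.isdisjoint(nodes_b)
        # each blob's nodes form a lattice-connected set
        dist = model.lattice_distances()
        for nodes in (nodes_a, nodes_b):
            idx = sorted(n - 1 for n in nodes)
            if len(idx) > 1:
                sub = dist[np.ix_(idx, idx)]
                reach = {idx[0]}
                frontier = {idx[0]}
                while frontier:
                    frontier = {
                        j for j in idx if j not in reach
                        and any(abs(dist[i, j] - 1.0) < 1e-9 for i in reach)
                    }
                    reach |= frontier
                assert reach == set(idx)

    def test_non_finite_profile_named(self):
        data = np.ones((10, 3))
        data[4, 1] = np.nan
        with pytest.raises(ValueError, match="g4"):
            som.train(data, som.SomConfig(map_units=2, total_steps=0),
                      gene_ids=[f"g{i}" for i in range(10)])

    def test_topographic_recovery_of_planted_groups(self):
        # separation ~20x the within-group noise; groups sized so that a
        # group fills ~2 lattice cells
        rng = np.random.default_rng(3)
        n_groups, per_group, dim = 8, 40, 6
        centers = rng.normal(0, 4, (n_groups, dim))
        data = np.repeat(centers, per_group, axis=0) + rng.normal(
            0, 0.3, (n_groups * per_group, dim)
        )
        groups = np.repeat(np.arange(n_groups), per_group)
        model = som.train(data, som.SomConfig(map_units=16, seed=0))
        m = synthetic.truth_metrics(model.assignment, groups, model.node_coords)
        assert m["pair_recall"] >= 0.9
        assert m["purity"] >= 0.95


class TestQuantizationError:
    def test_zero_when_data_equals_codebook(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(5, 3))
        assert som.quantization_error(data, data) == 0.0

    def test_single_gene_single_node_distance(self):
        cb = np.array([[0.0, 0.0]])
        data = np.array([[3.0, 4.0]])
        assert som.quantization_error(cb, data) == pytest.approx(5.0)

    def test_training_reduces_error_on_default_dataset(
        self, default_nm, default_som
    ):
        init = som.init_codebook(
            default_nm.values, default_som.map_units, seed=0
        )
        qe_init = som.quantization_error(init, default_nm.values)
        qe_final = som.quantization_error(
            default_som.codebook, default_nm.values
        )
        assert qe_final <= qe_init


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    data = rng.normal(size=(60, 4))
    model = som.train(data, som.SomConfig(map_units=6, seed=2),
                      gene_ids=[f"g{i}" for i in range(60)])
    som.save_model(model, tmp_path / "model")
    back = som.load_model(tmp_path / "model")
    np.testing.assert_array_equal(back.assignment, model.assignment)
    np.testing.assert_allclose(back.codebook, model.codebook)
    assert back.grid_shape == model.grid_shape
    assert back.gene_ids == model.gene_ids
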