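import numpy as np
import pytest

from segsom import som


def bfs_distance_oracle(grid, a, b):
    """Shortest-path steps over the explicit hex neighbor graph."""
    def neighbors(idx):
        r, c = divmod(idx, grid.cols)
        if r % 2 == 0:
            deltas = [(-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0)]
        else:
            deltas = [(-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1)]
        for dr, dc in deltas:
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.rows and 0 <= cc < grid.cols:
                yield rr * grid.cols + cc

    from collections import deque
    seen = {a: 0}
    q = deque([a])
    while q:
        cur = q.popleft()
        if cur == b:
            return seen[cur]
        for nxt in neighbors(cur):
            if nxt not in seen:
                seen[nxt] = seen[cur] + 1
                q.append(nxt)
    raise AssertionError("disconnected grid")


class TestHexGrid:
    def test_distance_zero_and_adjacent(self):
        g = som.HexGrid(7, 7)
        assert som.grid_distance(g, 10, 10) == 0
        assert som.grid_distance(g, 10, 11) == 1

    def test_interior_nodes_have_six_unit_neighbors(self):
        g = som.HexGrid(7, 7)
        D = g.distance_matrix()
        interior = [g.index_of(r, c) for r in range(1, 6) for c in range(1, 6)]
        for idx in interior:
            assert (D[idx] == 1).sum() == 6

    @pytest.mark.parametrize("rows,cols", [(7, 7), (3, 5), (4, 4)])
    def test_distances_match_bfs_oracle(self, rows, cols):
        g = som.HexGrid(rows, cols)
        rng = np.random.default_rng(0)
        pairs = rng.integers(0, g.n_nodes, size=(30, 2))
        for a, b in pairs:
            assert som.grid_distance(g, int(a), int(b)) == bfs_distance_oracle(g, int(a), int(b))
        # corner-to-corner explicitly
        assert som.grid_distance(g, 0, g.n_nodes - 1) == bfs_distance_oracle(g, 0, g.n_nodes - 1)

    def test_off_grid_raises(self):
        g = som.HexGrid(3, 3)
        with pytest.raises(IndexError):
            som.grid_distance(g, 0, 9)


class TestBMU:
    def test_exact_node_vector_matches_itself(self):
        grid = som.SOMGrid.initialize(4, 4, dim=6, seed=0)
        assert som.find_bmu(grid, grid.W[12]) == 12

    def test_two_node_toy_example(self):
        grid = som.SOMGrid(hex=som.HexGrid(1, 2),
                           W=np.array([[0.0, 0.0], [10.0, 0.0]]))
        assert som.find_bmu(grid, np.array([4.0, 0.0])) == 0

    def test_tie_breaks_to_lowest_index(self):
        grid = som.SOMGrid(hex=som.HexGrid(2, 2),
                           W=np.array([[0.0], [2.0], [0.0], [2.0]]))
        assert som.find_bmu(grid, np.array([1.0])) == 0

    def test_dimension_mismatch_raises(self):
        grid = som.SOMGrid.initialize(2, 2, dim=3, seed=0)
        with pytest.raises(ValueError):
            som.find_bmu(grid, np.zeros(5))


class TestUpdateStep:
    def test_zero_learning_rate_is_identity(self):
        grid = som.SOMGrid.initialize(3, 3, dim=4, seed=1)
        before = grid.W.copy()
        sched = som.TrainSchedule(epochs=1, learning_rate=[0.0], radius=[1.0])
        som.update_step(grid, np.ones(4), bmu=0, epoch=0, schedule=sched)
        np.testing.assert_array_equal(grid.W, before)

    def test_single_node_full_rate_jumps_to_datum(self):
        grid = som.SOMGrid(hex=som.HexGrid(1, 1), W=np.array([[5.0, -3.0]]))
        sched = som.TrainSchedule(epochs=1, learning_rate=[1.0], radius=[1.0])
        v = np.array([2.0, 2.0])
        som.update_step(grid, v, bmu=0, epoch=0, schedule=sched)
        np.testing.assert_allclose(grid.W[0], v)

    def test_two_node_closed_form(self):
        # w0 = 0 + 1*0.5*(2-0) = 1; w1 = 4 + exp(-1/2)*0.5*(2-4) = 3.3935
        grid = som.SOMGrid(hex=som.HexGrid(1, 2), W=np.array([[0.0], [4.0]]))
        sched = som.TrainSchedule(epochs=1, learning_rate=[0.5], radius=[1.0])
        som.update_step(grid, np.array([2.0]), bmu=0, epoch=0, schedule=sched)
        np.testing.assert_allclose(grid.W.ravel(),
                                   [1.0, 4.0 + 0.5 * np.exp(-0.5) * (2.0 - 4.0)],
                                   rtol=1e-9)
        assert grid.W[1, 0] == pytest.approx(3.3935, abs=5e-5)


class TestTraining:
    def test_single_datum_contracts_toward_it(self):
        rng = np.random.default_rng(0)
        grid = som.SOMGrid.initialize(3, 3, dim=5, seed=0)
        v = rng.random(5)
        d0 = np.linalg.norm(grid.W - v, axis=1).min()
        sched = som.TrainSchedule.for_grid(3, 3, epochs=20)
        som.train(grid, v[None, :], sched, seed=1)
        assert np.linalg.norm(grid.W - v, axis=1).min() < d0

    def test_duplicated_vector_converges_on_1x1_grid(self):
        grid = som.SOMGrid.initialize(1, 1, dim=3, seed=0)
        v = np.array([0.3, -1.2, 2.0])
        X = np.tile(v, (10, 1))
        som.train(grid, X, som.TrainSchedule.for_grid(1, 1, epochs=100), seed=0)
        np.testing.assert_allclose(grid.W[0], v, atol=1e-6)

    def test_quantization_error_decreases(self):
        rng = np.random.default_rng(2)
        X = rng.random((120, 8))
        grid = som.SOMGrid.initialize(4, 4, dim=8, seed=3)
        som.train(grid, X, som.TrainSchedule.for_grid(4, 4, epochs=30), seed=4)
        qe = [h[1] for h in grid.history]
        assert qe[-1] < qe[0]

    def test_convex_hull_bound(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 4)) * 10 - 5
        grid = som.SOMGrid.initialize(3, 4, dim=4, seed=6)
        lo = np.minimum(X.min(axis=0), grid.W.min(axis=0))
        hi = np.maximum(X.max(axis=0), grid.W.max(axis=0))
        som.train(grid, X, som.TrainSchedule.for_grid(3, 4, epochs=25), seed=7)
        assert np.all(grid.W >= lo - 1e-9) and np.all(grid.W <= hi + 1e-9)

    def test_training_is_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.random((50, 6))
        runs = []
        for _ in range(2):
            grid = som.SOMGrid.initialize(3, 3, dim=6, seed=9)
            som.train(grid, X, som.TrainSchedule.for_grid(3, 3, epochs=10), seed=10)
            runs.append(grid.W.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_empty_data_rejected(self):
        grid = som.SOMGrid.initialize(2, 2, dim=3, seed=0)
        with pytest.raises(ValueError):
            som.train(grid, np.zeros((0, 3)))


class TestAssignment:
    def test_node_vectors_assign_to_themselves(self):
        grid = som.SOMGrid.initialize(3, 3, dim=4, seed=11)
        np.testing.assert_array_equal(som.assign_all(grid, grid.W), np.arange(9))

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(12)
        grid = som.SOMGrid.initialize(2, 2, dim=5, seed=13)
        X = rng.random((3, 5))
        expected = [int(np.argmin([np.linalg.norm(x - w) for w in grid.W])) for x in X]
        np.testing.assert_array_equal(som.assign_all(grid, X), expected)

    def test_invariant_under_metric_rescaling(self):
        # argmin of RMSE equals argmin of Euclidean distance
        rng = np.random.default_rng(14)
        grid = som.SOMGrid.initialize(3, 2, dim=7, seed=15)
        X = rng.random((20, 7))
        base = som.assign_all(grid, X)
        rmse = np.stack([np.sqrt(np.mean((X - w) ** 2, axis=1)) for w in grid.W], axis=1)
        np.testing.assert_array_equal(base, np.argmin(rmse, axis=1))


class TestTopologyQuality:
    def test_ordered_line_map_has_zero_topographic_error(self):
        grid = som.SOMGrid(hex=som.HexGrid(1, 4),
                           W=np.array([[0.0], [1.0], [2.0], [3.0]]))
        X = np.array([[0.1], [1.1], [1.9], [2.9]])
        assert som.topographic_error(grid, X) == 0.0

    def test_scrambled_prototypes_raise_topographic_error(self):
        # swapping two distant prototypes breaks best/second-best adjacency
        grid = som.SOMGrid(hex=som.HexGrid(1, 4),
                           W=np.array([[0.0], [3.0], [2.0], [1.0]]))
        X = np.linspace(0, 3, 16)[:, None]
        assert som.topographic_error(grid, X) > 0.0

    def test_restart_selection_is_deterministic_and_trained(self):
        rng = np.random.default_rng(0)
        X = rng.random((80, 5))
        a = som.train_selected(3, 3, X, som.TrainSchedule.for_grid(3, 3, epochs=10),
                               seed=4, n_restarts=2)
        b = som.train_selected(3, 3, X, som.TrainSchedule.for_grid(3, 3, epochs=10),
                               seed=4, n_restarts=2)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.trained

    def test_restart_selection_never_worse_than_single_run(self):
        rng = np.random.default_rng(1)
        X = rng.random((100, 6))
        sched = som.TrainSchedule.for_grid(3, 3, epochs=15)
        best = som.train_selected(3, 3, X, sched, seed=2, n_restarts=3)
        single_tes = []
        from segsom.config import child_seed
        for r in range(3):
            g = som.SOMGrid.initialize(3, 3, 6, seed=child_seed(2, f"som-init-{r}"))
            som.train(g, X, sched, seed=child_seed(2, f"som-shuffle-{r}"))
            single_tes.append(som.topographic_error(g, X))
        assert som.topographic_error(best, X) == min(single_tes)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        grid = som.SOMGrid.initialize(3, 3, dim=4, seed=0)
        som.train(grid, np.random.default_rng(0).random((20, 4)),
                  som.TrainSchedule.for_grid(3, 3, epochs=5), seed=1)
        path = tmp_path / "som.npz"
        som.save_som(path, grid, seed=1)
        loaded = som.load_som(path)
        np.testing.assert_array_equal(loaded.W, grid.W)
        assert loaded.trained
        assert loaded.hex.rows == 3 and loaded.hex.cols == 3


class TestSchedule:
    def test_rejects_increasing_sequences(self):
        with pytest.raises(ValueError):
            som.TrainSchedule(epochs=2, learning_rate=[0.1, 0.2], radius=[1, 1])
        with pytest.raises(ValueError):
            som.TrainSchedule(epochs=2, learning_rate=[0.2, 0.1], radius=[1, 2])

    def test_defaults_decay_monotonically(self):
        sched = som.TrainSchedule.for_grid(7, 7, epochs=100)
        assert sched.learning_rate[0] == 0.5 and sched.learning_rate[-1] == pytest.approx(0.01)
        assert sched.radius[0] == 3.5 and sched.radius[-1] == 0.5
        assert np.all(np.diff(sched.learning_rate) <= 0)
        assert np.all(np.diff(sched.radius) <= 0)
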