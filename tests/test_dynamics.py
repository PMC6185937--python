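"""The weighted midpoint update rule and convergence detection."""

import numpy as np
import pytest

from leksim import (
    DynamicsConfig,
    HIGH,
    NeighborGraph,
    RankedPopulation,
    initialize_random,
    run_to_convergence,
    step,
    weighted_neighbor_center,
)
from leksim.geometry import wrap_position


def _tiny_pop(positions, weights):
    positions = np.asarray(positions, float)
    n = len(positions)
    return RankedPopulation(
        positions=positions,
        ranks=np.array([HIGH] * n),
        weights=np.asarray(weights, float),
    )


class TestWeightedNeighborCenter:
    def test_weighted_average(self):
        # focal at 0.3; neighbors at 0 (weight 5) and 0.6 (weight 1):
        # center = (5*0 + 1*0.6)/6 = 0.1
        pop = _tiny_pop([[0.3, 0.0], [0.0, 0.0], [0.6, 0.0]], [1.0, 5.0, 1.0])
        graph = NeighborGraph(3, np.array([[0, 1], [0, 2]]))
        c = weighted_neighbor_center(0, pop, graph)
        assert c == pytest.approx([0.1, 0.0], abs=1e-12)

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        pop = _tiny_pop([[0.5, 0.5], [0.2, 0.4], [0.7, 0.9]], [1, 1, 1])
        graph = NeighborGraph(3, np.array([[0, 1], [0, 2]]))
        c = weighted_neighbor_center(0, pop, graph)
        assert c == pytest.approx([0.45, 0.65], abs=1e-12)

    def test_periodic_unwrap_across_boundary(self):
        # neighbors at 0.95 and 0.15 straddle the focal at 0.05: their
        # minimum images are -0.05 and +0.15, center = 0.05
        pop = _tiny_pop([[0.05, 0.5], [0.95, 0.5], [0.15, 0.5]], [1, 1, 1])
        graph = NeighborGraph(3, np.array([[0, 1], [0, 2]]))
        c = weighted_neighbor_center(0, pop, graph)
        assert c == pytest.approx([0.05, 0.5], abs=1e-12)


class TestStep:
    def test_move_is_half_way_to_weighted_center(self):
        """Vectorized step agrees with the per-individual midpoint rule."""
        pop = initialize_random(60, 0.5, 0.3, seed=8)
        from leksim.geometry import periodic_neighbor_graph, minimum_image_displacement

        graph = periodic_neighbor_graph(pop.positions)
        moved, msd = step(pop, graph)
        expected_sq = 0.0
        for i in range(pop.n):
            center = weighted_neighbor_center(i, pop, graph)
            d = minimum_image_displacement(pop.positions[i], center)
            target = wrap_position(pop.positions[i] + 0.5 * d)
            assert moved.positions[i] == pytest.approx(target, abs=1e-12)
            expected_sq += float(d @ d) / 4.0
        assert msd == pytest.approx(expected_sq / pop.n, rel=1e-9)

    def test_fixed_point_has_zero_msd(self, converged_two_class):
        final, report = converged_two_class
        _, msd = step(final)
        assert msd < 1e-12

    def test_positions_stay_wrapped(self):
        pop = initialize_random(80, 0.3, 0.5, seed=2)
        for _ in range(5):
            pop, _ = step(pop)
            assert np.all(pop.positions >= 0) and np.all(pop.positions < 1)

    def test_weight_scale_invariance(self):
        """Scaling all weights by a constant leaves the step unchanged."""
        pop = initialize_random(50, 0.5, 1.0, seed=4)
        scaled = RankedPopulation(
            positions=pop.positions, ranks=pop.ranks, weights=pop.weights * 3.7
        )
        a, msd_a = step(pop)
        b, msd_b = step(scaled)
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-13)
        assert msd_a == pytest.approx(msd_b, rel=1e-12)


class TestRunToConvergence:
    def test_equal_weight_population_converges(self):
        pop = initialize_random(100, 0.5, 1.0, seed=6)
        final, report = run_to_convergence(pop, DynamicsConfig(msd_threshold=1e-14, max_steps=20_000))
        assert report.converged
        assert report.steps < 20_000
        assert report.final_msd < 1e-14

    def test_step_cap_marks_non_converged(self):
        pop = initialize_random(30, 0.5, 0.5, seed=7)
        _, report = run_to_convergence(pop, DynamicsConfig(msd_threshold=1e-20, max_steps=1))
        assert not report.converged
        assert report.steps == 1

    def test_converged_configuration_is_a_fixed_point(self, converged_two_class):
        final, report = converged_two_class
        again, report2 = run_to_convergence(final, DynamicsConfig(msd_threshold=1e-12, max_steps=5))
        assert report2.converged
        assert report2.steps == 1

    def test_translated_fixed_point_is_a_fixed_point(self, converged_two_class):
        final, _ = converged_two_class
        shifted = final.with_positions(wrap_position(final.positions + np.array([0.37, 0.81])))
        _, msd = step(shifted)
        assert msd < 1e-12

    def test_msd_trace_and_snapshots_recorded(self, tmp_path):
        pop = initialize_random(40, 0.5, 1.0, seed=11)
        _, report = run_to_convergence(
            pop,
            DynamicsConfig(msd_threshold=1e-30, max_steps=20, record_interval=5),
            snapshot_dir=tmp_path,
        )
        assert len(report.msd_trace) == 4
        snaps = sorted(tmp_path.glob("step_*.csv"))
        assert [p.name for p in snaps] == ["step_10.csv", "step_15.csv", "step_20.csv", "step_5.csv"]

    def test_degenerate_collapse_reported_not_raised(self):
        # small phi with strong weight asymmetry drives individuals to
        # coincide; the run must end as non-converged, not crash
        pop = initialize_random(100, 0.1, 0.1, seed=11)
        _, report = run_to_convergence(pop, DynamicsConfig(msd_threshold=1e-10, max_steps=3000))
        assert not report.converged or report.steps <= 3000

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DynamicsConfig(msd_threshold=0.0)
        with pytest.raises(ValueError):
            DynamicsConfig(max_steps=0)
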