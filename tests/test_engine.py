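"""Gillespie engine: sampling, trajectories, ensemble statistics,
exact master-equation oracle, fixed points, limits and determinism."""

import numpy as np
import pytest

from boolmc.engine import (
    CompiledNetwork,
    SimulationError,
    SimulationSettings,
    exact_transient,
    fixed_points_exhaustive,
    initial_distribution_vector,
    project_distribution,
    run_ensemble,
    sample_initial_state,
    simulate_trajectory,
    total_variation,
)
from boolmc.expressions import parse_expression
from boolmc.fixtures import make_nk_network, make_toy
from boolmc.model import (
    InitialStateDistribution,
    NodeDefinition,
    ValidationError,
    build_network,
)


class TestInitialSampling:
    def test_degenerate_block_always_sampled(self, toggle):
        dist = InitialStateDistribution.degenerate({"A": 1, "B": 0})
        rng = np.random.default_rng(0)
        draws = {sample_initial_state(dist, rng, toggle) for _ in range(100)}
        assert draws == {(1, 0)}

    def test_joint_block_is_atomic(self, toggle):
        dist = InitialStateDistribution(
            blocks=[(("A", "B"), [((1, 1), 0.5), ((0, 0), 0.5)])]
        )
        rng = np.random.default_rng(1)
        draws = [sample_initial_state(dist, rng, toggle) for _ in range(10000)]
        assert set(draws) <= {(1, 1), (0, 0)}  # mixed states never occur

    def test_default_bernoulli_frequency(self, toggle):
        dist = InitialStateDistribution()  # all nodes free at p=0.5
        rng = np.random.default_rng(2)
        n = 10000
        freq = sum(sample_initial_state(dist, rng, toggle)[0] for _ in range(n)) / n
        se = np.sqrt(0.25 / n)
        assert abs(freq - 0.5) < 3 * se


class TestTrajectories:
    def test_single_irreversible_jump(self):
        node = NodeDefinition(
            name="N",
            rate_up=parse_expression("1", "rate"),
            rate_down=parse_expression("0", "rate"),
        )
        net = build_network([node])
        compiled = CompiledNetwork(net)
        times = []
        for i in range(10000):
            rng = np.random.default_rng(i)
            traj = simulate_trajectory(compiled, (0,), 50.0, rng)
            assert len(traj.jumps) == 1
            assert traj.absorbed
            times.append(traj.jumps[0][0])
        # waiting time ~ Exponential(1): mean 1, SE 1/sqrt(n)
        assert abs(np.mean(times) - 1.0) < 3 / np.sqrt(len(times))

    def test_fixed_point_start_produces_no_jumps(self, toggle):
        compiled = CompiledNetwork(toggle)
        traj = simulate_trajectory(compiled, (1, 0), 10.0, np.random.default_rng(0))
        assert traj.jumps == [] and traj.absorbed

    def test_division_by_zero_rate_is_simulation_error(self):
        node = NodeDefinition(
            name="N",
            rate_up=parse_expression("$k / 0", "rate"),
            rate_down=parse_expression("0", "rate"),
        )
        net = build_network([node], params={"k": 1.0})
        compiled = CompiledNetwork(net)
        with pytest.raises(SimulationError, match="N"):
            simulate_trajectory(compiled, (0,), 10.0, np.random.default_rng(0))

    def test_negative_rate_is_simulation_error(self):
        node = NodeDefinition(
            name="N",
            rate_up=parse_expression("0 - 1", "rate"),
            rate_down=parse_expression("0", "rate"),
        )
        net = build_network([node])
        with pytest.raises(SimulationError, match="non-negative"):
            simulate_trajectory(CompiledNetwork(net), (0,), 10.0, np.random.default_rng(0))


class TestEnsemble:
    def test_two_state_ctmc_transient(self, single_node_21, start_off):
        """P(on at t) = (2/3)(1 - e^{-3t}); at t=10 effectively 2/3."""
        settings = SimulationSettings(
            initial=start_off, sample_count=10000, max_time=10.0, time_points=100, seed=5
        )
        result = run_ensemble(single_node_21, settings)
        assert abs(result.node_probabilities["N"].iloc[-1] - 2.0 / 3.0) < 0.02

    def test_symmetric_toggle_last_state_split(self, toggle):
        settings = SimulationSettings(
            initial=InitialStateDistribution.degenerate({"A": 0, "B": 0}),
            sample_count=10000,
            seed=8,
        )
        result = run_ensemble(toggle, settings)
        p_a = result.last_state_distribution.get("A", 0.0)
        p_b = result.last_state_distribution.get("B", 0.0)
        assert p_a + p_b == pytest.approx(1.0)
        se = np.sqrt(0.25 / settings.sample_count)
        assert abs(p_a - 0.5) < 3 * se

    def test_window_distributions_sum_to_one(self, toggle, fast_settings):
        result = run_ensemble(toggle, fast_settings)
        sums = result.state_probabilities.sum(axis=1).to_numpy()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert sum(result.last_state_distribution.values()) == pytest.approx(1.0)

    def test_node_marginals_consistent_with_state_table(self, toggle, fast_settings):
        result = run_ensemble(toggle, fast_settings)
        for name in result.outputs:
            cols = [
                c for c in result.state_probabilities.columns
                if name in (c.split(" -- ") if c != "<nil>" else [])
            ]
            expected = result.state_probabilities[cols].sum(axis=1)
            assert np.allclose(result.node_probabilities[name], expected)

    def test_determinism_bit_identical(self, toggle, fast_settings):
        a = run_ensemble(toggle, fast_settings)
        b = run_ensemble(toggle, fast_settings)
        assert a.state_probabilities.equals(b.state_probabilities)
        assert a.last_state_distribution == b.last_state_distribution
        assert a.fixed_points.equals(b.fixed_points)

    def test_ensemble_fixed_points_confirmed_exhaustively(self, toggle, fast_settings):
        result = run_ensemble(toggle, fast_settings)
        exhaustive = {
            "".join(map(str, s)) for s in fixed_points_exhaustive(toggle)
        }
        assert set(result.fixed_points["state"]) <= exhaustive
        # absorbed trajectories end where they are absorbed
        for _, row in result.fixed_points.iterrows():
            assert result.last_state_distribution[row["label"]] == pytest.approx(
                row["share"]
            )

    def test_output_limit_enforced(self):
        net = make_nk_network(16, 2, seed=0)
        settings = SimulationSettings(outputs=net.names)  # 16 > 15
        with pytest.raises(ValidationError, match="15"):
            run_ensemble(net, settings)

    def test_time_point_limit_enforced(self, toggle):
        with pytest.raises(ValidationError, match="100"):
            run_ensemble(toggle, SimulationSettings(time_points=101))


class TestExactTransient:
    def test_two_state_closed_form(self, single_node_21, start_off):
        probs = exact_transient(single_node_21, start_off, [10.0])
        assert probs[0, 1] == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_time_zero_returns_initial_distribution(self, toggle):
        dist = InitialStateDistribution(blocks=[(("A", "B"), [((1, 0), 0.3), ((0, 1), 0.7)])])
        probs = exact_transient(toggle, dist, [0.0])
        assert np.allclose(probs[0], initial_distribution_vector(dist, toggle))

    def test_repressilator_keeps_cycling(self, repressilator3):
        # no fixed points: distribution at large t has full support nowhere absorbed
        probs = exact_transient(repressilator3, InitialStateDistribution(), [50.0])
        assert fixed_points_exhaustive(repressilator3) == []
        assert probs[0].sum() == pytest.approx(1.0)
        assert (probs[0] > 0).all()

    def test_oracle_matches_simulation_on_concentrated_network(self):
        net = make_nk_network(6, 2, seed=0)
        settings = SimulationSettings(sample_count=10000, seed=100)
        result = run_ensemble(net, settings)
        sim = {
            c: result.state_probabilities[c].iloc[-1]
            for c in result.state_probabilities.columns
        }
        mid = (result.window_edges[-2] + result.window_edges[-1]) / 2
        exact = exact_transient(net, settings.initial, [mid])[0]
        tv = total_variation(sim, project_distribution(exact, net, result.outputs))
        assert tv <= 0.02


class TestFixedPoints:
    def test_toggle_switch(self, toggle):
        assert set(fixed_points_exhaustive(toggle)) == {(1, 0), (0, 1)}

    def test_repressilator_has_none(self, repressilator3):
        assert fixed_points_exhaustive(repressilator3) == []

    def test_all_constant_network(self):
        nodes = [
            NodeDefinition(name=n, logic=parse_expression("1"))
            for n in ("A", "B", "C")
        ]
        net = build_network(nodes)
        from boolmc.model import default_rates_from_logic

        assert fixed_points_exhaustive(default_rates_from_logic(net)) == [(1, 1, 1)]
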