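"""Tests for pathway counting, simulation, enumeration and map selection."""

import itertools

import numpy as np
import pytest

from viadapp.dapp import (
    DecisionSchedule,
    build_graph_from_pathways,
    count_pathways,
    enumerate_viable,
    es_trajectories,
    iter_viable_pathways,
    optimal_for_es,
    simulate_pathway,
    top_secured,
)
from viadapp.viability import ESBound, SatisfactoryDomain

from conftest import AffineToyModel

SCHED3 = DecisionSchedule(2020, 10, 5)   # 3 epochs, 2 intervals
SCHED4 = DecisionSchedule(2020, 15, 5)   # 4 epochs, 3 intervals
X0 = np.array([0.6, 0.6])


def _brute_force(model, x0, schedule, domain):
    """Exhaustive tally of viable pathways and per-edge traversals."""
    n = model.n_controls
    edge = np.zeros((schedule.n_intervals, n, n), dtype=int)
    total = 0
    viable_set = []
    for controls in itertools.product(range(n), repeat=schedule.epochs):
        result = simulate_pathway(model, x0, controls, schedule, domain)
        if result.viable:
            total += 1
            viable_set.append((controls, result.security))
            for k in range(schedule.n_intervals):
                edge[k, controls[k], controls[k + 1]] += 1
    return total, edge, viable_set


class TestCountPathways:
    def test_nine_arrangements_seven_epochs(self):
        assert count_pathways(9, DecisionSchedule(2020, 30, 5)) == 4_782_969

    def test_ten_actions_ten_reassessments(self):
        assert count_pathways(10, DecisionSchedule(0, 9, 1)) == 10_000_000_000

    def test_single_arrangement(self):
        assert count_pathways(1, DecisionSchedule(2020, 30, 5)) == 1

    def test_requires_at_least_one(self):
        with pytest.raises(ValueError):
            count_pathways(0, SCHED3)


class TestSimulatePathway:
    def test_vacuous_constraints_viable_with_full_security(
            self, toy_model, vacuous_domain):
        result = simulate_pathway(toy_model, X0, [0, 1, 2], SCHED3,
                                  vacuous_domain)
        assert result.viable
        assert result.security == pytest.approx(1.0)

    def test_initial_state_outside_domain_fails_at_start(
            self, toy_model, toy_domain):
        result = simulate_pathway(toy_model, np.array([0.1, 0.1]),
                                  [2, 2, 2], SCHED3, toy_domain)
        assert not result.viable
        assert result.first_violation_year == SCHED3.start_year

    def test_matches_hand_iteration(self, toy_model, toy_domain):
        result = simulate_pathway(toy_model, X0, [0, 1, 2], SCHED3,
                                  toy_domain)
        x = X0.copy()
        expected = [x.copy()]
        for u in (0, 1):
            for _ in range(5):
                x = 0.7 * x + 0.3 * toy_model.targets[u]
                expected.append(x.copy())
        np.testing.assert_allclose(result.states, np.asarray(expected))
        assert result.states.shape == (SCHED3.horizon + 1, 2)

    def test_wrong_length_rejected(self, toy_model, toy_domain):
        with pytest.raises(ValueError, match="length"):
            simulate_pathway(toy_model, X0, [0, 1], SCHED3, toy_domain)


class TestEnumerateViable:
    def test_matches_brute_force_3x4(self, toy_model, toy_domain):
        graph = enumerate_viable(toy_model, X0, SCHED4, toy_domain)
        total, edge, _ = _brute_force(toy_model, X0, SCHED4, toy_domain)
        assert graph.total_viable == total
        np.testing.assert_array_equal(graph.edge_counts, edge)

    def test_zero_viable_pathways(self, toy_model):
        domain = SatisfactoryDomain({
            "es_x": ESBound("service", 0.999),
            "es_y": ESBound("service", 0.999),
        })
        graph = enumerate_viable(toy_model, X0, SCHED4, domain)
        assert graph.total_viable == 0
        assert not graph.edge_counts.any()
        assert not graph.shades.any()

    def test_vacuous_constraints_forced_by_symmetry(
            self, toy_model, vacuous_domain):
        graph = enumerate_viable(toy_model, X0, SCHED3, vacuous_domain)
        n = toy_model.n_controls
        assert graph.total_viable == graph.total_pathways == n ** 3
        # every edge is crossed by the same forced share of pathways
        np.testing.assert_array_equal(
            graph.edge_counts, np.full((2, n, n), n ** 3 // n ** 2))

    def test_layer_conservation(self, toy_model, toy_domain):
        graph = enumerate_viable(toy_model, X0, SCHED4, toy_domain)
        np.testing.assert_array_equal(graph.layer_sums(),
                                      graph.total_viable)

    def test_iterated_pathways_match_brute_force(self, toy_model, toy_domain):
        got = list(iter_viable_pathways(toy_model, X0, SCHED4, toy_domain))
        _, _, want = _brute_force(toy_model, X0, SCHED4, toy_domain)
        assert [c for c, _ in got] == sorted(c for c, _ in want)
        want_sec = dict(want)
        for controls, sec in got:
            assert sec == pytest.approx(want_sec[controls], abs=1e-12)

    def test_pathway_cap_raises_instead_of_truncating(
            self, toy_model, vacuous_domain):
        with pytest.raises(RuntimeError, match="cap"):
            list(iter_viable_pathways(toy_model, X0, SCHED3, vacuous_domain,
                                      max_pathways=5))


class TestTopSecured:
    def test_fraction_of_hundred(self):
        pathways = [((i, i), 1.0 - i / 200.0) for i in range(100)]
        kept, _ = top_secured(pathways, 0.10, 100,
                              DecisionSchedule(2020, 5, 5))
        assert len(kept) == 10
        assert kept[0][1] == pytest.approx(1.0)

    def test_ties_broken_lexicographically(self):
        pathways = [((1, 1), 0.5), ((0, 1), 0.5), ((0, 0), 0.5), ((1, 0), 0.5)]
        kept, _ = top_secured(pathways, 0.5, 2, DecisionSchedule(2020, 5, 5))
        assert [c for c, _ in kept] == [(0, 0), (0, 1)]

    def test_matches_sort_then_cut_oracle(self, toy_model, toy_domain):
        pathways = list(iter_viable_pathways(toy_model, X0, SCHED3,
                                             toy_domain))
        kept, graph = top_secured(pathways, 0.25, toy_model.n_controls,
                                  SCHED3)
        ranked = sorted(pathways, key=lambda p: (-p[1], p[0]))
        assert kept == ranked[:int(np.ceil(0.25 * len(pathways)))]
        assert graph.total_viable == len(kept)

    def test_full_fraction_returns_whole_viable_set(self, toy_model,
                                                    toy_domain):
        pathways = list(iter_viable_pathways(toy_model, X0, SCHED3,
                                             toy_domain))
        kept, _ = top_secured(pathways, 1.0, toy_model.n_controls, SCHED3)
        assert sorted(kept) == sorted(pathways)

    def test_empty_viable_set_is_not_an_error(self):
        kept, graph = top_secured([], 0.1, 3, SCHED3)
        assert kept == [] and graph.total_viable == 0


class TestOptimalForES:
    def test_single_viable_pathway_wins_every_es(self, toy_model, toy_domain):
        result = simulate_pathway(toy_model, X0, [2, 2, 2], SCHED3,
                                  toy_domain)
        for name in toy_model.es_names:
            assert optimal_for_es([result], name, "maximize") == [result]

    def test_dominated_trajectory_loses(self, toy_model, toy_domain):
        hi = simulate_pathway(toy_model, X0, [0, 0, 0], SCHED3, toy_domain)
        lo = simulate_pathway(toy_model, X0, [1, 1, 1], SCHED3, toy_domain)
        # control 0 drives es_x toward 0.9, control 1 toward 0.3
        best = optimal_for_es([hi, lo], "es_x", "maximize")
        assert best == [hi]
        assert optimal_for_es([hi, lo], "es_x", "minimize") == [lo]

    def test_matches_exhaustive_argmax(self, toy_model, toy_domain):
        results = [
            simulate_pathway(toy_model, X0, c, SCHED3, toy_domain)
            for c in itertools.product(range(3), repeat=3)
        ]
        best = optimal_for_es(results, "es_y", "maximize")
        viable = [r for r in results if r.viable]
        values = [r.es_levels[:, 1].mean() for r in viable]
        top = max(values)
        want = [r for r, v in zip(viable, values) if abs(v - top) <= 1e-12]
        assert best == want

    def test_unknown_es_rejected(self, toy_model, toy_domain):
        result = simulate_pathway(toy_model, X0, [0, 0, 0], SCHED3,
                                  toy_domain)
        with pytest.raises(KeyError):
            optimal_for_es([result], "nope", "maximize")


class TestESTrajectories:
    def test_constant_state_model_gives_constant_rows(self, vacuous_domain):
        model = AffineToyModel(targets=((0.5, 0.5),) * 3, contraction=1.0)
        table = es_trajectories(model, np.array([0.5, 0.5]), [0, 1, 2],
                                SCHED3)
        assert (table.nunique() == 1).all()

    def test_matches_hand_iteration(self, toy_model):
        table = es_trajectories(toy_model, X0, [1, 0, 2], SCHED3)
        x = X0.copy()
        rows = [x.copy()]
        for u in (1, 0):
            for _ in range(5):
                x = 0.7 * x + 0.3 * toy_model.targets[u]
                rows.append(x.copy())
        np.testing.assert_allclose(table.to_numpy(), np.asarray(rows))

    def test_row_count_is_horizon_plus_one(self, toy_model):
        table = es_trajectories(toy_model, X0, [0] * SCHED4.epochs, SCHED4)
        assert len(table) == SCHED4.horizon + 1


class TestGraphExport:
    def test_graphml_and_dot_written(self, tmp_path, toy_model, toy_domain):
        graph = enumerate_viable(toy_model, X0, SCHED3, toy_domain,
                                 labels=("a", "b", "c"))
        graph.write_graphml(tmp_path / "g.graphml")
        graph.write_dot(tmp_path / "g.dot")
        text = (tmp_path / "g.dot").read_text()
        assert "traversals=" in text and "shade=" in text
        import networkx as nx

        g = nx.read_graphml(tmp_path / "g.graphml")
        assert sum(d["traversals"] for _, _, d in g.edges(data=True)) \
            == graph.edge_counts.sum()
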