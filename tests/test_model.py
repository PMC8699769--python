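"""Propagation semantics, truth-table scoring, and the annealing fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mi_remodel.model import (
    ModelEnsembleResults,
    Rule,
    SignedNetworkModel,
    TruthTable,
    fit_monte_carlo,
    propagate,
    score_solution,
    squash,
    topology_prior,
)
from mi_remodel.network import SignedNetwork


class TestPropagate:
    def test_zero_stimulus_gives_all_zero_state(self, mixed_net):
        # clamping a node at 0 propagates nothing
        state = propagate(mixed_net, {"A": 0.0})
        assert all(v == 0.0 for v in state.values())

    def test_single_activating_edge_closed_form(self):
        net = SignedNetwork.from_edges([("A", "B", 1)])
        state = propagate(net, {"A": 1.0})
        assert state["B"] == pytest.approx(np.tanh(1.0), abs=1e-9)

    def test_single_inhibiting_edge_flips_sign(self):
        net = SignedNetwork.from_edges([("A", "B", -1)])
        state = propagate(net, {"A": 1.0})
        assert state["B"] == pytest.approx(-np.tanh(1.0), abs=1e-9)

    def test_unknown_stimulus_node_raises(self, chain_net):
        with pytest.raises(KeyError):
            propagate(chain_net, {"nope": 1.0})

    @settings(deadline=None, max_examples=40)
    @given(
        st.integers(2, 8),
        st.lists(st.sampled_from([1, -1]), min_size=7, max_size=7),
        st.lists(st.floats(0.05, 1.0), min_size=7, max_size=7),
    )
    def test_dag_chain_equals_nested_squash_composition(self, length, signs, weights):
        # on an acyclic chain the fixed point is the explicit nested
        # composition squash(w_k * s_k * squash(... squash(w_1 * s_1)))
        signs, weights = signs[: length - 1], weights[: length - 1]
        nodes = [f"N{i}" for i in range(length)]
        edges = [
            (nodes[i], nodes[i + 1], signs[i]) for i in range(length - 1)
        ]
        net = SignedNetwork.from_edges(edges)
        w = np.array(
            [dict(zip([(e[0], e[1]) for e in edges], weights))[(u, v)]
             for u, v, _ in net.edges]
        )
        state = propagate(net, {nodes[0]: 1.0}, weights=w, tol=1e-12)
        expected = 1.0
        for s, wt in zip(signs, weights):
            expected = float(squash(s * wt * expected))
        assert state[nodes[-1]] == pytest.approx(expected, abs=1e-9)


class TestScoreSolution:
    def test_satisfiable_rule_scores_one(self, chain_net, single_rule_table):
        assert score_solution(chain_net, chain_net.default_weights(), single_rule_table) == 1.0

    def test_zero_activity_counts_as_unsatisfied(self, chain_net):
        table = TruthTable([Rule(stimulus={"A": 1.0}, response={"C": 1})])
        # zero weight on B->C never moves C off zero
        weights = np.array(
            [0.0 if (u, v) == ("B", "C") else 1.0 for u, v, _ in chain_net.edges]
        )
        assert score_solution(chain_net, weights, table) == 0.0

    def test_half_satisfied_with_equal_rule_weights(self, chain_net):
        table = TruthTable(
            [
                Rule(stimulus={"A": 1.0}, response={"C": 1}),
                Rule(stimulus={"A": 1.0}, response={"C": -1}),
            ]
        )
        assert score_solution(chain_net, chain_net.default_weights(), table) == 0.5

    def test_empty_truth_table_rejected(self, chain_net):
        with pytest.raises(ValueError):
            score_solution(chain_net, chain_net.default_weights(), TruthTable([]))

    def test_upweighting_a_violated_rule_never_raises_score(self, chain_net):
        satisfied = Rule(stimulus={"A": 1.0}, response={"C": 1})
        w = chain_net.default_weights()
        for factor in (2.0, 5.0, 10.0):
            violated = Rule(
                stimulus={"A": 1.0}, response={"C": -1}, weight=factor
            )
            base = score_solution(
                chain_net,
                w,
                TruthTable([satisfied, Rule(stimulus={"A": 1.0}, response={"C": -1})]),
            )
            heavier = score_solution(chain_net, w, TruthTable([satisfied, violated]))
            assert heavier <= base + 1e-12


class TestTopologyPrior:
    def test_fan_in_normalisation(self, mixed_net):
        prior = topology_prior(mixed_net)
        frame = mixed_net.edge_frame(prior)
        # B and C have indegree 1; D has indegree 2
        by_edge = {(r.src, r.dst): r.weight for r in frame.itertuples()}
        assert by_edge[("A", "B")] == 1.0
        assert by_edge[("B", "D")] == 0.5
        assert by_edge[("C", "D")] == 0.5

    def test_total_incoming_weight_is_one_per_reached_node(self):
        from mi_remodel.synthetic import generate_network

        net = generate_network(60, 3, 0.3, seed=8)
        prior = topology_prior(net)
        frame = net.edge_frame(prior)
        sums = frame.groupby("dst")["weight"].sum()
        assert np.allclose(sums.to_numpy(), 1.0)


class TestFit:
    def test_converges_to_perfect_accuracy_on_satisfiable_chain(
        self, chain_net, single_rule_table
    ):
        results = fit_monte_carlo(
            chain_net, single_rule_table, n_solutions=2, n_steps=200, seed=0
        )
        assert results.best_accuracy == 1.0

    def test_seed_determinism(self, chain_net, single_rule_table):
        a = fit_monte_carlo(chain_net, single_rule_table, n_solutions=3, n_steps=50, seed=9)
        b = fit_monte_carlo(chain_net, single_rule_table, n_solutions=3, n_steps=50, seed=9)
        assert np.array_equal(a.solutions, b.solutions)
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_zero_steps_returns_jittered_priors(self, chain_net, single_rule_table):
        model = SignedNetworkModel(chain_net, single_rule_table)
        results = model.fit(n_solutions=3, n_steps=0, seed=1, jitter_sd=0.0)
        prior = model.topology_prior()
        assert np.allclose(results.solutions, prior[None, :])

    def test_best_accuracy_non_decreasing_in_steps(self):
        from mi_remodel.synthetic import generate_network, generate_truth_table

        net = generate_network(30, 2, 0.3, seed=6)
        table = generate_truth_table(net, n_rules=4, seed=6)
        accs = [
            fit_monte_carlo(net, table, n_solutions=1, n_steps=n, seed=5).best_accuracy
            for n in (0, 100, 400)
        ]
        assert accs == sorted(accs)

    def test_unsatisfiable_table_returns_best_effort(self, chain_net):
        table = TruthTable(
            [
                Rule(stimulus={"A": 1.0}, response={"C": 1}),
                Rule(stimulus={"A": 1.0}, response={"C": -1}),
            ]
        )
        results = fit_monte_carlo(chain_net, table, n_solutions=2, n_steps=50, seed=0)
        assert results.best_accuracy < 1.0

    def test_results_summary_mentions_best_accuracy(self, chain_net, single_rule_table):
        results = fit_monte_carlo(chain_net, single_rule_table, n_solutions=2, n_steps=20, seed=2)
        assert "best accuracy" in results.summary()

    def test_empty_ensemble_rejected(self, chain_net, single_rule_table):
        model = SignedNetworkModel(chain_net, single_rule_table)
        with pytest.raises(ValueError):
            ModelEnsembleResults(model, np.empty((0, chain_net.n_edges)), np.empty(0))
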