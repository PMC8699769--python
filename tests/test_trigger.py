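"""Explain graphs, greedy source selection, and mechanism sampling."""

import networkx as nx
import numpy as np
import pytest

from mi_remodel.expression import ProteinRestriction
from mi_remodel.model import Rule, TruthTable, fit_monte_carlo
from mi_remodel.network import SignedNetwork
from mi_remodel.relate import EffectorSignature
from mi_remodel.synthetic import (
    generate_network,
    plant_ground_truth,
    restrictions_from_truth,
)
from mi_remodel.trigger import (
    build_explain_graph,
    common_sources,
    intersect_source_sets,
    max_explainable_fraction,
    sample_mechanism,
    select_sources,
    triggering_report,
)


def _restrictions(directions: dict[str, int], cohort: str = "C6"):
    return [
        ProteinRestriction(protein=p, cohort=cohort, direction=d)
        for p, d in directions.items()
    ]


def exhaustive_explain_arcs(net, directions, max_len):
    """Oracle: enumerate every simple path and check composed signs."""
    sign_of = {(u, v): s for u, v, s in net.edges}
    arcs = set()
    for u in directions:
        for v in directions:
            if u == v:
                continue
            for path in nx.all_simple_paths(net.graph, u, v, cutoff=max_len):
                composed = np.prod([sign_of[e] for e in zip(path, path[1:])])
                if composed == directions[u] * directions[v]:
                    arcs.add((u, v))
                    break
    return arcs


class TestBuildExplainGraph:
    def test_activating_chain_all_downstream_arcs(self, chain_net):
        g = build_explain_graph(chain_net, _restrictions({"A": 1, "B": 1, "C": 1}), 3)
        assert set(g.edges) == {("A", "B"), ("A", "C"), ("B", "C")}

    def test_sign_inconsistent_pair_has_no_arc(self):
        net = SignedNetwork.from_edges([("A", "B", -1)])
        g = build_explain_graph(net, _restrictions({"A": 1, "B": 1}), 3)
        assert set(g.edges) == set()

    def test_inhibition_explains_opposite_direction(self):
        net = SignedNetwork.from_edges([("A", "B", -1)])
        g = build_explain_graph(net, _restrictions({"A": 1, "B": -1}), 3)
        assert set(g.edges) == {("A", "B")}

    def test_single_node_gives_empty_arcs(self, chain_net):
        g = build_explain_graph(chain_net, _restrictions({"A": 1}), 2)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_path_length_cap_respected(self, chain_net):
        g = build_explain_graph(chain_net, _restrictions({"A": 1, "C": 1}), 1)
        assert ("A", "C") not in g.edges

    def test_missing_protein_dropped_with_warning(self, chain_net):
        with pytest.warns(UserWarning, match="absent"):
            g = build_explain_graph(
                chain_net, _restrictions({"A": 1, "GHOST": 1}), 2
            )
        assert set(g.nodes) == {"A"}

    def test_matches_exhaustive_path_oracle_on_random_network(self):
        net = generate_network(25, 2, 0.4, seed=3)
        rng = np.random.default_rng(3)
        picks = rng.choice(net.nodes, size=10, replace=False)
        directions = {p: int(rng.choice([-1, 1])) for p in picks}
        g = build_explain_graph(net, _restrictions(directions), 3)
        assert set(g.edges) == exhaustive_explain_arcs(net, directions, 3)


class TestExplainableAndSources:
    def test_chain_fraction_and_single_source(self, chain_net):
        g = build_explain_graph(chain_net, _restrictions({"A": 1, "B": 1, "C": 1}), 3)
        assert max_explainable_fraction(g) == pytest.approx(200.0 / 3)
        sources, pct = select_sources(g)
        assert sources == ["A"]
        assert pct == 100.0

    def test_isolated_nodes_zero_percent(self):
        net = SignedNetwork.from_edges([("A", "X", 1)])
        g = build_explain_graph(net, _restrictions({"A": 1}), 2)
        assert max_explainable_fraction(g) == 0.0

    def test_two_disconnected_chains_need_two_sources(self):
        net = SignedNetwork.from_edges([("A", "B", 1), ("C", "D", 1)])
        g = build_explain_graph(net, _restrictions({"A": 1, "B": 1, "C": 1, "D": 1}), 2)
        sources, pct = select_sources(g)
        assert len(sources) == 2
        assert pct == 100.0

    def test_greedy_never_selects_zero_gain_and_beats_singletons(self):
        net = generate_network(60, 1, 0.3, seed=2)
        truth = plant_ground_truth(net, n_sources=2, depth=3, seed=2)
        g = build_explain_graph(net, restrictions_from_truth(truth, "C6"), 3)
        sources, pct = select_sources(g)
        explainable = {v for v, d in g.in_degree() if d >= 1}
        for s in sources:
            assert len(set(g.successors(s)) & explainable) > 0
        for node in g.nodes:
            single_cover = len(set(g.successors(node)) & explainable)
            assert pct >= 100.0 * single_cover / max(len(explainable), 1)

    def test_planted_source_recovery_noiseless(self):
        # identifiable planting: sparse tree-like skeleton, sources far
        # enough apart that their cones cannot explain each other
        net = generate_network(200, 1, 0.3, seed=0)
        truth = plant_ground_truth(
            net, n_sources=3, depth=3, seed=0, min_separation=6
        )
        g = build_explain_graph(net, restrictions_from_truth(truth, "C6"), 3)
        sources, pct = select_sources(g)
        assert truth.planted_sources["C6"] <= set(sources)
        assert pct == 100.0

    def test_report_layout_matches_four_row_convention(self, chain_net):
        report = triggering_report(
            chain_net, _restrictions({"A": 1, "B": 1, "C": 1}), "C6"
        )
        frame = report.to_frame()
        assert list(frame.columns) == ["metric", "C6"]
        assert len(frame) == 4
        # the printed layout: available count, explainable %, source count,
        # explained % (e.g. 1182 / 49% / 16 / 92% in a full-scale study)
        assert frame.iloc[0, 1] == 3
        assert frame.iloc[2, 1] == 1


class TestIntersections:
    def test_exact_combination_partition(self):
        combos = intersect_source_sets(
            {"C6": {"A", "B"}, "C30": {"B", "C"}, "C45": {"B"}}
        )
        assert combos[("C30", "C45", "C6")] == {"B"}
        assert combos[("C6",)] == {"A"}
        assert combos[("C30",)] == {"C"}
        assert common_sources({"C6": {"A", "B"}, "C30": {"B", "C"}, "C45": {"B"}}) == {"B"}

    def test_disjoint_sets_have_empty_common(self):
        assert common_sources({"C6": {"A"}, "C30": {"B"}}) == set()

    def test_needs_two_cohorts(self):
        with pytest.raises(ValueError):
            intersect_source_sets({"C6": {"A"}})


@pytest.fixture(scope="module")
def fitted_chain():
    net = SignedNetwork.from_edges([("A", "B", 1), ("B", "C", 1)])
    table = TruthTable([Rule(stimulus={"A": 1.0}, response={"C": 1})])
    ensemble = fit_monte_carlo(net, table, n_solutions=2, n_steps=50, seed=1)
    return net, ensemble


class TestSampleMechanism:

    def test_unique_path_has_frequency_one(self, fitted_chain):
        net, ensemble = fitted_chain
        sig = EffectorSignature("s", {"C": 1})
        mech = sample_mechanism(ensemble, net, ["A"], sig, n_samples=100, seed=0)
        assert mech.edges[("A", "B")]["frequency"] == 1.0
        assert mech.edges[("B", "C")]["frequency"] == 1.0
        assert mech.nodes["A"]["role"] == "source"
        assert mech.nodes["B"]["role"] == "intermediate"
        assert mech.nodes["C"]["role"] == "effector"

    def test_parallel_equal_paths_split_evenly(self):
        net = SignedNetwork.from_edges(
            [("A", "B1", 1), ("A", "B2", 1), ("B1", "C", 1), ("B2", "C", 1)]
        )
        table = TruthTable([Rule(stimulus={"A": 1.0}, response={"C": 1})])
        ensemble = fit_monte_carlo(net, table, n_solutions=1, n_steps=0, seed=0)
        # equal weights by construction: override with the unit ensemble
        ensemble.solutions[:] = 1.0
        sig = EffectorSignature("s", {"C": 1})
        mech = sample_mechanism(ensemble, net, ["A"], sig, n_samples=10000, seed=3)
        freq = mech.edges[("A", "B1")]["frequency"]
        assert abs(freq - 0.5) < 0.02  # ~4 binomial SDs

    def test_no_path_warns_and_returns_empty(self, fitted_chain):
        net, ensemble = fitted_chain
        sig = EffectorSignature("s", {"A": 1})  # nothing reaches A
        with pytest.warns(UserWarning, match="no path"):
            mech = sample_mechanism(ensemble, net, ["C"], sig, n_samples=10, seed=0)
        assert mech.number_of_edges() == 0
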