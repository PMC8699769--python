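"""Shared fixtures: small hand-built networks and a synthetic study bundle."""

from __future__ import annotations

import pytest

from mi_remodel.model import Rule, TruthTable, fit_monte_carlo
from mi_remodel.network import SignedNetwork
from mi_remodel.synthetic import (
    generate_network,
    generate_truth_table,
    make_signature,
    plant_ground_truth,
)


@pytest.fixture(scope="session")
def chain_net() -> SignedNetwork:
    """A -> B -> C chain, both edges activating."""
    return SignedNetwork.from_edges([("A", "B", 1), ("B", "C", 1)])


@pytest.fixture(scope="session")
def mixed_net() -> SignedNetwork:
    """Small branching network with one inhibitory edge."""
    return SignedNetwork.from_edges(
        [("A", "B", 1), ("A", "C", -1), ("B", "D", 1), ("C", "D", 1)]
    )


@pytest.fixture(scope="session")
def study():
    """A fitted synthetic study: network, planted truth, signature, ensemble.

    Session-scoped because the annealing fit is the expensive part; tests
    must not mutate it.
    """
    net = generate_network(120, 2, 0.3, seed=4)
    truth = plant_ground_truth(net, n_sources=3, depth=3, seed=4)
    table = generate_truth_table(net, n_rules=6, seed=4)
    ensemble = fit_monte_carlo(net, table, n_solutions=4, n_steps=300, seed=4)
    signature = make_signature(truth, "C6", n_effectors=12, seed=4)
    return {
        "net": net,
        "truth": truth,
        "truth_table": table,
        "ensemble": ensemble,
        "signature": signature,
    }


@pytest.fixture()
def single_rule_table() -> TruthTable:
    return TruthTable([Rule(stimulus={"A": 1.0}, response={"C": 1})])
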