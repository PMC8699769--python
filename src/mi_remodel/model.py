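"""Signed-network signal propagation and truth-table constrained fitting.

The mechanistic model treats each protein as a node carrying an activity
in [-1, +1] (0 = unperturbed). A stimulus clamps a subset of nodes to
fixed activities; the perturbation spreads over the signed, weighted
edges by synchronous iteration

    x_v  <-  tanh( sum over edges (u -> v) of sign * weight * x_u )

until a fixed point (or an iteration cap) is reached. A model — a weight
assignment on the edges — is scored against a truth table of known
stimulus -> response rules: the weighted fraction of response proteins
whose propagated sign matches the expected sign. Because the weight
space is large and the score is non-smooth, fitting draws an ensemble of
solutions by simulated annealing, each chain seeded from a topology
prior (fan-in normalised weights) plus jitter.

The entry point is :class:`SignedNetworkModel`; ``fit`` returns a
:class:`ModelEnsembleResults` holding the solutions, their truth-table
accuracies, and summary/plotting helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .network import SignedNetwork

__all__ = [
    "Rule",
    "TruthTable",
    "squash",
    "propagate",
    "score_solution",
    "topology_prior",
    "fit_monte_carlo",
    "SignedNetworkModel",
    "ModelEnsembleResults",
]


def squash(x):
    """Bounded, odd, monotone activation used by the propagation map."""
    return np.tanh(x)


@dataclass(frozen=True)
class Rule:
    """One truth-table row: clamp *stimulus*, expect *response* signs."""

    stimulus: Mapping[str, float]
    response: Mapping[str, int]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.stimulus or not self.response:
            raise ValueError("rule needs a non-empty stimulus and response")
        if self.weight <= 0:
            raise ValueError("rule weight must be positive")
        if any(s not in (1, -1) for s in self.response.values()):
            raise ValueError("expected response signs must be +1 or -1")


@dataclass
class TruthTable:
    """Stimulus -> response rules every fitted model should satisfy."""

    rules: list[Rule] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rules)

    def validate_against(self, net: SignedNetwork) -> None:
        for rule in self.rules:
            for node in list(rule.stimulus) + list(rule.response):
                if node not in net:
                    raise KeyError(f"truth-table node {node!r} not in network")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "stimulus": dict(r.stimulus),
                "response": dict(r.response),
                "weight": r.weight,
            }
            for r in self.rules
        ]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            [
                Rule(
                    stimulus={k: float(v) for k, v in r["stimulus"].items()},
                    response={k: int(v) for k, v in r["response"].items()},
                    weight=float(r.get("weight", 1.0)),
                )
                for r in payload
            ]
        )


class _PropagationEngine:
    """Cached sparse adjacency for fast repeated propagation on one network.

    The CSR sparsity pattern is fixed by the network; only the data
    vector (sign * weight per edge) changes between solutions, so weight
    updates are O(n_edges) with no re-allocation.
    """

    def __init__(self, net: SignedNetwork):
        src, dst, sign = net.edge_arrays
        n = net.n_nodes
        if len(src):
            coo = sparse.coo_matrix(
                (np.arange(1.0, len(src) + 1.0), (dst, src)), shape=(n, n)
            )
            csr = coo.tocsr()
            self._perm = csr.data.astype(np.intp) - 1
            csr.data = csr.data.copy()
            self._A = csr
        else:
            self._A = sparse.csr_matrix((n, n))
            self._perm = np.array([], dtype=np.intp)
        self._sign = sign
        self._n = n

    def run_batch(
        self,
        weights: np.ndarray,
        clamp_rows: np.ndarray,
        clamp_cols: np.ndarray,
        clamp_vals: np.ndarray,
        n_cols: int,
        max_iter: int,
        tol: float,
    ) -> np.ndarray:
        """Iterate several independent stimuli (columns) simultaneously.

        Column trajectories are independent, so batching changes nothing
        numerically; converged columns are stable under further sweeps.
        Columns still oscillating at *max_iter* are replaced by the
        time-average of their last 10 states.
        """
        A = self._A
        A.data = (self._sign * weights)[self._perm]
        x = np.zeros((self._n, n_cols))
        x[clamp_rows, clamp_cols] = clamp_vals
        tail: list[np.ndarray] = []
        for _ in range(max_iter):
            x_new = np.tanh(A.dot(x))
            x_new[clamp_rows, clamp_cols] = clamp_vals
            delta = float(np.max(np.abs(x_new - x))) if x.size else 0.0
            x = x_new
            if delta < tol:
                return x
            tail.append(x)
            if len(tail) > 10:
                tail.pop(0)
        x = np.mean(tail, axis=0)
        x[clamp_rows, clamp_cols] = clamp_vals
        return x

    def run(
        self,
        weights: np.ndarray,
        clamp_idx: np.ndarray,
        clamp_val: np.ndarray,
        max_iter: int,
        tol: float,
    ) -> np.ndarray:
        zeros = np.zeros(len(clamp_idx), dtype=np.intp)
        return self.run_batch(
            weights, clamp_idx, zeros, clamp_val, 1, max_iter, tol
        )[:, 0]


def _engine(net: SignedNetwork) -> _PropagationEngine:
    engine = getattr(net, "_propagation_engine", None)
    if engine is None:
        engine = _PropagationEngine(net)
        net._propagation_engine = engine
    return engine


def _check_weights(net: SignedNetwork, weights: np.ndarray | None) -> np.ndarray:
    w = net.default_weights() if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (net.n_edges,):
        raise ValueError("weights must cover every edge")
    return w


def propagate(
    net: SignedNetwork,
    stimulus: Mapping[str, float],
    weights: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> dict[str, float]:
    """Spread a clamped stimulus through the signed network.

    Stimulus nodes are held fixed at their given activity; all other
    nodes update synchronously under the squashed weighted-sum map. If
    the iteration has not converged (max state change < *tol*) after
    *max_iter* sweeps — which happens on oscillating cycles — the
    time-average of the last 10 states is returned instead.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    w = _check_weights(net, weights)
    clamp_idx = np.array([net.node_index(n) for n in stimulus], dtype=np.intp)
    clamp_val = np.array([float(v) for v in stimulus.values()], dtype=float)
    x = _engine(net).run(w, clamp_idx, clamp_val, max_iter, tol)
    return {node: float(x[i]) for i, node in enumerate(net.nodes)}


class _CompiledRules:
    """Flattened index-array form of a truth table for fast batch scoring."""

    def __init__(self, net: SignedNetwork, truth_table: TruthTable):
        clamp_rows, clamp_cols, clamp_vals = [], [], []
        resp_rows, resp_cols, resp_signs, resp_rule = [], [], [], []
        self.rule_weights = np.array([r.weight for r in truth_table.rules])
        self.resp_counts = np.array(
            [len(r.response) for r in truth_table.rules], dtype=float
        )
        for col, rule in enumerate(truth_table.rules):
            for node, val in rule.stimulus.items():
                clamp_rows.append(net.node_index(node))
                clamp_cols.append(col)
                clamp_vals.append(float(val))
            for node, sign in rule.response.items():
                resp_rows.append(net.node_index(node))
                resp_cols.append(col)
                resp_signs.append(float(sign))
                resp_rule.append(col)
        self.n_rules = len(truth_table.rules)
        self.clamp_rows = np.array(clamp_rows, dtype=np.intp)
        self.clamp_cols = np.array(clamp_cols, dtype=np.intp)
        self.clamp_vals = np.array(clamp_vals)
        self.resp_rows = np.array(resp_rows, dtype=np.intp)
        self.resp_cols = np.array(resp_cols, dtype=np.intp)
        self.resp_signs = np.array(resp_signs)
        self.resp_rule = np.array(resp_rule, dtype=np.intp)


def _score_compiled(
    engine: _PropagationEngine,
    compiled: _CompiledRules,
    weights: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> float:
    x = engine.run_batch(
        weights,
        compiled.clamp_rows,
        compiled.clamp_cols,
        compiled.clamp_vals,
        compiled.n_rules,
        max_iter,
        tol,
    )
    satisfied = x[compiled.resp_rows, compiled.resp_cols] * compiled.resp_signs > 0
    hits = np.bincount(
        compiled.resp_rule, weights=satisfied.astype(float), minlength=compiled.n_rules
    )
    per_rule = hits / compiled.resp_counts
    return float(
        np.sum(compiled.rule_weights * per_rule) / np.sum(compiled.rule_weights)
    )


def score_solution(
    net: SignedNetwork, weights: np.ndarray, truth_table: TruthTable
) -> float:
    """Weighted fraction of truth-table response entries satisfied.

    A response entry counts as satisfied only when the propagated
    activity is strictly on the expected side of zero; an exactly zero
    (unreached) node never satisfies a +/-1 expectation.
    """
    if len(truth_table) == 0:
        raise ValueError("empty truth table")
    truth_table.validate_against(net)
    w = _check_weights(net, weights)
    return _score_compiled(_engine(net), _CompiledRules(net, truth_table), w)


def topology_prior(net: SignedNetwork) -> np.ndarray:
    """Fan-in normalised initial weights: edge (u -> v) gets 1/indegree(v)."""
    _, dst, _ = net.edge_arrays
    indegree = np.bincount(dst, minlength=net.n_nodes)
    return 1.0 / indegree[dst]


class SignedNetworkModel:
    """Signed propagation model of a protein network under truth-table rules.

    Parameters
    ----------
    net:
        The signed interaction network (model skeleton).
    truth_table:
        The stimulus -> response rules the fitted weights must satisfy.
    """

    def __init__(self, net: SignedNetwork, truth_table: TruthTable):
        truth_table.validate_against(net)
        if len(truth_table) == 0:
            raise ValueError("empty truth table")
        self.net = net
        self.truth_table = truth_table
        self._compiled = _CompiledRules(net, truth_table)

    def topology_prior(self) -> np.ndarray:
        return topology_prior(self.net)

    def score(self, weights: np.ndarray) -> float:
        return _score_compiled(
            _engine(self.net), self._compiled, _check_weights(self.net, weights)
        )

    def propagate(self, stimulus: Mapping[str, float], weights=None, **kw):
        return propagate(self.net, stimulus, weights=weights, **kw)

    def fit(
        self,
        n_solutions: int = 10,
        n_steps: int = 2000,
        seed: int = 0,
        t0: float = 1.0,
        cooling: float = 0.995,
        proposal_sd: float = 0.1,
        jitter_sd: float = 0.05,
    ) -> "ModelEnsembleResults":
        """Draw an ensemble of weight solutions by simulated annealing.

        Each of the *n_solutions* chains starts from the topology prior
        plus Gaussian jitter, proposes single-edge Gaussian perturbations
        (sd *proposal_sd*, clipped to [0, 1]) and accepts by the
        Metropolis rule under a geometric temperature schedule
        ``T_k = t0 * cooling**k``. Chains keep their best-so-far weights;
        a chain that reaches accuracy 1.0 stops early. With
        ``n_steps=0`` the ensemble is the jittered priors themselves.
        Deterministic for a fixed seed.
        """
        if n_solutions < 1:
            raise ValueError("n_solutions must be >= 1")
        if n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        prior = self.topology_prior()
        n_edges = self.net.n_edges
        children = np.random.SeedSequence(seed).spawn(n_solutions)
        solutions = np.empty((n_solutions, n_edges))
        accuracies = np.empty(n_solutions)
        for c, child_seed in enumerate(children):
            rng = np.random.default_rng(child_seed)
            w = np.clip(prior + rng.normal(0.0, jitter_sd, n_edges), 0.0, 1.0)
            score = self.score(w)
            best_w, best_score = w.copy(), score
            for k in range(n_steps):
                if best_score >= 1.0:
                    break
                temperature = t0 * cooling**k
                i = rng.integers(n_edges)
                proposal = w.copy()
                proposal[i] = np.clip(
                    proposal[i] + rng.normal(0.0, proposal_sd), 0.0, 1.0
                )
                new_score = self.score(proposal)
                delta = new_score - score
                if delta >= 0 or rng.random() < np.exp(delta / temperature):
                    w, score = proposal, new_score
                    if score > best_score:
                        best_w, best_score = w.copy(), score
            solutions[c] = best_w
            accuracies[c] = best_score
        return ModelEnsembleResults(self, solutions, accuracies)


class ModelEnsembleResults:
    """Fitted weight ensemble with per-solution truth-table accuracies."""

    def __init__(
        self,
        model: SignedNetworkModel,
        solutions: np.ndarray,
        accuracies: np.ndarray,
    ):
        solutions = np.asarray(solutions, dtype=float)
        accuracies = np.asarray(accuracies, dtype=float)
        if solutions.ndim != 2 or len(solutions) != len(accuracies):
            raise ValueError("solutions and accuracies must align")
        if len(solutions) == 0:
            raise ValueError("empty ensemble")
        self.model = model
        self.net = model.net
        self.solutions = solutions
        self.accuracies = accuracies

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)

    @property
    def best_index(self) -> int:
        # ties broken by earlier chain index (argmax returns first maximum)
        return int(np.argmax(self.accuracies))

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracies[self.best_index])

    @property
    def best_weights(self) -> np.ndarray:
        return self.solutions[self.best_index]

    def mean_weights(self) -> np.ndarray:
        """Ensemble-averaged edge weights (used by mechanism sampling)."""
        return self.solutions.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        edges = self.net.edges
        rows = [
            (s, u, v, sign, self.solutions[s, e])
            for s in range(self.n_solutions)
            for e, (u, v, sign) in enumerate(edges)
        ]
        return pd.DataFrame(rows, columns=["solution", "src", "dst", "sign", "weight"])

    def accuracy_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"solution": np.arange(self.n_solutions), "accuracy": self.accuracies}
        )

    def summary(self) -> str:
        lines = [
            "Signed network model ensemble",
            "=============================",
            f"nodes: {self.net.n_nodes}    edges: {self.net.n_edges}",
            f"truth-table rules: {len(self.model.truth_table)}",
            f"solutions: {self.n_solutions}",
            f"best accuracy: {self.best_accuracy:.4f} (solution {self.best_index})",
            f"mean accuracy: {self.accuracies.mean():.4f}",
            f"min accuracy:  {self.accuracies.min():.4f}",
        ]
        return "\n".join(lines)

    def plot_accuracies(self, ax=None):
        """Bar plot of per-solution truth-table accuracies."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(np.arange(self.n_solutions), self.accuracies)
        ax.set_xlabel("solution")
        ax.set_ylabel("truth-table accuracy")
        ax.set_ylim(0, 1.05)
        return ax


def fit_monte_carlo(
    net: SignedNetwork,
    truth_table: TruthTable,
    n_solutions: int = 10,
    n_steps: int = 2000,
    seed: int = 0,
    **kwargs,
) -> ModelEnsembleResults:
    """Functional wrapper around :meth:`SignedNetworkModel.fit`."""
    return SignedNetworkModel(net, truth_table).fit(
        n_solutions=n_solutions, n_steps=n_steps, seed=seed, **kwargs
    )
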