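"""Seeded synthetic inputs with planted ground truth.

Every downstream stage of the pipeline is exercised on data generated
here: a scale-free signed network, per-cohort differential expression
driven by planted source proteins, an ortholog score matrix with known
reciprocal best hits, and a satisfiable truth table. The generators are
deterministic for a fixed seed, and the planted structure (sources,
true signed states, RBH pairs) is returned so tests can assert recovery.

The cohort design mirrors the study layout: three infarct-core cohorts
with a large differential set and three remote cohorts whose
differential sets are two orders of magnitude smaller, all expressed as
log2 ratios against an implicit shared control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohorts import CORE_COHORTS, REMOTE_COHORTS
from .expression import ProteinRestriction
from .model import Rule, TruthTable, propagate
from .network import SignedNetwork
from .orthologs import ScoreMatrix
from .relate import EffectorSignature


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic dataset.

    ``planted_sources`` and ``true_states`` are per-cohort; every protein
    in a cohort's ``true_states`` is reachable from one of that cohort's
    sources along the signed path that assigned its state.
    ``rbh_pairs`` is the one-to-one (swine gene, human protein) mapping.
    """

    planted_sources: dict[str, set[str]] = field(default_factory=dict)
    true_states: dict[str, dict[str, int]] = field(default_factory=dict)
    rbh_pairs: set[tuple[str, str]] = field(default_factory=set)

    def swine_for(self, protein: str) -> str:
        for gene, prot in self.rbh_pairs:
            if prot == protein:
                return gene
        raise KeyError(protein)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_sources": {c: sorted(v) for c, v in self.planted_sources.items()},
            "true_states": {
                c: dict(sorted(v.items())) for c, v in self.true_states.items()
            },
            "rbh_pairs": sorted(list(p) for p in self.rbh_pairs),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_sources={c: set(v) for c, v in d["planted_sources"].items()},
            true_states={
                c: {p: int(s) for p, s in v.items()} for c, v in d["true_states"].items()
            },
            rbh_pairs={tuple(p) for p in d["rbh_pairs"]},
        )


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def _swine_id(i: int) -> str:
    return f"SSC{i:04d}"


def generate_network(
    n_nodes: int,
    mean_degree: float = 3.0,
    inhibitory_fraction: float = 0.3,
    seed: int = 0,
) -> SignedNetwork:
    """Scale-free signed directed network.

    A preferential-attachment (Barabasi-Albert) skeleton gives the
    heavy-tailed degree distribution typical of curated interactomes;
    each undirected edge is oriented uniformly at random and assigned an
    inhibitory sign with probability *inhibitory_fraction*. The result
    is weakly connected with roughly ``n_nodes * mean_degree`` edges.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if mean_degree <= 0:
        raise ValueError("mean_degree must be positive")
    if not 0.0 <= inhibitory_fraction <= 1.0:
        raise ValueError("inhibitory_fraction must lie in [0, 1]")
    m = max(1, min(round(mean_degree), n_nodes - 1))
    skeleton = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    rng = np.random.default_rng(seed)
    edges = []
    for u, v in sorted(skeleton.edges()):
        if rng.random() < 0.5:
            u, v = v, u
        sign = -1 if rng.random() < inhibitory_fraction else 1
        edges.append((_protein_id(u), _protein_id(v), sign))
    nodes = [_protein_id(i) for i in range(n_nodes)]
    return SignedNetwork.from_edges(edges, nodes=nodes)


def _grow_states(
    net: SignedNetwork,
    sources: Sequence[str],
    source_signs: Mapping[str, int],
    depth: int,
    max_perturbed: int,
) -> dict[str, int]:
    """Signed BFS from the sources; first visit fixes a node's state.

    The perturbation budget is split evenly across sources so every
    source owns a non-trivial downstream cone even when an early hub
    could claim the whole budget by itself.
    """
    states: dict[str, int] = {s: source_signs[s] for s in sources}
    g = net.graph
    budget = max(1, (max_perturbed - len(states)) // max(len(sources), 1))
    frontiers: dict[str, list[str]] = {s: [s] for s in sources}
    claimed: dict[str, int] = {s: 0 for s in sources}
    for _ in range(depth):
        for s in sources:
            nxt: list[str] = []
            for u in frontiers[s]:
                for _, v, sign in sorted(g.out_edges(u, data="sign")):
                    if v in states or claimed[s] >= budget:
                        continue
                    states[v] = states[u] * sign
                    claimed[s] += 1
                    nxt.append(v)
            frontiers[s] = nxt
    return states


def plant_ground_truth(
    net: SignedNetwork,
    n_sources: int = 3,
    core_fraction: float = 0.4,
    remote_fraction: float = 0.02,
    depth: int = 3,
    seed: int = 0,
    min_separation: int | None = None,
) -> GroundTruth:
    """Plant source proteins and derive per-cohort true signed states.

    Core cohorts receive *n_sources* sources drawn from a shared,
    slightly rotating pool (so cohorts overlap but are not identical, as
    longitudinal source sets do) and perturb about
    ``core_fraction * n_nodes`` proteins; remote cohorts get a single
    source and a differential set of roughly ``remote_fraction`` times
    the core's size, reproducing the strong core-vs-remote asymmetry of
    infarct transcriptomes. RBH pairs cover every network protein.

    ``min_separation`` enforces a pairwise undirected distance between
    planted sources. Source identity is only identifiable when one
    source's downstream cone cannot sign-consistently explain another's;
    keeping sources far apart (more than ``3 * depth`` on tree-like
    networks) guarantees the cones stay mutually unexplainable, at the
    price of requiring a sparse enough network.
    """
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = net.nodes
    # a driver must drive something: only nodes with at least two
    # downstream proteins within the planting depth qualify as sources,
    # ranked by descending out-degree so cones are non-trivial
    out_deg = dict(net.graph.out_degree())

    def cone_size(n: str) -> int:
        reach = nx.single_source_shortest_path_length(net.graph, n, cutoff=depth)
        return len(reach) - 1

    ranked = [
        n
        for n in sorted(nodes, key=lambda n: (-out_deg[n], n))
        if cone_size(n) >= 2
    ]
    if len(ranked) < n_sources:
        raise ValueError("network has too few viable source nodes")
    pool_target = min(n_sources + 2, len(ranked))
    if min_separation is None:
        pool = ranked[:pool_target]
    else:
        undirected = net.graph.to_undirected(as_view=True)
        def distance(a: str, b: str) -> float:
            try:
                return nx.shortest_path_length(undirected, a, b)
            except nx.NetworkXNoPath:
                return float("inf")

        pool = []
        for candidate in ranked:
            if all(distance(candidate, s) >= min_separation for s in pool):
                pool.append(candidate)
            if len(pool) == pool_target:
                break
        if len(pool) < n_sources:
            raise ValueError(
                f"only {len(pool)} sources admit pairwise separation "
                f">= {min_separation}; lower min_separation or n_sources"
            )
    pool_size = len(pool)
    signs = {p: int(rng.choice([-1, 1])) for p in pool}

    core_target = max(n_sources + 1, int(round(core_fraction * net.n_nodes)))
    truth = GroundTruth()
    for i, cohort in enumerate(CORE_COHORTS):
        rotated = pool[i % pool_size :] + pool[: i % pool_size]
        sources = sorted(rotated[:n_sources])
        states = _grow_states(net, sources, signs, depth, core_target)
        truth.planted_sources[cohort] = set(sources)
        truth.true_states[cohort] = states
    core_size = max(len(truth.true_states[c]) for c in CORE_COHORTS)
    remote_target = max(2, int(round(remote_fraction * core_size)))
    for i, cohort in enumerate(REMOTE_COHORTS):
        source = pool[i % pool_size]
        states = _grow_states(net, [source], signs, 1, remote_target)
        truth.planted_sources[cohort] = {source}
        truth.true_states[cohort] = states
    truth.rbh_pairs = {
        (_swine_id(i), p) for i, p in enumerate(nodes)
    }
    return truth


def simulate_cohorts(
    net: SignedNetwork,
    truth: GroundTruth,
    noise_sd: float = 0.1,
    effect_size: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cohort log2 ratios and p-values keyed by swine gene.

    Perturbed proteins get ``effect_size * state`` plus Gaussian noise
    and a p-value drawn from Beta(0.05, 1) (concentrated near zero);
    unperturbed proteins get pure noise and a Uniform(0, 1) p-value.
    Ratios are relative to the implicit control group.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if effect_size <= 0:
        raise ValueError("effect_size must be positive")
    if not set().union(*truth.true_states.values()) <= set(net.nodes):
        raise ValueError("true states refer to proteins outside the network")
    rng = np.random.default_rng(seed)
    protein_to_swine = {p: g for g, p in truth.rbh_pairs}
    rows = []
    for cohort in sorted(truth.true_states):
        states = truth.true_states[cohort]
        for protein in net.nodes:
            state = states.get(protein, 0)
            log2 = effect_size * state + (
                rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            if state != 0:
                pvalue = rng.beta(0.05, 1.0)
            else:
                pvalue = rng.uniform(0.0, 1.0)
            rows.append((protein_to_swine[protein], cohort, log2, pvalue))
    return pd.DataFrame(rows, columns=["id", "cohort", "log2_ratio", "pvalue"])


def simulate_sample_matrix(
    net: SignedNetwork,
    truth: GroundTruth,
    cohorts: Sequence[str],
    n_per_cohort: int = 4,
    noise_sd: float = 0.3,
    effect_size: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level sample matrix (rows: samples; columns: proteins + cohort).

    Used by the biomarker search, which classifies individual samples
    rather than cohort-level summaries.
    """
    if n_per_cohort < 1:
        raise ValueError("n_per_cohort must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = net.nodes
    records = []
    for cohort in cohorts:
        states = truth.true_states.get(cohort, {})
        base = np.array([effect_size * states.get(p, 0) for p in nodes], dtype=float)
        for _ in range(n_per_cohort):
            noise = rng.normal(0.0, noise_sd, len(nodes)) if noise_sd > 0 else 0.0
            records.append(list(base + noise) + [cohort])
    return pd.DataFrame(records, columns=list(nodes) + ["cohort"])


def generate_ortholog_scores(
    swine_genes: Sequence[str],
    human_proteins: Sequence[str],
    n_true_pairs: int,
    decoy_level: float = 0.2,
    seed: int = 0,
) -> tuple[ScoreMatrix, set[tuple[str, str]]]:
    """Similarity matrix in which *n_true_pairs* planted pairs are the
    strict row and column maxima.

    Decoy scores are uniform on [0, decoy_level]; planted pairs score in
    [0.6, 1.0], so recovery by reciprocal best hits is guaranteed by
    construction. Returns the matrix and the planted pair set.
    """
    if len(set(swine_genes)) != len(swine_genes):
        raise ValueError("duplicate swine gene identifiers")
    if len(set(human_proteins)) != len(human_proteins):
        raise ValueError("duplicate human protein identifiers")
    if n_true_pairs > min(len(swine_genes), len(human_proteins)):
        raise ValueError("n_true_pairs exceeds the smaller identifier list")
    if not 0.0 <= decoy_level < 0.6:
        raise ValueError("decoy_level must lie in [0, 0.6) to stay below true pairs")
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.0, decoy_level, (len(swine_genes), len(human_proteins)))
    rows = rng.permutation(len(swine_genes))[:n_true_pairs]
    cols = rng.permutation(len(human_proteins))[:n_true_pairs]
    pairs = set()
    for i, j in zip(rows, cols):
        scores[i, j] = rng.uniform(0.6, 1.0)
        pairs.add((swine_genes[i], human_proteins[j]))
    return ScoreMatrix(list(swine_genes), list(human_proteins), scores), pairs


def scores_for_pairs(
    pairs: set[tuple[str, str]],
    decoy_level: float = 0.2,
    seed: int = 0,
) -> ScoreMatrix:
    """Score matrix whose reciprocal best hits are exactly *pairs*."""
    if not pairs:
        raise ValueError("need at least one pair")
    swine = sorted({g for g, _ in pairs})
    human = sorted({p for _, p in pairs})
    if len(swine) != len(pairs) or len(human) != len(pairs):
        raise ValueError("pairs must be one-to-one")
    if not 0.0 <= decoy_level < 0.6:
        raise ValueError("decoy_level must lie in [0, 0.6)")
    rng = np.random.default_rng(seed)
    scores = rng.uniform(0.0, decoy_level, (len(swine), len(human)))
    gi = {g: i for i, g in enumerate(swine)}
    pj = {p: j for j, p in enumerate(human)}
    for g, p in sorted(pairs):
        scores[gi[g], pj[p]] = rng.uniform(0.6, 1.0)
    return ScoreMatrix(swine, human, scores)


def generate_truth_table(
    net: SignedNetwork,
    n_rules: int = 10,
    path_length_max: int = 3,
    seed: int = 0,
    responses_per_rule: int = 2,
    min_activity: float = 0.1,
) -> TruthTable:
    """Satisfiable stimulus -> response rules read off the network itself.

    Each rule clamps one stimulus node and records the signs that a
    unit-weight propagation actually produces on nodes within
    *path_length_max* hops, so the all-ones weight assignment satisfies
    every rule by construction. Stimulus nodes are distinct across
    rules; asking for more rules than stimulus nodes with usable
    responses raises.
    """
    if n_rules < 1:
        raise ValueError("n_rules must be >= 1")
    rng = np.random.default_rng(seed)
    ones = net.default_weights()
    candidates = list(net.nodes)
    order = rng.permutation(len(candidates))
    rules: list[Rule] = []
    g = net.graph
    for idx in order:
        if len(rules) == n_rules:
            break
        stim = candidates[idx]
        direction = int(rng.choice([-1, 1]))
        state = propagate(net, {stim: float(direction)}, weights=ones)
        within = {
            n
            for n, dist in nx.single_source_shortest_path_length(
                g, stim, cutoff=path_length_max
            ).items()
            if n != stim
        }
        usable = sorted(
            n for n in within if abs(state[n]) >= min_activity
        )
        if not usable:
            continue
        take = min(responses_per_rule, len(usable))
        chosen = [usable[i] for i in rng.permutation(len(usable))[:take]]
        response = {n: (1 if state[n] > 0 else -1) for n in sorted(chosen)}
        rules.append(Rule(stimulus={stim: float(direction)}, response=response))
    if len(rules) < n_rules:
        raise ValueError(
            f"only {len(rules)} distinct satisfiable rules available, "
            f"{n_rules} requested"
        )
    return TruthTable(rules)


def restrictions_from_truth(
    truth: GroundTruth, cohort: str
) -> list[ProteinRestriction]:
    """Noise-free restrictions taken directly from the planted states."""
    return [
        ProteinRestriction(protein=p, cohort=cohort, direction=s)
        for p, s in sorted(truth.true_states[cohort].items())
    ]


def make_signature(
    truth: GroundTruth,
    cohort: str = "C6",
    n_effectors: int = 15,
    seed: int = 0,
    name: str = "cardiac_remodeling",
) -> EffectorSignature:
    """Effector signature sampled from a cohort's perturbed non-sources."""
    states = truth.true_states[cohort]
    sources = truth.planted_sources[cohort]
    candidates = sorted(p for p in states if p not in sources)
    if not candidates:
        raise ValueError("no non-source perturbed proteins to sample")
    rng = np.random.default_rng(seed)
    take = min(n_effectors, len(candidates))
    chosen = [candidates[i] for i in rng.permutation(len(candidates))[:take]]
    return EffectorSignature(name, {p: states[p] for p in sorted(chosen)})
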