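"""Triggering-protein (source) analysis and mechanism sampling.

A differential protein u "explains" another differential protein v when
the network contains a directed path u => v of bounded length whose
composed sign (the product of edge signs) converts u's observed
direction into v's: sign(path) == direction(u) * direction(v). The
explain graph collects these arcs; its structure yields the cohort-level
triggering report (how many proteins are explainable at all, and how few
sources suffice to explain them) and a greedy set cover picks the source
proteins. Mechanism subnetworks are then drawn by sampling source ->
effector paths in proportion to the fitted ensemble's edge weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ProteinRestriction
from .model import ModelEnsembleResults
from .network import SignedNetwork
from .relate import EffectorSignature


@dataclass
class TriggeringReport:
    """Per-cohort source-protein metrics (the standard four-row report)."""

    cohort: str
    n_available: int
    max_explainable_pct: float
    sources: list[str]
    explained_pct: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Proteins available for analysis", self.n_available),
            (
                "Maximum % of proteins explained by other differential proteins",
                f"{self.max_explainable_pct:.0f}%",
            ),
            ("Number of source proteins", len(self.sources)),
            (
                "% of explainable proteins explained by triggering proteins",
                f"{self.explained_pct:.0f}%",
            ),
        ]
        return pd.DataFrame(rows, columns=["metric", self.cohort])


def _signed_reachability(
    net: SignedNetwork, start: str, max_path_len: int
) -> dict[str, set[int]]:
    """Signs of directed paths of length <= max_path_len from *start*.

    Breadth-first search over (node, accumulated sign) states; a node may
    be reachable with both signs via different paths.
    """
    g = net.graph
    reached: dict[str, set[int]] = {}
    frontier = {(start, 1)}
    seen = {(start, 1)}
    for _ in range(max_path_len):
        nxt = set()
        for node, sign in frontier:
            for _, succ, edge_sign in g.out_edges(node, data="sign"):
                state = (succ, sign * edge_sign)
                if state not in seen:
                    seen.add(state)
                    nxt.add(state)
                reached.setdefault(succ, set()).add(sign * edge_sign)
        frontier = nxt
        if not frontier:
            break
    return reached


def build_explain_graph(
    net: SignedNetwork,
    restrictions: Sequence[ProteinRestriction],
    max_path_len: int = 3,
) -> nx.DiGraph:
    """Arc u -> v iff u sign-consistently explains v within *max_path_len*.

    *restrictions* must belong to a single cohort. Restriction proteins
    absent from the network are dropped with a warning.
    """
    if max_path_len < 1:
        raise ValueError("max_path_len must be >= 1")
    cohorts = {r.cohort for r in restrictions}
    if len(cohorts) > 1:
        raise ValueError(f"restrictions span several cohorts: {sorted(cohorts)}")
    directions: dict[str, int] = {}
    for r in restrictions:
        if r.protein not in net:
            warnings.warn(
                f"restriction protein {r.protein!r} absent from network; dropped",
                stacklevel=2,
            )
            continue
        directions[r.protein] = r.direction
    g = nx.DiGraph()
    g.add_nodes_from(sorted(directions))
    for u in sorted(directions):
        reached = _signed_reachability(net, u, max_path_len)
        for v, signs in reached.items():
            if v == u or v not in directions:
                continue
            if directions[u] * directions[v] in signs:
                g.add_edge(u, v)
    return g


def max_explainable_fraction(explain_graph: nx.DiGraph) -> float:
    """Percentage of differential proteins explainable by another one."""
    n = explain_graph.number_of_nodes()
    if n == 0:
        raise ValueError("empty explain graph")
    explainable = sum(1 for _, d in explain_graph.in_degree() if d >= 1)
    return 100.0 * explainable / n


def select_sources(
    explain_graph: nx.DiGraph, max_sources: int | None = None
) -> tuple[list[str], float]:
    """Greedy set cover of the explainable proteins.

    Repeatedly picks the protein explaining the most not-yet-covered
    explainable proteins (a protein never covers itself). Ties break by
    total out-coverage, then lexicographic ID. Stops when the marginal
    gain reaches zero or *max_sources* have been chosen; returns the
    sources and the percentage of explainable proteins covered.
    """
    if explain_graph.number_of_nodes() == 0:
        raise ValueError("empty explain graph")
    explainable = {v for v, d in explain_graph.in_degree() if d >= 1}
    if not explainable:
        return [], 0.0
    cover = {
        u: set(explain_graph.successors(u)) & explainable
        for u in explain_graph.nodes
    }
    covered: set[str] = set()
    sources: list[str] = []
    while covered != explainable:
        if max_sources is not None and len(sources) >= max_sources:
            break
        best = max(
            cover,
            key=lambda u: (len(cover[u] - covered), len(cover[u]), _neg_lex(u)),
        )
        gain = len(cover[best] - covered)
        if gain == 0:
            break
        sources.append(best)
        covered |= cover[best]
        del cover[best]
    return sources, 100.0 * len(covered) / len(explainable)


class _neg_lex(str):
    """Reverse lexicographic ordering helper so max() prefers smaller IDs."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


def triggering_report(
    net: SignedNetwork,
    restrictions: Sequence[ProteinRestriction],
    cohort: str,
    max_path_len: int = 3,
    max_sources: int | None = None,
) -> TriggeringReport:
    """Full per-cohort triggering analysis (the four-row report)."""
    g = build_explain_graph(net, restrictions, max_path_len=max_path_len)
    sources, explained_pct = select_sources(g, max_sources=max_sources)
    return TriggeringReport(
        cohort=cohort,
        n_available=g.number_of_nodes(),
        max_explainable_pct=max_explainable_fraction(g),
        sources=sources,
        explained_pct=explained_pct,
    )


def intersect_source_sets(
    per_cohort_sources: Mapping[str, Iterable[str]],
) -> dict[tuple[str, ...], set[str]]:
    """Partition source proteins by the exact cohort combination they share.

    Returns a map from a sorted cohort tuple to the proteins found in
    exactly those cohorts; the key covering every cohort holds the
    proteins common to all.
    """
    if len(per_cohort_sources) < 2:
        raise ValueError("need at least two cohorts to intersect")
    membership: dict[str, set[str]] = {}
    for cohort, proteins in per_cohort_sources.items():
        for p in proteins:
            membership.setdefault(p, set()).add(cohort)
    combos: dict[tuple[str, ...], set[str]] = {}
    for protein, cohorts in membership.items():
        combos.setdefault(tuple(sorted(cohorts)), set()).add(protein)
    return combos


def common_sources(per_cohort_sources: Mapping[str, Iterable[str]]) -> set[str]:
    """Source proteins shared by every cohort."""
    sets = [set(v) for v in per_cohort_sources.values()]
    return set.intersection(*sets) if sets else set()


def sample_mechanism(
    ensemble: ModelEnsembleResults,
    net: SignedNetwork,
    sources: Sequence[str],
    effectors: EffectorSignature,
    n_samples: int = 1000,
    seed: int = 0,
    max_path_len: int = 5,
) -> nx.DiGraph:
    """Sample source -> effector paths weighted by ensemble edge weights.

    Candidate simple paths (length <= *max_path_len*) from any source to
    any effector are enumerated; each is drawn with probability
    proportional to the product of its ensemble-averaged edge weights.
    The union of the sampled paths is returned with per-edge visit
    frequencies; nodes carry a ``role`` attribute (source / effector /
    intermediate).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    for s in sources:
        if s not in net:
            raise KeyError(f"unknown source {s!r}")
    mean_w = ensemble.mean_weights()
    edge_attr = {
        (u, v): (sign, mean_w[e]) for e, (u, v, sign) in enumerate(net.edges)
    }
    paths: list[list[str]] = []
    for src in sorted(set(sources)):
        for eff in sorted(effectors.effectors):
            if eff == src or eff not in net:
                continue
            for path in nx.all_simple_paths(
                net.graph, src, eff, cutoff=max_path_len
            ):
                paths.append(path)
    out = nx.DiGraph()
    if not paths:
        warnings.warn("no path from any source to any effector", stacklevel=2)
        return out
    weights = np.array(
        [
            np.prod([edge_attr[(u, v)][1] for u, v in zip(p, p[1:])])
            for p in paths
        ]
    )
    total = weights.sum()
    if total <= 0:  # all candidate paths carry zero weight
        probs = np.full(len(paths), 1.0 / len(paths))
    else:
        probs = weights / total
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_samples, probs)
    edge_visits: dict[tuple[str, str], int] = {}
    for path, count in zip(paths, counts):
        if count == 0:
            continue
        for u, v in zip(path, path[1:]):
            edge_visits[(u, v)] = edge_visits.get((u, v), 0) + count
    for (u, v), visits in sorted(edge_visits.items()):
        sign, w = edge_attr[(u, v)]
        out.add_edge(u, v, sign=sign, weight=float(w), frequency=visits / n_samples)
    for node in out.nodes:
        if node in set(sources):
            out.nodes[node]["role"] = "source"
        elif node in effectors.effectors:
            out.nodes[node]["role"] = "effector"
        else:
            out.nodes[node]["role"] = "intermediate"
    return out


def mechanism_frame(mechanism: nx.DiGraph) -> pd.DataFrame:
    """Edge list of a sampled mechanism with signs and visit frequencies."""
    rows = [
        (u, v, d["sign"], d["weight"], d["frequency"])
        for u, v, d in sorted(mechanism.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["src", "dst", "sign", "weight", "frequency"])
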