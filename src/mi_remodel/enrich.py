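"""Enrichment scores, cross-cohort overlap accounting and summary statistics.

The enrichment score (ES) follows the classic running-sum definition:
walk down a list of genes ranked by their correlation with the
phenotype, stepping the sum up when the gene belongs to the query set
(in proportion to |correlation|^p, normalised over the set's members)
and down by 1/(N-K) otherwise. The ES is the signed maximum deviation
from zero encountered on the walk — positive when the set piles up at
the top of the list, negative at the bottom.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class RankedList:
    """Genes ordered by descending phenotype correlation."""

    genes: list[str]
    correlations: list[float]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.correlations):
            raise ValueError("genes and correlations must align")
        c = np.asarray(self.correlations, dtype=float)
        if np.any(np.diff(c) > 0):
            raise ValueError("correlations must be sorted descending")

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "RankedList":
        """Build a ranked list from unordered gene scores (stable on ties)."""
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls([g for g, _ in items], [s for _, s in items])


def enrichment_score(
    ranked: RankedList, gene_set: set[str], weight_exponent: float = 1.0
) -> float:
    """Signed maximum deviation of the GSEA running sum.

    With ``weight_exponent=0`` the walk is the unweighted Kolmogorov-
    Smirnov form; the default 1 weights each hit by |correlation|. When
    the set covers the whole list there are no miss decrements and the
    ES degenerates to 1.
    """
    hits = np.array([g in gene_set for g in ranked.genes], dtype=bool)
    n = len(ranked.genes)
    k = int(hits.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked list")
    corr = np.abs(np.asarray(ranked.correlations, dtype=float)) ** weight_exponent
    hit_weight = corr * hits
    total_hit = hit_weight.sum()
    if total_hit == 0:  # all hit correlations zero: fall back to equal steps
        hit_weight = hits / k
    else:
        hit_weight = hit_weight / total_hit
    miss_step = 0.0 if k == n else 1.0 / (n - k)
    steps = np.where(hits, hit_weight, -miss_step)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak])


@dataclass
class OverlapCounts:
    """Cross-cohort set algebra per annotation category."""

    cohorts: list[str]
    categories: list[str]
    triple_common: dict[str, int]  # per category, |intersection of all cohorts|
    pairwise: dict[tuple[str, str, str], int]  # (category, cohort_a, cohort_b)
    common_total: int
    total_terms: int
    n_up: int | None = None
    n_down: int | None = None


def overlap_accounting(
    sets_by_category: Mapping[str, Mapping[str, Iterable[str]]],
    directions: Mapping[str, str] | None = None,
) -> OverlapCounts:
    """Exact intersection bookkeeping across cohorts and categories.

    *sets_by_category* maps category -> cohort -> term set. The total
    common to all cohorts is the sum over categories of the all-cohort
    intersections; the grand total is the size of the union of every
    term, split into up/down counts when *directions* labels the terms.
    """
    categories = sorted(sets_by_category)
    cohort_names = sorted({c for sets in sets_by_category.values() for c in sets})
    if len(cohort_names) < 2:
        raise ValueError("need at least two cohorts")
    triple_common: dict[str, int] = {}
    pairwise: dict[tuple[str, str, str], int] = {}
    union: set[str] = set()
    for cat in categories:
        cohort_sets = {c: set(v) for c, v in sets_by_category[cat].items()}
        union |= set.union(*cohort_sets.values()) if cohort_sets else set()
        present = [cohort_sets.get(c, set()) for c in cohort_names]
        triple_common[cat] = len(set.intersection(*present)) if present else 0
        for i, a in enumerate(cohort_names):
            for b in cohort_names[i + 1 :]:
                pairwise[(cat, a, b)] = len(
                    cohort_sets.get(a, set()) & cohort_sets.get(b, set())
                )
    n_up = n_down = None
    if directions is not None:
        n_up = sum(1 for t in union if directions.get(t) == "up")
        n_down = sum(1 for t in union if directions.get(t) == "down")
    return OverlapCounts(
        cohorts=cohort_names,
        categories=categories,
        triple_common=triple_common,
        pairwise=pairwise,
        common_total=sum(triple_common.values()),
        total_terms=len(union),
        n_up=n_up,
        n_down=n_down,
    )


def network_summary(
    nodes: int | Sequence[str], edges: Iterable[tuple]
) -> tuple[float, float]:
    """(average degree, average local clustering) of an undirected graph.

    Uses the undirected conventions of interaction-database reports:
    average degree is 2|E|/|V| over *all* nodes (isolated ones included)
    and the local clustering of a node with degree < 2 counts as 0.
    """
    g = nx.Graph()
    if isinstance(nodes, int):
        if nodes < 1:
            raise ValueError("need at least one node")
        g.add_nodes_from(range(nodes))
    else:
        g.add_nodes_from(nodes)
        if g.number_of_nodes() < 1:
            raise ValueError("need at least one node")
    node_set = set(g.nodes)
    for u, v in edges:
        if u not in node_set or v not in node_set:
            raise ValueError(f"edge ({u!r}, {v!r}) endpoint outside node set")
        g.add_edge(u, v)
    avg_degree = 2.0 * g.number_of_edges() / g.number_of_nodes()
    avg_clustering = nx.average_clustering(g, count_zeros=True)
    return avg_degree, float(avg_clustering)


def proportion_report(
    numerator: int, denominator: int, decimals: int = 1
) -> float:
    """Percentage with half-up rounding (as printed in study reports)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator or numerator < 0:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def time_overlap_table(detection: pd.DataFrame) -> list[str]:
    """Proteins detected at every time point in at least one region.

    *detection* is indexed by protein with one boolean-like column per
    cohort (C6...R45). A protein qualifies when for each day d in
    {6, 30, 45} it is detected in the core or the remote cohort of that
    day. Missing cohort columns count as undetected.
    """
    days = (6, 30, 45)
    out = []
    for protein, row in detection.iterrows():
        ok = True
        for d in days:
            detected = False
            for region in ("C", "R"):
                col = f"{region}{d}"
                if col in detection.columns:
                    val = row[col]
                    if pd.notna(val) and bool(val):
                        detected = True
            if not detected:
                ok = False
                break
        if ok:
            out.append(str(protein))
    return sorted(out)
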