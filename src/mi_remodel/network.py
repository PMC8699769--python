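"""Signed directed protein-interaction networks.

The model skeleton is a directed graph whose edges carry a sign
(+1 activation, -1 inhibition) and, once fitted, a weight in [0, 1].
Edges are kept in a canonical sorted order so that weight vectors can be
stored as plain numpy arrays aligned with :attr:`SignedNetwork.edges`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

_SIGN_WORD = {1: "activates", -1: "inhibits"}
_WORD_SIGN = {v: k for k, v in _SIGN_WORD.items()}


class SignedNetwork:
    """Directed graph of protein nodes with signed edges.

    Parameters
    ----------
    graph:
        A :class:`networkx.DiGraph` whose edges all carry a ``sign``
        attribute in {+1, -1}. Self-loops are rejected.
    """

    def __init__(self, graph: nx.DiGraph):
        for u, v, data in graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            if data.get("sign") not in (1, -1):
                raise ValueError(f"edge ({u!r}, {v!r}) must have sign +1 or -1")
        self._g = graph
        self._nodes: list[str] = sorted(graph.nodes)
        self._index = {n: i for i, n in enumerate(self._nodes)}
        edges = sorted(graph.edges(data="sign"))
        self._edges: list[tuple[str, str, int]] = [(u, v, int(s)) for u, v, s in edges]
        self._src = np.array([self._index[u] for u, _, _ in self._edges], dtype=np.intp)
        self._dst = np.array([self._index[v] for _, v, _ in self._edges], dtype=np.intp)
        self._sign = np.array([s for _, _, s in self._edges], dtype=np.float64)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        nodes: Sequence[str] | None = None,
    ) -> "SignedNetwork":
        g = nx.DiGraph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v, sign in edges:
            g.add_edge(u, v, sign=int(sign))
        return cls(g)

    @classmethod
    def read_sif(cls, path: str | Path) -> "SignedNetwork":
        """Read a 3-column SIF file (src TAB activates|inhibits TAB dst)."""
        edges = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            src, word, dst = parts
            if word not in _WORD_SIGN:
                raise ValueError(f"unknown interaction type {word!r}")
            edges.append((src, dst, _WORD_SIGN[word]))
        return cls.from_edges(edges)

    def write_sif(self, path: str | Path) -> None:
        lines = [f"{u}\t{_SIGN_WORD[s]}\t{v}" for u, v, s in self._edges]
        Path(path).write_text("\n".join(lines) + "\n")

    # -- views -------------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        return self._g

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        """Edges as (src, dst, sign) tuples in canonical sorted order."""
        return list(self._edges)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node_index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    @property
    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src_index, dst_index, sign) arrays aligned with :attr:`edges`."""
        return self._src, self._dst, self._sign

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def __repr__(self) -> str:
        return f"SignedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    def default_weights(self) -> np.ndarray:
        """Unit weight on every edge."""
        return np.ones(self.n_edges)

    def inhibitory_fraction(self) -> float:
        if not self._edges:
            return 0.0
        return float(np.mean(self._sign < 0))

    def edge_frame(self, weights: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self._edges, columns=["src", "dst", "sign"])
        if weights is not None:
            df["weight"] = np.asarray(weights, dtype=float)
        return df
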