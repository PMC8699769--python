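"""Swine-to-human identifier translation.

Cross-species translation runs in two passes, mirroring the usual
comparative-genomics practice: reciprocal best hits (RBH) on a similarity
score matrix first, then an exact (case-insensitive) gene-name match for
genes the RBH pass leaves unresolved. The mapped entries are one-to-one:
a gene whose best hit is tied, or not reciprocated, stays unmapped rather
than being guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RBH = "rbh"
GENE_NAME = "gene_name"


@dataclass
class ScoreMatrix:
    """Similarity scores between swine genes (rows) and human proteins (columns)."""

    swine_ids: list[str]
    human_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.swine_ids), len(self.human_ids)):
            raise ValueError("score matrix shape does not match identifier lists")
        if len(set(self.swine_ids)) != len(self.swine_ids):
            raise ValueError("duplicate swine identifiers")
        if len(set(self.human_ids)) != len(self.human_ids):
            raise ValueError("duplicate human identifiers")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.scores, index=self.swine_ids, columns=self.human_ids).to_csv(
            path, sep="\t"
        )

    def transpose(self) -> "ScoreMatrix":
        return ScoreMatrix(list(self.human_ids), list(self.swine_ids), self.scores.T)


@dataclass
class OrthologMap:
    """One-to-one swine gene -> human protein mapping with provenance.

    ``entries`` maps each resolved swine gene to ``(human_protein, method)``
    where method is ``"rbh"`` or ``"gene_name"``; ``unmapped`` lists genes
    no pass could resolve.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        targets = [h for h, _ in self.entries.values()]
        if len(set(targets)) != len(targets):
            raise ValueError("mapping is not one-to-one on human proteins")
        if set(self.entries) & set(self.unmapped):
            raise ValueError("a gene cannot be both mapped and unmapped")

    def merge(self, other: "OrthologMap") -> "OrthologMap":
        """Combine two passes; *other* resolves genes this map left unmapped."""
        entries = dict(self.entries)
        for g, (h, method) in other.entries.items():
            if g in entries:
                raise ValueError(f"gene {g!r} mapped twice")
            entries[g] = (h, method)
        unmapped = [g for g in self.unmapped if g not in other.entries]
        unmapped += [g for g in other.unmapped if g not in entries and g not in unmapped]
        return OrthologMap(entries, unmapped)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, h, m) for g, (h, m) in sorted(self.entries.items())]
        return pd.DataFrame(rows, columns=["swine_id", "human_id", "method"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def reciprocal_best_hits(matrix: ScoreMatrix) -> OrthologMap:
    """Map gene g to protein h iff each is the other's unique best score.

    A tied row or column maximum disqualifies the pair: best hits must be
    unique to count as reciprocal.
    """
    s = matrix.scores
    if s.size == 0:
        raise ValueError("empty score matrix")
    if np.any(np.isnan(s)):
        raise ValueError("score matrix contains NaN")
    entries: dict[str, tuple[str, str]] = {}
    row_max = s.max(axis=1)
    col_max = s.max(axis=0)
    for i, gene in enumerate(matrix.swine_ids):
        hits = np.flatnonzero(s[i] == row_max[i])
        if len(hits) != 1:
            continue
        j = hits[0]
        back = np.flatnonzero(s[:, j] == col_max[j])
        if len(back) == 1 and back[0] == i:
            entries[gene] = (matrix.human_ids[j], RBH)
    unmapped = [g for g in matrix.swine_ids if g not in entries]
    return OrthologMap(entries, unmapped)


def resolve_by_gene_name(
    unmapped: Sequence[str], human_name_table: Mapping[str, str]
) -> OrthologMap:
    """Second-pass resolution by exact, case-insensitive gene-name match."""
    folded: dict[str, str] = {}
    for name, protein in human_name_table.items():
        key = name.casefold()
        if key in folded and folded[key] != protein:
            raise ValueError(f"gene name {name!r} maps to more than one protein")
        folded[key] = protein
    entries: dict[str, tuple[str, str]] = {}
    still_unmapped: list[str] = []
    for gene in unmapped:
        protein = folded.get(gene.casefold())
        if protein is None:
            still_unmapped.append(gene)
        else:
            entries[gene] = (protein, GENE_NAME)
    return OrthologMap(entries, still_unmapped)


def map_expression(table: pd.DataFrame, omap: OrthologMap) -> pd.DataFrame:
    """Re-key an expression table from swine genes to human proteins.

    Rows whose gene has no mapping are dropped; two swine genes landing on
    the same protein would break the one-to-one contract and raise.
    """
    if table.empty:
        return table.copy()
    mapped = table[table["id"].isin(omap.entries)].copy()
    mapped["id"] = [omap.entries[g][0] for g in mapped["id"]]
    dup = mapped.duplicated(subset=["id", "cohort"], keep=False)
    if dup.any():
        clashing = sorted(mapped.loc[dup, "id"].unique())
        raise ValueError(f"multiple swine genes map to protein(s) {clashing}")
    return mapped.reset_index(drop=True)
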