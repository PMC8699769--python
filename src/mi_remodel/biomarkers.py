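"""Combinatorial biomarker panel search with leave-one-out validation.

Candidate panels of 2, 3 or 5 proteins are scanned exhaustively; each is
judged by how well a nearest-centroid classifier on z-scored features
assigns samples to their cohort. Two numbers are kept per panel:
resubstitution accuracy and leave-one-out (LOO) accuracy — the latter is
the "generalization capability" and is the primary ranking key, since
resubstitution flatters any sufficiently flexible panel.

Four search strategies mirror the way a model-driven and a data-driven
candidate list can gate each other: ``models`` and ``HT`` scan the raw
candidate list (classifying model solutions or high-throughput samples
respectively), while ``models/HT`` keeps only panels whose proteins are
all HT-significant and ``HT/models`` keeps only panels fully contained
in the model-related list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STRATEGIES = ("models", "models/HT", "HT", "HT/models")
DEFAULT_SIZES = (2, 3, 5)


@dataclass
class LabeledSampleSet:
    """Feature matrix (samples x proteins) with a cohort label per sample."""

    X: np.ndarray
    labels: list[str]
    proteins: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x proteins)")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("one label per sample required")
        if self.X.shape[1] != len(self.proteins):
            raise ValueError("one protein per feature column required")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def columns(self, proteins: Sequence[str]) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.proteins)}
        try:
            cols = [index[p] for p in proteins]
        except KeyError as exc:
            raise KeyError(f"protein {exc.args[0]!r} not in sample set") from None
        return self.X[:, cols]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_column: str = "cohort") -> "LabeledSampleSet":
        labels = df[label_column].astype(str).tolist()
        features = df.drop(columns=[label_column])
        return cls(features.to_numpy(dtype=float), labels, list(features.columns))


@dataclass(frozen=True)
class CombinationResult:
    proteins: tuple[str, ...]
    strategy: str
    accuracy: float
    generalization: float

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not (0 <= self.accuracy <= 1 and 0 <= self.generalization <= 1):
            raise ValueError("metrics must lie in [0, 1]")


def enumerate_combinations(
    candidates: Sequence[str], sizes: Iterable[int] = DEFAULT_SIZES
) -> Iterator[tuple[str, ...]]:
    """All protein subsets of each requested size, in deterministic order."""
    sizes = tuple(sizes)
    for size in sizes:
        if size < 1 or size > len(candidates):
            raise ValueError(
                f"combination size {size} invalid for {len(candidates)} candidates"
            )
    for size in sizes:
        yield from combinations(candidates, size)


def n_combinations(n_candidates: int, sizes: Iterable[int] = DEFAULT_SIZES) -> int:
    return sum(comb(n_candidates, s) for s in sizes)


def _nearest_centroid_predict(
    X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    """Nearest-centroid prediction on z-scored features.

    Standardisation parameters come from the training rows only; a
    zero-variance feature gets unit scale. Distance ties go to the first
    class in sorted label order.
    """
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Z_train = (X_train - mu) / sd
    Z_test = (X_test - mu) / sd
    classes = np.unique(y_train)
    centroids = np.stack([Z_train[y_train == c].mean(axis=0) for c in classes])
    d2 = ((Z_test[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return classes[np.argmin(d2, axis=1)]


def evaluate_combination_loo(
    proteins: Sequence[str], data: LabeledSampleSet
) -> tuple[float, float]:
    """(resubstitution accuracy, leave-one-out accuracy) of a panel."""
    if data.n_samples < 3:
        raise ValueError("need at least 3 samples")
    X = data.columns(proteins)
    y = np.asarray(data.labels)
    if np.all(X.std(axis=0) == 0):
        warnings.warn(
            "all features constant across samples; accuracy is at chance",
            stacklevel=2,
        )
    accuracy = float(np.mean(_nearest_centroid_predict(X, y, X) == y))
    hits = 0
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        train_labels = y[mask]
        if len(np.unique(train_labels)) < 2:
            mask[i] = True
            continue
        pred = _nearest_centroid_predict(X[mask], train_labels, X[i : i + 1])
        hits += int(pred[0] == y[i])
        mask[i] = True
    return accuracy, hits / len(y)


def strategy_filter(
    combos: Iterable[tuple[str, ...]],
    strategy: str,
    model_related: set[str] | None = None,
    ht_significant: set[str] | None = None,
) -> Iterator[tuple[str, ...]]:
    """Gate a combination stream by the chosen search strategy."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if strategy == "models/HT":
        if ht_significant is None:
            raise ValueError("models/HT strategy needs the HT-significant set")
        return (c for c in combos if set(c) <= ht_significant)
    if strategy == "HT/models":
        if model_related is None:
            raise ValueError("HT/models strategy needs the model-related set")
        return (c for c in combos if set(c) <= model_related)
    return iter(combos)


def rank_and_report(
    results: Iterable[CombinationResult], top_k: int = 10
) -> pd.DataFrame:
    """Top panels sorted by (generalization, accuracy, smaller size, IDs)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = sorted(
        results,
        key=lambda r: (-r.generalization, -r.accuracy, len(r.proteins), r.proteins),
    )[:top_k]
    return pd.DataFrame(
        [
            {
                "proteins": "+".join(r.proteins),
                "size": len(r.proteins),
                "generalization": r.generalization,
                "accuracy": r.accuracy,
                "strategy": r.strategy,
            }
            for r in ranked
        ]
    )


def cap_candidates(
    scores: pd.DataFrame, cap: int = 30, score_column: str = "predictive_value"
) -> list[str]:
    """Keep the *cap* best candidates by descending score (ties by ID)."""
    ordered = scores.sort_values(
        [score_column, "protein"], ascending=[False, True], kind="mergesort"
    )
    return ordered["protein"].head(cap).tolist()


def search_combinations(
    data: LabeledSampleSet,
    candidates: Sequence[str],
    sizes: Iterable[int] = DEFAULT_SIZES,
    strategy: str = "models",
    model_related: set[str] | None = None,
    ht_significant: set[str] | None = None,
    top_k: int = 10,
) -> pd.DataFrame:
    """Exhaustive scan of all allowed panels, ranked by LOO accuracy."""
    combos = strategy_filter(
        enumerate_combinations(candidates, sizes),
        strategy,
        model_related=model_related,
        ht_significant=ht_significant,
    )
    results = []
    for combo in combos:
        accuracy, generalization = evaluate_combination_loo(combo, data)
        results.append(
            CombinationResult(combo, strategy, accuracy, generalization)
        )
    return rank_and_report(results, top_k=top_k)
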