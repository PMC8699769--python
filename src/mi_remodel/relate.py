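"""Relationship scoring between differential proteins and effector signatures.

For each differential protein the question is mechanistic: if the model
clamps this protein up (or down), does the perturbation that spreads
through the fitted network reproduce the expected direction of the
cardiac-remodeling effectors? The score averages the sign agreement over
the effectors of the signature and over the solutions of the fitted
ensemble, mapped from [-1, 1] to a [0, 1] "predictive value". A protein
with no influence on any effector scores exactly 0.5 (chance); the
inclusion rule of the downstream analyses is strictly greater than 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .model import ModelEnsembleResults, propagate
from .network import SignedNetwork


@dataclass(frozen=True)
class EffectorSignature:
    """Literature-curated effector set with expected perturbation signs."""

    name: str
    effectors: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.effectors:
            raise ValueError("signature must contain at least one effector")
        if any(s not in (1, -1) for s in self.effectors.values()):
            raise ValueError("effector signs must be +1 or -1")

    def validate_against(self, net: SignedNetwork) -> None:
        missing = [p for p in self.effectors if p not in net]
        if missing:
            raise KeyError(f"signature proteins not in network: {missing}")


@dataclass(frozen=True)
class RelationScore:
    protein: str
    predictive_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.predictive_value <= 1.0:
            raise ValueError("predictive value must lie in [0, 1]")


class FprEstimate(NamedTuple):
    """Monte Carlo false-positive-rate estimate with a binomial 95% CI."""

    fpr: float
    ci_low: float
    ci_high: float
    n_null: int


def predictive_value(
    ensemble: ModelEnsembleResults,
    net: SignedNetwork,
    protein: str,
    signature: EffectorSignature,
    direction: int = 1,
) -> RelationScore:
    """Probability-like score that perturbing *protein* reproduces *signature*.

    Each ensemble solution clamps the protein to *direction*, propagates,
    and records the mean sign agreement between the propagated effector
    activities and the signature's expected signs (an unreached effector,
    activity 0, contributes 0). The ensemble-averaged agreement
    ``a in [-1, 1]`` is mapped to ``(a + 1) / 2``.
    """
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    if protein not in net:
        raise KeyError(f"unknown node {protein!r}")
    signature.validate_against(net)
    agreements = []
    for weights in ensemble.solutions:
        state = propagate(net, {protein: float(direction)}, weights=weights)
        agreements.append(
            np.mean(
                [np.sign(state[e]) * s for e, s in signature.effectors.items()]
            )
        )
    a = float(np.mean(agreements))
    return RelationScore(protein, (a + 1.0) / 2.0)


def score_proteins(
    ensemble: ModelEnsembleResults,
    net: SignedNetwork,
    directions: Mapping[str, int],
    signature: EffectorSignature,
) -> pd.DataFrame:
    """Score several proteins (with their observed directions) at once."""
    rows = [
        (p, predictive_value(ensemble, net, p, signature, direction=d).predictive_value)
        for p, d in directions.items()
    ]
    return pd.DataFrame(rows, columns=["protein", "predictive_value"])


def select_related(
    scores: Sequence[RelationScore], threshold: float = 0.5
) -> list[str]:
    """Proteins with predictive value strictly above *threshold*.

    The boundary is exclusive: a protein at exactly the threshold carries
    no information beyond chance and is not included. Output is sorted by
    descending predictive value (ties by protein ID for reproducibility).
    """
    kept = [s for s in scores if s.predictive_value > threshold]
    kept.sort(key=lambda s: (-s.predictive_value, s.protein))
    return [s.protein for s in kept]


def calibrate_fpr(
    ensemble: ModelEnsembleResults,
    net: SignedNetwork,
    signature: EffectorSignature,
    n_null: int = 200,
    seed: int = 0,
) -> FprEstimate:
    """Estimate the false-positive rate of the >0.5 inclusion rule.

    Draws *n_null* randomly-signed proteins outside the signature, scores
    each, and reports the fraction exceeding 0.5 with a Wilson 95%
    binomial confidence interval.
    """
    if n_null < 50:
        raise ValueError("n_null must be >= 50 for a stable estimate")
    rng = np.random.default_rng(seed)
    candidates = sorted(set(net.nodes) - set(signature.effectors))
    if not candidates:
        raise ValueError("no proteins outside the signature to sample")
    picks = rng.choice(len(candidates), size=n_null, replace=True)
    signs = rng.choice([-1, 1], size=n_null)
    hits = 0
    for idx, sign in zip(picks, signs):
        score = predictive_value(
            ensemble, net, candidates[idx], signature, direction=int(sign)
        )
        if score.predictive_value > 0.5:
            hits += 1
    low, high = proportion_confint(hits, n_null, alpha=0.05, method="wilson")
    return FprEstimate(hits / n_null, float(low), float(high), n_null)
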