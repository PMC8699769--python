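"""Compilation of differential expression into signed molecular restrictions.

An expression table is a tidy :class:`pandas.DataFrame` with one row per
(identifier, cohort) measurement and columns::

    id          gene or protein identifier
    cohort      one of C6, C30, C45, R6, R30, R45
    log2_ratio  log2 expression ratio against control
    pvalue      raw p-value of the differential test

Compilation removes sign-contradictory duplicates, adjusts p-values by
Benjamini-Hochberg at FDR 0.01 and turns each significant entry into a
:class:`ProteinRestriction` — a protein pinned up (+1) or down (-1) in the
network model for that cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohorts import validate_cohort

EXPRESSION_COLUMNS = ("id", "cohort", "log2_ratio", "pvalue")


@dataclass(frozen=True)
class ProteinRestriction:
    """A protein constrained up or down in one cohort's model."""

    protein: str
    cohort: str
    direction: int  # +1 up, -1 down
    baseline: str = "active"  # physiological baseline state
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if self.baseline not in ("active", "inactive"):
            raise ValueError("baseline must be 'active' or 'inactive'")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        validate_cohort(self.cohort)


def _check_expression(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EXPRESSION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    pv = table["pvalue"].to_numpy(dtype=float)
    if len(pv) and (np.nanmin(pv) < 0 or np.nanmax(pv) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return table


def drop_contradictions(table: pd.DataFrame) -> pd.DataFrame:
    """Resolve duplicate (id, cohort) entries.

    An identifier measured with both a strictly positive and a strictly
    negative log2 ratio in the same cohort carries contradictory sign
    information and is discarded from that cohort. Sign-consistent
    duplicates are collapsed to a single row with the mean log2 ratio and
    the minimum p-value.
    """
    _check_expression(table)
    if table.empty:
        return table.copy()

    def resolve(group: pd.DataFrame) -> pd.DataFrame | None:
        lr = group["log2_ratio"].to_numpy(dtype=float)
        if (lr > 0).any() and (lr < 0).any():
            return None
        if len(group) == 1:
            return group
        row = group.iloc[[0]].copy()
        row["log2_ratio"] = lr.mean()
        row["pvalue"] = group["pvalue"].min()
        return row

    parts = [
        resolved
        for _, group in table.groupby(["id", "cohort"], sort=False)
        if (resolved := resolve(group)) is not None
    ]
    if not parts:
        return table.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)


def bh_adjust(
    pvalues: Sequence[float], fdr: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns the adjusted p-values and a boolean significance flag
    (adjusted <= *fdr*, boundary inclusive).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted, adjusted <= fdr


def adjust_table(
    table: pd.DataFrame, fdr: float = 0.01, per_cohort: bool = True
) -> pd.DataFrame:
    """Add ``adj_pvalue`` and ``significant`` columns.

    The correction pool is each cohort separately by default (restrictions
    are compiled per cohort); set ``per_cohort=False`` to pool all rows.
    """
    _check_expression(table)
    out = table.copy()
    if out.empty:
        out["adj_pvalue"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    adj = np.empty(len(out), dtype=float)
    sig = np.empty(len(out), dtype=bool)
    if per_cohort:
        for _, idx in out.groupby("cohort", sort=False).indices.items():
            a, s = bh_adjust(out["pvalue"].to_numpy()[idx], fdr=fdr)
            adj[idx], sig[idx] = a, s
    else:
        adj, sig = bh_adjust(out["pvalue"].to_numpy(), fdr=fdr)
    out["adj_pvalue"] = adj
    out["significant"] = sig
    return out


def build_restrictions(
    table: pd.DataFrame,
    baseline_labels: Mapping[str, str] | None = None,
    fdr: float = 0.01,
    per_cohort: bool = True,
) -> list[ProteinRestriction]:
    """Compile significant rows into signed restrictions.

    The table is first passed through :func:`drop_contradictions` and
    :func:`adjust_table`; each significant (protein, cohort) pair becomes
    one restriction whose direction is the sign of its log2 ratio.
    Proteins absent from *baseline_labels* default to an active baseline.
    A significant row with a log2 ratio of exactly zero has no sign and is
    rejected.
    """
    baseline_labels = baseline_labels or {}
    clean = drop_contradictions(table)
    adjusted = adjust_table(clean, fdr=fdr, per_cohort=per_cohort)
    restrictions: list[ProteinRestriction] = []
    sig = adjusted[adjusted["significant"]]
    for row in sig.itertuples(index=False):
        lr = float(row.log2_ratio)
        if lr == 0.0:
            raise ValueError(
                f"significant entry {row.id!r} in {row.cohort} has zero "
                "log2 ratio and therefore no direction"
            )
        restrictions.append(
            ProteinRestriction(
                protein=str(row.id),
                cohort=str(row.cohort),
                direction=1 if lr > 0 else -1,
                baseline=baseline_labels.get(str(row.id), "active"),
            )
        )
    return restrictions


def restrictions_frame(restrictions: Sequence[ProteinRestriction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.protein, r.cohort, r.direction, r.baseline, r.weight) for r in restrictions],
        columns=["protein", "cohort", "direction", "baseline", "weight"],
    )
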