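"""Cohort summarization and the group-comparison statistical utilities.

The clinical summary reproduces printed-table descriptive statistics
(means rounded half-up to one decimal, per-term counts, proportions).
Group comparisons use the Mann-Whitney U test — exact by enumeration for
small tie-free samples, normal approximation with tie and continuity
correction otherwise — with Benjamini-Hochberg step-up FDR adjustment
across parameters. Per-subject imaging values are not published, so the
imaging comparison is exposed as a procedure plus an explicitly synthetic
demonstration generator, never as a reproduced result.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "round_half_up",
    "summarize_cohort",
    "mann_whitney_u",
    "bh_adjust",
    "GroupComparison",
    "compare_groups",
    "synthetic_imaging_cohort",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at 1 digit), matching printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(table: pd.DataFrame) -> dict:
    """Descriptive summary of the clinical cohort table.

    Expects the layout of :func:`adfunnel.fixtures.load_cohort_table`:
    one row per participant with a Beighton score, tokenized complication
    and laxity-event lists, and an optional ankle symptom.
    """
    if table.empty:
        raise ValueError("cohort table is empty")
    n = len(table)
    beighton = table["beighton"].astype(int)
    if not beighton.between(0, 9).all():
        raise ValueError("Beighton scores must lie in [0, 9]")
    complications = Counter(t for row in table["complications"] for t in row)
    laxity = Counter(t for row in table["laxity_events"] for t in row)
    ankle = Counter(t for t in table["ankle_symptom"] if t)
    n_ankle = int(table["ankle_symptom"].notna().sum())
    n_laxity = int(table["laxity_events"].map(bool).sum())
    return {
        "n": n,
        "mean_age": round_half_up(table["age"].mean()),
        "mean_beighton": round_half_up(beighton.mean()),
        "beighton_histogram": dict(sorted(Counter(beighton).items())),
        "n_dance_major": int(table["dance_major"].sum()),
        "n_family_history": int(table["family_history"].sum()),
        "complication_counts": dict(complications.most_common()),
        "ankle_symptom_counts": dict(ankle.most_common()),
        "laxity_event_counts": dict(laxity.most_common()),
        "n_with_ankle_symptom": n_ankle,
        "pct_with_ankle_symptom": round_half_up(100.0 * n_ankle / n),
        "n_with_laxity_sign": n_laxity,
        "pct_with_laxity_sign": round_half_up(100.0 * n_laxity / n),
    }


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    use_continuity: bool = True,
) -> tuple[float, float]:
    """Mann-Whitney U statistic for ``x`` and its p-value.

    U is computed from rank sums with midranks for ties. The p-value is
    exact (full enumeration of rank assignments) when the pooled sample
    has at most 12 observations and no ties, and otherwise uses the
    normal approximation with tie correction and, by default, continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=use_continuity
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(v) for v in multipletests(arr, method="fdr_bh")[1]]


@dataclass(frozen=True)
class GroupComparison:
    """One imaging parameter compared between two groups."""

    parameter: str
    mean_a: float
    mean_b: float
    u_statistic: float
    p_value: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_value:
            raise ValueError("adjusted p must be >= raw p")


def compare_groups(
    data: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    alternative: str = "two-sided",
) -> list[GroupComparison]:
    """Mann-Whitney comparisons across parameters with BH FDR adjustment.

    ``data`` maps a parameter name to the two groups' value vectors.
    """
    names = list(data)
    raw: list[tuple[float, float]] = [
        mann_whitney_u(data[k][0], data[k][1], alternative=alternative) for k in names
    ]
    adjusted = bh_adjust([p for _, p in raw])
    return [
        GroupComparison(
            parameter=k,
            mean_a=float(np.mean(data[k][0])),
            mean_b=float(np.mean(data[k][1])),
            u_statistic=u,
            p_value=p,
            p_adjusted=p_adj,
        )
        for k, (u, p), p_adj in zip(names, raw, adjusted)
    ]


def synthetic_imaging_cohort(
    params: Mapping[str, tuple[float, float, float, float]],
    n_a: int = 22,
    n_b: int = 24,
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Illustrative synthetic two-group imaging data (NOT real measurements).

    ``params`` maps a parameter name to (mean_a, spread_a, mean_b,
    spread_b); values are drawn from truncated-at-zero normals with
    sigma = spread / 4 (a range-to-sigma rule of thumb). Useful only to
    demonstrate the comparison procedure end to end.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, (mean_a, spread_a, mean_b, spread_b) in params.items():
        a = np.clip(rng.normal(mean_a, max(spread_a, 1e-9) / 4, size=n_a), 0, None)
        b = np.clip(rng.normal(mean_b, max(spread_b, 1e-9) / 4, size=n_b), 0, None)
        out[name] = (a, b)
    return out
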