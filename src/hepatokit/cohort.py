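"""Cohort-level aggregation and exact nonparametric group comparison.

With 4-5 animals per group the normal approximation to the Mann-Whitney U
null distribution is unreliable, so the test is computed exactly: the null
distribution of U is enumerated over all C(n_a + n_b, n_a) assignments of
the pooled observations (mid-ranks for ties), and the two-sided p-value is
twice the smaller tail probability, capped at 1.  No multiple-testing
correction is applied across parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mann_whitney_exact",
    "fold_change",
    "significance_stars",
    "CohortTable",
    "summarize_cohort",
]

_MAX_ENUM = 5_000_000  # cap on C(n_a+n_b, n_a); n<=12 per group stays below


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test for small samples.

    Returns ``(U, p)`` where U = min(U_a, U_b) under the rank-sum
    definition.  Ties are handled with mid-ranks; the p-value enumerates the
    full permutation null, so it is exact even with ties (unlike the
    classical tables).  p is in (0, 1].
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    from math import comb

    if comb(n_a + n_b, n_a) > _MAX_ENUM:
        raise ValueError(
            f"exact enumeration over C({n_a + n_b}, {n_a}) assignments is "
            "too large; this test targets n <= 12 per group"
        )
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    u_b = float(n_a * n_b - u_a)

    combos = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(n_a + n_b), n_a)
        ),
        dtype=np.intp,
    ).reshape(-1, n_a)
    u_all = ranks[combos].sum(axis=1) - n_a * (n_a + 1) / 2
    eps = 1e-9
    p_le = np.mean(u_all <= u_a + eps)
    p_ge = np.mean(u_all >= u_a - eps)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return min(u_a, u_b), float(p)


def fold_change(mean_wt: float, mean_ko: float) -> float:
    """Wild-type / knockout ratio of group means."""
    if mean_ko <= 0:
        raise ValueError("knockout mean must be positive")
    return mean_wt / mean_ko


def significance_stars(p: float) -> str:
    """'**' at p <= 0.01, '*' at p <= 0.05, '' otherwise."""
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


@dataclass
class CohortTable:
    """Per-animal rows plus group summaries and pairwise exact U tests."""

    rows: pd.DataFrame
    summary: pd.DataFrame
    tests: pd.DataFrame
    parameters: list[str] = field(default_factory=list)

    def recompute_summary(self) -> pd.DataFrame:
        """Re-derive the summary from the rows (round-trip check)."""
        return _group_summary(self.rows, self.parameters)


def _group_summary(rows: pd.DataFrame, parameters) -> pd.DataFrame:
    recs = []
    for group, sub in rows.groupby("group", sort=False):
        for p in parameters:
            vals = sub[p].to_numpy(dtype=float)
            rec = {
                "group": group,
                "parameter": p,
                "n": vals.size,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            }
            cv_col = f"cv_{p}"
            if cv_col in sub.columns and sub[cv_col].notna().any():
                rec["cv_min"] = float(sub[cv_col].min())
                rec["cv_max"] = float(sub[cv_col].max())
            recs.append(rec)
    return pd.DataFrame(recs)


def summarize_cohort(
    rows: pd.DataFrame,
    parameters=("cl1", "k2", "k3"),
    group_order=("wild-type", "knockout"),
) -> CohortTable:
    """Build a Table-1-style cohort report.

    ``rows`` needs columns ``animal_id``, ``group`` and one column per
    parameter (optionally ``cv_<param>`` columns with per-fit %CV).  Group
    summaries use the n-1 (sample) SD; each parameter is compared across the
    first two groups with the exact Mann-Whitney U test.
    """
    if not len(rows):
        raise ValueError("cohort has no animals")
    parameters = [p for p in parameters if p in rows.columns]
    if not parameters:
        raise ValueError("no parameter columns found in rows")
    groups = [g for g in group_order if g in set(rows["group"])]
    groups += [g for g in rows["group"].unique() if g not in groups]
    if any((rows["group"] == g).sum() < 1 for g in groups):
        raise ValueError("every group needs at least one animal")

    summary = _group_summary(rows, parameters)

    test_recs = []
    if len(groups) >= 2:
        g1, g2 = groups[0], groups[1]
        for p in parameters:
            a = rows.loc[rows["group"] == g1, p].to_numpy(dtype=float)
            b = rows.loc[rows["group"] == g2, p].to_numpy(dtype=float)
            u, pval = mann_whitney_exact(a, b)
            test_recs.append({
                "parameter": p, "group_a": g1, "group_b": g2,
                "U": u, "p_two_sided": pval,
                "stars": significance_stars(pval),
                "fold_change": fold_change(float(a.mean()), float(b.mean()))
                if b.mean() > 0 else np.nan,
            })
    tests = pd.DataFrame(test_recs)
    return CohortTable(
        rows=rows.reset_index(drop=True), summary=summary, tests=tests,
        parameters=list(parameters),
    )
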