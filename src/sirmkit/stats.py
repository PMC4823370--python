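"""Group statistics: one-way ANOVA, Tukey HSD, Benjamini-Hochberg FDR.

FDR is applied across metabolites within one measurement family (pool
sizes, enrichments, exchanges); Tukey adjusts across the pairwise line
contrasts within each metabolite but is not additionally adjusted across
metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "one_way_anova",
    "tukey_hsd",
    "bh_fdr",
    "analyze_family",
    "star",
]


@dataclass
class TestResult:
    metabolite: str
    F: float
    p: float
    p_adj: float
    pairwise: dict[tuple[str, str], float]
    group_means: dict[str, float]
    group_sems: dict[str, float]
    n_per_group: dict[str, int]


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        if not np.all(np.isfinite(g)):
            raise ValueError("groups must be finite")
    return groups


def one_way_anova(*groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA; (F, p).

    Groups whose values are all identical across the board yield F = 0,
    p = 1 (scipy returns nan for zero within-group variance).
    """
    gs = _check_groups(list(groups))
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    F, p = sps.f_oneway(*gs)
    if not np.isfinite(F):  # zero within-group variance, nonzero between
        return float("inf"), 0.0
    return float(F), float(p)


def tukey_hsd(*groups) -> np.ndarray:
    """Studentized-range adjusted pairwise p-values.

    Returns the condensed upper-triangle order of ``itertools.combinations``
    over group indices.
    """
    gs = _check_groups(list(groups))
    if np.ptp(np.concatenate(gs)) == 0:
        return np.ones(len(gs) * (len(gs) - 1) // 2)
    res = sps.tukey_hsd(*gs)
    return np.array([res.pvalue[i, j] for i, j in combinations(range(len(gs)), 2)])


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def star(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 thresholds."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def analyze_family(
    table: pd.DataFrame,
    value_col: str = "value",
    line_col: str = "line",
    lines: tuple[str, ...] | None = None,
) -> list[TestResult]:
    """ANOVA + Tukey per metabolite, BH-FDR on the ANOVA p across metabolites.

    ``table`` is long-format with one measurement family (one ``kind``).
    """
    if lines is None:
        lines = tuple(pd.unique(table[line_col]))
    results = []
    for met, sub in table.groupby("metabolite", sort=True):
        groups = [sub.loc[sub[line_col] == ln, value_col].to_numpy() for ln in lines]
        F, p = one_way_anova(*groups)
        pw = tukey_hsd(*groups)
        results.append(
            TestResult(
                metabolite=str(met),
                F=F,
                p=p,
                p_adj=np.nan,
                pairwise={
                    pair: float(pv)
                    for pair, pv in zip(combinations(lines, 2), pw)
                },
                group_means={ln: float(np.mean(g)) for ln, g in zip(lines, groups)},
                group_sems={
                    ln: float(np.std(g, ddof=1) / np.sqrt(g.size))
                    for ln, g in zip(lines, groups)
                },
                n_per_group={ln: int(g.size) for ln, g in zip(lines, groups)},
            )
        )
    adj = bh_fdr([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"metabolite": r.metabolite, "F": r.F, "p": r.p, "p_adj": r.p_adj,
               "stars": star(r.p_adj)}
        for (a, b), pv in r.pairwise.items():
            row[f"tukey_{a}_vs_{b}"] = pv
        for ln, m in r.group_means.items():
            row[f"mean_{ln}"] = m
            row[f"sem_{ln}"] = r.group_sems[ln]
            row[f"n_{ln}"] = r.n_per_group[ln]
        rows.append(row)
    return pd.DataFrame(rows)
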