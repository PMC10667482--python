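"""Shared nonparametric statistics.

Omnibus comparisons of three or more groups use Kruskal-Wallis with Dunn's
post hoc z tests; two-group comparisons use the Wilcoxon rank-sum test.
All multiple-comparison families are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as ss
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p: float
    comparison: str = "omnibus"
    q: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p outside [0, 1]: {self.p}")


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    levels = sorted(pd.unique(labels).tolist())
    groups = [values[labels == lv] for lv in levels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    return levels, groups


def kruskal_wallis(values, labels) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df)."""
    levels, groups = _split_groups(values, labels)
    if len(levels) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    if np.unique(np.concatenate(groups)).size == 1:
        # every observation identical: H = 0 by definition
        return TestResult(statistic=0.0, p=1.0)
    stat, p = ss.kruskal(*groups)
    return TestResult(statistic=float(stat), p=float(p))


def dunn_posthoc(values, labels) -> list[TestResult]:
    """Dunn's pairwise z tests on mean ranks after a Kruskal-Wallis omnibus.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    where T = sum(t^3 - t) over tie groups; p-values are two-sided normal and
    BH-corrected across the pairwise family.
    """
    levels, groups = _split_groups(values, labels)
    if len(levels) < 2:
        raise ValueError("dunn_posthoc needs >= 2 groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = rankdata(pooled)
    mean_rank = {}
    start = 0
    for lv, g in zip(levels, groups):
        mean_rank[lv] = ranks[start : start + len(g)].mean()
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    results = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            ni, nj = len(groups[i]), len(groups[j])
            se = np.sqrt(var_base * (1.0 / ni + 1.0 / nj))
            if se == 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_rank[levels[i]] - mean_rank[levels[j]]) / se
                p = 2.0 * ss.norm.sf(abs(z))
            results.append(
                TestResult(statistic=float(z), p=float(min(p, 1.0)),
                           comparison=f"{levels[i]} vs {levels[j]}")
            )
    qs = benjamini_hochberg([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact enumeration when n1 + n2 <= 12 and the data are tie-free; otherwise
    the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (a.size + b.size <= 12 and tie_free) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = ss.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                  use_continuity=True)
    return TestResult(statistic=float(stat), p=float(p), comparison="a vs b")


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test (sum of hypergeometric probabilities <= observed)."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2x2 table")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("table entries must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise ValueError("table entries must be non-negative")
    odds, p = ss.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p))


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up q-values, input order preserved, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    mask = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def cohens_d(a, b) -> float:
    """Cohen's d with (n-1)-pooled standard deviation; sign preserved."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d needs >= 2 values per group")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def alpha_diversity(table, index: str = "shannon", rarefy_to: int | None = None,
                    seed: int = 0) -> pd.Series:
    """Per-sample alpha diversity.

    Shannon H = -sum p ln p (0 ln 0 := 0); Simpson is the Gini-Simpson index
    1 - sum p^2.  Computed on per-sample proportions; an optional fixed-seed
    rarefaction of counts is available via ``rarefy_to``.
    """
    from .tables_io import AbundanceTable, TableError, to_relative

    if index not in ("shannon", "simpson"):
        raise ValueError(f"unknown diversity index {index!r}")
    if rarefy_to is not None:
        if table.mode != "counts":
            raise TableError("rarefaction requires a counts-mode table")
        rng = np.random.default_rng(seed)
        counts = table.values().astype(int)
        if (counts.sum(axis=1) < rarefy_to).any():
            raise TableError("a sample has fewer counts than the rarefaction depth")
        rare = np.zeros_like(counts)
        for i, row in enumerate(counts):
            picks = rng.choice(np.repeat(np.arange(row.size), row), size=rarefy_to,
                               replace=False)
            rare[i] = np.bincount(picks, minlength=row.size)
        table = AbundanceTable(
            pd.DataFrame(rare, index=table.data.index, columns=table.data.columns),
            mode="counts",
        )
    rel = to_relative(table)
    p = rel.values()
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        vals = -terms.sum(axis=1)
    else:
        vals = 1.0 - (p**2).sum(axis=1)
    return pd.Series(vals, index=rel.data.index, name=index)


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Flatten a list of TestResult into the standard results-table layout."""
    return pd.DataFrame(
        {
            "comparison": [r.comparison for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
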