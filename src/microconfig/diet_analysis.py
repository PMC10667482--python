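"""Diet-pattern analysis: Kendall-tau ordination of food-frequency profiles,
per-item correlations with a group's median dietary centroid, and per-item
pairwise group comparisons.

This module composes the same ordination / centroid / statistics machinery
used for the microbiota (single implementation, two metrics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss

from .ordination import (CentroidDistanceResult, OrdinationResult,
                         PermanovaResult, median_centroid, pcoa, permanova)
from .stats_core import benjamini_hochberg, wilcoxon_rank_sum
from .transforms import kendall_tau_distance


@dataclass
class DietOrdination:
    ordination: OrdinationResult
    centroid: CentroidDistanceResult
    permanova: PermanovaResult


def diet_ordination(
    diet: pd.DataFrame,
    groups: pd.Series,
    reference: str = "control",
    metadata: pd.DataFrame | None = None,
    confounders: list | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> DietOrdination:
    """Kendall-tau distance -> PCoA -> reference median centroid -> PERMANOVA."""
    dm = kendall_tau_distance(diet)
    if np.allclose(dm.values, 0.0):
        raise ValueError("all diet profiles are identical: degenerate distance matrix")
    ordination = pcoa(dm, k=2)
    groups = groups.reindex(diet.index)
    centroid = median_centroid(ordination, reference, groups)
    meta = metadata.loc[diet.index].copy() if metadata is not None else pd.DataFrame(index=diet.index)
    meta["_group"] = groups
    perm = permanova(dm, meta, "_group", confounders=confounders,
                     n_perm=n_perm, seed=seed)
    return DietOrdination(ordination=ordination, centroid=centroid, permanova=perm)


def item_centroid_correlation(diet: pd.DataFrame,
                              centroid: CentroidDistanceResult) -> pd.DataFrame:
    """Spearman rho between each food item's consumption and the centroid
    distance, BH across items.

    A negative rho means higher consumption the closer a sample sits to the
    reference group's median dietary pattern, i.e. the item is associated with
    that pattern; positive means least associated.  Constant items are
    skipped with a warning.
    """
    common = diet.index.intersection(centroid.distances.index)
    dist = centroid.distances.loc[common].to_numpy()
    rows, skipped = [], 0
    for item in diet.columns:
        x = diet.loc[common, item].to_numpy(dtype=float)
        if np.unique(x).size == 1:
            skipped += 1
            continue
        res = ss.spearmanr(x, dist)
        rows.append({"food_id": item, "rho": float(res.statistic),
                     "p": float(res.pvalue)})
    if skipped:
        warnings.warn(f"{skipped} constant food items skipped", stacklevel=2)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def item_group_tests(diet: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Pairwise Wilcoxon tests per food item, BH across the item x pair grid.

    Direction is the group with the higher median consumption of the item.
    """
    groups = groups.reindex(diet.index).dropna()
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("item_group_tests needs >= 2 groups")
    pairs = [(levels[i], levels[j]) for i in range(len(levels))
             for j in range(i + 1, len(levels))]
    rows = []
    for item in diet.columns:
        series = diet.loc[groups.index, item]
        for a, b in pairs:
            xa = series[groups == a].to_numpy(dtype=float)
            xb = series[groups == b].to_numpy(dtype=float)
            res = wilcoxon_rank_sum(xa, xb)
            med = {a: float(np.median(xa)), b: float(np.median(xb))}
            rows.append({
                "food_id": item, "pair": f"{a} vs {b}",
                "statistic": res.statistic, "p": res.p,
                "direction": max(med, key=med.get),
            })
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out
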