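"""Genus - inflammatory-marker association.

Two complementary routes:

* simple linear regression of each marker on each (differentially abundant)
  genus, BH-corrected across the grid; and
* a compositionality-corrected correlation in the ReBoot/CCREPE spirit:
  the observed statistic is the Spearman correlation between the ranked
  marker and the genus relative abundance, and its null is built by
  permuting that genus across samples, renormalising every sample's
  composition back to sum 1, and recomputing the correlation.  The p-value
  is a two-sided normal tail of the observed statistic against the
  permutation null's mean and standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from scipy.stats import rankdata

from .stats_core import benjamini_hochberg
from .tables_io import AbundanceTable, TableError


def marker_genus_regression(
    markers: pd.DataFrame,
    table: AbundanceTable,
    genus_set: list | None = None,
    min_pairs: int = 10,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simple linear regression marker ~ genus abundance for every pair.

    Pairs with fewer than ``min_pairs`` complete observations or a constant
    predictor are skipped with a warning.  Returns the edge table (slope, p,
    BH q across the grid) and the per-marker count of associations with
    q < ``alpha``.
    """
    genus_set = list(genus_set) if genus_set is not None else table.genus_ids
    missing = set(genus_set) - set(table.genus_ids)
    if missing:
        raise ValueError(f"genera not in table: {sorted(missing)[:5]}")
    common = table.data.index.intersection(markers.index)
    rows = []
    skipped = 0
    for marker in markers.columns:
        m = markers.loc[common, marker].to_numpy(dtype=float)
        for genus in genus_set:
            x = table.data.loc[common, genus].to_numpy(dtype=float)
            ok = ~np.isnan(m) & ~np.isnan(x)
            if ok.sum() < min_pairs:
                skipped += 1
                continue
            if np.unique(x[ok]).size == 1:
                skipped += 1
                continue
            fit = ss.linregress(x[ok], m[ok])
            rows.append({
                "genus_id": genus, "marker_id": marker,
                "slope": float(fit.slope), "stderr": float(fit.stderr),
                "r": float(fit.rvalue), "p": float(fit.pvalue),
                "n": int(ok.sum()),
            })
    if skipped:
        warnings.warn(f"{skipped} marker-genus pairs skipped "
                      "(too few complete pairs or constant predictor)", stacklevel=2)
    edges = pd.DataFrame(rows)
    if edges.empty:
        return edges, pd.Series(dtype=int)
    edges["q"] = benjamini_hochberg(edges["p"].to_numpy())
    counts = (
        edges.loc[edges["q"] < alpha]
        .groupby("marker_id").size()
        .reindex(markers.columns, fill_value=0)
        .rename("n_significant")
    )
    return edges, counts


def permute_and_renormalize(x: np.ndarray, genus_idx: int,
                            perm: np.ndarray) -> np.ndarray:
    """Permute one genus column of a relative-abundance matrix and renormalise
    every sample back to sum 1.  Exposed for invariant checks."""
    out = x.copy()
    out[:, genus_idx] = x[perm, genus_idx]
    out /= out.sum(axis=1, keepdims=True)
    return out


def ccrepe_association(
    markers: pd.DataFrame,
    table: AbundanceTable,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-renormalisation corrected marker-genus correlations.

    For each (marker, genus) edge the observed measure is Spearman's rho
    between the ranked marker and the genus relative abundance.  The null is
    generated by permuting the genus across samples and renormalising each
    composition; only the permuted genus's renormalised column
    ``x_perm / (1 - x + x_perm)`` is needed for the correlation, which keeps
    the null fully vectorised.  Missing marker values are handled
    pairwise-complete, with n reported per edge.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if table.mode != "relative":
        raise TableError("ccrepe_association requires a relative-mode table")
    common = table.data.index.intersection(markers.index)
    if len(common) < 10:
        raise ValueError("fewer than 10 shared samples")
    x = table.data.loc[common].to_numpy(dtype=float)
    n = len(common)
    rng = np.random.default_rng(seed)

    marker_vals = {m: markers.loc[common, m].to_numpy(dtype=float)
                   for m in markers.columns}
    marker_masks = {m: ~np.isnan(v) for m, v in marker_vals.items()}

    def standardized_ranks(a: np.ndarray, axis: int = -1) -> np.ndarray:
        r = rankdata(a, axis=axis)
        r = r - r.mean(axis=axis, keepdims=True)
        norm = np.sqrt((r**2).sum(axis=axis, keepdims=True))
        norm[norm == 0] = 1.0
        return r / norm

    rows = []
    for j, genus in enumerate(table.genus_ids):
        xg = x[:, j]
        rest = 1.0 - xg
        idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
        xg_perm = xg[idx]                                  # (n_perm, n)
        xg_renorm = xg_perm / (rest[None, :] + xg_perm)    # renormalised column
        for marker in markers.columns:
            mask = marker_masks[marker]
            if mask.sum() < 10:
                continue
            mv = marker_vals[marker][mask]
            if np.unique(mv).size == 1 or np.unique(xg[mask]).size == 1:
                continue
            obs = float(ss.spearmanr(mv, xg[mask]).statistic)
            zm = standardized_ranks(mv)
            zn = standardized_ranks(xg_renorm[:, mask], axis=1)
            null = zn @ zm
            mu, sd = float(null.mean()), float(null.std(ddof=1))
            if sd == 0:
                continue
            z = (obs - mu) / sd
            p = float(2.0 * ss.norm.sf(abs(z)))
            rows.append({
                "genus_id": genus, "marker_id": marker, "rho": obs,
                "z": z, "p": min(p, 1.0), "null_mean": mu, "null_sd": sd,
                "n": int(mask.sum()), "n_perm": n_perm, "seed": seed,
            })
    edges = pd.DataFrame(rows)
    if not edges.empty:
        edges["q"] = benjamini_hochberg(edges["p"].to_numpy())
    return edges
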