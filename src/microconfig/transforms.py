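"""Rank normalisation and pairwise dissimilarity / correlation machinery.

The rank normalisation used throughout is
``(rank(x) - min(rank(x))) / (max(rank(x)) - min(rank(x)))`` with average
ranks for ties, which maps any non-constant vector onto [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .tables_io import AbundanceTable, TableError, to_relative

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-10


@dataclass
class DistanceMatrix:
    """Symmetric sample-pairwise dissimilarity matrix with a metric tag."""

    ids: list
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=_SYMMETRY_TOL):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(self.values).all():
            raise ValueError("distance matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def subset(self, ids) -> "DistanceMatrix":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)], self.metric)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, metric: str = "unknown") -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index), frame.to_numpy(dtype=float), metric)


def rank_normalize(x) -> np.ndarray:
    """Rank-normalise one feature vector to [0, 1] (average ranks for ties).

    A constant vector has zero rank range; it maps to all-zeros with a
    warning so degenerate simulated features do not halt a pipeline.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("rank_normalize needs a 1-d vector of length >= 2")
    r = rankdata(x)
    span = r.max() - r.min()
    if span == 0:
        warnings.warn("constant vector rank-normalised to all-zeros", stacklevel=2)
        return np.zeros_like(r)
    return (r - r.min()) / span


def rank_normalize_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Rank-normalise every column (feature) of a samples x features frame."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {c: rank_normalize(frame[c].to_numpy()) for c in frame.columns}
    return pd.DataFrame(out, index=frame.index)


def bray_curtis(table: AbundanceTable, on_relative: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|x-y| / sum(x+y) over genera.

    By default counts are converted to per-sample proportions first; pass
    ``on_relative=False`` to use raw values as given.
    """
    if table.mode == "counts" and on_relative:
        table = to_relative(table)
    values = table.values()
    if (values < 0).any():
        raise TableError("Bray-Curtis requires non-negative abundances")
    row_sums = values.sum(axis=1)
    if (row_sums == 0).any():
        bad = table.data.index[row_sums == 0][0]
        raise TableError(f"sample {bad!r} is all-zero; Bray-Curtis undefined")
    dist = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(table.sample_ids, dist, "bray_curtis")


def kendall_tau_distance(diet: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Kendall tau-b distance between sample diet profiles.

    For each sample pair the tie-corrected tau_b is computed over the food
    items, then mapped to a distance via ``(1 - tau) / 2`` in [0, 1].

    The computation is vectorised through item-pair sign vectors: with
    ``s_i[ab] = sign(x_i[a] - x_i[b])`` over all item pairs a < b,
    ``tau_b(i, j) = <s_i, s_j> / sqrt(|s_i|^2 |s_j|^2)``, which is exactly
    the tie-corrected tau_b.
    """
    X = diet.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("kendall_tau_distance needs at least two food items")
    a, b = np.triu_indices(m, k=1)
    signs = np.sign(X[:, a] - X[:, b])
    untied = (signs != 0).sum(axis=1).astype(float)
    if (untied == 0).any():
        bad = diet.index[untied == 0][0]
        raise ValueError(f"sample {bad!r} has a constant diet vector; tau undefined")
    tau = (signs @ signs.T) / np.sqrt(np.outer(untied, untied))
    tau = np.clip(tau, -1.0, 1.0)
    dist = (1.0 - tau) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(list(diet.index), dist, "kendall_tau")


def spearman_matrix(data, axis: str = "genera") -> pd.DataFrame:
    """Spearman rank correlation matrix between genera (columns) or samples
    (rows) of a samples x genera table.

    Constant vectors have undefined correlations; these are set to 0 with a
    warning and the diagonal is forced to 1.
    """
    frame = data.data if isinstance(data, AbundanceTable) else data
    if axis == "samples":
        frame = frame.T
    elif axis != "genera":
        raise ValueError(f"axis must be 'genera' or 'samples', got {axis!r}")
    values = frame.to_numpy(dtype=float)
    if values.shape[0] < 3:
        raise ValueError("spearman_matrix needs >= 3 observations per vector")
    ranks = rankdata(values, axis=0)
    constant = ranks.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "%d constant vectors in spearman_matrix; their correlations set to 0",
            int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=frame.columns, columns=frame.columns)
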