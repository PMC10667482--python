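"""Principal coordinates analysis, the median-centroid distance statistic,
and PERMANOVA with confounder adjustment.

The median-centroid statistic quantifies how far each sample's community sits
from a reference group's typical composition: the coordinate-wise median of
the reference samples on the first two principal coordinates defines the
centroid, and every sample's Euclidean distance to it in that plane is the
statistic.  Group differences in this distance are tested with
Kruskal-Wallis/Dunn.

PERMANOVA partitions the Gower-centred distance matrix sequentially
(Type-I, confounders entered before the term of interest, adonis-style) and
obtains the pseudo-F null distribution by permuting samples.  When a
confounder saturates the design (e.g. a patient identifier with the group
constant within patients) it is demoted to a permutation stratum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import TestResult, benjamini_hochberg, dunn_posthoc, kruskal_wallis
from .transforms import DistanceMatrix

logger = logging.getLogger(__name__)

_EIG_TOL_FACTOR = 1e-10


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues and explained-variance fractions."""

    coordinates: pd.DataFrame          # samples x PCo1..PCok
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # per retained axis, over positive eigenvalues

    @property
    def sample_ids(self) -> list:
        return list(self.coordinates.index)

    def to_tsv(self, path) -> None:
        self.coordinates.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class CentroidDistanceResult:
    """Per-sample Euclidean distance from a reference group's median centroid."""

    reference: str
    centroid: np.ndarray               # (k,) median reference coordinates
    distances: pd.Series               # per-sample distance, index = sample ids
    axes: int = 2


@dataclass
class PermanovaResult:
    terms: pd.DataFrame                # name, df, SS, R2, F, p
    n_perm: int
    seed: int
    strata: list = field(default_factory=list)

    @property
    def p(self) -> float:
        return float(self.terms["p"].dropna().iloc[0])

    def r2(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "R2"])

    def to_tsv(self, path) -> None:
        self.terms.to_csv(path, sep="\t", index=False)


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical metric multidimensional scaling (Gower double-centering).

    Coordinates are eigenvectors scaled by the square root of their (positive)
    eigenvalues; negative eigenvalues are excluded from the explained-variance
    denominator and ``k`` is truncated (with a warning) if fewer positive
    axes exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    b = _gower_center(dm.values)
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * _EIG_TOL_FACTOR
    positive = evals > tol
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError("distance matrix has no positive eigenvalues")
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    pos_evals = evals[:n_pos]
    coords = evecs[:, :k] * np.sqrt(pos_evals[:k])
    # deterministic sign: largest-magnitude loading per axis is positive
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1.0
    frame = pd.DataFrame(coords, index=dm.ids,
                         columns=[f"PCo{j + 1}" for j in range(k)])
    explained = pos_evals[:k] / pos_evals.sum()
    return OrdinationResult(frame, evals, explained)


def median_centroid(ordination: OrdinationResult, reference: str,
                    groups: pd.Series, axes: int = 2) -> CentroidDistanceResult:
    """Distance of every sample from the reference group's median centroid.

    The centroid is the coordinate-wise median of reference samples on the
    first ``axes`` principal coordinates (the first two by default, matching
    the planar statistic); distances are Euclidean in that subspace and are
    reported for all samples including the reference group itself.
    """
    coords = ordination.coordinates
    if axes > coords.shape[1]:
        raise ValueError(f"ordination has only {coords.shape[1]} axes")
    groups = groups.reindex(coords.index)
    ref_ids = groups.index[groups == reference]
    if len(ref_ids) == 0:
        raise ValueError(f"reference group {reference!r} absent from ordination")
    sub = coords.iloc[:, :axes]
    centroid = sub.loc[ref_ids].median(axis=0).to_numpy()
    dist = np.sqrt(((sub.to_numpy() - centroid) ** 2).sum(axis=1))
    return CentroidDistanceResult(
        reference=reference,
        centroid=centroid,
        distances=pd.Series(dist, index=coords.index, name="centroid_distance"),
        axes=axes,
    )


def centroid_group_test(centroid: CentroidDistanceResult, groups: pd.Series):
    """Kruskal-Wallis omnibus + Dunn pairwise tests on centroid distances."""
    groups = groups.reindex(centroid.distances.index).dropna()
    values = centroid.distances.loc[groups.index].to_numpy()
    omnibus = kruskal_wallis(values, groups.to_numpy())
    if groups.nunique() >= 3:
        pairwise = dunn_posthoc(values, groups.to_numpy())
    else:
        from .stats_core import wilcoxon_rank_sum

        levels = sorted(groups.unique())
        res = wilcoxon_rank_sum(values[groups == levels[0]], values[groups == levels[1]])
        res.comparison = f"{levels[0]} vs {levels[1]}"
        res.q = res.p
        pairwise = [res]
    return omnibus, pairwise


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _term_design(metadata: pd.DataFrame, term: str) -> np.ndarray:
    col = metadata[term]
    if col.isna().any():
        raise ValueError(f"term {term!r} has missing values")
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
        levels = pd.unique(col)
        if len(levels) < 2:
            raise ValueError(f"term {term!r} has a single level")
        dummies = pd.get_dummies(col.astype(str), drop_first=True)
        return dummies.to_numpy(dtype=float)
    x = col.to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(f"term {term!r} has a single level")
    return (x - x.mean())[:, None]


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, plus its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    rank = int((diag > diag.max() * 1e-10).sum()) if diag.size else 0
    q = q[:, :rank] if rank else q[:, :0]
    return q @ q.T, rank


def _strata_permuter(strata_labels: np.ndarray, interest: np.ndarray):
    """Return a function drawing a strata-respecting permutation.

    If the term of interest is constant within each stratum (e.g. study group
    within patient), whole strata of equal size are exchanged; otherwise
    samples are shuffled within strata.
    """
    strata = pd.Series(strata_labels)
    blocks = {lv: np.flatnonzero(strata.to_numpy() == lv) for lv in strata.unique()}
    constant_within = all(
        len(set(map(str, interest[idx]))) == 1 for idx in blocks.values()
    )
    if constant_within:
        by_size: dict[int, list[np.ndarray]] = {}
        for idx in blocks.values():
            by_size.setdefault(len(idx), []).append(idx)

        def permute(rng: np.random.Generator) -> np.ndarray:
            p = np.arange(len(strata_labels))
            for same_size in by_size.values():
                if len(same_size) < 2:
                    continue
                order = rng.permutation(len(same_size))
                for dest, src in zip(same_size, [same_size[i] for i in order]):
                    p[dest] = src
            return p

        return permute

    def permute(rng: np.random.Generator) -> np.ndarray:
        p = np.arange(len(strata_labels))
        for idx in blocks.values():
            p[idx] = rng.permutation(idx)
        return p

    return permute


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    term_of_interest: str,
    confounders: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    strata: list[str] | None = None,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA with confounders entered first.

    The pseudo-F of the term of interest is compared against ``n_perm`` free
    permutations of the samples (within strata when given); the p-value uses
    the +1 correction, so the smallest attainable value is 1/(n_perm + 1).
    A confounder that drives the term of interest or the residual to zero
    degrees of freedom is demoted to a permutation stratum with a warning.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    confounders = list(confounders or [])
    strata = list(strata or [])
    meta = metadata.loc[dm.ids]
    n = dm.n

    while True:
        designs = [_term_design(meta, t) for t in confounders]
        designs.append(_term_design(meta, term_of_interest))
        names = confounders + [term_of_interest]
        ones = np.ones((n, 1))
        cum = ones
        hats, ranks = [_hat(cum)[0]], [1]
        for x in designs:
            cum = np.hstack([cum, x])
            h, r = _hat(cum)
            hats.append(h)
            ranks.append(r)
        dfs = np.diff(ranks)
        df_res = n - ranks[-1]
        df_interest = dfs[-1]
        if df_interest > 0 and df_res > 0:
            break
        if not confounders:
            raise ValueError("design saturated with no confounder left to demote")
        # demote the widest confounder (typically the patient identifier)
        widths = [d.shape[1] for d in designs[:-1]]
        worst = confounders[int(np.argmax(widths))]
        logger.warning(
            "confounder %r saturates the design (term df=%d, residual df=%d); "
            "demoting it to a permutation stratum", worst, df_interest, df_res,
        )
        confounders.remove(worst)
        strata.append(worst)

    g = _gower_center(dm.values)
    ss_total = float(np.trace(g))
    deltas = [hats[i + 1] - hats[i] for i in range(len(designs))]
    ss_terms = np.array([float((m * g).sum()) for m in deltas])
    h_model = hats[-1] - hats[0]
    ss_res = ss_total - float((h_model * g).sum())

    m_int = deltas[-1]
    f_obs = (ss_terms[-1] / df_interest) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    if strata:
        key = meta[strata].astype(str).agg("|".join, axis=1).to_numpy()
        draw = _strata_permuter(key, meta[term_of_interest].to_numpy())
    else:
        draw = lambda r: r.permutation(n)  # noqa: E731

    count = 0
    for _ in range(n_perm):
        p = draw(rng)
        gp = g[np.ix_(p, p)]
        ss_int_p = float((m_int * gp).sum())
        ss_res_p = ss_total - float((h_model * gp).sum())
        f_p = (ss_int_p / df_interest) / (ss_res_p / df_res)
        if f_p >= f_obs:
            count += 1
    p_value = (1 + count) / (1 + n_perm)

    rows = []
    for name, df_t, ss_t in zip(names, dfs, ss_terms):
        rows.append({
            "term": name,
            "df": int(df_t),
            "SS": ss_t,
            "R2": ss_t / ss_total,
            "F": (ss_t / df_t) / (ss_res / df_res) if df_t else np.nan,
            "p": p_value if name == term_of_interest else np.nan,
        })
    rows.append({"term": "residual", "df": int(df_res), "SS": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "total", "df": n - 1, "SS": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return PermanovaResult(pd.DataFrame(rows), n_perm=n_perm, seed=seed, strata=strata)


def pairwise_permanova(
    dm: DistanceMatrix,
    groups: pd.Series,
    metadata: pd.DataFrame | None = None,
    confounders: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA for every group pair on the subset distance matrix, BH across pairs.

    Pairs are processed in canonical (sorted) order with per-pair seeds spawned
    from ``seed``, so the result is invariant to input ordering.
    """
    groups = groups.reindex(dm.ids).dropna()
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("pairwise_permanova needs >= 2 groups")
    pairs = [(levels[i], levels[j]) for i in range(len(levels))
             for j in range(i + 1, len(levels))]
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    rows = []
    for (a, b), sub_seed in zip(pairs, seeds):
        ids = [s for s in dm.ids if groups.get(s) in (a, b)]
        sub_dm = dm.subset(ids)
        meta = (metadata.loc[ids] if metadata is not None
                else pd.DataFrame(index=ids))
        meta = meta.copy()
        meta["_group"] = groups.loc[ids]
        res = permanova(sub_dm, meta, "_group", confounders=confounders,
                        n_perm=n_perm, seed=int(sub_seed.generate_state(1)[0] % 2**31))
        rows.append({
            "pair": f"{a} vs {b}",
            "df": int(res.terms.set_index("term").loc["_group", "df"]),
            "R2": res.r2("_group"),
            "F": float(res.terms.set_index("term").loc["_group", "F"]),
            "p": res.p,
        })
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out
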