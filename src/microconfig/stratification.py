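"""Stratification of one patient group into microbiota-configuration sub-clusters.

Samples from a single group are split in two by Ward-D2 clustering of the
sample-sample Spearman correlation of rank-normalised genus abundances.
The sub-cluster whose members sit closer (smaller mean distance) to the
reference (control) median centroid of the full-cohort ordination is labelled
"NM-like" (normal microbiota); the other "CDM-like" (Crohn's-disease-like).
A replication procedure applies the same clustering to an external cohort and
labels the clusters by marker-genus abundance instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .ordination import CentroidDistanceResult, OrdinationResult
from .stats_core import TestResult, wilcoxon_rank_sum
from .tables_io import AbundanceTable, TableError, to_relative
from .transforms import rank_normalize_table, spearman_matrix

logger = logging.getLogger(__name__)

NM_LABEL = "NM-like"
CDM_LABEL = "CDM-like"


@dataclass
class StratificationResult:
    """Two-way sub-clustering of a group with NM/CDM labels and evidence."""

    assignments: pd.Series            # sample -> cluster id (1..2)
    labels: dict                      # cluster id -> NM-like / CDM-like
    evidence: dict                    # cluster id -> mean reference-centroid distance
    sizes: dict                       # cluster id -> n samples
    silhouette: float | None = None

    def label_of(self, sample_id) -> str:
        return self.labels[int(self.assignments[sample_id])]

    @property
    def sample_labels(self) -> pd.Series:
        return self.assignments.map(lambda c: self.labels[int(c)]).rename("configuration")

    def to_tsv(self, path, distances: pd.Series | None = None) -> None:
        frame = self.assignments.rename("cluster").to_frame()
        frame["label"] = self.sample_labels
        if distances is not None:
            frame["centroid_distance"] = distances.reindex(frame.index)
        frame.to_csv(path, sep="\t", index_label="sample_id")


def stratify_group(table: AbundanceTable, k: int = 2,
                   silhouette_warn: float = 0.3) -> pd.Series:
    """Split one group's samples into k sub-clusters (k = 2 by default).

    Each genus is rank-normalised across the subgroup's samples, sample-sample
    Spearman correlation is computed on those profiles, and Ward-D2
    agglomeration of 1 - rho is cut at k.  A silhouette width below
    ``silhouette_warn`` flags a split with no real sub-structure; the default
    threshold of 0.3 was calibrated on single-configuration null simulations
    (their silhouettes stay below ~0.3 while planted two-configuration cohorts
    sit well above it).  The procedure is fully deterministic.
    """
    if table.n_samples < 2 * k:
        raise ValueError(f"need >= {2 * k} samples to form {k} clusters")
    ranked = rank_normalize_table(table.data)
    corr = spearman_matrix(ranked, axis="samples")
    dis = 1.0 - corr.to_numpy()
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    z = linkage(squareform(dis, checks=False), method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    clusters = pd.Series([relabel[lab] for lab in raw], index=table.data.index,
                         name="cluster")
    if clusters.nunique() == k and min(np.bincount(raw)[1:]) >= 2:
        sil = float(silhouette_score(dis, clusters.to_numpy(), metric="precomputed"))
        if sil < silhouette_warn:
            warnings.warn(
                f"silhouette {sil:.3f} < {silhouette_warn}: the split may be "
                "arbitrary (no detectable sub-structure)", stacklevel=2,
            )
    else:
        sil = None
    clusters.attrs["silhouette"] = sil
    return clusters


def gap_diagnostic(table: AbundanceTable, k_max: int = 6, n_ref: int = 10,
                   seed: int = 0) -> pd.Series:
    """Within-cluster dispersion gap versus permuted reference tables.

    Purely diagnostic: reported alongside the fixed k = 2 stratification,
    never used to change k.
    """
    rng = np.random.default_rng(seed)
    ranked = rank_normalize_table(table.data).to_numpy()

    def log_wk(data: np.ndarray, k: int) -> float:
        frame = pd.DataFrame(data, index=[f"s{i}" for i in range(data.shape[0])],
                             columns=table.data.columns)
        corr = spearman_matrix(frame, axis="samples").to_numpy()
        dis = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dis, 0.0)
        z = linkage(squareform(dis, checks=False), method="ward")
        labels = fcluster(z, t=k, criterion="maxclust")
        wk = 0.0
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if len(idx) > 1:
                wk += dis[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return np.log(wk + 1e-12)

    gaps = {}
    for k in range(1, k_max + 1):
        obs = log_wk(ranked, k)
        refs = [log_wk(rng.permuted(ranked, axis=0), k) for _ in range(n_ref)]
        gaps[k] = float(np.mean(refs) - obs)
    return pd.Series(gaps, name="gap")


def label_clusters(
    clusters: pd.Series,
    control_centroid: CentroidDistanceResult,
    ordination: OrdinationResult | None = None,
) -> StratificationResult:
    """Name the two sub-clusters by proximity to the reference median centroid.

    The cluster with the smaller mean distance to the (full-cohort) control
    centroid becomes NM-like, the other CDM-like.  Ties fall back to the
    median distance; a tie there too is an error.
    """
    if ordination is not None:
        missing = set(clusters.index) - set(ordination.sample_ids)
        if missing:
            raise ValueError(f"samples without ordination coordinates: {sorted(missing)[:5]}")
    dist = control_centroid.distances
    missing = set(clusters.index) - set(dist.index)
    if missing:
        raise ValueError(f"samples without centroid distances: {sorted(missing)[:5]}")
    ids = sorted(clusters.unique())
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 clusters, got {len(ids)}")
    means = {int(c): float(dist.loc[clusters.index[clusters == c]].mean()) for c in ids}
    if means[ids[0]] != means[ids[1]]:
        nm = min(ids, key=lambda c: means[int(c)])
    else:
        medians = {int(c): float(dist.loc[clusters.index[clusters == c]].median())
                   for c in ids}
        if medians[ids[0]] == medians[ids[1]]:
            raise ValueError("clusters tie on both mean and median centroid distance")
        nm = min(ids, key=lambda c: medians[int(c)])
    cdm = ids[0] if nm == ids[1] else ids[1]
    labels = {int(nm): NM_LABEL, int(cdm): CDM_LABEL}
    sizes = {int(c): int((clusters == c).sum()) for c in ids}
    return StratificationResult(
        assignments=clusters, labels=labels, evidence=means, sizes=sizes,
        silhouette=clusters.attrs.get("silhouette"),
    )


def replicate_stratification(
    external: AbundanceTable,
    normal_genera: list,
    cd_genera: list,
    min_overlap: float = 0.5,
) -> tuple[StratificationResult, pd.DataFrame]:
    """Replicate the two-configuration stratification on an external cohort.

    The external table is clustered exactly as :func:`stratify_group`; the
    clusters are then labelled by marker-set abundance: the cluster with the
    higher median summed relative abundance of the normal-associated genera is
    NM-like.  Both marker sets are compared between clusters by Wilcoxon.
    Requires at least ``min_overlap`` of each marker set present in the
    external genus universe.
    """
    present = set(external.genus_ids)
    checks = {}
    for name, genera in (("normal", normal_genera), ("cd", cd_genera)):
        if not genera:
            raise ValueError(f"empty {name} marker set")
        hit = [g for g in genera if g in present]
        frac = len(hit) / len(genera)
        if frac < min_overlap:
            missing = sorted(set(genera) - present)
            raise ValueError(
                f"external table shares only {frac:.0%} of the {name} marker "
                f"genera (need >= {min_overlap:.0%}); missing: {missing}"
            )
        checks[name] = hit
    rel = to_relative(external)
    clusters = stratify_group(external, k=2)
    sums = {name: rel.data[hit].sum(axis=1) for name, hit in checks.items()}
    ids = sorted(clusters.unique())
    med_normal = {int(c): float(sums["normal"][clusters == c].median()) for c in ids}
    if med_normal[ids[0]] == med_normal[ids[1]]:
        raise ValueError("clusters tie on normal-genera abundance")
    nm = max(ids, key=lambda c: med_normal[int(c)])
    cdm = ids[0] if nm == ids[1] else ids[1]
    labels = {int(nm): NM_LABEL, int(cdm): CDM_LABEL}
    rows = []
    for name, series in sums.items():
        a = series[clusters == nm].to_numpy()
        b = series[clusters == cdm].to_numpy()
        res = wilcoxon_rank_sum(a, b)
        rows.append({
            "marker_set": name,
            "median_nm": float(np.median(a)),
            "median_cdm": float(np.median(b)),
            "statistic": res.statistic,
            "p": res.p,
        })
    result = StratificationResult(
        assignments=clusters, labels=labels,
        evidence={int(c): med_normal[int(c)] for c in ids},
        sizes={int(c): int((clusters == c).sum()) for c in ids},
        silhouette=clusters.attrs.get("silhouette"),
    )
    return result, pd.DataFrame(rows)
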