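"""Co-abundance group (CAG) detection and CAG-level summaries.

CAGs are clusters of genera whose abundances co-vary across samples.  They
are detected by Ward-D2 agglomeration of the genus-genus Spearman correlation
matrix (dissimilarity 1 - rho), cutting the dendrogram at k clusters
(k = 4 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss
from scipy.cluster.hierarchy import fcluster, linkage

from .ordination import CentroidDistanceResult
from .tables_io import AbundanceTable, TableError
from .transforms import spearman_matrix


@dataclass
class CAGAssignment:
    """Mapping genus -> cluster id (1..k) with the Ward-D2 merge tree."""

    assignments: pd.Series      # index genus, values 1..k
    k: int
    linkage_matrix: np.ndarray
    labels: dict | None = None  # optional user-supplied id -> name map

    def members(self, cag_id: int) -> list:
        return list(self.assignments.index[self.assignments == cag_id])

    def to_tsv(self, path) -> None:
        frame = self.assignments.rename("cag_id").to_frame()
        if self.labels:
            frame["cag_label"] = self.assignments.map(self.labels)
        frame.to_csv(path, sep="\t", index_label="genus_id")


def detect_cags(table: AbundanceTable, k: int = 4,
                sqrt_transform: bool = False) -> CAGAssignment:
    """Cluster genera into k co-abundance groups.

    Dissimilarity is 1 - Spearman rho between genus abundance profiles
    (optionally square-rooted for Euclidean validity) followed by Ward-D2
    agglomeration (scipy ``linkage(method="ward")`` on the precomputed
    dissimilarity, the ward.D2 update).  Cluster ids are renumbered 1..k in
    order of first appearance along the genus list, so the assignment is
    deterministic.
    """
    if k < 1 or k > table.n_genera:
        raise ValueError(f"k={k} outside [1, {table.n_genera}]")
    if table.n_samples < 3:
        raise ValueError("detect_cags needs >= 3 samples")
    corr = spearman_matrix(table, axis="genera")
    dis = 1.0 - corr.to_numpy()
    np.fill_diagonal(dis, 0.0)
    if sqrt_transform:
        dis = np.sqrt(np.clip(dis, 0.0, None))
    from scipy.spatial.distance import squareform

    z = linkage(squareform(dis, checks=False), method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    assign = pd.Series([relabel[lab] for lab in raw], index=corr.index, name="cag_id")
    return CAGAssignment(assignments=assign, k=int(assign.max()), linkage_matrix=z)


def cag_abundance(table: AbundanceTable, assignment: CAGAssignment) -> pd.DataFrame:
    """Per-sample summed relative abundance of each CAG (columns cag_1..cag_k)."""
    if table.mode != "relative":
        raise TableError("cag_abundance requires a relative-mode table")
    missing = set(table.genus_ids) - set(assignment.assignments.index)
    if missing:
        raise TableError(f"genera missing from CAG assignment: {sorted(missing)[:10]}")
    groups = assignment.assignments.loc[table.genus_ids]
    out = table.data.T.groupby(groups).sum().T
    out.columns = [f"cag_{c}" for c in out.columns]
    return out


def cag_centroid_correlation(
    table: AbundanceTable,
    assignment: CAGAssignment,
    centroid: CentroidDistanceResult,
    mode: str = "member",
) -> pd.DataFrame:
    """Spearman correlation between abundance and centroid distance, by CAG.

    ``mode="member"`` (default) correlates each member genus individually and
    returns the per-genus rho grouped by CAG, for distributional comparison;
    ``mode="summed"`` correlates the per-CAG summed abundance instead.
    A negative rho means the genus/CAG is more abundant close to the reference
    centroid, i.e. associated with that group's typical composition.
    """
    common = table.data.index.intersection(centroid.distances.index)
    if len(common) < 3:
        raise TableError("fewer than 3 samples shared with the centroid distances")
    dist = centroid.distances.loc[common].to_numpy()
    if np.unique(dist).size == 1:
        raise ValueError("centroid distance vector is constant")
    if mode == "member":
        rows = []
        for genus in table.genus_ids:
            x = table.data.loc[common, genus].to_numpy()
            if np.unique(x).size == 1:
                rho = 0.0
            else:
                rho = ss.spearmanr(x, dist).statistic
            rows.append({"genus_id": genus,
                         "cag_id": int(assignment.assignments[genus]),
                         "rho": float(rho)})
        return pd.DataFrame(rows)
    if mode == "summed":
        abund = cag_abundance(table, assignment).loc[common]
        rows = [
            {"cag_id": int(col.split("_")[1]),
             "rho": float(ss.spearmanr(abund[col].to_numpy(), dist).statistic)}
            for col in abund.columns
        ]
        return pd.DataFrame(rows)
    raise ValueError(f"unknown mode {mode!r}")
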