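"""Tabular input/output and genus-level quality filtering.

All tables are tab-separated UTF-8 text with a header row.  The in-memory
containers are thin wrappers around :class:`pandas.DataFrame`:

* :class:`AbundanceTable` — samples x genera counts or per-sample proportions;
* sample metadata, diet-frequency and inflammatory-marker tables are plain
  DataFrames indexed by ``sample_id`` (validated by their readers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns every metadata table must carry
REQUIRED_METADATA_COLUMNS = ("patient_id", "group", "study")

#: recognised study-group labels
GROUPS = ("control", "CD", "HS")

_ROW_SUM_TOL = 1e-9


class TableError(ValueError):
    """Raised when a table violates its contract (parse error, bad values...)."""


@dataclass
class AbundanceTable:
    """Samples x genera abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and genus ids as columns.
        Values are non-negative counts or proportions.
    mode:
        ``"counts"`` or ``"relative"``.  In relative mode every row must sum
        to 1 within 1e-9.
    """

    data: pd.DataFrame
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise TableError(f"unknown abundance mode {self.mode!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate genus ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise TableError("abundance table contains non-finite values")
        if (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)][0]
            raise TableError(f"negative abundance in sample {bad!r}")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if off.any():
                bad = self.data.index[off][0]
                raise TableError(
                    f"relative-mode row does not sum to 1 (sample {bad!r}, "
                    f"sum {sums[off][0]:.12g})"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def genus_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genera(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def restrict_samples(self, sample_ids) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(sample_ids)], mode=self.mode)

    def to_tsv(self, path, orientation: str = "genera_rows") -> None:
        """Write the table; default orientation mirrors the common genus-rows layout."""
        frame = self.data.T if orientation == "genera_rows" else self.data
        label = "genus_id" if orientation == "genera_rows" else "sample_id"
        frame.to_csv(path, sep="\t", index_label=label)


def read_abundance_table(
    path,
    orientation: str = "auto",
    known_sample_ids=None,
) -> AbundanceTable:
    """Read a counts TSV into an :class:`AbundanceTable`.

    ``orientation`` is one of ``"genera_rows"`` (genus per row, samples in the
    header — the common layout), ``"samples_rows"`` or ``"auto"``.  Auto
    detection compares the header tokens against ``known_sample_ids`` when
    given, falling back to genus-rows.  Duplicate genus rows are summed;
    duplicate sample ids are an error.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        frame = raw.astype(float)
    except ValueError as exc:
        for col in raw.columns:
            bad = pd.to_numeric(raw[col], errors="coerce")
            mask = bad.isna() & raw[col].notna()
            if mask.any():
                row = raw.index[mask][0]
                raise TableError(
                    f"non-numeric value {raw.loc[row, col]!r} at row {row!r}, "
                    f"column {col!r}"
                ) from exc
        raise TableError(f"could not parse {path}: {exc}") from exc

    if orientation == "auto":
        if known_sample_ids is not None:
            header_hits = len(set(frame.columns) & set(known_sample_ids))
            index_hits = len(set(frame.index) & set(known_sample_ids))
            orientation = "genera_rows" if header_hits >= index_hits else "samples_rows"
        else:
            orientation = "genera_rows"

    if orientation == "genera_rows":
        frame = frame.T  # -> samples x genera
    elif orientation != "samples_rows":
        raise TableError(f"unknown orientation {orientation!r}")

    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise TableError(f"duplicate sample ids: {dupes}")
    if frame.columns.has_duplicates:
        n_dupes = int(frame.columns.duplicated().sum())
        logger.info("summing %d duplicate genus rows", n_dupes)
        frame = frame.T.groupby(level=0, sort=False).sum().T
    frame.index.name = None
    frame.columns.name = None
    return AbundanceTable(frame, mode="counts")


def aggregate_to_genus(asv_table: AbundanceTable, genus_of_asv: dict) -> AbundanceTable:
    """Optional pre-step: sum ASV columns sharing a genus label.

    ASVs whose genus label is missing/empty are dropped; the dropped count is
    logged.
    """
    labels = {a: genus_of_asv.get(a) for a in asv_table.genus_ids}
    keep = [a for a, g in labels.items() if g]
    dropped = asv_table.n_genera - len(keep)
    if dropped:
        logger.info("dropping %d ASVs without a genus assignment", dropped)
    if not keep:
        raise TableError("no ASV has a genus assignment")
    frame = asv_table.data[keep]
    frame = frame.T.groupby(lambda a: labels[a], sort=False).sum().T
    return AbundanceTable(frame, mode=asv_table.mode)


def prevalence_filter(table: AbundanceTable, min_fraction: float = 0.10) -> AbundanceTable:
    """Drop genera present (value strictly > 0) in fewer than ``min_fraction``
    of samples.  The boundary is inclusive: a genus present in exactly 10% of
    samples is retained at the default threshold."""
    if not 0 <= min_fraction <= 1:
        raise TableError(f"min_fraction must be in [0, 1], got {min_fraction}")
    presence = (table.values() > 0).mean(axis=0)
    keep = presence >= min_fraction
    removed = [g for g, k in zip(table.genus_ids, keep) if not k]
    if removed:
        logger.info("prevalence filter removed %d genera: %s", len(removed), removed[:20])
    if not keep.any():
        raise TableError("prevalence filter removed every genus")
    return AbundanceTable(table.data.loc[:, keep], mode=table.mode)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample proportions (rows sum to 1)."""
    if table.mode == "relative":
        return table
    values = table.values()
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = table.data.index[totals <= 0][0]
        raise TableError(f"sample {bad!r} has zero total abundance")
    frame = pd.DataFrame(
        values / totals[:, None], index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(frame, mode="relative")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by ``sample_id``.

    Requires columns ``patient_id``, ``group`` and ``study``; every sample
    maps to exactly one patient and group labels must be in :data:`GROUPS`.
    Optional clinical columns (age, hurley, drug exposures...) pass through.
    """
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in meta.columns:
            raise TableError(f"metadata is missing required column {col!r}")
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique().tolist()
        raise TableError(f"duplicate sample ids in metadata: {dupes}")
    unknown = set(meta["group"].unique()) - set(GROUPS)
    if unknown:
        raise TableError(f"unknown group labels {sorted(unknown)}; expected {GROUPS}")
    return meta


def read_feature_table(path) -> pd.DataFrame:
    """Read a samples x features TSV (diet frequencies or marker panel).

    Values must be non-negative; missing entries are allowed (markers) and
    kept as NaN.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        raise TableError("duplicate sample ids")
    values = frame.to_numpy(dtype=float)
    if np.nanmin(values) < 0 if values.size else False:
        raise TableError("negative values in feature table")
    return frame


def align_samples(tables: dict):
    """Restrict every table in ``tables`` (name -> AbundanceTable | DataFrame)
    to the common sample universe, in one canonical (sorted) order.

    Returns the aligned dict; dropped ids are logged per table.
    """
    if len(tables) < 2:
        raise TableError("align_samples needs at least two tables")

    def ids_of(obj):
        return obj.data.index if isinstance(obj, AbundanceTable) else obj.index

    common = None
    for obj in tables.values():
        ids = set(ids_of(obj))
        common = ids if common is None else common & ids
    if not common:
        raise TableError("tables share no sample ids")
    order = sorted(common)
    out = {}
    for name, obj in tables.items():
        dropped = set(ids_of(obj)) - common
        if dropped:
            logger.info("align_samples dropped %d ids from %s", len(dropped), name)
        if isinstance(obj, AbundanceTable):
            out[name] = AbundanceTable(obj.data.loc[order], mode=obj.mode)
        else:
            out[name] = obj.loc[order]
    return out
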