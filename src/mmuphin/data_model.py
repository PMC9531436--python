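"""Core containers, IO, QC filters, transforms and community dissimilarities.

The canonical in-memory layout is samples x features. Feature tables are
backed by a :class:`pandas.DataFrame` with sample IDs as the index and
feature IDs as columns; all downstream modules consume this orientation.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

#: Canonical taxonomic ranks, coarsest to finest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"


class FeatureTableError(ValueError):
    """Raised when a feature table violates its invariants."""


@dataclass
class FeatureTable:
    """Sample-by-feature non-negative abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample IDs as index, feature IDs as columns, and
        non-negative numeric values (counts or relative abundances).
    is_relative:
        True when every row sums to one (relative abundances).
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample IDs: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate feature IDs: {dups}")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isnan(values).any():
            raise FeatureTableError("missing (NaN) abundance values")
        if (values < 0).any():
            raise FeatureTableError("negative abundance values")
        if self.is_relative:
            rowsums = values.sum(axis=1)
            if not np.allclose(rowsums, 1.0, atol=1e-8):
                raise FeatureTableError(
                    "is_relative=True but row sums deviate from 1 by more than 1e-8"
                )

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), is_relative=self.is_relative)

    def with_values(self, values: np.ndarray, is_relative: bool | None = None) -> "FeatureTable":
        """New table with the same IDs but different values."""
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        rel = self.is_relative if is_relative is None else is_relative
        return FeatureTable(df, is_relative=rel)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(sample_ids)], is_relative=self.is_relative)

    def write_tsv(self, path: str | os.PathLike) -> None:
        """Write as TSV, samples in rows, deterministic column order."""
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


@dataclass
class SampleMetadata:
    """Per-sample metadata aligned with a :class:`FeatureTable`.

    ``batch`` is the technical grouping corrected for; ``study`` defaults to
    batch when not given.  ``subject`` optionally groups repeated measures.
    Remaining columns are covariates (categorical or continuous).  Missing
    categorical values become the distinct level ``"missing"``; they are
    never imputed.
    """

    data: pd.DataFrame
    batch_col: str = "batch"
    study_col: str | None = None
    subject_col: str | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FeatureTableError("duplicate sample IDs in metadata")
        if self.batch_col not in self.data.columns:
            raise KeyError(f"batch column {self.batch_col!r} not in metadata")
        for col in self.data.columns:
            s = self.data[col]
            if not pd.api.types.is_numeric_dtype(s):
                self.data[col] = s.astype("object").where(s.notna(), "missing")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def batch(self) -> pd.Series:
        return self.data[self.batch_col].astype(str)

    @property
    def study(self) -> pd.Series:
        col = self.study_col or self.batch_col
        return self.data[col].astype(str)

    @property
    def subject(self) -> pd.Series | None:
        if self.subject_col is None:
            return None
        return self.data[self.subject_col].astype(str)

    def aligned_to(self, table: FeatureTable) -> "SampleMetadata":
        """Metadata reindexed to a table's samples; errors on mismatch."""
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise FeatureTableError(f"metadata missing samples: {sorted(missing)[:5]}")
        return SampleMetadata(
            self.data.loc[table.sample_ids].copy(),
            batch_col=self.batch_col,
            study_col=self.study_col,
            subject_col=self.subject_col,
        )


@dataclass
class TaxonomyMap:
    """feature_id -> ordered lineage (kingdom ... genus).

    Lineages shorter than the full rank list, or containing the literal
    ``"unclassified"``, are treated as unclassified at the absent ranks.
    """

    lineages: Mapping[str, Sequence[str]]
    ranks: Sequence[str] = RANKS

    def lineage_at(self, feature_id: str, rank: str) -> tuple[str, bool]:
        """Name of the taxon at ``rank``; second value marks classified.

        Unclassified features are named ``"<deepest classified parent>
        unclassified"`` so that e.g. OTUs known only to family level pool
        into a per-family unclassified bin.
        """
        if feature_id not in self.lineages:
            raise KeyError(f"feature {feature_id!r} absent from taxonomy map")
        idx = list(self.ranks).index(rank)
        lin = [str(x) for x in self.lineages[feature_id]]
        if idx < len(lin) and lin[idx].lower() != UNCLASSIFIED:
            return lin[idx], True
        parent = UNCLASSIFIED
        for name in lin[:idx][::-1]:
            if name.lower() != UNCLASSIFIED:
                parent = name
                break
        return f"{parent} {UNCLASSIFIED}", False


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_feature_table(
    path: str | os.PathLike,
    orientation: str = "samples",
) -> FeatureTable:
    """Read a TSV abundance table.

    Parameters
    ----------
    orientation:
        ``"samples"`` if samples are in rows, ``"features"`` if features are
        in rows (classic BIOM-TSV export with a ``#OTU ID`` header); the
        table is transposed to the canonical samples x features layout.
    """
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("# Constructed from biom file") else 0
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip, comment=None)
    if str(df.index.name or "").strip().lstrip("#").strip().upper() == "OTU ID":
        orientation = "features"
    if orientation == "features":
        df = df.T
    elif orientation != "samples":
        raise ValueError("orientation must be 'samples' or 'features'")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FeatureTableError(f"non-numeric abundance values in {path}: {exc}") from exc
    return FeatureTable(df, is_relative=False)


def read_metadata(
    path: str | os.PathLike,
    batch_col: str = "batch",
    study_col: str | None = None,
    subject_col: str | None = None,
) -> SampleMetadata:
    """Read a TSV metadata table (first column: sample ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df, batch_col=batch_col, study_col=study_col, subject_col=subject_col)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def tss_normalize(table: FeatureTable) -> FeatureTable:
    """Total-sum scaling: divide each sample row by its total.

    Idempotent; errors on all-zero sample rows.
    """
    values = table.values
    totals = values.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(zero)[:5]]
        raise FeatureTableError(f"all-zero sample rows cannot be normalized: {bad}")
    return table.with_values(values / totals[:, None], is_relative=True)


def arcsin_sqrt_transform(table: FeatureTable) -> np.ndarray:
    """Variance-stabilizing arcsin(sqrt(p)) of relative abundances.

    Output is in [0, pi/2]. Requires a relative-abundance table.
    """
    if not table.is_relative:
        raise FeatureTableError("arcsin-sqrt transform requires relative abundances")
    values = table.values
    if (values < 0).any() or (values > 1 + 1e-12).any():
        raise FeatureTableError("values outside [0, 1]")
    return np.arcsin(np.sqrt(np.clip(values, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def filter_quality(
    table: FeatureTable,
    studies: pd.Series | Sequence[str] | None = None,
    min_abund: float = 5e-5,
    min_prev: float = 0.10,
    min_depth: int = 3000,
) -> FeatureTable:
    """Depth and abundance/prevalence quality-control filter for count tables.

    Samples with total count strictly below ``min_depth`` are dropped first.
    A feature is retained when, within at least one study, its relative
    abundance strictly exceeds ``min_abund`` in at least a ``min_prev``
    fraction of that study's samples.  ID order is preserved.
    """
    if table.is_relative:
        raise FeatureTableError("quality filter expects a count table")
    values = table.values
    depth = values.sum(axis=1)
    keep_samples = depth >= min_depth
    if not keep_samples.any():
        raise FeatureTableError("quality filter removed every sample")
    data = table.data.loc[keep_samples]
    if studies is None:
        study_labels = pd.Series("all", index=data.index)
    else:
        study_labels = pd.Series(np.asarray(studies, dtype=object), index=table.data.index)
        study_labels = study_labels.loc[data.index].astype(str)

    kept = np.zeros(data.shape[1], dtype=bool)
    vals = data.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    rel = np.divide(vals, totals[:, None], out=np.zeros_like(vals), where=totals[:, None] > 0)
    for study in study_labels.unique():
        rows = (study_labels == study).to_numpy()
        prev = (rel[rows] > min_abund).mean(axis=0)
        kept |= prev >= min_prev
    if not kept.any():
        raise FeatureTableError("quality filter removed every feature")
    return FeatureTable(data.loc[:, data.columns[kept]], is_relative=False)


def aggregate_taxonomy(table: FeatureTable, taxonomy: TaxonomyMap, rank: str) -> FeatureTable:
    """Sum features by lineage truncated at ``rank``.

    Features unclassified at the rank pool into a ``"<parent> unclassified"``
    bin keyed by their deepest classified ancestor.  Per-sample totals are
    conserved exactly.
    """
    groups: dict[str, list[str]] = {}
    for fid in table.feature_ids:
        name, _ = taxonomy.lineage_at(fid, rank)
        groups.setdefault(name, []).append(fid)
    out = {}
    for name, members in groups.items():
        out[name] = table.data[members].sum(axis=1)
    df = pd.DataFrame(out, index=table.data.index)
    return FeatureTable(df, is_relative=table.is_relative)


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------

def _check_no_empty_rows(values: np.ndarray) -> None:
    if (values.sum(axis=1) <= 0).any():
        raise FeatureTableError("all-zero sample rows have undefined dissimilarity")


def bray_curtis(table: FeatureTable | np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix, D[a,b] = 1 - 2 sum(min) / sum(total)."""
    values = table.values if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    _check_no_empty_rows(values)
    return squareform(pdist(values, metric="braycurtis"))


def jaccard(table: FeatureTable | np.ndarray) -> np.ndarray:
    """Binary Jaccard dissimilarity on presence/absence, 1 - |A&B| / |A|B|."""
    values = table.values if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    _check_no_empty_rows(values)
    return squareform(pdist(values > 0, metric="jaccard"))


def root_jsd(table: FeatureTable | np.ndarray) -> np.ndarray:
    """Root Jensen-Shannon divergence on relative abundances (natural log).

    Rows are re-closed to sum to one; 0*log(0) is taken as 0.
    """
    values = table.values if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    _check_no_empty_rows(values)
    p = values / values.sum(axis=1, keepdims=True)
    n = p.shape[0]
    out = np.zeros((n, n))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
        ent = -(p * logp).sum(axis=1)  # per-row Shannon entropy
        for a in range(n):
            m = 0.5 * (p[a][None, :] + p[a + 1:])
            logm = np.where(m > 0, np.log(m), 0.0)
            ent_m = -(m * logm).sum(axis=1)
            jsd = ent_m - 0.5 * (ent[a] + ent[a + 1:])
            out[a, a + 1:] = out[a + 1:, a] = np.sqrt(np.clip(jsd, 0.0, None))
    return out


DISSIMILARITIES = {
    "braycurtis": bray_curtis,
    "jaccard": jaccard,
    "rjsd": root_jsd,
}


def dissimilarity(table: FeatureTable | np.ndarray, metric: str = "braycurtis") -> np.ndarray:
    """Dispatch to a named dissimilarity ("braycurtis", "jaccard", "rjsd")."""
    try:
        fn = DISSIMILARITIES[metric]
    except KeyError:
        raise ValueError(f"unknown dissimilarity {metric!r}; choose from {sorted(DISSIMILARITIES)}")
    return fn(table)
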