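"""In-memory containers and tab-separated I/O.

A :class:`CountMatrix` holds an integer feature × sample count table together
with a two-level group label per sample; a :class:`FeatureMap` holds the
many-to-one mapping of feature IDs (exons, transcripts, equivalence classes)
to gene IDs that serves as the aggregation key.

All on-disk formats are plain tab-separated text: count matrices with a header
row of sample IDs and feature IDs in the first column; sample annotations as
two columns (sample_id, group); feature maps as two columns
(feature_id, gene_id), with an optional comma-separated multi-gene third form
handled by the multi-gene filter in :mod:`featde.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "FeatureMap",
    "read_counts",
    "write_counts",
    "read_groups",
    "write_groups",
    "read_feature_map",
    "write_feature_map",
]


@dataclass
class CountMatrix:
    """Integer counts (features × samples) with a two-group sample design."""

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            raise ValueError("feature IDs must be unique")
        if not self.counts.columns.is_unique:
            raise ValueError("sample IDs must be unique")
        self.groups = pd.Series(self.groups).reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.counts.columns[self.groups.isna()])
            raise ValueError(f"samples without a group label: {missing}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def group_levels(self) -> list:
        """Group levels in order of first appearance in the sample annotation."""
        return list(dict.fromkeys(self.groups))

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[feature_ids], self.groups.copy())

    def subset_samples(self, sample_ids, groups=None) -> "CountMatrix":
        """Restrict to ``sample_ids``; optionally relabel their groups."""
        g = self.groups.loc[sample_ids] if groups is None else pd.Series(groups, index=sample_ids)
        return CountMatrix(self.counts.loc[:, sample_ids], g)

    def require_two_groups(self, min_per_group: int = 2) -> None:
        levels = self.group_levels
        if len(levels) != 2:
            raise ValueError(f"exactly two group levels required, got {levels}")
        sizes = self.groups.value_counts()
        if (sizes < min_per_group).any():
            raise ValueError(
                f"each group needs >= {min_per_group} samples, got {dict(sizes)}"
            )


@dataclass
class FeatureMap:
    """Many-to-one mapping feature_id → gene_id.

    ``level`` records the feature level ('exon', 'transcript', 'tcc', or
    'gene') for bookkeeping; it does not change behaviour.
    """

    mapping: pd.Series
    level: str = field(default="exon")

    def __post_init__(self) -> None:
        self.mapping = pd.Series(self.mapping)
        if not self.mapping.index.is_unique:
            raise ValueError("feature IDs must map to exactly one gene")
        if self.mapping.isna().any() or (self.mapping.astype(str) == "").any():
            raise ValueError("gene IDs must be nonempty")

    @property
    def feature_ids(self) -> pd.Index:
        return self.mapping.index

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.mapping.unique())

    def genes_of(self, feature_ids) -> pd.Series:
        return self.mapping.loc[feature_ids]

    def subset(self, feature_ids) -> "FeatureMap":
        return FeatureMap(self.mapping.loc[feature_ids], level=self.level)

    def features_per_gene(self, feature_ids=None) -> pd.Series:
        m = self.mapping if feature_ids is None else self.mapping.loc[feature_ids]
        return m.groupby(m).size()


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str, comment="#")
    if df["sample_id"].iloc[0] == "sample_id":  # tolerate a header row
        df = df.iloc[1:]
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_groups(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_feature_map(path, level: str = "exon"):
    """Read a feature→gene table.

    Two columns give a plain map.  Rows whose second field contains a
    comma-separated list of genes form a multi-map; the result is then a plain
    pandas Series of feature → set-of-genes suitable for
    :func:`featde.pipeline.remove_multigene_features`.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "gene_id"],
                     dtype=str, comment="#")
    if df["feature_id"].iloc[0] == "feature_id":
        df = df.iloc[1:]
    if df["gene_id"].str.contains(",").any():
        multi = pd.Series(
            [set(g.split(",")) for g in df["gene_id"]],
            index=df["feature_id"].values,
        )
        return multi
    return FeatureMap(pd.Series(df["gene_id"].values, index=df["feature_id"].values),
                      level=level)


def write_feature_map(fm: FeatureMap, path) -> None:
    pd.DataFrame({"feature_id": fm.mapping.index, "gene_id": fm.mapping.values}).to_csv(
        path, sep="\t", header=False, index=False
    )
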