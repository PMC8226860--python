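"""Relative abundances, rank aggregation and the dominant-phylum rule."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, FeatureKind, Rank, ValidationError

__all__ = ["DominantPartition", "to_relative", "collapse_rank",
           "dominant_partition", "read_rank_mapping"]


@dataclasses.dataclass(frozen=True)
class DominantPartition:
    """Dominant features plus the pooled "Others" residual per sample.

    A feature is dominant when its relative abundance exceeds the threshold
    in *every* sample; everything else is summed into ``others_mass``, so for
    each sample the dominant proportions plus others_mass equal 1.
    """

    sample_ids: tuple[str, ...]
    dominant_ids: tuple[str, ...]
    per_sample_props: np.ndarray  # samples x dominant features
    others_mass: np.ndarray  # per sample
    threshold: float

    def mean_relative_abundance(self) -> pd.Series:
        """Mean of per-sample proportions per dominant feature, plus Others."""
        means = pd.Series(
            self.per_sample_props.mean(axis=0), index=list(self.dominant_ids)
        ).sort_values(ascending=False)
        means["Others"] = float(self.others_mass.mean())
        return means


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample proportions (no-op on relative input)."""
    if table.is_relative:
        return table
    sums = table.values.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValidationError(
            f"all-zero sample row: {table.sample_ids[int(zero[0])]!r}"
        )
    return dataclasses.replace(
        table, values=table.values / sums[:, None], is_relative=True
    )


def collapse_rank(
    table: AbundanceTable, mapping: Mapping[str, str], rank: Rank | str | None = None
) -> AbundanceTable:
    """Sum child features into parent labels; per-sample mass is conserved.

    Every feature must be mapped. Parent columns appear in first-use order.
    """
    missing = [f for f in table.feature_ids if f not in mapping]
    if missing:
        raise ValidationError(f"unmapped feature(s): {missing[:5]}")
    parents: list[str] = []
    index: dict[str, int] = {}
    for f in table.feature_ids:
        p = mapping[f]
        if p not in index:
            index[p] = len(parents)
            parents.append(p)
    out = np.zeros((table.n_samples, len(parents)))
    for j, f in enumerate(table.feature_ids):
        out[:, index[mapping[f]]] += table.values[:, j]
    new_rank = table.rank
    if rank is not None:
        new_rank = Rank(rank)
    return AbundanceTable(
        sample_ids=table.sample_ids,
        feature_ids=tuple(parents),
        values=out,
        feature_kind=table.feature_kind,
        rank=new_rank,
        is_relative=table.is_relative,
    )


def dominant_partition(
    table: AbundanceTable, threshold: float = 0.01
) -> DominantPartition:
    """Split a relative taxonomic table into dominant features and "Others".

    Dominance requires relative abundance strictly greater than ``threshold``
    in all samples (the default 1% rule).
    """
    if not table.is_relative:
        raise ValidationError("dominant_partition requires a relative table")
    if table.feature_kind is not FeatureKind.taxon:
        raise ValidationError("dominant_partition applies to taxonomic tables")
    keep = np.all(table.values > threshold, axis=0)
    props = table.values[:, keep]
    others = 1.0 - props.sum(axis=1)
    # guard against float residue pushing slightly below 0
    others = np.clip(others, 0.0, None)
    return DominantPartition(
        sample_ids=table.sample_ids,
        dominant_ids=tuple(np.array(table.feature_ids)[keep]),
        per_sample_props=props,
        others_mass=others,
        threshold=threshold,
    )


def read_rank_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column (child, parent) TSV without a header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"], dtype=str)
    if df["child"].duplicated().any():
        dup = df.loc[df["child"].duplicated(), "child"].iloc[0]
        raise ValidationError(f"duplicate child feature in mapping: {dup!r}")
    return dict(zip(df["child"], df["parent"]))
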