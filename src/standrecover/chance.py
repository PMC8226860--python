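"""Deterministic vs stochastic partition of community change.

The internal variation of a reference stand (its mean pairwise distance,
R0) anchors two components of change in a focal stand:

    D = (mean distance between reference and focal samples) - R0
    S = (mean distance within the focal stand) - R0

The importance of chance is |S| / (|D| + |S|): values below 0.5 mean the
deterministic component dominates, values above 0.5 the stochastic one.
The reference stand itself is assigned importance 1 by convention.

Distances are Euclidean on relative abundances; the statistic is invariant
to rescaling all distances by a positive constant, so the fraction-vs-
percent choice for proportions does not affect it.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from .composition import to_relative
from .datamodel import (
    AbundanceTable,
    DistanceMatrix,
    StudyMetadata,
    ValidationError,
)
from .ordination import euclidean

__all__ = ["ChancePartition", "reference_point", "chance_partition",
           "partition_study", "partitions_frame"]


@dataclasses.dataclass(frozen=True)
class ChancePartition:
    reference_stand: str
    focal_stand: str
    reference_point: float  # mean pairwise distance within the reference stand
    cross_mean: float  # mean reference x focal pairwise distance
    within_focal_mean: float
    D: float  # deterministic change
    S: float  # stochastic change
    importance_of_chance: float  # in [0, 1]
    regime: str  # deterministic | stochastic | reference


def _pair_indices(dm: DistanceMatrix, sample_ids) -> np.ndarray:
    try:
        return np.array([dm.sample_ids.index(s) for s in sample_ids])
    except ValueError as exc:
        raise ValidationError(f"sample missing from distance matrix: {exc}") from exc


def reference_point(
    dm: DistanceMatrix, meta: StudyMetadata, reference_stand: str
) -> float:
    """Mean pairwise distance among the reference stand's samples."""
    ids = meta.samples_of(reference_stand)
    if len(ids) < 2:
        raise ValidationError(
            f"reference stand {reference_stand!r} has fewer than 2 samples"
        )
    idx = _pair_indices(dm, ids)
    sub = dm.d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def chance_partition(
    dm: DistanceMatrix,
    meta: StudyMetadata,
    reference_stand: str,
    focal_stand: str,
    cross_method: str = "pairs",
) -> ChancePartition:
    """Partition the focal stand's change into D and S relative to a reference.

    ``cross_method`` "pairs" (default) uses the mean over all reference x
    focal sample pairs; "centroid" uses the distance between the two stand
    centroids in the embedding implied by mean coordinates of raw distances
    — offered for sensitivity analysis only.
    """
    r0 = reference_point(dm, meta, reference_stand)
    if focal_stand == reference_stand:
        return ChancePartition(
            reference_stand, focal_stand, r0, r0, r0,
            D=0.0, S=0.0, importance_of_chance=1.0, regime="reference",
        )
    focal_ids = meta.samples_of(focal_stand)
    if len(focal_ids) < 2:
        raise ValidationError(f"focal stand {focal_stand!r} has fewer than 2 samples")
    ref_idx = _pair_indices(dm, meta.samples_of(reference_stand))
    foc_idx = _pair_indices(dm, focal_ids)
    if cross_method == "pairs":
        cross = float(dm.d[np.ix_(ref_idx, foc_idx)].mean())
    elif cross_method == "centroid":
        # mean of cross distances minus half the within-spreads, floored at 0:
        # a distance-only surrogate for the between-centroid separation
        sub_r = dm.d[np.ix_(ref_idx, ref_idx)]
        sub_f = dm.d[np.ix_(foc_idx, foc_idx)]
        iur = np.triu_indices(len(ref_idx), k=1)
        iuf = np.triu_indices(len(foc_idx), k=1)
        raw = (dm.d[np.ix_(ref_idx, foc_idx)] ** 2).mean() \
            - 0.5 * (sub_r[iur] ** 2).mean() - 0.5 * (sub_f[iuf] ** 2).mean()
        cross = float(np.sqrt(max(raw, 0.0)))
    else:
        raise ValidationError(f"unknown cross_method {cross_method!r}")
    sub_f = dm.d[np.ix_(foc_idx, foc_idx)]
    iuf = np.triu_indices(len(foc_idx), k=1)
    within_focal = float(sub_f[iuf].mean())

    D = cross - r0
    S = within_focal - r0
    denom = abs(D) + abs(S)
    if denom == 0.0:
        warnings.warn(
            "both change components are zero; importance of chance set to 1 "
            "(reference convention)", stacklevel=2)
        importance = 1.0
    else:
        importance = abs(S) / denom
    regime = "deterministic" if importance < 0.5 else "stochastic"
    return ChancePartition(
        reference_stand, focal_stand, r0, cross, within_focal,
        D=D, S=S, importance_of_chance=importance, regime=regime,
    )


def partition_study(
    tables: Mapping[str, Mapping[str, AbundanceTable]],
    meta: StudyMetadata,
    reference_stand: str,
) -> list[tuple[str, str, ChancePartition]]:
    """Chance partitions for every (group, aspect, stand) of a study.

    ``tables[group][aspect]`` holds the class-level taxonomic table
    (aspect "structure") and the KEGG level-3 table (aspect "function") per
    microbial group. Returns (group, aspect, partition) for each stand,
    including the reference rows at importance 1.
    """
    out: list[tuple[str, str, ChancePartition]] = []
    for group, aspects in tables.items():
        for aspect, table in aspects.items():
            dm = euclidean(to_relative(table))
            for stand in meta.stands:
                out.append(
                    (group, aspect, chance_partition(dm, meta, reference_stand, stand))
                )
    return out


def partitions_frame(
    partitions: list[tuple[str, str, ChancePartition]]
) -> pd.DataFrame:
    """Tabulate partitions: one row per (group, aspect, stand)."""
    rows = []
    for group, aspect, cp in partitions:
        rows.append({
            "group": group,
            "aspect": aspect,
            "stand": cp.focal_stand,
            "reference_point": cp.reference_point,
            "D": cp.D,
            "S": cp.S,
            "importance_of_chance": cp.importance_of_chance,
            "regime": cp.regime,
        })
    return pd.DataFrame(rows)
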