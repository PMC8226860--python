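"""Distance matrices (Bray-Curtis, Euclidean, single-variable) and PCoA."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .composition import to_relative
from .datamodel import AbundanceTable, DistanceMatrix, ValidationError

__all__ = ["OrdinationResult", "bray_curtis", "euclidean", "env_distance", "pcoa"]


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between samples.

    Counts are first converted to relative abundances, which makes the
    distance invariant to per-sample sequencing depth.
    """
    rel = to_relative(table)
    d = squareform(pdist(rel.values, metric="braycurtis"))
    return DistanceMatrix(rel.sample_ids, d, "bray_curtis")


def euclidean(table: AbundanceTable) -> DistanceMatrix:
    """Euclidean distance between sample rows of a relative-abundance table."""
    if not table.is_relative:
        raise ValidationError("euclidean distance is defined on relative abundances")
    d = squareform(pdist(table.values, metric="euclidean"))
    return DistanceMatrix(table.sample_ids, d, "euclidean")


def env_distance(
    values: Sequence[float] | pd.Series,
    sample_ids: Sequence[str] | None = None,
    standardize: bool = False,
) -> DistanceMatrix:
    """One-dimensional distance |v_i - v_j| for a single environmental variable.

    With ``standardize`` the variable is z-scored first (sd with ddof=1).
    """
    if isinstance(values, pd.Series):
        if sample_ids is None:
            sample_ids = tuple(map(str, values.index))
        values = values.to_numpy()
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValidationError("env_distance needs at least 3 samples")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite environmental value")
    if sample_ids is None:
        sample_ids = tuple(f"s{i + 1}" for i in range(v.size))
    if standardize:
        sd = np.std(v, ddof=1)
        if sd == 0:
            raise ValidationError("cannot standardize a constant variable")
        v = (v - np.mean(v)) / sd
    d = np.abs(v[:, None] - v[None, :])
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(sample_ids), d, "abs_diff")


@dataclasses.dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: coordinates for positive-eigenvalue axes only.

    ``eigenvalues`` holds the full spectrum (descending), including any
    negative values from non-Euclidean distances; ``proportion_explained``
    is computed over the positive eigenvalues and sums to 1.
    """

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # full spectrum, descending
    proportion_explained: np.ndarray  # over positive eigenvalues

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids), columns=cols)


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering.

    B = -1/2 J D^2 J with J the centering projector; eigendecompose B;
    coordinates are eigenvectors scaled by sqrt(lambda) for lambda > 0.
    Negative eigenvalues are reported, not corrected. Axis signs are fixed
    by making the largest-magnitude loading on each axis positive.
    """
    n = dm.n_samples
    if n < 3:
        raise ValidationError("pcoa needs at least 3 samples")
    d2 = dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1.0, float(np.abs(eigvals).max(initial=0.0))) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for k in range(coords.shape[1]):  # deterministic axis orientation
        j = int(np.argmax(np.abs(coords[:, k])))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return OrdinationResult(
        sample_ids=dm.sample_ids,
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
    )
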