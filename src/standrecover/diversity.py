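"""Shannon alpha-diversity (nats) and the percent-change summaries.

The Shannon index H = -sum p ln p is computed per sample on proportions,
in natural-log units: species-level H of a few thousand taxa lands around
6-7 nats, matching typical shotgun-profile reports. No rarefaction or depth
correction is applied.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .composition import to_relative
from .datamodel import AbundanceTable, StudyMetadata, ValidationError

__all__ = ["DiversityResult", "shannon", "percent_decrease", "stand_means"]


@dataclasses.dataclass(frozen=True)
class DiversityResult:
    sample_ids: tuple[str, ...]
    H: np.ndarray  # per-sample Shannon index, nats
    level: str  # e.g. species | kegg_l3

    def to_series(self) -> pd.Series:
        return pd.Series(self.H, index=list(self.sample_ids), name=f"H_{self.level}")


def shannon(table: AbundanceTable, level: str | None = None) -> DiversityResult:
    """Per-sample Shannon index H = -sum_i p_i ln p_i, with 0 ln 0 = 0."""
    rel = to_relative(table)
    p = rel.values
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H = -terms.sum(axis=1)
    if level is None:
        level = rel.rank.value if rel.rank is not None else rel.feature_kind.value
    return DiversityResult(sample_ids=rel.sample_ids, H=H, level=level)


def percent_decrease(reference: float, value: float) -> int:
    """Percent decrease of ``value`` relative to ``reference``, integer-rounded."""
    if reference <= 0:
        raise ValidationError("reference must be > 0")
    return int(round(100.0 * (reference - value) / reference))


def stand_means(result: DiversityResult, meta: StudyMetadata) -> pd.DataFrame:
    """Per-stand mean and standard error (sd/sqrt(n)) of the Shannon index."""
    groups = meta.groups(result.sample_ids)
    rows = []
    for stand in meta.stands:
        h = result.H[groups == stand]
        n = len(h)
        se = float(np.std(h, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"stand": stand, "mean": float(np.mean(h)), "se": se, "n": n})
    return pd.DataFrame(rows)
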