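"""Shared data types and delimited-text I/O.

All tables are plain TSV with a header row; samples are rows, features are
columns. Proportions are stored as fractions internally; percent formatting
is a report-time concern.
"""

from __future__ import annotations

import dataclasses
import enum
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "Rank",
    "AbundanceTable",
    "StudyMetadata",
    "DistanceMatrix",
    "TestResult",
    "ValidationError",
    "read_abundance_table",
    "read_metadata",
    "write_report",
]

#: Environmental variables of the study design, in report order.
ENV_VARIABLES = (
    "SOC", "TN", "C/N", "AN", "NN", "AP", "AK", "pH", "BD", "MWHC",
    "PR", "tree_shannon", "shrub_shannon", "herb_shannon",
)

_REL_TOL = 1e-6  # row sums within this of 1 => table auto-detected as relative


class ValidationError(ValueError):
    """Raised when an input table or argument violates a documented invariant."""


class FeatureKind(str, enum.Enum):
    taxon = "taxon"
    kegg_l3 = "kegg_l3"


class Rank(str, enum.Enum):
    phylum = "phylum"
    class_ = "class"
    order = "order"
    species = "species"


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclasses.dataclass(frozen=True)
class AbundanceTable:
    """Sample x feature nonnegative abundance matrix.

    Parameters
    ----------
    sample_ids, feature_ids
        Ordered, unique labels for rows and columns.
    values
        Nonnegative real matrix (counts or proportions), shape
        ``(len(sample_ids), len(feature_ids))``.
    feature_kind
        Whether features are taxa or KEGG level-3 categories.
    rank
        Taxonomic rank; required iff ``feature_kind`` is ``taxon``.
    is_relative
        True when every row sums to 1 (proportions).
    """

    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    values: np.ndarray
    feature_kind: FeatureKind
    rank: Rank | None = None
    is_relative: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "feature_ids", tuple(map(str, self.feature_ids)))
        object.__setattr__(self, "feature_kind", FeatureKind(self.feature_kind))
        if self.rank is not None:
            object.__setattr__(self, "rank", Rank(self.rank))
        if vals.ndim != 2 or vals.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if vals.size == 0:
            raise ValidationError("empty abundance table")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(vals)):
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if np.any(vals < 0):
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative value {vals[i, j]} at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r}"
            )
        if (self.feature_kind is FeatureKind.taxon) != (self.rank is not None):
            raise ValidationError("rank must be given iff feature_kind is 'taxon'")
        if self.is_relative:
            sums = vals.sum(axis=1)
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-9)
            if bad.size:
                i = int(bad[0])
                raise ValidationError(
                    f"is_relative table but row {self.sample_ids[i]!r} sums to {sums[i]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_ids)
        )


@dataclasses.dataclass(frozen=True)
class StudyMetadata:
    """Sample -> stand/plot assignment plus per-sample environmental variables."""

    sample_ids: tuple[str, ...]
    stand: tuple[str, ...]
    plot: tuple[str, ...]
    env: pd.DataFrame  # samples x variables, numeric

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "stand", tuple(map(str, self.stand)))
        object.__setattr__(self, "plot", tuple(map(str, self.plot)))
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if len(self.stand) != n or len(self.plot) != n:
            raise ValidationError("stand/plot length does not match sample count")
        env = self.env.loc[list(self.sample_ids)]
        for col in env.columns:
            if not np.issubdtype(env[col].dtype, np.number):
                raise ValidationError(f"non-numeric environmental variable {col!r}")
        object.__setattr__(self, "env", env.astype(float))
        counts: dict[str, int] = {}
        for s in self.stand:
            counts[s] = counts.get(s, 0) + 1
        for s, k in counts.items():
            if k < 2:
                raise ValidationError(
                    f"stand {s!r} has a single sample; distance-based tests "
                    "need within-group pairs"
                )

    @property
    def stands(self) -> tuple[str, ...]:
        """Stand levels in first-appearance order."""
        out: list[str] = []
        for s in self.stand:
            if s not in out:
                out.append(s)
        return tuple(out)

    def samples_of(self, stand: str) -> tuple[str, ...]:
        return tuple(
            sid for sid, st in zip(self.sample_ids, self.stand) if st == stand
        )

    def groups(self, sample_ids: Sequence[str]) -> np.ndarray:
        lut = dict(zip(self.sample_ids, self.stand))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise ValidationError(f"unknown sample(s): {missing}")
        return np.array([lut[s] for s in sample_ids])


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over labelled samples."""

    sample_ids: tuple[str, ...]
    d: np.ndarray
    metric: str  # bray_curtis | euclidean | abs_diff

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(d)):
            raise ValidationError("non-finite distance")
        if np.any(d < 0):
            raise ValidationError("negative distance")
        if not np.allclose(d, d.T, rtol=0, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal is not zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(tuple(sample_ids), self.d[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) distances in row-major pair order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.d[iu]


@dataclasses.dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (ANOSIM R, Mantel r or ANOVA F)."""

    statistic_name: str  # anosim_r | mantel_r | anova_f
    statistic: float
    p_value: float
    n_permutations: int = 0  # 0 for parametric tests
    seed: int | None = None
    exact: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p_value {self.p_value} outside (0, 1]")
        if self.n_permutations > 0 and not self.exact:
            if self.p_value < 1.0 / (self.n_permutations + 1) - 1e-15:
                raise ValidationError(
                    "Monte-Carlo p below 1/(B+1); permutation count inconsistent"
                )

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    feature_kind: FeatureKind | str,
    rank: Rank | str | None = None,
) -> AbundanceTable:
    """Read a tab-delimited sample x feature table.

    First column holds sample ids; the header row holds feature labels.
    ``is_relative`` is auto-detected (all row sums within 1e-6 of 1).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty table: {path}")
    try:
        vals = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"non-numeric abundance value in {path}: {exc}") from exc
    sums = vals.sum(axis=1)
    is_relative = bool(np.all(np.abs(sums - 1.0) <= _REL_TOL))
    if is_relative:
        vals = vals / sums[:, None]  # tighten to the 1e-9 storage invariant
    return AbundanceTable(
        sample_ids=tuple(df.index.astype(str)),
        feature_ids=tuple(df.columns.astype(str)),
        values=vals,
        feature_kind=FeatureKind(feature_kind),
        rank=Rank(rank) if rank is not None else None,
        is_relative=is_relative,
    )


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write a TSV that ``read_abundance_table`` round-trips to 12 significant digits."""
    df = table.to_frame()
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="sample")


def read_metadata(path: str | Path) -> StudyMetadata:
    """Read a tab-delimited metadata table: sample, stand, plot, then env columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "stand", "plot"):
        if col not in df.columns:
            raise ValidationError(f"metadata file missing required column {col!r}")
    env_cols = [c for c in df.columns if c not in ("sample", "stand", "plot")]
    try:
        env = df[env_cols].astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric environmental value: {exc}") from exc
    env.index = df["sample"].astype(str)
    return StudyMetadata(
        sample_ids=tuple(df["sample"].astype(str)),
        stand=tuple(df["stand"].astype(str)),
        plot=tuple(df["plot"].astype(str)),
        env=env,
    )


def write_metadata(meta: StudyMetadata, path: str | Path) -> None:
    df = meta.env.copy()
    df.insert(0, "plot", list(meta.plot))
    df.insert(0, "stand", list(meta.stand))
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="sample")


def test_results_frame(results: Mapping[str, TestResult]) -> pd.DataFrame:
    """Arrange named test results as a row-per-test table with r and p columns."""
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "name": name,
                "statistic_name": res.statistic_name,
                "r": res.statistic,
                "p": res.p_value,
                "n_permutations": res.n_permutations,
                "exact": res.exact,
                "significance": (
                    "**" if res.significant_01 else "*" if res.significant_05 else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def write_report(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    *,
    seed: int | None = None,
    config: Mapping | None = None,
) -> dict:
    """Write one TSV per report table plus a JSON run manifest.

    Returns the manifest. Numeric cells are formatted with %.12g, so a rerun
    with identical inputs produces byte-identical files.
    """
    if not tables:
        raise ValidationError("empty result set: nothing to report")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in tables.items():
        fname = f"{name}.tsv"
        df.to_csv(outdir / fname, sep="\t", float_format="%.12g", index=False)
        files[name] = fname
    cfg_json = json.dumps(config, sort_keys=True, default=str) if config else ""
    manifest = {
        "files": files,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "config": config,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return manifest
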