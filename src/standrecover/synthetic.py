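"""Study-shaped synthetic data: abundance tables and environment metadata.

The generator emulates a three-stand, three-plots-per-stand forest soil
design. Each microbial group (bacteria, fungi, archaea) has its own
between-stand compositional divergence so that the fungal community is
strongly structured by stand, bacteria moderately and archaea weakly.

Generative model
----------------
For each (group, feature kind): an ancestor composition is drawn from a
log-normal rank-abundance profile (softmax of N(0, 2) logits). Each stand's
composition displaces the ancestor by an independent N(0, 1) logit shift per
feature scaled by ``group_effect[group]``. Each plot draws a Dirichlet
composition around its stand composition (precision ``concentration``) and
is sampled multinomially at the target depth. Random streams are derived
per (group, feature kind, stand) so that adding a table never perturbs
existing draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    ENV_VARIABLES,
    AbundanceTable,
    FeatureKind,
    Rank,
    StudyMetadata,
    ValidationError,
)

__all__ = ["SimConfig", "generate_profiles", "generate_env", "STAND_NAMES",
           "MICROBIAL_GROUPS", "ENV_TABLE_DEFAULTS", "DEFAULT_N_FEATURES"]

STAND_NAMES = ("25-year-old", "40-year-old", "PCF")
MICROBIAL_GROUPS = ("bacteria", "fungi", "archaea")

#: Per-rank feature counts: desk-scale while preserving rank structure.
DEFAULT_N_FEATURES = {
    "phylum": 40,
    "class": 120,
    "order": 300,
    "species": 2000,
    "kegg_l3": 300,
}

#: Per-stand (mean, SE) with n=3 plots per stand, for the three stands in
#: STAND_NAMES order. Units: SOC/TN g kg^-1; AN/NN/AP/AK mg kg^-1; BD g cm^-3;
#: MWHC %; PR species count; Shannon diversities in nats; pH and C/N unitless.
ENV_TABLE_DEFAULTS: dict[str, tuple[tuple[float, float], ...]] = {
    "SOC": ((102.98, 5.22), (124.41, 10.74), (103.27, 17.91)),
    "TN": ((6.14, 0.27), (6.19, 0.47), (5.86, 0.91)),
    "AN": ((28.34, 7.18), (15.02, 3.87), (32.83, 12.05)),
    "NN": ((7.82, 1.31), (1.41, 3.18), (0.78, 0.54)),
    "AP": ((15.58, 2.15), (18.37, 2.92), (7.50, 1.32)),
    "AK": ((397.67, 42.48), (390.33, 69.93), (160.33, 26.64)),
    "pH": ((5.65, 0.03), (5.47, 0.17), (4.79, 0.06)),
    "BD": ((0.67, 0.02), (0.48, 0.05), (0.60, 0.04)),
    "MWHC": ((34.58, 2.46), (27.42, 1.31), (35.75, 2.63)),
    "PR": ((22.0, 2.0), (27.0, 2.0), (23.0, 3.0)),
    "tree_shannon": ((0.05, 0.02), (0.73, 0.09), (0.78, 0.12)),
    "shrub_shannon": ((0.74, 0.13), (1.31, 0.08), (1.60, 0.04)),
    "herb_shannon": ((2.04, 0.07), (2.26, 0.04), (1.92, 0.11)),
}

# every variable here (concentrations, pH, densities, diversities) is >= 0
_NONNEG_VARS = frozenset(ENV_TABLE_DEFAULTS)


def _stable_hash(*parts: object) -> int:
    h = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study.

    Defaults mirror the study design: 3 stands x 3 plots; fungi strongly,
    bacteria moderately and archaea weakly structured between stands;
    environment means/SEs at the reported per-stand values.
    """

    n_stands: int = 3
    n_plots_per_stand: int = 3
    n_features: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_N_FEATURES)
    )
    group_effect: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"fungi": 1.0, "bacteria": 0.4, "archaea": 0.15}
    )
    concentration: float = 200.0
    depth: int = 50_000
    env_means_ses: Mapping[str, tuple] = dataclasses.field(
        default_factory=lambda: dict(ENV_TABLE_DEFAULTS)
    )
    stand_names: tuple[str, ...] = STAND_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots_per_stand < 2:
            raise ValidationError("n_plots_per_stand must be >= 2")
        if self.n_stands < 2:
            raise ValidationError("n_stands must be >= 2")
        if self.concentration <= 0:
            raise ValidationError("concentration must be > 0")
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        for g, e in self.group_effect.items():
            if e < 0:
                raise ValidationError(f"group_effect[{g!r}] must be >= 0")
        if len(self.stand_names) < self.n_stands:
            object.__setattr__(
                self,
                "stand_names",
                tuple(self.stand_names)
                + tuple(
                    f"stand-{i}" for i in range(len(self.stand_names), self.n_stands)
                ),
            )

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(
            f"{self.stand_names[s]}.p{p + 1}"
            for s in range(self.n_stands)
            for p in range(self.n_plots_per_stand)
        )


def _rng(cfg: SimConfig, *scope: object) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(_stable_hash(*scope),))
    )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max())
    return z / z.sum()


def generate_profiles(
    cfg: SimConfig,
    group: str,
    feature_kind: FeatureKind | str = FeatureKind.taxon,
    rank: Rank | str | None = Rank.species,
) -> AbundanceTable:
    """Generate one count table for a microbial group at a feature level.

    Identical config + seed yields an identical table. ``group_effect`` of 0
    makes all stands share one composition (downstream ANOSIM R ~ 0).
    """
    if group not in cfg.group_effect:
        raise ValidationError(
            f"unknown microbial group {group!r}; known: {sorted(cfg.group_effect)}"
        )
    feature_kind = FeatureKind(feature_kind)
    if feature_kind is FeatureKind.kegg_l3:
        rank = None
        level = "kegg_l3"
        prefix = "ko"
    else:
        rank = Rank(rank if rank is not None else Rank.species)
        level = rank.value
        prefix = f"{group[:3]}_{level[:3]}"
    m = int(cfg.n_features.get(level, DEFAULT_N_FEATURES[level]))
    effect = float(cfg.group_effect[group])

    anc_rng = _rng(cfg, group, level, "ancestor")
    ancestor_logits = anc_rng.normal(0.0, 2.0, size=m)

    rows = []
    for s in range(cfg.n_stands):
        rng = _rng(cfg, group, level, "stand", s)
        stand_logits = ancestor_logits + effect * rng.normal(0.0, 1.0, size=m)
        stand_comp = _softmax(stand_logits)
        alpha = cfg.concentration * stand_comp
        for _ in range(cfg.n_plots_per_stand):
            plot_comp = rng.dirichlet(alpha)
            rows.append(rng.multinomial(cfg.depth, plot_comp))
    values = np.array(rows, dtype=float)
    return AbundanceTable(
        sample_ids=cfg.sample_ids,
        feature_ids=tuple(f"{prefix}{i + 1:04d}" for i in range(m)),
        values=values,
        feature_kind=feature_kind,
        rank=rank,
        is_relative=False,
    )


def generate_env(cfg: SimConfig) -> StudyMetadata:
    """Generate plot-level environment metadata.

    Plot values for each (stand, variable) are drawn Normal(mean, SE*sqrt(n))
    — the SE is the reported standard error of the stand mean over n plots,
    so the plot-level standard deviation is SE*sqrt(n). Concentrations, pH
    and diversities are floored at 0; the C/N column is recomputed per plot
    as SOC/TN.
    """
    n = cfg.n_plots_per_stand
    records: dict[str, list[float]] = {v: [] for v in cfg.env_means_ses}
    for s in range(cfg.n_stands):
        for var, per_stand in cfg.env_means_ses.items():
            mean, se = per_stand[s]
            rng = _rng(cfg, "env", var, s)
            draws = rng.normal(mean, se * np.sqrt(n), size=n)
            if var in _NONNEG_VARS:
                draws = np.maximum(draws, 0.0)
            records[var].extend(draws.tolist())
    env = pd.DataFrame(records, index=list(cfg.sample_ids))
    with np.errstate(divide="ignore", invalid="ignore"):
        env["C/N"] = env["SOC"] / env["TN"]
    env = env[[v for v in ENV_VARIABLES if v in env.columns]]
    stands = [
        cfg.stand_names[s] for s in range(cfg.n_stands) for _ in range(n)
    ]
    plots = [f"p{p + 1}" for _ in range(cfg.n_stands) for p in range(n)]
    return StudyMetadata(
        sample_ids=cfg.sample_ids, stand=tuple(stands), plot=tuple(plots), env=env
    )
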