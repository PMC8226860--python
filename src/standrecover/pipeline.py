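"""End-to-end study analysis: simulate or ingest tables, run every stage.

One run emits, per microbial group, the dominant-phylum summary, Shannon
diversity with Tukey letters (taxonomic and functional), ANOSIM across
stands for structure and function, PCoA coordinates, per-KEGG-category
ANOVA tables, environment means with letters, Mantel tests of community
distance against each environmental variable, and the deterministic vs
stochastic chance partitions — plus a JSON manifest recording seeds and
permutation counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import composition, diversity, inference, ordination, synthetic
from .chance import partition_study, partitions_frame
from .datamodel import (
    AbundanceTable,
    FeatureKind,
    Rank,
    StudyMetadata,
    ValidationError,
    read_abundance_table,
    read_metadata,
    test_results_frame,
    write_report,
)

__all__ = ["RunConfig", "run_full_analysis", "load_config"]

#: Taxonomic levels generated/consumed per group, and their downstream use.
_TAXON_LEVELS = ("phylum", "class", "species")


def _sub_seed(seed: int, *scope: object) -> int:
    h = hashlib.sha256(("|".join(map(str, scope)) + f"|{seed}").encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Full-analysis configuration."""

    mode: str = "simulate"  # simulate | paths
    sim: synthetic.SimConfig = dataclasses.field(default_factory=synthetic.SimConfig)
    paths: Mapping[str, Mapping[str, str]] | None = None  # group -> level -> path
    metadata_path: str | None = None
    reference_stand: str = "25-year-old"
    n_perm: int = 999
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "paths"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_raw = raw.pop("sim", {})
    sim = synthetic.SimConfig(**sim_raw) if sim_raw else synthetic.SimConfig(
        seed=raw.get("seed", 0)
    )
    return RunConfig(sim=sim, **raw)


def _load_inputs(cfg: RunConfig):
    groups = tuple(cfg.sim.group_effect) if cfg.mode == "simulate" \
        else tuple(cfg.paths)
    tables: dict[str, dict[str, AbundanceTable]] = {}
    if cfg.mode == "simulate":
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        for g in groups:
            tables[g] = {
                lvl: synthetic.generate_profiles(sim, g, FeatureKind.taxon, lvl)
                for lvl in _TAXON_LEVELS
            }
            tables[g]["kegg_l3"] = synthetic.generate_profiles(
                sim, g, FeatureKind.kegg_l3
            )
        meta = synthetic.generate_env(sim)
        return tables, meta
    if cfg.metadata_path is None:
        raise ValidationError("paths mode requires metadata_path")
    for g, levels in cfg.paths.items():
        tables[g] = {}
        for lvl, p in levels.items():
            if not Path(p).exists():
                raise ValidationError(f"missing input table: {p}")
            kind = FeatureKind.kegg_l3 if lvl == "kegg_l3" else FeatureKind.taxon
            rank = None if lvl == "kegg_l3" else Rank(lvl)
            tables[g][lvl] = read_abundance_table(p, kind, rank)
    if not Path(cfg.metadata_path).exists():
        raise ValidationError(f"missing metadata file: {cfg.metadata_path}")
    meta = read_metadata(cfg.metadata_path)
    return tables, meta


def _dominant_table(tables, alpha_threshold: float = 0.01) -> pd.DataFrame:
    rows = []
    for g, levels in tables.items():
        if "phylum" not in levels:
            continue
        rel = composition.to_relative(levels["phylum"])
        part = composition.dominant_partition(rel, alpha_threshold)
        for feat, mean in part.mean_relative_abundance().items():
            rows.append({"group": g, "phylum": feat,
                         "mean_relative_abundance_percent": 100.0 * mean})
    return pd.DataFrame(rows)


def _shannon_table(tables, meta: StudyMetadata, level: str,
                   alpha: float) -> pd.DataFrame:
    rows = []
    for g, levels in tables.items():
        if level not in levels:
            continue
        res = diversity.shannon(levels[level])
        tk = inference.anova_tukey(res.H, meta.groups(res.sample_ids), alpha)
        per_stand = diversity.stand_means(res, meta)
        for _, r in per_stand.iterrows():
            rows.append({
                "group": g, "stand": r["stand"], "mean_H": r["mean"],
                "se": r["se"], "n": int(r["n"]),
                "letter": tk.letter_of(r["stand"]),
            })
    return pd.DataFrame(rows)


def _anosim_tables(tables, meta, cfg: RunConfig):
    out = {}
    for aspect, level in (("structure", "species"), ("function", "kegg_l3")):
        res = {}
        for g, levels in tables.items():
            if level not in levels:
                continue
            dm = ordination.bray_curtis(levels[level])
            res[g] = inference.anosim(
                dm, meta.groups(dm.sample_ids), n_perm=cfg.n_perm,
                seed=_sub_seed(cfg.seed, "anosim", aspect, g),
            )
        out[f"anosim_{aspect}"] = test_results_frame(res)
    return out


def _pcoa_tables(tables, cfg: RunConfig):
    out = {}
    for aspect, level in (("structure", "species"), ("function", "kegg_l3")):
        frames = []
        for g, levels in tables.items():
            if level not in levels:
                continue
            dm = ordination.bray_curtis(levels[level])
            ord_res = ordination.pcoa(dm)
            df = ord_res.to_frame().iloc[:, :2].reset_index(names="sample")
            df.insert(0, "group", g)
            for k in range(min(2, len(ord_res.proportion_explained))):
                df[f"PCo{k + 1}_pct"] = 100.0 * ord_res.proportion_explained[k]
            frames.append(df)
        out[f"pcoa_{aspect}"] = pd.concat(frames, ignore_index=True)
    return out


def _kegg_anova_table(tables, meta: StudyMetadata, alpha: float) -> pd.DataFrame:
    """Per-KEGG-category ANOVA across stands on relative abundance (percent).

    Only categories whose one-way ANOVA p is below alpha are listed, with
    per-stand mean (SE) and Tukey letters.
    """
    rows = []
    for g, levels in tables.items():
        if "kegg_l3" not in levels:
            continue
        rel = composition.to_relative(levels["kegg_l3"])
        labels = meta.groups(rel.sample_ids)
        # vectorised screening F-test, then full Tukey only on the hits
        for j, feat in enumerate(rel.feature_ids):
            col = rel.values[:, j] * 100.0
            samples = [col[labels == s] for s in meta.stands]
            if all(np.allclose(s, samples[0][0]) for s in samples):
                continue
            from scipy.stats import f_oneway

            f, p = f_oneway(*samples)
            if not np.isfinite(p) or p >= alpha:
                continue
            tk = inference.anova_tukey(col, labels, alpha)
            row = {"group": g, "kegg_l3": feat, "anova_p": float(p)}
            for stand in meta.stands:
                vals = col[labels == stand]
                row[f"{stand}_mean"] = float(vals.mean())
                row[f"{stand}_se"] = float(
                    np.std(vals, ddof=1) / np.sqrt(len(vals)))
                row[f"{stand}_letter"] = tk.letter_of(stand)
            rows.append(row)
    return pd.DataFrame(rows)


def _env_table(meta: StudyMetadata, alpha: float) -> pd.DataFrame:
    rows = []
    labels = meta.groups(meta.sample_ids)
    for var in meta.env.columns:
        vals = meta.env[var].to_numpy()
        tk = inference.anova_tukey(vals, labels, alpha)
        row = {"variable": var}
        for stand in meta.stands:
            v = vals[labels == stand]
            row[f"{stand}_mean"] = float(v.mean())
            row[f"{stand}_se"] = float(np.std(v, ddof=1) / np.sqrt(len(v)))
            row[f"{stand}_letter"] = tk.letter_of(stand).upper()
        rows.append(row)
    return pd.DataFrame(rows)


def _mantel_tables(tables, meta: StudyMetadata, cfg: RunConfig):
    out = {}
    for aspect, level in (("structure", "species"), ("function", "kegg_l3")):
        rows = []
        for var in meta.env.columns:
            env_dm = ordination.env_distance(
                meta.env[var].to_numpy(), meta.sample_ids
            )
            for g, levels in tables.items():
                if level not in levels:
                    continue
                com_dm = ordination.bray_curtis(levels[level])
                try:
                    res = inference.mantel(
                        com_dm, env_dm, n_perm=cfg.n_perm,
                        seed=_sub_seed(cfg.seed, "mantel", aspect, g, var),
                    )
                except ValidationError:
                    continue  # constant variable: r undefined
                rows.append({
                    "variable": var, "group": g, "r": res.statistic,
                    "p": res.p_value,
                    "significant": res.p_value < cfg.alpha,
                })
        out[f"mantel_{aspect}"] = pd.DataFrame(rows)
    return out


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage of the study analysis and write the report directory."""
    tables, meta = _load_inputs(cfg)
    report: dict[str, pd.DataFrame] = {}
    report["fig1_dominant_phyla"] = _dominant_table(tables)
    report["table2_shannon_taxonomic"] = _shannon_table(
        tables, meta, "species", cfg.alpha)
    report["table5_shannon_functional"] = _shannon_table(
        tables, meta, "kegg_l3", cfg.alpha)
    report.update(_anosim_tables(tables, meta, cfg))
    report.update(_pcoa_tables(tables, cfg))
    report["table4_kegg_anova"] = _kegg_anova_table(tables, meta, cfg.alpha)
    report["table7_environment"] = _env_table(meta, cfg.alpha)
    report.update(_mantel_tables(tables, meta, cfg))
    chance_inputs = {
        g: {
            aspect: levels[level]
            for aspect, level in (("structure", "class"), ("function", "kegg_l3"))
            if level in levels
        }
        for g, levels in tables.items()
    }
    parts = partition_study(chance_inputs, meta, cfg.reference_stand)
    report["fig4_chance_partition"] = partitions_frame(parts)

    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["sim"] = dataclasses.asdict(cfg.sim)
    return write_report(report, cfg.outdir, seed=cfg.seed, config=cfg_dict)
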