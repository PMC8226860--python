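"""Simulation studies over the synthetic generator.

Two standard checks on the statistical machinery:

* null calibration — with no between-stand effect, the ANOSIM and Mantel
  permutation tests should reject at the nominal rate;
* parameter recovery — with the default group effects (fungi 1.0 >
  bacteria 0.4 > archaea 0.15) the fungal ANOSIM R should rank first and
  fungal change partitions should fall in the deterministic regime.
"""

from __future__ import annotations

import numpy as np

from .chance import chance_partition
from .composition import to_relative
from .inference import anosim, mantel
from .ordination import bray_curtis, env_distance, euclidean
from .synthetic import SimConfig, generate_env, generate_profiles

__all__ = ["null_calibration", "parameter_recovery"]


def null_calibration(
    n_reps: int = 500,
    n_perm: int = 199,
    seed: int = 0,
    alpha: float = 0.05,
    n_features: int = 400,
    depth: int = 20_000,
) -> dict[str, float]:
    """Empirical rejection rates of ANOSIM and Mantel under a true null.

    Each replicate draws a species table with ``group_effect`` 0 (all stands
    share one composition) plus an independent environmental variable, and
    runs both tests at Monte-Carlo B = ``n_perm``.
    """
    labels = None
    anosim_rej = 0
    mantel_rej = 0
    master = np.random.default_rng(seed)
    for rep in range(n_reps):
        rep_seed = int(master.integers(2**31))
        cfg = SimConfig(
            group_effect={"bacteria": 0.0},
            n_features={"species": n_features},
            depth=depth,
            seed=rep_seed,
        )
        table = generate_profiles(cfg, "bacteria", "taxon", "species")
        dm = bray_curtis(table)
        if labels is None:
            labels = np.repeat(["a", "b", "c"], cfg.n_plots_per_stand)
        a = anosim(dm, labels, n_perm=n_perm, seed=rep_seed)
        anosim_rej += a.p_value < alpha
        env_rng = np.random.default_rng(rep_seed + 1)
        env_dm = env_distance(env_rng.normal(size=dm.n_samples), dm.sample_ids)
        m = mantel(dm, env_dm, n_perm=n_perm, seed=rep_seed, exact=False)
        mantel_rej += m.p_value < alpha
    return {
        "anosim_rejection_rate": anosim_rej / n_reps,
        "mantel_rejection_rate": mantel_rej / n_reps,
        "n_reps": n_reps,
        "n_perm": n_perm,
    }


def parameter_recovery(n_seeds: int = 100, seed: int = 0) -> dict[str, float]:
    """How often the default effect ordering is recovered downstream.

    For each seed: species-level ANOSIM R per microbial group (fungi must
    exceed both bacteria and archaea) and the class-level chance partitions
    of the fungal community (both non-reference stands must land in the
    deterministic regime).
    """
    labels = np.repeat(["a", "b", "c"], 3)
    order_hits = 0
    fungal_det_hits = 0
    r_values: dict[str, list[float]] = {g: [] for g in ("bacteria", "fungi",
                                                        "archaea")}
    master = np.random.default_rng(seed)
    for _ in range(n_seeds):
        cfg = SimConfig(seed=int(master.integers(2**31)))
        r = {}
        for g in r_values:
            dm = bray_curtis(generate_profiles(cfg, g, "taxon", "species"))
            r[g] = anosim(dm, labels, n_perm=0, seed=0).statistic
            r_values[g].append(r[g])
        if r["fungi"] > r["bacteria"] and r["fungi"] > r["archaea"]:
            order_hits += 1
        meta = generate_env(cfg)
        dm = euclidean(to_relative(generate_profiles(cfg, "fungi", "taxon",
                                                     "class")))
        regimes = [
            chance_partition(dm, meta, "25-year-old", focal).regime
            for focal in ("40-year-old", "PCF")
        ]
        if all(rg == "deterministic" for rg in regimes):
            fungal_det_hits += 1
    return {
        "fungal_R_highest_fraction": order_hits / n_seeds,
        "fungal_deterministic_fraction": fungal_det_hits / n_seeds,
        "mean_R_bacteria": float(np.mean(r_values["bacteria"])),
        "mean_R_fungi": float(np.mean(r_values["fungi"])),
        "mean_R_archaea": float(np.mean(r_values["archaea"])),
        "n_seeds": n_seeds,
    }
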