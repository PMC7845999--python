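"""End-to-end orchestration: simulate -> normalize -> select -> validate ->
composite -> registry comparison, with every artifact written to a run
directory.

Each stochastic stage derives its seed deterministically from the global
seed and the stage name, so a rerun with the same seed reproduces every
number.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ants import ColonyConfig, run_colony
from .cohort import (
    assemble_training_records,
    normalize_minmax,
    split_completers,
    subset_by_patients,
    summarize_cohort,
    write_cohort,
)
from .composite import (
    effect_size_paired,
    frequency_match_registry,
    greedy_forward,
    paired_changes,
    repeated_holdout,
    sample_size_reduction,
)
from .embedding import correlation_distances, spe_embed, EmbeddingConfig, pca_variance_profile
from .nets import NetworkConfig, network_evaluator, predict, train_ensemble
from .simulate import GeneratorConfig, generate_cohort, generate_historical_registry
from .validation import ensemble_builder, external_validation, repeated_cv

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    The defaults are desk-scale: a few hundred ants, two restarts and
    three cross-validation repetitions run the whole chain in minutes on
    one CPU.  ``full_scale`` restores the original protocol sizes
    (3,000 ants, 10 restarts, 10 repetitions, the full K and h grids),
    at the cost of hundreds of thousands of network trainings.
    """

    seed: int = 0
    out_dir: str = "kinemark_run"
    scales: tuple[str, ...] = ("FM", "NIH")
    K: int = 8
    h: int = 2
    n_ants: int = 300
    n_restarts: int = 2
    cv_repetitions: int = 3
    folds: int = 10
    ensemble_size: int = 10
    epochs: int = 100
    holdout_repeats: int = 100
    registry_size: int = 30_000
    registry_ratio: int = 14
    generator: GeneratorConfig | None = None
    full_scale: bool = False

    def resolved(self) -> "RunConfig":
        if not self.full_scale:
            return self
        return RunConfig(
            seed=self.seed, out_dir=self.out_dir, scales=("FM", "MP", "NIH", "MR"),
            K=self.K, h=self.h, n_ants=3000, n_restarts=10, cv_repetitions=10,
            folds=10, ensemble_size=10, epochs=100, holdout_repeats=100,
            registry_size=self.registry_size, registry_ratio=self.registry_ratio,
            generator=self.generator, full_scale=False,
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return the summary dict.

    Artifacts written to ``config.out_dir``: the simulated cohort and
    ground truth, descriptive statistics, per-scale selected subsets and
    validation results, effect-size curves, the SPE coordinates, and a
    ``summary.json`` collating the headline numbers with provenance.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {"version": __version__, "seed": cfg.seed}

    # --- simulate ---------------------------------------------------------
    gen = cfg.generator or GeneratorConfig(seed=stage_seed(cfg.seed, "simulate"))
    raw, truth = generate_cohort(gen)
    write_cohort(raw, out / "cohort.csv")
    (out / "ground_truth.json").write_text(json.dumps(
        {"support": {k: list(map(list, v)) for k, v in truth.support.items()},
         "ceiling": truth.ceiling}, indent=1))
    cohort = normalize_minmax(raw)
    completers, non_completers = split_completers(cohort)
    summarize_cohort(cohort).to_csv(out / "descriptives.csv", index=False)
    summary["n_patients"] = len(cohort.patients)
    summary["n_completers"] = len(completers)
    summary["ceiling"] = truth.ceiling

    train_cohort = subset_by_patients(cohort, completers)
    ext_cohort = subset_by_patients(cohort, non_completers)

    # --- correlation structure -------------------------------------------
    dist = correlation_distances(cohort)
    coords, stress = spe_embed(dist, EmbeddingConfig(seed=stage_seed(cfg.seed, "embed")))
    pd.DataFrame(coords, index=list(dist.variables), columns=["x", "y"]).to_csv(
        out / "spe_coordinates.csv")
    summary["spe_stress"] = stress
    feats_table = cohort.data[list(cohort.schema.features)].dropna()
    _, levels = pca_variance_profile(feats_table)
    summary["pca_components_for_90pct"] = levels[90]

    # --- per-scale selection + validation --------------------------------
    net_cfg = NetworkConfig(n_hidden=cfg.h, epochs=cfg.epochs)
    per_scale: dict[str, dict] = {}
    best_subsets: dict[str, tuple[str, ...]] = {}
    for scale in cfg.scales:
        s_seed = stage_seed(cfg.seed, f"select:{scale}")
        table = assemble_training_records(train_cohort, scale)
        features = list(train_cohort.schema.features)
        evaluator = network_evaluator(table, scale,
                                      NetworkConfig(n_hidden=cfg.h, epochs=cfg.epochs, seed=s_seed))
        subset, train_r2, _ = run_colony(
            features, evaluator,
            ColonyConfig(K=cfg.K, n_ants=cfg.n_ants, n_restarts=cfg.n_restarts, seed=s_seed),
        )
        cv = repeated_cv(table, scale, ensemble_builder(net_cfg, cfg.ensemble_size),
                         subset, repetitions=cfg.cv_repetitions, folds=cfg.folds,
                         base_seed=stage_seed(cfg.seed, f"cv:{scale}"))
        ens = train_ensemble(table, scale, subset, net_cfg, n_members=cfg.ensemble_size,
                             base_seed=stage_seed(cfg.seed, f"ensemble:{scale}"))
        try:
            ext_table = assemble_training_records(ext_cohort, scale)
            ext_r2 = external_validation(lambda rows: predict(ens, rows), ext_table, scale)
        except ValueError:
            ext_r2 = float("nan")
        per_scale[scale] = dict(subset=list(subset), training_r2=train_r2,
                                r2cv_mean=cv.mean, r2cv_sd=cv.sd, external_r2=ext_r2)
        best_subsets[scale] = subset
    summary["models"] = per_scale
    pd.DataFrame([
        dict(scale=s, subset="|".join(v["subset"]), training_r2=v["training_r2"],
             r2cv_mean=v["r2cv_mean"], r2cv_sd=v["r2cv_sd"], external_r2=v["external_r2"])
        for s, v in per_scale.items()
    ]).to_csv(out / "models.csv", index=False)

    # --- composite endpoint ----------------------------------------------
    pool_scale = "NIH" if "NIH" in best_subsets else cfg.scales[0]
    pool = list(best_subsets[pool_scale])
    changes = paired_changes(train_cohort, pool, sorted(completers))
    composites, train_ds = greedy_forward(changes, pool)
    hold = repeated_holdout(changes, pool, repeats=cfg.holdout_repeats,
                            seed=stage_seed(cfg.seed, "holdout"))
    pd.DataFrame({
        "size": np.arange(1, hold.train_d.shape[1] + 1),
        "train_d_mean": hold.mean_train, "train_d_sd": hold.sd_train,
        "validation_d_mean": hold.mean_validation, "validation_d_sd": hold.sd_validation,
    }).to_csv(out / "composite_curves.csv", index=False)

    # clinical-scale reference effect sizes on the completers
    scale_d = {}
    for scale in ("FM", "MP", "NIH"):
        pre = [float(train_cohort.rows_for(p, 7).iloc[0][scale]) for p in sorted(completers)]
        post = [float(train_cohort.rows_for(p, 90).iloc[0][scale]) for p in sorted(completers)]
        if any(pd.isna(pre)) or any(pd.isna(post)):
            continue
        d = effect_size_paired(pre, post).d
        scale_d[scale] = abs(d)  # improvement direction differs by scale
    summary["scale_effect_sizes"] = scale_d
    summary["composite_train_d"] = train_ds[-1]
    summary["composite_val_d_4features"] = float(hold.mean_validation[min(3, hold.train_d.shape[1] - 1)])
    summary["composite_val_d_final"] = float(hold.mean_validation[-1])

    # --- historical registry comparison ----------------------------------
    reg_seed = stage_seed(cfg.seed, "registry")
    registry = generate_historical_registry(gen, cfg.registry_size, seed=reg_seed)
    day7 = [int(train_cohort.rows_for(p, 7).iloc[0]["NIH"]) for p in sorted(completers)]
    matched = frequency_match_registry(day7, registry, ratio=cfg.registry_ratio,
                                       seed=stage_seed(cfg.seed, "match"))
    improvement = matched["nih_day7"] - matched["nih_day90"]
    hist_d = effect_size_paired(np.zeros(len(improvement)), improvement.to_numpy()).d
    summary["registry_n_matched"] = int(len(matched))
    summary["registry_effect_size"] = hist_d
    ratio = summary["composite_val_d_final"] / hist_d if hist_d > 0 else float("nan")
    summary["effect_ratio_vs_registry"] = ratio
    summary["sample_size_reduction_pct"] = sample_size_reduction(ratio) if np.isfinite(ratio) else None

    summary["runtime_s"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
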