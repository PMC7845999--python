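"""Synthetic longitudinal stroke-cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage (normalization, feature selection, ensemble
regression, cross-validation, composite design) can be exercised and its
parameter recovery verified without access to a real cohort:

* a per-patient latent impairment trajectory that improves over time
  (linear in log-day with a patient-level random slope),
* clusters of correlated RMK features (each feature loads on a shared
  severity factor, a cluster factor, and unique noise),
* clinical scores produced by a saturating (scaled-logistic) link from a
  sparse "true support" subset of the features, plus observation noise,
  clipped and rounded to the documented scale ranges,
* the NIH and modified Rankin scales inverted (higher = more impaired),
* modified Rankin observed only at days 30 and 90,
* missingness (whole visits and single cells) producing completer and
  non-completer strata,
* a synthetic historical registry of day-7/day-90 NIH pairs standing in
  for a large stroke-trials archive.

Identical (config, seed) pairs produce identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, summarize_cohort  # noqa: F401  (re-exported convenience)
from .schema import (
    DEFAULT_SCHEMA,
    INVERTED_SCALES,
    MR_DAYS,
    SCALE_NAMES,
    SCALE_RANGES,
    RMKSchema,
)

#: Default correlation clusters over metric names, mirroring the groups of
#: correlated variables seen on the correlation map of the real assay
#: (sub-movement shape; resistance/accuracy; speed; tempo).  Metrics not
#: listed load on their own singleton factor.
DEFAULT_CLUSTERS: dict[str, tuple[str, ...]] = {
    "submovement_shape": ("Overlap Subm", "Sigma Subm", "Dur Subm"),
    "resistance_accuracy": ("Rnd Dyn Mean Dist", "Aim", "Deviation"),
    "speed": ("Peak Speed", "Mean Speed", "Max Subm", "Dist Subm", "Smooth J2"),
    "tempo": ("Numb Subm", "Duration", "Smooth M/P"),
}

#: Default generative support per scale: (feature, weight) pairs, strongest
#: first.  Resistance against dynamic force on the affected side dominates
#: every scale, as in real robotic stroke assessments; supports overlap
#: across scales but are not identical.
DEFAULT_SUPPORT: dict[str, tuple[tuple[str, float], ...]] = {
    "FM": (
        ("Rnd Dyn Mean Dist Aff", 1.00),
        ("Smooth M/P Aff", 0.85),
        ("Peak Speed Aff", 0.70),
        ("Overlap Subm Aff", 0.60),
        ("Plbck Mean Aff", 0.30),
        ("Ellipse Aff", 0.25),
        ("Aim Aff", 0.20),
        ("Mean Z Aff", 0.15),
    ),
    "MP": (
        ("Rnd Dyn Mean Dist Aff", 1.00),
        ("Plbck Mean Aff", 0.80),
        ("Mean Z Aff", 0.70),
        ("Peak Speed Aff", 0.55),
        ("Smooth M/P Aff", 0.30),
        ("Deviation Aff", 0.25),
        ("Max Subm Aff", 0.20),
        ("Aim Aff", 0.15),
    ),
    "NIH": (
        ("Rnd Dyn Mean Dist Aff", 1.00),
        ("Plbck Mean Aff", 0.80),
        ("Peak Speed Aff", 0.65),
        ("Deviation Aff", 0.55),
        ("Smooth M/P Aff", 0.30),
        ("Deviation NonAff", 0.25),
        ("Mean Speed Aff", 0.20),
        ("Numb Subm Aff", 0.15),
    ),
    "MR": (
        ("Aim Aff", 1.00),
        ("Rnd Dyn Mean Dist Aff", 0.85),
        ("Plbck Mean Aff", 0.65),
        ("Mean Speed NonAff", 0.55),
        ("Dist Subm Aff", 0.30),
        ("Duration Aff", 0.25),
        ("Deviation Aff", 0.20),
        ("Smooth J1 Aff", 0.15),
    ),
}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    The defaults describe a two-site cohort of 208 patients assessed on
    days 7, 14, 21, 30 and 90 after stroke, with a noise level giving a
    best-achievable prediction R^2 (the noise ceiling) of about 0.8 for
    the continuous scales.
    """

    n_patients: int = 208
    site_mix: dict[str, float] = field(default_factory=lambda: {"Burke": 0.7, "Glasgow": 0.3})
    days: tuple[int, ...] = (7, 14, 21, 30, 90)
    cluster_map: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_CLUSTERS))
    true_support: dict[str, tuple[tuple[str, float], ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SUPPORT.items()}
    )
    #: logistic link steepness (per unit of the weighted feature mean)
    link_steepness: float = 6.0
    #: observation noise on each scale, as a fraction of the sd of the
    #: noiseless score; 0.5 gives a theoretical R^2 ceiling of 0.8
    noise_to_signal: dict[str, float] = field(
        default_factory=lambda: {s: 0.5 for s in SCALE_NAMES}
    )
    #: loading of each feature on the shared severity factor (affected side)
    severity_loading: float = 0.60
    #: severity loading on the non-affected side (milder involvement)
    severity_loading_nonaff: float = 0.30
    #: loading on the cluster factor
    cluster_loading: float = 0.55
    #: mean and sd of the per-patient recovery slope, per unit log(day/7)
    recovery_rate: tuple[float, float] = (0.35, 0.25)
    #: sd of the per-visit wobble around the latent trajectory
    visit_wobble: float = 0.25
    #: probability that an entire visit record is missing, per day
    visit_missing: dict[int, float] = field(
        default_factory=lambda: {14: 0.05, 21: 0.05, 30: 0.05, 90: 0.30}
    )
    #: per-cell missing probability for RMK features and scales
    cell_missing: float = 0.006
    #: historical-registry day-7 -> day-90 NIH improvement (mean, sd)
    registry_improvement: tuple[float, float] = (2.1, 3.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.site_mix.values()) - 1.0) > 1e-9:
            raise ValueError("site_mix proportions must sum to 1")
        if any(v < 0 for v in self.noise_to_signal.values()):
            raise ValueError("noise_to_signal must be non-negative")
        feats = set(DEFAULT_SCHEMA.features)
        for scale, sup in self.true_support.items():
            unknown = [f for f, _ in sup if f not in feats]
            if unknown:
                raise ValueError(f"true_support for {scale} has unknown features {unknown}")
        if not (0 <= self.cell_missing < 1):
            raise ValueError("cell_missing must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to verify parameter recovery on a generated cohort."""

    config: GeneratorConfig
    #: per-patient (baseline severity, recovery slope)
    trajectories: pd.DataFrame
    #: per scale: ordered (feature, weight) support
    support: dict[str, tuple[tuple[str, float], ...]]
    #: realized noise ceiling: squared Pearson r between the noiseless
    #: score and the observed (noisy, clipped, rounded) score
    ceiling: dict[str, float]

    def top_features(self, scale: str, n: int = 4) -> list[str]:
        sup = sorted(self.support[scale.upper()], key=lambda fw: -abs(fw[1]))
        return [f for f, _ in sup[:n]]


def _feature_factors(schema: RMKSchema, cluster_map: Mapping[str, Sequence[str]]) -> dict[str, str]:
    """Map each of the 35 features to its latent-factor label (per side)."""
    metric_to_cluster: dict[str, str] = {}
    for cname, metrics in cluster_map.items():
        for m in metrics:
            metric_to_cluster[m] = cname
    out: dict[str, str] = {}
    for feat in schema.features:
        if feat.endswith(schema.affected_suffix):
            metric, side = feat[: -len(schema.affected_suffix)], "Aff"
        else:
            metric, side = feat[: -len(schema.non_affected_suffix)], "NonAff"
        cluster = metric_to_cluster.get(metric, f"solo:{metric}")
        out[feat] = f"{cluster}|{side}"
    return out


#: plausible raw spans cycled over the features, so the generated file has
#: the divergent units a real multi-instrument export would
_RAW_SPANS = ((0.0, 1.0), (0.0, 25.0), (-5.0, 5.0), (0.0, 300.0), (10.0, 90.0))


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort and its ground truth from the generative model.

    Returns a *raw* cohort (features on arbitrary plausible scales); run
    :func:`kinemark.cohort.normalize_minmax` before modeling, as with real
    data.
    """
    schema = DEFAULT_SCHEMA
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, days = config.n_patients, list(config.days)
    feats = schema.features
    factor_of = _feature_factors(schema, config.cluster_map)
    factor_names = sorted(set(factor_of.values()))

    if n == 0:
        empty = pd.DataFrame(columns=list(schema.columns()))
        truth = GroundTruth(config, pd.DataFrame(columns=["patient_id", "baseline", "slope"]),
                            {k: tuple(v) for k, v in config.true_support.items()}, {})
        return Cohort(schema=schema, data=empty.astype({"day": int}, errors="ignore")), truth

    sites = list(config.site_mix)
    site_assign = rng.choice(sites, size=n, p=[config.site_mix[s] for s in sites])
    pids = [f"P{i:04d}" for i in range(n)]

    # latent trajectories: severity and one trajectory per factor
    mu_slope, sd_slope = config.recovery_rate
    baseline = rng.normal(0.0, 1.0, size=n)
    slope = rng.normal(mu_slope, sd_slope, size=n)
    fac_baseline = {f: rng.normal(0.0, 1.0, size=n) for f in factor_names}
    fac_slope = {f: rng.normal(mu_slope * 0.4, sd_slope * 0.6, size=n) for f in factor_names}

    n_days = len(days)
    logday = np.log(np.asarray(days, float) / 7.0)

    # severity and factor states, shape (n, n_days)
    sev = baseline[:, None] + slope[:, None] * logday[None, :]
    sev = sev + rng.normal(0.0, config.visit_wobble, size=sev.shape)
    fac = {
        f: fac_baseline[f][:, None] + fac_slope[f][:, None] * logday[None, :]
        + rng.normal(0.0, config.visit_wobble, size=(n, n_days))
        for f in factor_names
    }

    g_aff, g_non, h = config.severity_loading, config.severity_loading_nonaff, config.cluster_loading
    internal: dict[str, np.ndarray] = {}
    for feat in feats:
        g = g_aff if feat.endswith(schema.affected_suffix) else g_non
        u = np.sqrt(max(1.0 - g * g - h * h, 1e-9))
        z = g * sev + h * fac[factor_of[feat]] + u * rng.normal(0.0, 1.0, size=(n, n_days))
        internal[feat] = 1.0 / (1.0 + np.exp(-z))  # squash to (0, 1)

    # clinical scores from the observed (pre-missingness) feature values
    scores: dict[str, np.ndarray] = {}
    noiseless: dict[str, np.ndarray] = {}
    for scale in SCALE_NAMES:
        sup = config.true_support[scale]
        wsum = sum(w for _, w in sup)
        u = sum(w * internal[f] for f, w in sup) / wsum  # in (0, 1)
        y01 = 1.0 / (1.0 + np.exp(-config.link_steepness * (u - 0.5)))
        if scale in INVERTED_SCALES:
            y01 = 1.0 - y01
        lo, hi = SCALE_RANGES[scale]
        signal = lo + (hi - lo) * y01
        noiseless[scale] = signal
        sd_sig = float(signal.std())
        noise = rng.normal(0.0, config.noise_to_signal[scale] * sd_sig, size=signal.shape)
        obs = np.clip(signal + noise, lo, hi)
        scores[scale] = np.round(obs)  # all four scales are integer-valued

    # realized noise ceiling per scale (over MR-eligible visits for MR)
    ceiling: dict[str, float] = {}
    for scale in SCALE_NAMES:
        cols = [j for j, d in enumerate(days) if scale != "MR" or d in MR_DAYS]
        if not cols:
            continue
        a = noiseless[scale][:, cols].ravel()
        b = scores[scale][:, cols].ravel()
        r = np.corrcoef(a, b)[0, 1]
        ceiling[scale] = float(r * r)

    # assemble long table with raw (affine-rescaled) feature values
    rows = []
    for i in range(n):
        for j, day in enumerate(days):
            row = {"patient_id": pids[i], "site": site_assign[i], "day": day}
            for k, feat in enumerate(feats):
                lo, hi = _RAW_SPANS[k % len(_RAW_SPANS)]
                row[feat] = lo + (hi - lo) * internal[feat][i, j]
            for scale in SCALE_NAMES:
                if scale == "MR" and day not in MR_DAYS:
                    row[scale] = np.nan
                else:
                    row[scale] = scores[scale][i, j]
            rows.append(row)
    data = pd.DataFrame(rows)

    # missingness last: whole visits, then single cells
    miss_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    keep = np.ones(len(data), dtype=bool)
    for day, p in config.visit_missing.items():
        if day not in days or p <= 0:
            continue
        day_rows = data.index[data["day"] == day].to_numpy()
        drop = miss_rng.random(len(day_rows)) < p
        keep[day_rows[drop]] = False
    data = data.loc[keep].reset_index(drop=True)
    if config.cell_missing > 0:
        cell_cols = list(feats) + list(SCALE_NAMES)
        mask = miss_rng.random((len(data), len(cell_cols))) < config.cell_missing
        vals = data[cell_cols].to_numpy(float)
        vals[mask] = np.nan
        data[cell_cols] = vals

    truth = GroundTruth(
        config=config,
        trajectories=pd.DataFrame({"patient_id": pids, "baseline": baseline, "slope": slope}),
        support={k: tuple(v) for k, v in config.true_support.items()},
        ceiling=ceiling,
    )
    return Cohort(schema=schema, data=data), truth


def generate_historical_registry(
    config: GeneratorConfig,
    n_subjects: int,
    nih_day7_dist: Mapping[int, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic registry of (subject_id, nih_day7, nih_day90) rows.

    Stands in for a large historical stroke-trials archive.  Day-7 NIH
    scores are drawn from ``nih_day7_dist`` (default: the day-7 NIH
    histogram of a cohort generated from ``config``); the day-7 to day-90
    improvement is normal with ``config.registry_improvement`` parameters,
    rounded and clipped to keep day-90 NIH within its documented range.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + 2 if seed is None else seed))
    if nih_day7_dist is None:
        cohort, _ = generate_cohort(config)
        day7 = cohort.data.loc[cohort.data["day"] == 7, "NIH"].dropna().astype(int)
        counts = day7.value_counts().sort_index()
        nih_day7_dist = (counts / counts.sum()).to_dict()
    levels = np.array(sorted(nih_day7_dist), dtype=int)
    probs = np.array([nih_day7_dist[v] for v in levels], dtype=float)
    probs = probs / probs.sum()
    nih7 = rng.choice(levels, size=n_subjects, p=probs)
    mean_impr, sd_impr = config.registry_improvement
    impr = np.round(rng.normal(mean_impr, sd_impr, size=n_subjects))
    lo, hi = SCALE_RANGES["NIH"]
    nih90 = np.clip(nih7 - impr, lo, hi).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"R{i:06d}" for i in range(n_subjects)],
            "nih_day7": nih7.astype(int),
            "nih_day90": nih90,
        }
    )
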