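"""End-to-end study pipeline on synthetic data.

``run_study`` chains every stage — simulate, grid, group comparisons,
saturation curves, repeat-vs-random fidelity, province metrics, residency,
habitat annotation, and mixed-model selection — and returns one JSON-safe
report dictionary, deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from . import ecoregions as eco
from . import fidelity as fid
from .gridding import GridSpec, occupied_cells, range_size
from .models import FULL_TERMS, fit_region_models, vif
from .residency import ResidencyConfig, annotate_habitat, residency_time, transform_covariates
from .sharing import permutation_test, saturation_curve
from .simulate import SimConfig, simulate_population

__all__ = ["run_study", "STUDY_CONFIG"]

#: study-scale conditions: 3 winters, ~38 birds/winter across two colonies,
#: 50-replicate clouds, 151-day seasons
STUDY_CONFIG = SimConfig(n_birds_per_group=19, n_years=3, days=151,
                         n_replicates=50, n_returners=9)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return _jsonify(obj.to_dict())
    return obj


def run_study(config: SimConfig | None = None, seed: int = 0, cell_km: float = 45.0,
              n_permutations: int = 1000, n_curve_iterations: int = 200,
              scales=(45.0, 100.0, 400.0), n_random_pairs: int = 59,
              months=(10, 11, 12, 1, 2), model_terms=FULL_TERMS,
              residency_config: ResidencyConfig = ResidencyConfig()) -> dict:
    """Run the full analysis chain and return a report dict.

    The simulation seed is taken from ``seed`` (overriding the config's),
    and all downstream randomness draws from generators derived from it.
    """
    if config is None:
        config = STUDY_CONFIG
    config = SimConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(seed)

    pop = simulate_population(config)
    clouds = pop.clouds
    grid = GridSpec(cell_size=cell_km)
    cellsets = [occupied_cells(c, grid, months=months) for c in clouds]

    report: dict = {"seed": seed, "n_clouds": len(clouds),
                    "cell_km": cell_km,
                    "config": _jsonify(config.__dict__)}

    # --- individual range size and movement scale
    sizes = np.array([range_size(cs) for cs in cellsets])
    steps = np.concatenate([np.hypot(np.diff(c.best_x), np.diff(c.best_y))
                            for c in clouds])
    report["range_size_cells"] = {"mean": float(sizes.mean()), "sd": float(sizes.std(ddof=1))}
    report["mean_daily_distance_km"] = float(steps.mean())

    # --- group similarity with permutation nulls
    comparisons = {}
    colony = np.array([c.colony for c in clouds])
    sex = np.array([c.sex for c in clouds])
    year = np.array([c.year for c in clouds])
    comparisons["colony"] = permutation_test(
        cellsets, colony, n_iterations=n_permutations, seed=rng).summary()
    comparisons["sex"] = permutation_test(
        cellsets, sex, n_iterations=n_permutations, seed=rng).summary()
    for y1, y2 in combinations(sorted(set(year.tolist())), 2):
        mask = np.isin(year, [y1, y2])
        sub = [cs for cs, m in zip(cellsets, mask) if m]
        comparisons[f"year_{y1}_vs_{y2}"] = permutation_test(
            sub, year[mask], n_iterations=n_permutations, seed=rng).summary()
    report["comparisons"] = comparisons

    # --- saturation curves per colony
    curves = {}
    for name in sorted(set(colony.tolist())):
        group = [cs for cs, c in zip(cellsets, colony) if c == name]
        sc = saturation_curve(group, n_iterations=n_curve_iterations, seed=rng)
        curves[name] = {"n_birds": sc.n_birds.tolist(),
                        "mean_cumulative_cells": sc.mean_cumulative_cells.tolist()}
    report["saturation"] = curves

    # --- individual fidelity, repeat vs random
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = fid.repeat_fidelity(clouds, scales=scales, months=("pooled",))
    fidelity_block: dict = {"n_repeat_birds": int(rep["pair_id"].nunique())}
    try:
        ran = fid.random_pair_null(clouds, n_pairs=n_random_pairs, scales=scales,
                                   months=("pooled",), seed=rng)
        both = pd.concat([rep, ran], ignore_index=True)
        summary = fid.fidelity_summary(both)
        fidelity_block["summary"] = _jsonify(summary.to_dict(orient="records"))
        gaps = {}
        for s in scales:
            r = summary[(summary.scale_km == s) & (summary.pair_type == "repeat")]
            q = summary[(summary.scale_km == s) & (summary.pair_type == "random")]
            if len(r) and len(q):
                gaps[str(int(s))] = float(r["mean"].iloc[0] - q["mean"].iloc[0])
        fidelity_block["repeat_minus_random_gap"] = gaps
    except ValueError as exc:  # constrained pair universe too small
        fidelity_block["random_pairs_error"] = str(exc)
    report["fidelity"] = fidelity_block

    # --- ecoregion occupancy
    emap = eco.assign_cells(grid, pop.ecoregions)
    metrics = eco.region_metrics(clouds, emap, grid)
    per_bird, summaries = eco.per_bird_region_count(clouds, emap, grid)
    share = eco.monthly_region_share(clouds, emap, grid)
    report["regions"] = {
        "metrics": _jsonify(metrics.to_dict(orient="records")),
        "per_bird_mean_regions": float(per_bird["n_regions"].mean()),
        "per_bird_sd_regions": float(per_bird["n_regions"].std(ddof=1)),
        "group_summaries": _jsonify(summaries.to_dict(orient="records")),
        "monthly_share_rows": int(len(share)),
    }

    # --- residency + habitat models
    profiles = []
    for c in clouds:
        profiles.append(residency_time(c, residency_config))
    prof = pd.concat(profiles, ignore_index=True)
    report["residency"] = {
        "mean_days": float(prof["residency_days"].mean()),
        "mean_high_threshold_days": float(
            prof.groupby("bird_id")["residency_days"].quantile(
                residency_config.high_quantile).mean()),
    }

    samples = annotate_habitat(prof, pop.habitat)
    ci, cj = grid.cell_indices(samples["x"].to_numpy(), samples["y"].to_numpy())
    samples["region"] = emap.region_of_cells(zip(ci.tolist(), cj.tolist()))
    design = transform_covariates(samples)
    vifs = vif(design, covariates=list(model_terms))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = fit_region_models(design, terms=model_terms)
    report["habitat_models"] = {
        "vif": _jsonify(vifs.round(3)),
        "regions": {
            name: {"full": res["full"].to_dict(), "best": res["best"].to_dict(),
                   "delta_aic": float(res["full"].aic - res["best"].aic)}
            for name, res in fits.items()
        },
    }
    return _jsonify(report)
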