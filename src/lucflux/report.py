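"""Derived statistics, display rounding, and the end-to-end pipeline driver.

Rates and shares follow the conventions of land-change reporting:
the deforestation rate is the mean annual area loss over the period,
expressed absolutely (Mha yr^-1) and relative to the starting area
(% yr^-1); shares are plain percentages of a total.  Display rounding is
applied only at the formatting boundary — full precision is retained in
every computation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import CATEGORIES, Category

__all__ = [
    "deforestation_rate",
    "share_of_total",
    "fire_climate_correlation",
    "category_area_series",
    "display_round",
    "run_pipeline",
]

log = logging.getLogger("lucflux")


def deforestation_rate(area_start: float, area_end: float, n_years: int):
    """Mean annual forest loss: absolute (area units yr^-1) and % yr^-1.

    The percent rate is the absolute rate relative to the starting area;
    with a zero starting area the percent rate is undefined (NaN).
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if area_start < 0 or area_end < 0:
        raise ValueError("areas must be non-negative")
    abs_rate = (area_start - area_end) / n_years
    pct_rate = abs_rate / area_start * 100.0 if area_start > 0 else float("nan")
    return abs_rate, pct_rate


def share_of_total(part: float, total: float) -> float:
    """part / total as a percentage; total must be positive."""
    if total <= 0:
        raise ValueError("total must be positive")
    return part / total * 100.0


def fire_climate_correlation(fire_emissions, climate_index):
    """Pearson correlation of annual fire emissions with a climate index.

    Computed from first principles (centered cross-products) with the
    two-sided p-value from the t transform; series must be aligned by year
    with n >= 3.  A zero-variance series yields (nan, nan).
    """
    x = np.asarray(fire_emissions, dtype=float)
    y = np.asarray(climate_index, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be aligned 1-d arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 aligned years")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.dot(xc, xc))
    syy = float(np.dot(yc, yc))
    if sxx == 0.0 or syy == 0.0:
        return float("nan"), float("nan")
    r = float(np.dot(xc, yc)) / np.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    from scipy import stats

    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def category_area_series(maps: np.ndarray, years, cell_area_m2: float) -> pd.DataFrame:
    """Area per category and year, Mha; columns partition the land area."""
    maps = np.asarray(maps)
    area_mha = cell_area_m2 / 1e4 / 1e6
    rows = {}
    for c in CATEGORIES:
        rows[c.name.lower()] = (maps == int(c)).sum(axis=0) * area_mha
    return pd.DataFrame(rows, index=pd.Index(list(years), name="year"))


#: display convention: integers where reports print integers, one decimal
#: where they print one decimal
DISPLAY_FORMATS = {"share_pct": 1, "share_pct_int": 0, "rate_mha": 1, "rate_pct": 1}


def display_round(value: float, kind: str) -> float:
    """Round for display only; never feed the result back into computation."""
    return round(value, DISPLAY_FORMATS[kind])


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: dict, seed: int, out_dir) -> dict:
    """Execute simulate -> preprocess -> classify -> state -> account -> report.

    ``config`` mirrors :class:`lucflux.scene.SceneConfig` plus optional
    keys ``cloud_fraction``, ``noise_sd``, ``n_days``, ``n_per_class``,
    ``n_estimators``, ``params_path``, ``scenario`` (avg/max/min),
    ``fire_regime`` (NCM/LCM).  Writes CSV ledgers, maps, the regional
    summary and a JSON manifest under ``out_dir``; deterministic for fixed
    (config, seed).  Returns a dict of the in-memory artifacts.
    """
    from . import classify as cls
    from . import features as feat
    from .emissions import aggregate_regions, envelope_run, ledger_from_scene
    from .parameters import default_parameters, load_parameters, select_scenario
    from .scene import (
        SceneConfig,
        Transition,
        FireEvent,
        build_scene,
        sample_supervised_points,
        simulate_reflectance_year,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene_keys = {
        "width", "height", "year_start", "year_end", "base", "transitions",
        "fires", "peat_cells", "region_id", "cell_area_m2", "agb0",
        "agb0_jitter_sd",
    }
    raw = dict(config)
    sc_kwargs = {k: raw[k] for k in scene_keys & set(raw)}
    if "transitions" in sc_kwargs:
        sc_kwargs["transitions"] = [
            t if isinstance(t, Transition) else Transition(**t)
            for t in sc_kwargs["transitions"]
        ]
    if "fires" in sc_kwargs:
        sc_kwargs["fires"] = [
            f if isinstance(f, FireEvent) else FireEvent(**f)
            for f in sc_kwargs["fires"]
        ]
    if "agb0" in sc_kwargs and not isinstance(
        next(iter(sc_kwargs["agb0"])), Category
    ):
        sc_kwargs["agb0"] = {
            Category[k.upper()]: v for k, v in sc_kwargs["agb0"].items()
        }
    scfg = SceneConfig(**sc_kwargs)

    params_path = raw.get("params_path")
    params = load_parameters(params_path) if params_path else default_parameters()
    central = select_scenario(params, "central")
    log.info("building scene %dx%d, years %s", scfg.width, scfg.height, scfg.years)
    scene = build_scene(scfg, seed=seed, params=central)
    scene.save(out / "scene")

    cloud = float(raw.get("cloud_fraction", 0.0))
    noise = float(raw.get("noise_sd", 0.01))
    n_days = int(raw.get("n_days", 46))
    n_per_class = int(raw.get("n_per_class", 20))
    n_estimators = int(raw.get("n_estimators", 60))
    points = sample_supervised_points(scene, n_per_class, seed=seed)

    raw_maps = np.zeros_like(scene.truth_category)
    for t, year in enumerate(scene.years):
        days, refl, qa = simulate_reflectance_year(
            scene, year, cloud_fraction=cloud, noise_sd=noise, seed=seed,
            n_days=n_days,
        )
        valid, X, _names = feat.build_feature_matrix(days, refl, qa, scene.shape)
        cells, labels = points.for_year(year)
        row_of = {cell: i for i, cell in enumerate(valid)}
        keep = [i for i, c in enumerate(cells) if int(c) in row_of]
        rows = np.array([row_of[int(cells[i])] for i in keep], dtype=int)
        maps5, _folds = cls.five_fold_classify(
            X, rows, labels[keep], seed=seed, n_estimators=n_estimators
        )
        sup_counts = dict(zip(*np.unique(labels[keep], return_counts=True)))
        vote = cls.resolve_votes(maps5, sup_counts)
        full = np.zeros(scene.n_cells, dtype=np.int8)
        full[valid] = vote
        raw_maps[:, t] = full
        log.info("classified year %d (%d valid cells)", year, valid.size)

    maps = cls.post_process(raw_maps, scene.shape)
    pd.DataFrame(maps, columns=[str(y) for y in scene.years]).to_csv(
        out / "landuse_maps.csv", index_label="cell"
    )

    regime = str(raw.get("fire_regime", "NCM")).upper()
    scenario = str(raw.get("scenario", "avg"))
    mode = {"avg": "central", "max": "max", "min": "min"}[scenario]
    point = select_scenario(params, mode)
    from .emissions import compute_ledger
    from .state import fire_history

    fh = fire_history(scene.fires, scene.years[1:], scene.n_cells, regime=regime)
    ledger = compute_ledger(
        maps, scene.years, scene.agb0, fh, scene.peat_mask,
        scene.cell_area_m2, point, combination=regime,
    )
    ledger.annual_totals_tg().to_csv(out / "annual_totals_tg.csv")
    table = aggregate_regions(
        ledger, scene.region_id, scene.peat_mask, scene.cell_area_m2
    )
    table.to_csv(out / "regional_summary.csv")

    areas = category_area_series(maps, scene.years, scene.cell_area_m2)
    areas.to_csv(out / "category_areas_mha.csv")
    rate = deforestation_rate(
        areas["forest"].iloc[0], areas["forest"].iloc[-1], len(scene.years) - 1
    )
    manifest = {
        "seed": seed,
        "scenario": scenario,
        "fire_regime": regime,
        "years": scene.years,
        "deforestation_rate_mha_yr": rate[0],
        "deforestation_rate_pct_yr": rate[1],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "scene": scene,
        "maps": maps,
        "ledger": ledger,
        "regional_summary": table,
        "areas": areas,
        "manifest": manifest,
    }
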