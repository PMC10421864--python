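"""Synthetic gridded worlds and a brute-force emissions oracle.

A :class:`Scene` is a fully specified toy landscape: a per-year categorical
truth map, an initial aboveground-biomass field, a static peat mask, region
labels, and a scripted fire schedule.  Everything a real accounting run
would read from satellite products (daily reflectance, fire detections,
supervised points) is emulated here so the whole pipeline is testable
offline.

:func:`oracle_emissions` is an independent reference implementation of the
accounting equations: a literal per-cell, per-year event walk in plain
Python loops with the fuel-depletion sum evaluated iteratively.  The
vectorised pipeline is tested for exact (float-tolerance) agreement with it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    CATEGORIES,
    DRAINING_CATEGORIES,
    Category,
    PointParams,
)

__all__ = [
    "FireEvent",
    "Transition",
    "SceneConfig",
    "Scene",
    "SupervisedPoints",
    "build_scene",
    "simulate_reflectance_year",
    "sample_supervised_points",
    "oracle_emissions",
    "DEFAULT_SIGNATURES",
    "DEFAULT_AGB0",
]

CONFIDENCES = ("low", "nominal", "high")

#: default initial AGB by category, t dry matter ha^-1
DEFAULT_AGB0 = {
    Category.FOREST: 250.0,
    Category.SHRUB_GRASS: 10.0,
    Category.PLANTATION: 20.0,
    Category.URBAN: 2.0,
    Category.WATER: 0.0,
}

#: default 7-band spectral signatures (reflectance) — deliberately disjoint
#: so noise-free scenes are separable by construction
DEFAULT_SIGNATURES = {
    Category.FOREST: (0.04, 0.45, 0.03, 0.08, 0.25, 0.18, 0.09),
    Category.SHRUB_GRASS: (0.10, 0.35, 0.06, 0.14, 0.30, 0.26, 0.18),
    Category.PLANTATION: (0.06, 0.52, 0.04, 0.10, 0.35, 0.22, 0.12),
    Category.URBAN: (0.22, 0.28, 0.18, 0.22, 0.32, 0.34, 0.30),
    Category.WATER: (0.03, 0.02, 0.05, 0.04, 0.02, 0.01, 0.01),
}


class SceneConfigError(ValueError):
    """Invalid scene configuration."""


@dataclass(frozen=True)
class FireEvent:
    """Scripted fire detections at one cell within one year.

    ``days`` are day-of-year values; consecutive days belong to one ongoing
    fire when counted downstream.  Confidence is explicit (not random) so
    the nominal-confidence / low-confidence map branching is deterministic.
    """

    cell: int
    year: int
    days: tuple[int, ...]
    confidence: str = "high"

    def __post_init__(self):
        days = tuple(sorted(self.days))
        object.__setattr__(self, "days", days)
        if not days:
            raise SceneConfigError("fire event needs at least one detection day")
        if days[0] < 1 or days[-1] > 366:
            raise SceneConfigError(f"fire days must lie in [1, 366], got {days}")
        if self.confidence not in CONFIDENCES:
            raise SceneConfigError(f"confidence must be one of {CONFIDENCES}")


@dataclass(frozen=True)
class Transition:
    """Scripted land-use conversion: the listed cells become ``to`` in ``year``."""

    cells: tuple[int, ...]
    year: int
    to: Category

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(self.cells))
        object.__setattr__(self, "to", Category(self.to))
        if self.to is Category.NODATA:
            raise SceneConfigError("cannot transition into nodata")


@dataclass
class SceneConfig:
    width: int = 10
    height: int = 10
    year_start: int = 2000
    year_end: int = 2005
    base: object = Category.FOREST  # Category, or per-cell array of codes
    transitions: Sequence[Transition] = field(default_factory=list)
    fires: Sequence[FireEvent] = field(default_factory=list)
    peat_cells: Sequence[int] = field(default_factory=list)
    region_id: object = 0  # int, or per-cell array of labels
    cell_area_m2: float = 214369.0  # ~463 m MODIS-like grid -> 21.44 ha
    agb0: dict = field(default_factory=lambda: dict(DEFAULT_AGB0))
    agb0_jitter_sd: float = 0.0  # t/ha, truncated at zero

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))


@dataclass
class Scene:
    """A truth world: categories per year, AGB, peat, regions, fires."""

    width: int
    height: int
    years: list[int]
    cell_area_m2: float
    truth_category: np.ndarray  # (n_cells, n_years) int8
    truth_agb: np.ndarray  # (n_cells, n_years) float, central-parameter walk
    agb0: np.ndarray  # (n_cells,) AGB at the first year
    peat_mask: np.ndarray  # (n_cells,) bool
    region_id: np.ndarray  # (n_cells,) int
    fires: list[FireEvent]

    @property
    def n_cells(self) -> int:
        return self.width * self.height

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def year_index(self, year: int) -> int:
        return self.years.index(year)

    def category_map(self, year: int) -> np.ndarray:
        return self.truth_category[:, self.year_index(year)]

    # -- serialization (CSV layers + JSON manifest) --------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "width": self.width,
            "height": self.height,
            "years": self.years,
            "cell_area_m2": self.cell_area_m2,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        cols = [str(y) for y in self.years]
        pd.DataFrame(self.truth_category, columns=cols).to_csv(
            d / "category.csv", index_label="cell"
        )
        pd.DataFrame(self.truth_agb, columns=cols).to_csv(
            d / "agb.csv", index_label="cell"
        )
        pd.DataFrame(
            {"peat": self.peat_mask.astype(int), "region": self.region_id}
        ).to_csv(d / "layers.csv", index_label="cell")
        rows = [
            {
                "cell": f.cell,
                "year": f.year,
                "day": day,
                "confidence": f.confidence,
            }
            for f in self.fires
            for day in f.days
        ]
        pd.DataFrame(rows, columns=["cell", "year", "day", "confidence"]).to_csv(
            d / "fires.csv", index=False
        )

    @classmethod
    def load(cls, directory) -> "Scene":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        cat = pd.read_csv(d / "category.csv", index_col="cell")
        agb = pd.read_csv(d / "agb.csv", index_col="cell")
        layers = pd.read_csv(d / "layers.csv", index_col="cell")
        fires_df = pd.read_csv(d / "fires.csv")
        fires = [
            FireEvent(
                cell=int(cell),
                year=int(year),
                days=tuple(int(x) for x in grp["day"]),
                confidence=str(grp["confidence"].iloc[0]),
            )
            for (cell, year, _conf), grp in fires_df.groupby(
                ["cell", "year", "confidence"], sort=True
            )
        ] if len(fires_df) else []
        return cls(
            width=manifest["width"],
            height=manifest["height"],
            years=list(manifest["years"]),
            cell_area_m2=manifest["cell_area_m2"],
            truth_category=cat.to_numpy(dtype=np.int8),
            truth_agb=agb.to_numpy(dtype=float),
            agb0=agb.to_numpy(dtype=float)[:, 0].copy(),
            peat_mask=layers["peat"].to_numpy(dtype=bool),
            region_id=layers["region"].to_numpy(dtype=int),
            fires=fires,
        )


def build_scene(config: SceneConfig, seed: int, params: PointParams | None = None) -> "Scene":
    """Construct a deterministic truth world from a config and seed.

    The reference ``truth_agb`` trajectory is produced by the oracle's
    per-cell walk under ``params`` (central defaults if omitted), so the
    scene is self-consistent with the accounting dynamics.
    """
    n_cells = config.width * config.height
    years = config.years
    if len(years) < 1:
        raise SceneConfigError("year range is empty")
    rng = np.random.default_rng(seed)

    base = config.base
    if isinstance(base, (Category, int)):
        cat0 = np.full(n_cells, int(base), dtype=np.int8)
    else:
        cat0 = np.asarray(base, dtype=np.int8).ravel()
        if cat0.size != n_cells:
            raise SceneConfigError("base category map size mismatch")
    valid = {int(c) for c in CATEGORIES}
    if not set(np.unique(cat0)).issubset(valid):
        raise SceneConfigError("base map contains undefined categories")

    truth = np.tile(cat0[:, None], (1, len(years)))
    for tr in config.transitions:
        if tr.year not in years:
            raise SceneConfigError(f"transition year {tr.year} outside scene years")
        t = years.index(tr.year)
        for cell in tr.cells:
            if not (0 <= cell < n_cells):
                raise SceneConfigError(f"transition cell {cell} outside grid")
            truth[cell, t:] = int(tr.to)

    for f in config.fires:
        if f.year not in years:
            raise SceneConfigError(f"fire year {f.year} outside scene years")
        if not (0 <= f.cell < n_cells):
            raise SceneConfigError(f"fire cell {f.cell} outside grid")

    peat = np.zeros(n_cells, dtype=bool)
    peat[list(config.peat_cells)] = True

    if isinstance(config.region_id, (int, np.integer)):
        region = np.full(n_cells, int(config.region_id), dtype=int)
    else:
        region = np.asarray(config.region_id, dtype=int).ravel()
        if region.size != n_cells:
            raise SceneConfigError("region map size mismatch")

    agb0 = np.array([config.agb0[Category(c)] for c in cat0], dtype=float)
    if config.agb0_jitter_sd > 0:
        agb0 = np.maximum(0.0, agb0 + rng.normal(0.0, config.agb0_jitter_sd, n_cells))
    agb0[cat0 == int(Category.WATER)] = 0.0

    scene = Scene(
        width=config.width,
        height=config.height,
        years=years,
        cell_area_m2=config.cell_area_m2,
        truth_category=truth,
        truth_agb=np.tile(agb0[:, None], (1, len(years))),
        agb0=agb0,
        peat_mask=peat,
        region_id=region,
        fires=list(config.fires),
    )
    if params is None:
        from .parameters import default_parameters, select_scenario

        params = select_scenario(default_parameters(), "central")
    if len(years) > 1:
        ledger = oracle_emissions(scene, params)
        scene.truth_agb = ledger["agb"]
    return scene


# ---------------------------------------------------------------------------
# reflectance emulation


def simulate_reflectance_year(
    scene: Scene,
    year: int,
    cloud_fraction: float = 0.0,
    noise_sd: float = 0.01,
    seed: int = 0,
    n_days: int = 365,
    signatures: dict | None = None,
    seasonal_amplitude: float = 0.02,
):
    """Emulate one year of daily 7-band surface reflectance with QA flags.

    Each category has a distinct mean 7-band signature; a shared seasonal
    sinusoid and i.i.d. Gaussian noise are added, values clipped to [0, 1].
    A ``cloud_fraction`` share of cell-days is flagged bad; bad values are
    overwritten with a sentinel (-1) so downstream code cannot silently use
    them.  Deterministic for fixed (scene, year, seed).

    Returns ``(days, reflectance, qa_good)`` with shapes
    (n_days,), (n_cells, n_days, 7), (n_cells, n_days).
    """
    if not (0.0 <= cloud_fraction < 1.0):
        raise SceneConfigError("cloud_fraction must lie in [0, 1)")
    sig = signatures or DEFAULT_SIGNATURES
    rng = np.random.default_rng(np.random.SeedSequence((seed, year, 7)))
    cats = scene.category_map(year)
    n_cells = scene.n_cells
    days = np.unique(np.linspace(1, 365, n_days).round().astype(int))
    n_days = days.size

    sig_arr = np.zeros((6, 7))
    for c in CATEGORIES:
        sig_arr[int(c)] = sig[c]
    base = sig_arr[cats]  # (n_cells, 7)
    season = seasonal_amplitude * np.sin(2.0 * np.pi * days / 365.0)  # (n_days,)
    refl = base[:, None, :] + season[None, :, None]
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.0)

    qa_good = np.ones((n_cells, n_days), dtype=bool)
    if cloud_fraction > 0:
        qa_good = rng.random((n_cells, n_days)) >= cloud_fraction
    refl[~qa_good] = -1.0
    return days, refl, qa_good


# ---------------------------------------------------------------------------
# supervised points


@dataclass
class SupervisedPoints:
    """Labelled point set digitised at the first and last scene years.

    Points whose category is identical in both years are considered stable
    and usable for every intermediate year; unstable points are usable only
    for the two anchor years, each with its own-year label.
    """

    cells: np.ndarray
    label_first: np.ndarray
    label_last: np.ndarray
    year_first: int
    year_last: int

    @property
    def stable(self) -> np.ndarray:
        return self.label_first == self.label_last

    def for_year(self, year: int) -> tuple[np.ndarray, np.ndarray]:
        """Usable (cells, labels) for classifying the given year."""
        if year == self.year_first:
            return self.cells, self.label_first
        if year == self.year_last:
            return self.cells, self.label_last
        m = self.stable
        return self.cells[m], self.label_first[m]


def sample_supervised_points(
    scene: Scene,
    n_per_class: int,
    rule: str = "stable_only",
    seed: int = 0,
) -> SupervisedPoints:
    """Sample ``n_per_class`` cells per first-year category as labelled points.

    ``rule='stable_only'`` restricts intermediate-year usability to points
    whose category matches in the first and last years; ``rule='all'`` keeps
    every point usable in all years (labelled with its first-year category).
    """
    if rule not in ("stable_only", "all"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    first = scene.truth_category[:, 0]
    last = scene.truth_category[:, -1]
    cells_out: list[np.ndarray] = []
    for c in CATEGORIES:
        pool = np.flatnonzero(first == int(c))
        if pool.size == 0:
            continue
        if pool.size < n_per_class:
            raise ValueError(
                f"category {c.name} has {pool.size} cells, need {n_per_class}"
            )
        cells_out.append(rng.choice(pool, size=n_per_class, replace=False))
    if not cells_out:
        raise ValueError("scene has no categorised cells to sample")
    cells = np.sort(np.concatenate(cells_out))
    lf = first[cells].astype(np.int8)
    ll = last[cells].astype(np.int8)
    if rule == "all":
        ll = lf.copy()
    return SupervisedPoints(
        cells=cells,
        label_first=lf,
        label_last=ll,
        year_first=scene.years[0],
        year_last=scene.years[-1],
    )


# ---------------------------------------------------------------------------
# brute-force oracle


def _merge_runs(days: Iterable[int], merge_gap: int = 1) -> list[list[int]]:
    """Group sorted detection days into ongoing-fire runs; a gap larger than
    ``merge_gap`` days starts a new event."""
    runs: list[list[int]] = []
    for d in sorted(set(days)):
        if runs and d - runs[-1][-1] <= merge_gap:
            runs[-1].append(d)
        else:
            runs.append([d])
    return runs


def _cell_year_events(
    fires: Sequence[FireEvent], regime: str, merge_gap: int
) -> dict[tuple[int, int], int]:
    """Merged event count per (cell, year) under a confidence regime."""
    keep = {"NCM": ("nominal", "high"), "LCM": CONFIDENCES}[regime]
    days: dict[tuple[int, int], list[int]] = {}
    for f in fires:
        if f.confidence in keep:
            days.setdefault((f.cell, f.year), []).extend(f.days)
    return {key: len(_merge_runs(d, merge_gap)) for key, d in days.items()}


def oracle_emissions(
    scene: Scene,
    params: PointParams,
    regime: str = "NCM",
    merge_gap: int = 1,
) -> dict:
    """Ground-truth emission ledger by literal per-cell event enumeration.

    Walks every cell through every accounting year in plain Python,
    applying growth, per-event fuel depletion (iterative sum, no closed
    form), conversion, drainage bookkeeping, and the five flux terms.
    Returns a dict of (n_cells, n_accounting_years) arrays in g CO2 yr^-1
    for keys ``E_LUC, E_BB, E_PB, E_PD, Sink, E_T``, the accounting
    ``years``, and the per-year end-of-year ``agb`` trajectory
    (n_cells, n_years, t DM ha^-1, first column = initial state).
    """
    if regime not in ("NCM", "LCM"):
        raise ValueError(f"regime must be NCM or LCM, got {regime!r}")
    years = scene.years
    n_years = len(years)
    n_cells = scene.n_cells
    acc_years = years[1:]
    T = len(acc_years)
    events = _cell_year_events(scene.fires, regime, merge_gap)

    comp = {
        k: np.zeros((n_cells, T)) for k in ("E_LUC", "E_BB", "E_PB", "E_PD", "Sink")
    }
    agb_traj = np.zeros((n_cells, n_years))
    ba = scene.cell_area_m2
    area_ha = scene.cell_area_m2 / 1e4
    p = params
    factor_luc = p.CC_L + p.R_BGB * p.CC_L + p.R_WDL * p.CC_D

    for cell in range(n_cells):
        agb = float(scene.agb0[cell])
        agb_traj[cell, 0] = agb
        ordinal = 0
        peat = bool(scene.peat_mask[cell])
        drained = Category(int(scene.truth_category[cell, 0])) in DRAINING_CATEGORIES
        for t in range(T):
            cat_prev = Category(int(scene.truth_category[cell, t]))
            cat_cur = Category(int(scene.truth_category[cell, t + 1]))
            # (1) growth of the standing (previous-year) vegetation
            g = p.growth[cat_prev]
            agb += g
            comp["Sink"][cell, t] = area_ha * g * p.CC_L * p.C_CtoCO2 * 1e6
            # (2) fires of the target year, category from the target-year map
            n_ev = events.get((cell, acc_years[t]), 0)
            if n_ev > 0:
                be = p.BE[cat_cur]
                bd = 0.0
                for i in range(1, n_ev + 1):
                    bd += agb * (1.0 - be) ** (i - 1)
                bd_kg_m2 = bd * 0.1  # t/ha -> kg/m2
                comp["E_BB"][cell, t] = (
                    ba
                    * bd_kg_m2
                    * be
                    * p.EF_bb[cat_cur]
                    * (1.0 + p.R_BGB + p.R_WDL)
                )
                for _ in range(n_ev):
                    agb *= 1.0 - be
                if peat:
                    e_pb = 0.0
                    for _ in range(n_ev):
                        ordinal += 1
                        e_pb += (
                            ba
                            * p.BurnD
                            * p.dr(ordinal)
                            * p.BulkD[cat_cur]
                            * be
                            * p.EF_pb[cat_cur]
                        )
                    comp["E_PB"][cell, t] = e_pb
                else:
                    ordinal += n_ev
            # (3) conversion recorded in the end-of-year map
            if cat_cur != cat_prev:
                agb_post = p.AGB_post[cat_cur]
                d_agb = max(0.0, agb - agb_post)
                comp["E_LUC"][cell, t] = (
                    area_ha * d_agb * factor_luc * p.C_CtoCO2 * 1e6
                )
                agb = agb_post
            # (4) peat decomposition under the target-year category
            if peat:
                if cat_cur in DRAINING_CATEGORIES:
                    drained = True
                ef = (
                    p.EF_pd_drained[cat_cur]
                    if drained
                    else p.EF_pd_undrained[cat_cur]
                )
                comp["E_PD"][cell, t] = area_ha * ef * 1e6
            agb = max(0.0, agb)
            agb_traj[cell, t + 1] = agb

    e_t = (
        comp["E_LUC"] + comp["E_BB"] + comp["E_PB"] + comp["E_PD"] - comp["Sink"]
    )
    return {**comp, "E_T": e_t, "years": list(acc_years), "agb": agb_traj}
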