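"""Inter-annual landscape state: changes, fires, drainage, biomass.

Everything stateful between two consecutive annual maps lives here:

* change records (which cells converted, with the converted area and the
  aboveground-biomass drop that prices the conversion);
* fire histories (daily detections filtered by a confidence regime and
  merged into ongoing-fire events, with cumulative fire ordinals since the
  accounting start for the burn-depth decay lookup);
* drained-peat status (a peat cell counts as drained from the first year it
  is observed under shrub/grass, plantation or urban — water is flooding,
  not drainage — and stays drained thereafter);
* the evolving AGB field, updated annually in the fixed order
  growth -> fires -> conversion (fires burn stock grown that year; the
  conversion is recorded in the end-of-year map).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parameters import DRAINING_CATEGORIES, Category, PointParams
from .scene import CONFIDENCES, FireEvent, _merge_runs

__all__ = [
    "ChangeRecord",
    "FireHistory",
    "detect_change",
    "count_fire_events",
    "fire_history",
    "update_drainage",
    "backcast_agb",
    "advance_agb",
]


@dataclass(frozen=True)
class ChangeRecord:
    """One converted cell between two consecutive annual maps.

    ``d_agb`` may be negative when the target category's default stocking
    exceeds the pre-change biomass; the conversion emission term floors it
    at zero (regrowth is the sink's job, not a negative emission).
    """

    cell: int
    year: int
    from_category: Category
    to_category: Category
    ca_ha: float  # converted area, ha
    agb_pre: float  # t DM/ha before change
    agb_cur: float  # t DM/ha after change

    @property
    def d_agb(self) -> float:
        return self.agb_pre - self.agb_cur


def detect_change(
    map_prev: np.ndarray,
    map_cur: np.ndarray,
    cell_area_m2: float,
    year: int = 0,
    agb_pre: np.ndarray | None = None,
    agb_post: dict | None = None,
) -> list[ChangeRecord]:
    """Compare two consecutive annual maps and list the converted cells.

    AGB context is optional: when ``agb_pre`` (per-cell t DM/ha) and
    ``agb_post`` (category -> default post-conversion AGB) are given, the
    records carry the biomass drop needed by the conversion emission term.
    """
    map_prev = np.asarray(map_prev)
    map_cur = np.asarray(map_cur)
    if map_prev.shape != map_cur.shape:
        raise ValueError("map grids do not align")
    ca_ha = cell_area_m2 / 1e4
    records = []
    for cell in np.flatnonzero(map_prev != map_cur):
        pre = float(agb_pre[cell]) if agb_pre is not None else float("nan")
        to_cat = Category(int(map_cur[cell]))
        cur = float(agb_post[to_cat]) if agb_post is not None else float("nan")
        records.append(
            ChangeRecord(
                cell=int(cell),
                year=year,
                from_category=Category(int(map_prev[cell])),
                to_category=to_cat,
                ca_ha=ca_ha,
                agb_pre=pre,
                agb_cur=cur,
            )
        )
    return records


@dataclass
class FireHistory:
    """Merged fire events per cell and accounting year under one regime.

    ``counts[cell, t]`` is I, the number of ongoing-fire events in year t;
    ``start_ordinal[cell, t]`` is the cumulative number of events at the
    cell before year t (so the events of year t carry ordinals
    start_ordinal+1 ... start_ordinal+I for the burn-depth decay lookup).
    """

    regime: str
    years: list[int]
    counts: np.ndarray  # (n_cells, n_years) int
    start_ordinal: np.ndarray  # (n_cells, n_years) int

    @property
    def cumulative(self) -> np.ndarray:
        """Cumulative event count through the end of each year."""
        return self.start_ordinal + self.counts


def count_fire_events(
    fires: Sequence[FireEvent],
    year: int,
    n_cells: int,
    regime: str = "NCM",
    merge_gap: int = 1,
) -> np.ndarray:
    """Event counts I per cell for one year under a confidence regime.

    The regime filters detections (NCM keeps nominal+high confidence, LCM
    keeps all three classes); detections on consecutive days at one cell
    merge into a single ongoing fire.  A gap of more than ``merge_gap``
    days starts a new event.
    """
    if regime not in ("NCM", "LCM"):
        raise ValueError(f"regime must be NCM or LCM, got {regime!r}")
    keep = {"NCM": ("nominal", "high"), "LCM": CONFIDENCES}[regime]
    days_by_cell: dict[int, list[int]] = {}
    for f in fires:
        if f.year == year and f.confidence in keep:
            days_by_cell.setdefault(f.cell, []).extend(f.days)
    counts = np.zeros(n_cells, dtype=int)
    for cell, days in days_by_cell.items():
        counts[cell] = len(_merge_runs(days, merge_gap))
    return counts


def fire_history(
    fires: Sequence[FireEvent],
    years: Sequence[int],
    n_cells: int,
    regime: str = "NCM",
    merge_gap: int = 1,
) -> FireHistory:
    """Assemble the full multi-year fire history with cumulative ordinals."""
    years = list(years)
    counts = np.stack(
        [count_fire_events(fires, y, n_cells, regime, merge_gap) for y in years],
        axis=1,
    )
    start = np.zeros_like(counts)
    start[:, 1:] = np.cumsum(counts[:, :-1], axis=1)
    return FireHistory(
        regime=regime, years=years, counts=counts, start_ordinal=start
    )


def update_drainage(
    peat_mask: np.ndarray, maps: np.ndarray, static: bool = False
) -> np.ndarray:
    """Per-year drained status of peat cells.

    ``maps`` is the (n_cells, n_years) post-processed map stack including
    the start-year map.  A peat cell is drained from the first year it is
    observed under a draining category (shrub/grass, plantation, urban) and
    stays drained; with ``static=True`` a cell ever drained counts as
    drained for the whole period (the whole-record reading).  Non-peat
    cells are never drained.
    """
    maps = np.asarray(maps)
    peat = np.asarray(peat_mask, dtype=bool)
    draining = np.isin(maps, [int(c) for c in DRAINING_CATEGORIES])
    drained = np.logical_or.accumulate(draining, axis=1)
    if static:
        ever = drained[:, -1]
        drained = np.tile(ever[:, None], (1, maps.shape[1]))
    return drained & peat[:, None]


def backcast_agb(
    agb_epoch: np.ndarray,
    epoch_year: int,
    target_year: int,
    epoch_map: np.ndarray,
    growth: dict,
) -> np.ndarray:
    """Roll an AGB map back in time by removing the intervening growth.

    AGB_target = max(0, AGB_epoch - growth(category) * (epoch - target)),
    with the category taken from the epoch-year map.  Used to place a
    later-epoch biomass product at the accounting start year.
    """
    if epoch_year <= target_year:
        raise ValueError("epoch_year must be after target_year")
    agb_epoch = np.asarray(agb_epoch, dtype=float)
    epoch_map = np.asarray(epoch_map)
    try:
        g = np.array(
            [growth.get(Category(int(c)), None) for c in np.arange(6)], dtype=object
        )
    except ValueError as exc:
        raise ValueError(f"bad category in epoch map: {exc}") from None
    rates = np.zeros(agb_epoch.shape)
    for cell, code in enumerate(epoch_map):
        rate = g[int(code)]
        if rate is None:
            raise KeyError(f"no growth rate for category {Category(int(code)).name}")
        rates[cell] = rate
    return np.maximum(0.0, agb_epoch - rates * (epoch_year - target_year))


def advance_agb(
    agb_prev: np.ndarray,
    map_prev: np.ndarray,
    map_cur: np.ndarray,
    fire_counts: np.ndarray,
    params: PointParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One annual AGB update in the fixed order growth -> fires -> conversion.

    Returns ``(agb_new, agb_pre_fire)`` in t DM/ha: the end-of-year state
    and the post-growth stock standing when the year's fires started (the
    fuel-availability input of the burning term).  Fire parameters are
    looked up under the target-year map category.  AGB is floored at zero
    throughout; NaN inputs are rejected.
    """
    agb_prev = np.asarray(agb_prev, dtype=float)
    if np.isnan(agb_prev).any():
        raise ValueError("NaN in AGB state")
    map_prev = np.asarray(map_prev)
    map_cur = np.asarray(map_cur)
    fire_counts = np.asarray(fire_counts)
    growth = np.array([params.growth.get(Category(c), 0.0) for c in range(6)])
    be = np.array([params.BE.get(Category(c), 0.0) for c in range(6)])
    agb_post = np.array([params.AGB_post.get(Category(c), 0.0) for c in range(6)])
    # (1) growth of the standing vegetation
    agb = agb_prev + growth[map_prev]
    agb_pre_fire = agb.copy()
    # (2) each fire event burns a BE share of the remaining stock
    agb = agb * (1.0 - be[map_cur]) ** fire_counts
    # (3) conversion resets the stock to the target category default
    changed = map_prev != map_cur
    agb = np.where(changed, agb_post[map_cur], agb)
    return np.maximum(0.0, agb), agb_pre_fire
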