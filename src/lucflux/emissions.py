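"""Net CO2 accounting: the five flux terms, envelopes, ensembles, regions.

Per cell p and year, the net flux is

    E_T(p) = E_LUC(p) + E_BB(p) + E_PB(p) + E_PD(p) - Sink(p)

with
  E_LUC  conversion emissions: CA * D_AGB * (CC_L + R_BGB*CC_L + R_WDL*CC_D)
         * 44/12 — the aboveground, belowground and debris/litter carbon
         lost when a cell changes category (D_AGB floored at zero);
  E_BB   biomass burning: BA * BD_AGB * BE * EF * (1 + R_BGB + R_WDL),
         where the year's available fuel BD_AGB sums the geometrically
         depleted stock over the I fires of the year,
         BD_AGB = sum_{i=1..I} AGB_pre * (1-BE)^(i-1);
  E_PB   peat burning per event: BA * BurnD * DR(ordinal) * BulkD * BE * EF,
         the burn depth decaying with the cumulative fire ordinal;
  E_PD   oxidative decomposition of drained peat: PA * EF(category);
  Sink   growth uptake: area * growth(category) * CC_L * 44/12.

Internal arithmetic is in g CO2 (areas m^2, fuel kg, depth m); biomass
state is carried in t dry matter ha^-1 and converted at the boundary
(1 t/ha = 0.1 kg/m^2).  Reports aggregate to Tg CO2 yr^-1 and
Mg CO2 ha^-1 yr^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    CATEGORIES,
    Category,
    ParameterSet,
    PointParams,
    select_scenario,
)
from .scene import Scene
from .state import ChangeRecord, FireHistory, advance_agb, fire_history, update_drainage

__all__ = [
    "EmissionLedger",
    "emission_luc",
    "burned_agb_density",
    "emission_biomass_burning",
    "emission_peat_burning",
    "emission_peat_decomposition",
    "sink",
    "total_net",
    "compute_ledger",
    "envelope_run",
    "ensemble_average",
    "aggregate_regions",
]

T_PER_HA_TO_KG_PER_M2 = 0.1
T_TO_G = 1e6
G_TO_TG = 1e-12

COMPONENTS = ("E_LUC", "E_BB", "E_PB", "E_PD", "Sink")


# ---------------------------------------------------------------------------
# per-term operations (scalar/array forms used by both pipeline and reports)


def emission_luc(record: ChangeRecord, params: PointParams) -> float:
    """Conversion emission for one change record, g CO2.

    Three additive carbon-loss terms (aboveground, belowground, woody
    debris + litter) priced at the live/dead carbon contents, times the
    converted area and the C->CO2 mass ratio.  A biomass *gain* on
    conversion contributes zero (regrowth is the sink's job).
    """
    if record.ca_ha < 0:
        raise ValueError("converted area must be non-negative")
    d_agb = max(0.0, record.d_agb)
    p = params
    per_ha_t_co2 = (
        d_agb * (p.CC_L + p.R_BGB * p.CC_L + p.R_WDL * p.CC_D) * p.C_CtoCO2
    )
    return record.ca_ha * per_ha_t_co2 * T_TO_G


def burned_agb_density(agb_pre, be, i_events):
    """Total fuel available over a year with I fires (same units as agb_pre).

    Closed form of the geometric depletion sum
    sum_{i=1..I} AGB_pre*(1-BE)^(i-1) = AGB_pre * (1-(1-BE)^I)/BE.
    BE = 0 degenerates to AGB_pre * I (nothing burns but the sum is
    defined); I = 0 gives 0.  Array-broadcastable.
    """
    agb_pre = np.asarray(agb_pre, dtype=float)
    be = np.asarray(be, dtype=float)
    i_events = np.asarray(i_events)
    if (i_events < 0).any():
        raise ValueError("fire count must be non-negative")
    if ((be < 0) | (be > 1)).any():
        raise ValueError("BE must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        closed = agb_pre * (1.0 - (1.0 - be) ** i_events) / be
    degenerate = be == 0
    out = np.where(degenerate, agb_pre * i_events, closed)
    return out if out.ndim else float(out)


def emission_biomass_burning(
    ba_m2, bd_agb_kg_m2, be, ef_bb, r_bgb, r_wdl
):
    """Biomass-burning emission, g CO2 (array-broadcastable).

    BA * BD_AGB * BE * EF applied to the aboveground pool plus the
    R_BGB and R_WDL shares for the belowground and debris/litter pools.
    """
    return np.asarray(ba_m2) * np.asarray(bd_agb_kg_m2) * be * ef_bb * (
        1.0 + r_bgb + r_wdl
    )


def emission_peat_burning(
    ba_m2, burn_d_m, dr, bulk_d_kg_m3, be, ef_pb
):
    """Peat-burning emission for one event, g CO2: burned volume (area x
    decayed depth) times bulk density, burning efficiency and the peat
    emission factor."""
    return ba_m2 * burn_d_m * dr * bulk_d_kg_m3 * be * ef_pb


def emission_peat_decomposition(pa_ha, ef_pd_t_co2_ha_yr):
    """Oxidative peat-decomposition emission, g CO2 yr^-1."""
    return np.asarray(pa_ha) * np.asarray(ef_pd_t_co2_ha_yr) * T_TO_G


def sink(area_ha, growth_t_dm_ha_yr, cc_l, growth_in_co2: bool = False):
    """Growth uptake, g CO2 yr^-1.

    Dry-matter growth is converted through the live carbon content and the
    C->CO2 ratio; ``growth_in_co2=True`` accepts growth already expressed
    in t CO2 ha^-1 yr^-1.
    """
    g = np.asarray(growth_t_dm_ha_yr, dtype=float)
    if not growth_in_co2:
        g = g * cc_l * (44.0 / 12.0)
    return np.asarray(area_ha) * g * T_TO_G


def total_net(e_luc, e_bb, e_pb, e_pd, sink_):
    """E_T = E_LUC + E_BB + E_PB + E_PD - Sink (exact signed sum)."""
    return (
        np.asarray(e_luc)
        + np.asarray(e_bb)
        + np.asarray(e_pb)
        + np.asarray(e_pd)
        - np.asarray(sink_)
    )


# ---------------------------------------------------------------------------
# the ledger and the vectorised accounting walk


@dataclass
class EmissionLedger:
    """Per-cell, per-year component fluxes in g CO2 yr^-1.

    ``components[name]`` has shape (n_cells, n_years) over the accounting
    years (the first mapped year prices no fluxes: it is the initial
    state).  ``E_T`` is always the exact signed sum of the five terms, and
    ``E_Fire = E_BB + E_PB`` is the aggregate used in fire reporting.
    """

    years: list[int]
    components: dict
    scenario: str = "central"
    combination: str = ""

    def __post_init__(self):
        missing = set(COMPONENTS) - set(self.components)
        if missing:
            raise ValueError(f"ledger missing components {sorted(missing)}")

    @property
    def E_T(self) -> np.ndarray:
        c = self.components
        return total_net(c["E_LUC"], c["E_BB"], c["E_PB"], c["E_PD"], c["Sink"])

    @property
    def E_Fire(self) -> np.ndarray:
        return self.components["E_BB"] + self.components["E_PB"]

    def annual_totals_tg(self) -> pd.DataFrame:
        """Grid-total annual series per component, Tg CO2 yr^-1."""
        rows = {}
        for name in COMPONENTS:
            rows[name] = self.components[name].sum(axis=0) * G_TO_TG
        rows["E_Fire"] = self.E_Fire.sum(axis=0) * G_TO_TG
        rows["E_T"] = self.E_T.sum(axis=0) * G_TO_TG
        return pd.DataFrame(rows, index=pd.Index(self.years, name="year"))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-cell frame (cell, year, component, value_g)."""
        frames = []
        comps = dict(self.components)
        comps["E_T"] = self.E_T
        for name, arr in comps.items():
            df = pd.DataFrame(arr, columns=self.years)
            df.index.name = "cell"
            long = df.reset_index().melt("cell", var_name="year", value_name="value_g")
            long["component"] = name
            frames.append(long)
        out = pd.concat(frames, ignore_index=True)
        out["scenario"] = self.scenario
        out["combination"] = self.combination
        return out


def compute_ledger(
    maps: np.ndarray,
    years,
    agb_start: np.ndarray,
    fires: FireHistory,
    peat_mask: np.ndarray,
    cell_area_m2: float,
    params: PointParams,
    drainage_static: bool = False,
    scenario: str | None = None,
    combination: str = "",
) -> EmissionLedger:
    """Run the annual accounting walk over a map stack.

    Parameters
    ----------
    maps : (n_cells, n_years) category codes, post-processed (no nodata),
        first column = state at the accounting start
    years : the mapped years (accounting prices years[1:])
    agb_start : (n_cells,) AGB at the first year, t DM/ha
    fires : multi-year :class:`FireHistory` aligned to years[1:]
    peat_mask, cell_area_m2 : static scene layers
    params : point-valued (collapsed) parameters

    The per-year order is growth -> fires -> conversion; fire parameters
    are looked up under the target-year map, growth under the standing
    (previous-year) map.
    """
    maps = np.asarray(maps)
    years = list(years)
    n_cells, n_years = maps.shape
    if len(years) != n_years:
        raise ValueError("years do not match the map stack")
    acc_years = years[1:]
    if list(fires.years) != acc_years:
        raise ValueError("fire history years must equal the accounting years")
    peat = np.asarray(peat_mask, dtype=bool)
    p = params
    area_ha = cell_area_m2 / 1e4
    ba = cell_area_m2

    def cat_arr(d: dict) -> np.ndarray:
        return np.array([d.get(Category(c), 0.0) for c in range(6)])

    growth = cat_arr(p.growth)
    be = cat_arr(p.BE)
    ef_bb = cat_arr(p.EF_bb)
    ef_pb = cat_arr(p.EF_pb)
    bulk_d = cat_arr(p.BulkD)
    ef_pd_dr = cat_arr(p.EF_pd_drained)
    ef_pd_un = cat_arr(p.EF_pd_undrained)
    agb_post = cat_arr(p.AGB_post)

    drained = update_drainage(peat, maps, static=drainage_static)

    T = len(acc_years)
    comp = {k: np.zeros((n_cells, T)) for k in COMPONENTS}
    agb = np.asarray(agb_start, dtype=float).copy()

    # per-year sum of DR over the events' cumulative ordinals, vectorised
    # through the envelope schedule
    sched = np.asarray(p.DR_schedule)

    def dr_sum(start_ord: np.ndarray, counts: np.ndarray) -> np.ndarray:
        out = np.zeros(start_ord.shape)
        max_i = int(counts.max()) if counts.size else 0
        for k in range(1, max_i + 1):
            active = counts >= k
            ords = np.minimum(start_ord[active] + k, sched.size) - 1
            vals = np.zeros(active.sum())
            vals = sched[ords]
            tmp = np.zeros(start_ord.shape)
            tmp[active] = vals
            out += tmp
        return out

    for t in range(T):
        cat_prev = maps[:, t]
        cat_cur = maps[:, t + 1]
        i_events = fires.counts[:, t]
        # growth + sink
        g = growth[cat_prev]
        comp["Sink"][:, t] = sink(area_ha, g, p.CC_L)
        agb_new, agb_pre_fire = advance_agb(agb, cat_prev, cat_cur, i_events, p)
        # biomass burning from the post-growth standing stock
        be_c = be[cat_cur]
        bd_t_ha = burned_agb_density(agb_pre_fire, be_c, i_events)
        comp["E_BB"][:, t] = emission_biomass_burning(
            ba,
            np.asarray(bd_t_ha) * T_PER_HA_TO_KG_PER_M2,
            be_c,
            ef_bb[cat_cur],
            p.R_BGB,
            p.R_WDL,
        )
        # peat burning with burn-depth decay by cumulative ordinal
        on_peat = peat & (i_events > 0)
        drs = dr_sum(fires.start_ordinal[:, t], i_events)
        comp["E_PB"][:, t] = np.where(
            on_peat,
            ba * p.BurnD * drs * bulk_d[cat_cur] * be_c * ef_pb[cat_cur],
            0.0,
        )
        # conversion: price the drop from the post-fire stock
        changed = cat_prev != cat_cur
        agb_after_fire = agb_pre_fire * (1.0 - be_c) ** i_events
        d_agb = np.maximum(0.0, agb_after_fire - agb_post[cat_cur])
        comp["E_LUC"][:, t] = np.where(
            changed,
            area_ha
            * d_agb
            * (p.CC_L + p.R_BGB * p.CC_L + p.R_WDL * p.CC_D)
            * p.C_CtoCO2
            * T_TO_G,
            0.0,
        )
        # peat decomposition under the target-year category
        ef = np.where(drained[:, t + 1], ef_pd_dr[cat_cur], ef_pd_un[cat_cur])
        comp["E_PD"][:, t] = np.where(peat, emission_peat_decomposition(area_ha, ef), 0.0)
        agb = agb_new

    return EmissionLedger(
        years=acc_years,
        components=comp,
        scenario=scenario or p.mode,
        combination=combination,
    )


def ledger_from_scene(
    scene: Scene,
    params: PointParams,
    regime: str = "NCM",
    merge_gap: int = 1,
    drainage_static: bool = False,
    combination: str | None = None,
) -> EmissionLedger:
    """Accounting walk over a scene's truth maps (oracle-comparable path)."""
    fh = fire_history(
        scene.fires, scene.years[1:], scene.n_cells, regime=regime, merge_gap=merge_gap
    )
    return compute_ledger(
        scene.truth_category,
        scene.years,
        scene.agb0,
        fh,
        scene.peat_mask,
        scene.cell_area_m2,
        params,
        drainage_static=drainage_static,
        combination=combination or regime,
    )


# ---------------------------------------------------------------------------
# envelope, ensemble, regional aggregation


def envelope_run(
    scene: Scene,
    params: ParameterSet,
    regime: str = "NCM",
    sign_aware: bool = True,
    **kwargs,
) -> dict[str, EmissionLedger]:
    """Three full runs at the central / emission-max / emission-min bounds.

    Returns ``{"Eavg": ..., "Emax": ..., "Emin": ...}``.  With sign-aware
    collapsing (growth to the opposite bound) the three runs bracket the
    net flux on the study scenes.
    """
    tags = {"Eavg": "central", "Emax": "max", "Emin": "min"}
    out = {}
    for tag, mode in tags.items():
        point = select_scenario(params, mode, sign_aware=sign_aware)
        led = ledger_from_scene(scene, point, regime=regime, **kwargs)
        led.scenario = tag
        out[tag] = led
    return out


def ensemble_average(ledgers: list[EmissionLedger]) -> EmissionLedger:
    """Arithmetic mean over aligned ledgers, component-wise.

    The standard ensemble is the 2 x 2 of fire regimes {NCM, LCM} and the
    two biomass-map sources; fewer members are averaged as-is.
    """
    if not ledgers:
        raise ValueError("no ledgers to average")
    years = ledgers[0].years
    for led in ledgers:
        if led.years != years:
            raise ValueError("ledger years are not aligned")
    comp = {
        name: np.mean([led.components[name] for led in ledgers], axis=0)
        for name in COMPONENTS
    }
    return EmissionLedger(
        years=years,
        components=comp,
        scenario=ledgers[0].scenario,
        combination="ensemble_mean_%d" % len(ledgers),
    )


def aggregate_regions(
    ledger: EmissionLedger,
    region_id: np.ndarray,
    peat_mask: np.ndarray,
    cell_area_m2: float,
) -> pd.DataFrame:
    """Regional summary table of the accounting period.

    One row per region (plus ``all``), with per-component period mean and
    SD of the annual totals (Tg CO2 yr^-1), the max/min years of the net
    flux, and per-area net intensities (Mg CO2 ha^-1 yr^-1) split by
    mineral soil vs peatland.
    """
    region_id = np.asarray(region_id)
    peat = np.asarray(peat_mask, dtype=bool)
    regions = [("all", np.ones(region_id.shape, dtype=bool))] + [
        (str(r), region_id == r) for r in np.unique(region_id)
    ]
    comps = dict(ledger.components)
    comps["E_Fire"] = ledger.E_Fire
    comps["E_T"] = ledger.E_T
    rows = []
    area_ha = cell_area_m2 / 1e4
    for name, mask in regions:
        row: dict = {"region": name}
        for cname, arr in comps.items():
            annual = arr[mask].sum(axis=0) * G_TO_TG
            row[f"{cname}_mean_tg"] = annual.mean()
            row[f"{cname}_sd_tg"] = annual.std(ddof=1) if annual.size > 1 else 0.0
        net = comps["E_T"][mask].sum(axis=0) * G_TO_TG
        years = np.asarray(ledger.years)
        row["E_T_max_tg"], row["E_T_max_year"] = net.max(), int(years[net.argmax()])
        row["E_T_min_tg"], row["E_T_min_year"] = net.min(), int(years[net.argmin()])
        for soil, smask in (("mineral", mask & ~peat), ("peat", mask & peat)):
            area = smask.sum() * area_ha
            if area > 0:
                mean_g = comps["E_T"][smask].sum(axis=0).mean()
                row[f"net_per_ha_{soil}_mg"] = mean_g / 1e6 / area
            else:
                row[f"net_per_ha_{soil}_mg"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")
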