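"""Scaling-factor handling for the emission model.

Every tunable quantity of the accounting scheme (burning efficiencies,
emission factors, biomass ratios, peat properties, growth rates) is carried
as a min/central/max envelope so the pipeline can be re-run at the central
values and at emission-maximising / emission-minimising bounds.

Internal unit regime: AGB and growth in t dry matter ha^-1 (yr^-1), burned
peat depth in m, bulk density in kg m^-3, combustion emission factors in
g CO2 per kg dry fuel, peat-decomposition emission factors in t CO2 ha^-1
yr^-1, areas in m^2 at the grid level.  Emission arithmetic converts to
g CO2 internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "Category",
    "EnvelopeValue",
    "GlobalParams",
    "CategoryParams",
    "ParameterSet",
    "PointParams",
    "load_parameters",
    "default_parameters",
    "select_scenario",
    "C_TO_CO2",
]

#: exact molar mass ratio converting carbon mass to CO2 mass
C_TO_CO2 = 44.0 / 12.0


class Category(IntEnum):
    """The five land-use categories, plus a nodata code for unclassified grids.

    Integer codes double as the fixed tie-break order and as raster values
    in serialized maps (0 is reserved for nodata).
    """

    NODATA = 0
    FOREST = 1
    SHRUB_GRASS = 2
    PLANTATION = 3
    URBAN = 4
    WATER = 5

    @property
    def is_forest(self) -> bool:
        return self is Category.FOREST


#: the five real categories in fixed order (excludes NODATA)
CATEGORIES = (
    Category.FOREST,
    Category.SHRUB_GRASS,
    Category.PLANTATION,
    Category.URBAN,
    Category.WATER,
)

#: categories whose presence on peat marks the cell as drained
#: (water is excluded: flooding is not drainage)
DRAINING_CATEGORIES = frozenset(
    {Category.SHRUB_GRASS, Category.PLANTATION, Category.URBAN}
)


class ParameterError(ValueError):
    """Configuration/validation problem in a parameter file."""


@dataclass(frozen=True)
class EnvelopeValue:
    """A scalar parameter with an uncertainty envelope (min <= central <= max)."""

    min: float
    central: float
    max: float

    def __post_init__(self) -> None:
        vals = (self.min, self.central, self.max)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite envelope {vals}")
        if not (self.min <= self.central <= self.max):
            raise ParameterError(
                f"envelope must satisfy min <= central <= max, got {vals}"
            )

    @classmethod
    def fixed(cls, value: float) -> "EnvelopeValue":
        return cls(value, value, value)

    def pick(self, mode: str) -> float:
        return {"min": self.min, "central": self.central, "max": self.max}[mode]


def _bounded(env: EnvelopeValue, lo: float, hi: float, name: str) -> None:
    if not (lo <= env.min and env.max <= hi):
        raise ParameterError(f"{name} must lie in [{lo}, {hi}], got {env}")


@dataclass(frozen=True)
class GlobalParams:
    """Category-independent scaling factors.

    R_BGB and R_WDL convert aboveground biomass to the belowground and
    woody-debris-plus-litter pools; CC_L / CC_D are carbon content fractions
    of live and dead biomass; BurnD is the peat depth consumed by a first
    fire; DR_schedule gives the burn-depth decreasing rate by cumulative
    fire ordinal (ordinal 1 -> 1.0, non-increasing).
    """

    R_BGB: EnvelopeValue
    R_WDL: EnvelopeValue
    CC_L: EnvelopeValue
    CC_D: EnvelopeValue
    BurnD: EnvelopeValue  # m
    DR_schedule: tuple[float, ...]
    C_CtoCO2: float = C_TO_CO2

    def __post_init__(self) -> None:
        for name in ("CC_L", "CC_D"):
            env = getattr(self, name)
            if not (0.0 < env.min and env.max < 1.0):
                raise ParameterError(f"{name} must be a fraction in (0,1), got {env}")
        for name in ("R_BGB", "R_WDL"):
            _bounded(getattr(self, name), 0.0, 10.0, name)
        _bounded(self.BurnD, 0.0, 10.0, "BurnD")
        if abs(self.C_CtoCO2 - C_TO_CO2) > 1e-12:
            raise ParameterError("C_CtoCO2 must be exactly 44/12")
        sched = self.DR_schedule
        if not sched or abs(sched[0] - 1.0) > 1e-12:
            raise ParameterError("DR_schedule must start at 1.0 for the first fire")
        for a, b in zip(sched, sched[1:]):
            if b > a + 1e-12:
                raise ParameterError("DR_schedule must be non-increasing")
        if any(not (0.0 <= d <= 1.0) for d in sched):
            raise ParameterError("DR values must lie in [0, 1]")

    def dr(self, ordinal: int) -> float:
        """Burn-depth decreasing rate for the given cumulative fire ordinal
        (1-based); ordinals beyond the schedule reuse the last entry."""
        if ordinal < 1:
            raise ValueError(f"fire ordinal must be >= 1, got {ordinal}")
        return self.DR_schedule[min(ordinal, len(self.DR_schedule)) - 1]


@dataclass(frozen=True)
class CategoryParams:
    """Per-category scaling factors.

    BE: burning efficiency (fraction of a fuel pool combusted per event);
    EF_bb / EF_pb: combustion emission factors for biomass and peat fuels,
    g CO2 per kg dry fuel; BulkD: peat bulk density, kg m^-3;
    EF_pd_drained / EF_pd_undrained: oxidative peat-decomposition emission
    factors, t CO2 ha^-1 yr^-1; growth: annual AGB increment, t DM ha^-1
    yr^-1; AGB_post: AGB assigned to a cell right after conversion into
    this category, t DM ha^-1.
    """

    category: Category
    BE: EnvelopeValue
    EF_bb: EnvelopeValue
    EF_pb: EnvelopeValue
    BulkD: EnvelopeValue
    EF_pd_drained: EnvelopeValue
    EF_pd_undrained: EnvelopeValue
    growth: EnvelopeValue
    AGB_post: float

    def __post_init__(self) -> None:
        _bounded(self.BE, 0.0, 1.0, "BE")
        if self.EF_bb.min < 0 or self.EF_pb.min < 0:
            raise ParameterError("emission factors must be non-negative")
        if self.BulkD.min < 0:
            raise ParameterError("BulkD must be non-negative")
        if self.growth.min < 0:
            raise ParameterError("growth must be non-negative")
        if self.EF_pd_drained.min < 0 or self.EF_pd_undrained.min < 0:
            raise ParameterError("EF_pd must be non-negative")
        if self.AGB_post < 0:
            raise ParameterError("AGB_post must be non-negative")


@dataclass(frozen=True)
class ParameterSet:
    """Validated envelope parameters: globals plus one entry per category."""

    globals: GlobalParams
    categories: Mapping[Category, CategoryParams]

    def __post_init__(self) -> None:
        missing = [c.name for c in CATEGORIES if c not in self.categories]
        if missing:
            raise ParameterError(f"missing category parameters: {missing}")

    def to_dict(self) -> dict:
        g = self.globals
        out = {
            "globals": {
                "R_BGB": _env_dict(g.R_BGB),
                "R_WDL": _env_dict(g.R_WDL),
                "CC_L": _env_dict(g.CC_L),
                "CC_D": _env_dict(g.CC_D),
                "BurnD": _env_dict(g.BurnD),
                "DR_schedule": list(g.DR_schedule),
                "C_CtoCO2": "44/12",
            },
            "categories": {},
        }
        for cat in CATEGORIES:
            cp = self.categories[cat]
            out["categories"][cat.name.lower()] = {
                "BE": _env_dict(cp.BE),
                "EF_bb": _env_dict(cp.EF_bb),
                "EF_pb": _env_dict(cp.EF_pb),
                "BulkD": _env_dict(cp.BulkD),
                "EF_pd_drained": _env_dict(cp.EF_pd_drained),
                "EF_pd_undrained": _env_dict(cp.EF_pd_undrained),
                "growth": _env_dict(cp.growth),
                "AGB_post": cp.AGB_post,
            }
        return out

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# point-valued (collapsed) parameters fed to the accounting equations


@dataclass(frozen=True)
class PointParams:
    """Envelope parameters collapsed to a single scenario (min/central/max)."""

    mode: str
    R_BGB: float
    R_WDL: float
    CC_L: float
    CC_D: float
    BurnD: float
    DR_schedule: tuple[float, ...]
    BE: dict = field(default_factory=dict)  # Category -> float
    EF_bb: dict = field(default_factory=dict)
    EF_pb: dict = field(default_factory=dict)
    BulkD: dict = field(default_factory=dict)
    EF_pd_drained: dict = field(default_factory=dict)
    EF_pd_undrained: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    AGB_post: dict = field(default_factory=dict)
    C_CtoCO2: float = C_TO_CO2

    def dr(self, ordinal: int) -> float:
        if ordinal < 1:
            raise ValueError(f"fire ordinal must be >= 1, got {ordinal}")
        return self.DR_schedule[min(ordinal, len(self.DR_schedule)) - 1]


_MODES = ("min", "central", "max")


def select_scenario(
    params: ParameterSet, mode: str, sign_aware: bool = True
) -> PointParams:
    """Collapse every envelope to one bound.

    With ``sign_aware=True`` (default) the growth envelope collapses to the
    *opposite* bound — the sink enters the net balance negatively, so the
    emission-maximising scenario pairs maximal emission factors with minimal
    growth, making the (min, central, max) runs a true bracket of E_T.
    ``sign_aware=False`` collapses every parameter, growth included, to the
    named bound.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    growth_mode = mode
    if sign_aware and mode == "max":
        growth_mode = "min"
    elif sign_aware and mode == "min":
        growth_mode = "max"
    g = params.globals
    return PointParams(
        mode=mode,
        R_BGB=g.R_BGB.pick(mode),
        R_WDL=g.R_WDL.pick(mode),
        CC_L=g.CC_L.pick(mode),
        CC_D=g.CC_D.pick(mode),
        BurnD=g.BurnD.pick(mode),
        DR_schedule=g.DR_schedule,
        BE={c: params.categories[c].BE.pick(mode) for c in CATEGORIES},
        EF_bb={c: params.categories[c].EF_bb.pick(mode) for c in CATEGORIES},
        EF_pb={c: params.categories[c].EF_pb.pick(mode) for c in CATEGORIES},
        BulkD={c: params.categories[c].BulkD.pick(mode) for c in CATEGORIES},
        EF_pd_drained={
            c: params.categories[c].EF_pd_drained.pick(mode) for c in CATEGORIES
        },
        EF_pd_undrained={
            c: params.categories[c].EF_pd_undrained.pick(mode) for c in CATEGORIES
        },
        growth={c: params.categories[c].growth.pick(growth_mode) for c in CATEGORIES},
        AGB_post={c: params.categories[c].AGB_post for c in CATEGORIES},
    )


# ---------------------------------------------------------------------------
# loading


def _env_dict(env: EnvelopeValue) -> dict:
    return {"min": env.min, "central": env.central, "max": env.max}


def _parse_env(raw, key: str) -> EnvelopeValue:
    if isinstance(raw, (int, float)):
        return EnvelopeValue.fixed(float(raw))
    if not isinstance(raw, dict):
        raise ParameterError(f"{key}: expected number or min/central/max mapping")
    unknown = set(raw) - {"min", "central", "max"}
    if unknown:
        raise ParameterError(f"{key}: unknown keys {sorted(unknown)}")
    missing = {"min", "central", "max"} - set(raw)
    if missing:
        raise ParameterError(f"{key}: missing keys {sorted(missing)}")
    try:
        return EnvelopeValue(float(raw["min"]), float(raw["central"]), float(raw["max"]))
    except ParameterError as exc:
        raise ParameterError(f"{key}: {exc}") from None


_GLOBAL_KEYS = {"R_BGB", "R_WDL", "CC_L", "CC_D", "BurnD", "DR_schedule", "C_CtoCO2"}
_CAT_KEYS = {
    "BE",
    "EF_bb",
    "EF_pb",
    "BulkD",
    "EF_pd_drained",
    "EF_pd_undrained",
    "growth",
    "AGB_post",
}


def _parse(doc: dict) -> ParameterSet:
    if not isinstance(doc, dict) or set(doc) - {"globals", "categories", "units"}:
        raise ParameterError(
            "parameter file must contain 'globals' and 'categories' sections only"
        )
    graw = doc.get("globals")
    if not isinstance(graw, dict):
        raise ParameterError("missing 'globals' section")
    unknown = set(graw) - _GLOBAL_KEYS
    if unknown:
        raise ParameterError(f"globals: unknown keys {sorted(unknown)}")
    for key in _GLOBAL_KEYS - {"C_CtoCO2"}:
        if key not in graw:
            raise ParameterError(f"globals: missing key {key!r}")
    ratio = graw.get("C_CtoCO2", "44/12")
    if isinstance(ratio, str):
        if ratio.replace(" ", "") != "44/12":
            raise ParameterError("C_CtoCO2 must be 44/12")
        ratio = C_TO_CO2
    g = GlobalParams(
        R_BGB=_parse_env(graw["R_BGB"], "R_BGB"),
        R_WDL=_parse_env(graw["R_WDL"], "R_WDL"),
        CC_L=_parse_env(graw["CC_L"], "CC_L"),
        CC_D=_parse_env(graw["CC_D"], "CC_D"),
        BurnD=_parse_env(graw["BurnD"], "BurnD"),
        DR_schedule=tuple(float(x) for x in graw["DR_schedule"]),
        C_CtoCO2=float(ratio),
    )
    craw = doc.get("categories")
    if not isinstance(craw, dict):
        raise ParameterError("missing 'categories' section")
    by_name = {c.name.lower(): c for c in CATEGORIES}
    unknown = set(craw) - set(by_name)
    if unknown:
        raise ParameterError(f"unknown categories {sorted(unknown)}")
    cats: dict[Category, CategoryParams] = {}
    for name, cat in by_name.items():
        if name not in craw:
            raise ParameterError(f"missing category {name!r}")
        entry = craw[name]
        unknown = set(entry) - _CAT_KEYS
        if unknown:
            raise ParameterError(f"{name}: unknown keys {sorted(unknown)}")
        missing = _CAT_KEYS - set(entry)
        if missing:
            raise ParameterError(f"{name}: missing keys {sorted(missing)}")
        cats[cat] = CategoryParams(
            category=cat,
            BE=_parse_env(entry["BE"], f"{name}.BE"),
            EF_bb=_parse_env(entry["EF_bb"], f"{name}.EF_bb"),
            EF_pb=_parse_env(entry["EF_pb"], f"{name}.EF_pb"),
            BulkD=_parse_env(entry["BulkD"], f"{name}.BulkD"),
            EF_pd_drained=_parse_env(entry["EF_pd_drained"], f"{name}.EF_pd_drained"),
            EF_pd_undrained=_parse_env(
                entry["EF_pd_undrained"], f"{name}.EF_pd_undrained"
            ),
            growth=_parse_env(entry["growth"], f"{name}.growth"),
            AGB_post=float(entry["AGB_post"]),
        )
    return ParameterSet(globals=g, categories=cats)


def load_parameters(path) -> ParameterSet:
    """Load and validate a YAML parameter file.

    The file must define a ``globals`` section and one entry per land-use
    category, every envelope given as a number (fixed) or a
    ``{min, central, max}`` mapping.  Unknown keys are rejected.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _parse(doc)


def default_parameters() -> ParameterSet:
    """The parameter file shipped with the package.

    The envelopes are documented placeholders spanning literature ranges for
    insular Southeast Asian landscapes; real accounting runs should supply a
    site-specific file.
    """
    ref = resources.files("lucflux.data").joinpath("default_params.yaml")
    with ref.open() as fh:
        return _parse(yaml.safe_load(fh))
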