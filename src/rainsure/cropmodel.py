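"""Water-limited drybean yield from a soil-bucket water balance.

The model tracks plant-available soil water through the season at the
dekad step.  Rain infiltrates after a runoff loss that grows with texture
heaviness and slope; the bucket holds at most the profile's plant-available
water-holding capacity (WHC), excess drains.  Each dekad the crop draws up
to its stage demand, and yield falls with the sensitivity-weighted sum of
the relative stage shortfalls:

    yield = potential * max(0, 1 - sum_s w_s * (1 - supply_s)) ** shape

with relative supply = (water taken up) / demand, capped at 1, and stage
weights ``w_s`` summing to 1 and peaking mid-cycle (flowering / pod
fill), so the same shortfall hurts far more at day 40 than at emergence.
The convexity exponent ``shape`` (default 2) makes severely stressed
seasons collapse towards zero yield while leaving the response
near-affine under mild stress.  Yield loss is thus additive across stage
shortfalls -- the dependence structure a summed dekadal rainfall-deficit
index presumes.  This is not a physiological crop model and makes no
claim about absolute yield levels, only about how yield falls with
dekadal water shortfalls.

Eight generic soils are shipped: four textures (sand .. silty clay), each
with a deep and a shallow profile.  Shallow sands buffer the least water
and are the droughtiest; heavy soils shed more rain as runoff, especially
on slopes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weathergen import (ClimateParams, DekadalSeason, OnsetRule,
                         aggregate_to_dekads, determine_sowing_date,
                         generate_daily)

#: texture classes in increasing heaviness
TEXTURES = ("sand", "loam", "clay_loam", "silty_clay")

#: base runoff fraction on flat ground, by texture
_RUNOFF_BASE = {"sand": 0.03, "loam": 0.07, "clay_loam": 0.12, "silty_clay": 0.16}

#: plant-available WHC (mm) of the deep profile, by texture
_WHC_DEEP = {"sand": 60.0, "loam": 100.0, "clay_loam": 120.0, "silty_clay": 140.0}


def runoff_fraction(texture: str, slope: float = 0.0) -> float:
    """Runoff fraction as a function of texture heaviness and slope
    (slope as a rise/run fraction, e.g. 0.3 for the 30% hillsides typical
    of the study region).  Monotone in both arguments, capped at 0.6."""
    if texture not in TEXTURES:
        raise ValueError(f"unknown texture {texture!r}; choose from {TEXTURES}")
    if slope < 0:
        raise ValueError("slope must be >= 0")
    return min(0.6, _RUNOFF_BASE[texture] * (1.0 + 2.0 * slope))


@dataclass(frozen=True)
class SoilProfile:
    """A generic soil: texture class, profile depth class, plant-available
    water-holding capacity and runoff fraction."""

    name: str
    texture: str
    depth: str  # "deep" | "shallow"
    whc_mm: float
    runoff_frac: float

    def __post_init__(self) -> None:
        if self.texture not in TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}")
        if self.depth not in ("deep", "shallow"):
            raise ValueError("depth must be 'deep' or 'shallow'")
        if self.whc_mm <= 0:
            raise ValueError("water-holding capacity must be > 0")
        if not 0.0 <= self.runoff_frac < 1.0:
            raise ValueError("runoff fraction must lie in [0, 1)")

    @property
    def texture_index(self) -> int:
        return TEXTURES.index(self.texture)


def default_soils(slope: float = 0.3) -> list[SoilProfile]:
    """The eight generic soils: 4 textures x {deep, shallow}.  Shallow
    profiles hold half the water of deep ones at equal texture."""
    soils = []
    for tex in TEXTURES:
        for depth, frac in (("deep", 1.0), ("shallow", 0.5)):
            soils.append(SoilProfile(
                name=f"{depth}_{tex}", texture=tex, depth=depth,
                whc_mm=_WHC_DEEP[tex] * frac,
                runoff_frac=runoff_fraction(tex, slope)))
    return soils


def get_soil(name: str, slope: float = 0.3) -> SoilProfile:
    for s in default_soils(slope):
        if s.name == name:
            return s
    raise KeyError(f"no default soil named {name!r}")


#: default per-dekad stage demand (mm) for the 8-dekad window from day -10:
#: a pre-sowing dekad with no demand, then establishment, vegetative growth,
#: flowering and pod fill (peak), and maturation.
DEFAULT_DEMAND = (0.0, 10.0, 10.0, 25.0, 40.0, 40.0, 40.0, 30.0)


@dataclass
class CropParams:
    """Crop cycle, stage water demands and stress sensitivities.

    ``demand_mm`` has one entry per dekad of the season window; dekads
    before sowing or after maturity carry zero demand.  ``sensitivity``
    holds the stage stress weights and defaults to the demand profile
    normalised to unit sum, putting peak stress sensitivity where peak
    demand sits (mid-cycle).
    """

    cycle_days: int = 70
    demand_mm: tuple[float, ...] = DEFAULT_DEMAND
    sensitivity: tuple[float, ...] | None = None
    potential_yield: float = 2000.0  # kg/ha
    stress_shape: float = 2.0
    noise_sigma: float = 0.05
    init_storage_frac: float = 0.25

    def __post_init__(self) -> None:
        if not 60 <= self.cycle_days <= 90:
            raise ValueError("cycle_days must lie in [60, 90]")
        d = np.asarray(self.demand_mm, dtype=float)
        if np.any(d < 0) or not np.all(np.isfinite(d)) or d.max() <= 0:
            raise ValueError("demands must be non-negative with a positive peak")
        if self.cycle_days > 10 * d.size:
            raise ValueError("crop cycle is longer than the configured dekad window")
        self.demand_mm = tuple(d)
        if self.sensitivity is None:
            self.sensitivity = tuple(d / d.sum())
        else:
            s = np.asarray(self.sensitivity, dtype=float)
            if s.shape != d.shape:
                raise ValueError("sensitivity and demand_mm must have equal length")
            if np.any(s < 0):
                raise ValueError("sensitivities must be >= 0")
            self.sensitivity = tuple(s)
        if self.stress_shape < 1:
            raise ValueError("stress_shape must be >= 1")
        if self.potential_yield <= 0:
            raise ValueError("potential_yield must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.init_storage_frac <= 1.0:
            raise ValueError("init_storage_frac must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"cycle_days": self.cycle_days,
                "demand_mm": list(self.demand_mm),
                "sensitivity": list(self.sensitivity),
                "potential_yield": self.potential_yield,
                "stress_shape": self.stress_shape,
                "noise_sigma": self.noise_sigma,
                "init_storage_frac": self.init_storage_frac}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CropParams":
        return cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})


def simulate_yield(season: DekadalSeason, soil: SoilProfile, crop: CropParams,
                   seed: int | None = None, noise: bool = True,
                   return_trace: bool = False):
    """Water-limited yield (kg/ha) for one season on one soil.

    Noise-free output is deterministic and non-decreasing in every dekad's
    rainfall; with ``noise=True`` a multiplicative lognormal term with unit
    mean and scale ``crop.noise_sigma`` is applied and the result clipped
    to [0, potential].  ``return_trace`` additionally returns the per-dekad
    water balance (infiltration, drainage, storage, uptake, supply).
    """
    rain = np.asarray(season.rain_mm, dtype=float)
    demand = np.asarray(crop.demand_mm)
    sens = np.asarray(crop.sensitivity)
    if rain.size != demand.size:
        raise ValueError(
            f"season has {rain.size} dekads but the crop demands cover "
            f"{demand.size}; configure matching windows")
    whc = soil.whc_mm
    storage = crop.init_storage_frac * whc
    infil = rain * (1.0 - soil.runoff_frac)
    supply = np.empty_like(rain)
    trace = {"infiltration_mm": infil, "drainage_mm": np.zeros_like(rain),
             "storage_mm": np.zeros_like(rain), "uptake_mm": np.zeros_like(rain)}
    for i in range(rain.size):
        storage += infil[i]
        drained = max(0.0, storage - whc)
        storage -= drained
        uptake = min(storage, demand[i])
        storage -= uptake
        supply[i] = 1.0 if demand[i] == 0 else uptake / demand[i]
        trace["drainage_mm"][i] = drained
        trace["uptake_mm"][i] = uptake
        trace["storage_mm"][i] = storage
    stress = max(0.0, 1.0 - float(np.sum(sens * (1.0 - supply))))
    y = crop.potential_yield * stress ** crop.stress_shape
    if noise and crop.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y *= rng.lognormal(-0.5 * crop.noise_sigma ** 2, crop.noise_sigma)
        y = float(np.clip(y, 0.0, crop.potential_yield))
    trace["supply"] = supply
    return (y, trace) if return_trace else y


def expected_run_count(n_pixels: int, n_soils: int, n_years: int) -> int:
    """Number of separate simulated crops for a full grid configuration."""
    if min(n_pixels, n_soils, n_years) < 1:
        raise ValueError("pixel, soil and year counts must all be >= 1")
    return n_pixels * n_soils * n_years


def run_grid(pixels: Sequence[str],
             soils: Sequence[SoilProfile],
             climate: ClimateParams | Mapping[str, ClimateParams],
             crop: CropParams,
             n_years: int,
             seed: int,
             sowing_day: int | None = 152,
             onset_rule: OnsetRule | None = None,
             sowing_window: tuple[int, int] | None = None,
             offset_days: int = -10,
             n_dekads: int = 8) -> pd.DataFrame:
    """Simulate every (pixel, soil, year) run and tabulate dekadal rainfall
    with yield.

    Weather is generated once per pixel and shared by its soils, so soil
    contrasts are at matched rainfall.  Sowing is either a fixed day of
    year or, when ``onset_rule`` and ``sowing_window`` are given, the
    rule's onset day (sowing on the window's last day in years the rule is
    never met).  Returns one row per run with columns
    ``pixel, soil, year, sowing_day, dekad_1..dekad_N, yield``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if not pixels or not soils:
        raise ValueError("need at least one pixel and one soil")
    if onset_rule is not None and sowing_window is None:
        raise ValueError("an onset rule needs a sowing window")
    root = np.random.SeedSequence(seed)
    weather_ss, noise_ss = root.spawn(2)
    weather_children = weather_ss.spawn(len(pixels))
    noise_children = iter(noise_ss.generate_state(
        len(pixels) * len(soils) * n_years, dtype=np.uint32).tolist())

    rows = []
    for pix, wchild in zip(pixels, weather_children):
        params = climate[pix] if isinstance(climate, Mapping) else climate
        try:
            daily = generate_daily(params, n_years, seed=wchild)
            seasons = []
            for series in daily:
                if onset_rule is not None:
                    sow = determine_sowing_date(series, onset_rule, sowing_window)
                    if sow is None:
                        sow = sowing_window[1]
                else:
                    sow = sowing_day
                seasons.append(aggregate_to_dekads(series, sow, offset_days, n_dekads))
        except Exception as exc:
            raise RuntimeError(f"weather/season generation failed for pixel {pix}") from exc
        for soil in soils:
            for season in seasons:
                try:
                    y = simulate_yield(season, soil, crop, seed=next(noise_children))
                except Exception as exc:
                    raise RuntimeError(
                        f"yield simulation failed for (pixel={pix}, "
                        f"soil={soil.name}, year={season.year})") from exc
                rows.append((pix, soil.name, season.year, season.sowing_day,
                             *season.rain_mm, y))
    cols = (["pixel", "soil", "year", "sowing_day"]
            + [f"dekad_{i}" for i in range(1, n_dekads + 1)] + ["yield"])
    return pd.DataFrame(rows, columns=cols)


def dekad_columns(table: pd.DataFrame) -> list[str]:
    """The dekad rainfall columns of a run table, in window order."""
    cols = [c for c in table.columns if c.startswith("dekad_")]
    return sorted(cols, key=lambda c: int(c.split("_")[1]))


def rain_matrix(table: pd.DataFrame) -> np.ndarray:
    """(n_runs, n_dekads) array of dekadal rainfall from a run table."""
    return table[dekad_columns(table)].to_numpy(dtype=float)


def write_run_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_run_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if (df["yield"] < 0).any():
        raise ValueError("run table contains negative yields")
    return df
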