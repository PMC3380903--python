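"""Stochastic daily rainfall for tropical sites, and its dekadal aggregation.

Daily rainfall occurrence follows a Markov chain on the wet/dry history of
the last ``order`` days (order 1-3, default 3: first-order chains reproduce
the orderly frontal weather of temperate latitudes but not the convective,
persistence-driven rainfall of the tropics).  Wet-day amounts are gamma
distributed with monthly parameters.  An optional mid-season dry-spell
window (the Central American *canicula*, typically July-August) multiplies
the wet probability by a depression factor, splitting the rainy season into
the *primera* and *postrera* cropping periods.

Years are 365 days (leap days carry no information at the dekad scale).
Each simulated year consumes an independent child stream of the master
seed, so adding years never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
#: month number (1-12) for each 1-based day of year
MONTH_OF_DOY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)


def day_of_year(day: int, month_name: str) -> int:
    """1-based day of a 365-day year for e.g. ``day_of_year(15, "May")``."""
    months = ("january february march april may june july august "
              "september october november december").split()
    m = months.index(month_name.strip().lower())
    return int(np.cumsum((0,) + MONTH_LENGTHS)[m]) + day


@dataclass(frozen=True)
class Canicula:
    """Mid-season dry-spell: wet probability is multiplied by ``factor``
    for days of year in [start_doy, end_doy]."""

    start_doy: int = day_of_year(15, "July")
    end_doy: int = day_of_year(15, "August")
    factor: float = 0.4

    def __post_init__(self) -> None:
        if not (1 <= self.start_doy <= self.end_doy <= DAYS_PER_YEAR):
            raise ValueError("canicula window must satisfy 1 <= start <= end <= 365")
        if not 0.0 <= self.factor <= 1.0:
            raise ValueError("canicula factor must be in [0, 1]")


@dataclass
class ClimateParams:
    """Occurrence-chain and amount parameters for one site.

    Parameters
    ----------
    order
        Markov order of the occurrence chain (1-3).  The chain state is the
        wet/dry indicator history of the last ``order`` days.
    p_wet
        Probability of a wet day given the history, per calendar month:
        array of shape ``(12, 2**order)``; column ``s`` is the history whose
        binary encoding has the most recent day in the least significant
        bit.  A scalar or a length-12 vector is broadcast.
    gamma_shape, gamma_scale
        Monthly gamma parameters (mm) for wet-day amounts; scalars broadcast.
    canicula
        Optional dry-spell depression window.
    seed
        Default master seed used when :func:`generate_daily` gets none.
    """

    p_wet: np.ndarray | float
    gamma_shape: np.ndarray | float = 1.0
    gamma_scale: np.ndarray | float = 8.0
    order: int = 3
    canicula: Canicula | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError(f"order must be 1, 2 or 3, got {self.order}")
        n_states = 2 ** self.order
        p = np.asarray(self.p_wet, dtype=float)
        if p.ndim == 0:
            p = np.full((12, n_states), float(p))
        elif p.shape == (12,):
            p = np.repeat(p[:, None], n_states, axis=1)
        elif p.shape != (12, n_states):
            raise ValueError(f"p_wet must broadcast to (12, {n_states}), got {p.shape}")
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ValueError("wet probabilities must lie in [0, 1]")
        self.p_wet = p
        for name in ("gamma_shape", "gamma_scale"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (12,)).copy()
            if np.any(v <= 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be strictly positive")
            setattr(self, name, v)

    def to_dict(self) -> dict:
        d = {
            "order": self.order,
            "p_wet": np.asarray(self.p_wet).tolist(),
            "gamma_shape": np.asarray(self.gamma_shape).tolist(),
            "gamma_scale": np.asarray(self.gamma_scale).tolist(),
        }
        if self.canicula is not None:
            d["canicula"] = {
                "start_doy": self.canicula.start_doy,
                "end_doy": self.canicula.end_doy,
                "factor": self.canicula.factor,
            }
        if self.seed is not None:
            d["seed"] = self.seed
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClimateParams":
        can = d.get("canicula")
        return cls(
            p_wet=np.asarray(d["p_wet"], dtype=float),
            gamma_shape=np.asarray(d["gamma_shape"], dtype=float),
            gamma_scale=np.asarray(d["gamma_scale"], dtype=float),
            order=int(d.get("order", 3)),
            canicula=Canicula(**can) if can else None,
            seed=d.get("seed"),
        )


def tropical_wet_season(
    p_dry_season: float = 0.08,
    p_wet_season: float = 0.45,
    persistence: float = 0.15,
    gamma_shape: float = 0.9,
    gamma_scale: float = 13.0,
    order: int = 3,
    canicula: Canicula | None = Canicula(),
    seed: int | None = None,
) -> ClimateParams:
    """A fixture climate with a June-November rainy season and a canicula.

    Wet probability is low December-May, high June-November, and increases
    with the number of recent wet days (``persistence`` per wet day in the
    history), mimicking the persistence structure of tropical convection.
    These values are illustrative study conditions, not an estimate of any
    particular station's climate.
    """
    base = np.full(12, p_dry_season)
    base[5:11] = p_wet_season  # June..November
    n_states = 2 ** order
    p = np.empty((12, n_states))
    for s in range(n_states):
        n_wet = bin(s).count("1")
        p[:, s] = np.clip(base * (1.0 + persistence * n_wet), 0.0, 1.0)
    return ClimateParams(p_wet=p, gamma_shape=gamma_shape, gamma_scale=gamma_scale,
                         order=order, canicula=canicula, seed=seed)


def droughty_wet_season(seed: int | None = None) -> ClimateParams:
    """A droughtier fixture climate: sparser, smaller rain events and a
    deeper canicula.  Typical season totals over an 8-dekad window sit
    just below the crop's 300-400 mm optimum, so most years are mildly
    stressed and the lowest yield quartile carries substantial deficits."""
    return tropical_wet_season(
        p_wet_season=0.42, gamma_scale=12.0,
        canicula=Canicula(factor=0.35), seed=seed,
    )


@dataclass(frozen=True)
class DailySeries:
    """One simulated year of daily rainfall (mm), 1-based day-of-year index."""

    year: int
    rain_mm: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rain_mm, dtype=float)
        if r.shape != (DAYS_PER_YEAR,):
            raise ValueError(f"rain_mm must have shape ({DAYS_PER_YEAR},)")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("rainfall amounts must be finite and non-negative")
        object.__setattr__(self, "rain_mm", r)

    def rain_on(self, doy: int) -> float:
        return float(self.rain_mm[doy - 1])


@dataclass(frozen=True)
class DekadalSeason:
    """Per-dekad rainfall totals for one cropping season.

    The window starts at ``sowing_day + offset_days`` and spans
    ``n_dekads`` half-open 10-day blocks; the default calibration window,
    offset -10 with 8 dekads, runs from 10 days before sowing to 70 days
    after it.
    """

    sowing_day: int
    offset_days: int
    rain_mm: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rain_mm, dtype=float)
        if r.ndim != 1 or r.size == 0:
            raise ValueError("rain_mm must be a non-empty 1-d array of dekad totals")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("dekad totals must be finite and non-negative")
        object.__setattr__(self, "rain_mm", r)

    @property
    def n_dekads(self) -> int:
        return int(self.rain_mm.size)


@dataclass(frozen=True)
class OnsetRule:
    """Sowing-onset rule: the first day preceded by ``run_length``
    consecutive days each with rainfall strictly over ``threshold_mm``."""

    run_length: int = 5
    threshold_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.threshold_mm < 0:
            raise ValueError("threshold_mm must be >= 0")


def generate_daily(params: ClimateParams, n_years: int,
                   seed: int | np.random.SeedSequence | None = None) -> list[DailySeries]:
    """Simulate ``n_years`` of daily rainfall.

    Deterministic for a fixed seed; each year has its own child stream of
    the master seed and starts from an all-dry occurrence history.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if seed is None:
        seed = params.seed
    if seed is None:
        raise ValueError("a seed is required (argument or ClimateParams.seed)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    mask = 2 ** params.order - 1
    can = params.canicula
    out = []
    for year, child in enumerate(ss.spawn(n_years), start=1):
        rng = np.random.default_rng(child)
        u = rng.random(DAYS_PER_YEAR)
        rain = np.zeros(DAYS_PER_YEAR)
        state = 0
        for i in range(DAYS_PER_YEAR):
            p = params.p_wet[MONTH_OF_DOY[i] - 1, state]
            if can is not None and can.start_doy <= i + 1 <= can.end_doy:
                p *= can.factor
            wet = u[i] < p
            if wet:
                m = MONTH_OF_DOY[i] - 1
                rain[i] = rng.gamma(params.gamma_shape[m], params.gamma_scale[m])
            state = ((state << 1) | int(wet)) & mask
        out.append(DailySeries(year=year, rain_mm=rain))
    return out


def aggregate_to_dekads(daily: DailySeries, sowing_day: int,
                        offset_days: int = -10, n_dekads: int = 8) -> DekadalSeason:
    """Sum daily rainfall into ``n_dekads`` 10-day totals starting at
    ``sowing_day + offset_days`` (1-based, window half-open)."""
    if n_dekads < 1:
        raise ValueError("n_dekads must be >= 1")
    start = sowing_day + offset_days
    stop = start + 10 * n_dekads  # exclusive
    if start < 1 or stop - 1 > DAYS_PER_YEAR:
        raise IndexError(
            f"dekad window days [{start}, {stop}) falls outside the "
            f"1..{DAYS_PER_YEAR} year")
    block = daily.rain_mm[start - 1:stop - 1].reshape(n_dekads, 10)
    return DekadalSeason(sowing_day=sowing_day, offset_days=offset_days,
                         rain_mm=block.sum(axis=1), year=daily.year)


def determine_sowing_date(daily: DailySeries, rule: OnsetRule,
                          window: tuple[int, int]) -> int | None:
    """First day ``d`` in ``window`` (inclusive day-of-year bounds) such
    that the ``rule.run_length`` days before ``d`` each exceed the rule
    threshold; ``None`` if the rule is never met in the window.

    The qualifying run may extend before the window start.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty sowing window ({lo}, {hi})")
    if not (1 <= lo and hi <= DAYS_PER_YEAR):
        raise ValueError("sowing window must lie within the year")
    k, tau = rule.run_length, rule.threshold_mm
    for d in range(max(lo, k + 1), hi + 1):
        if np.all(daily.rain_mm[d - 1 - k:d - 1] > tau):
            return d
    return None


# ---------------------------------------------------------------------------
# file round-tripping

def write_daily_csv(series: Sequence[DailySeries], path) -> None:
    """Columns ``year, doy, rain_mm``; one row per day."""
    frames = [pd.DataFrame({"year": s.year,
                            "doy": np.arange(1, DAYS_PER_YEAR + 1),
                            "rain_mm": s.rain_mm}) for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_daily_csv(path) -> list[DailySeries]:
    df = pd.read_csv(path)
    out = []
    for year, grp in df.groupby("year", sort=True):
        grp = grp.sort_values("doy")
        if not np.array_equal(grp["doy"].to_numpy(), np.arange(1, DAYS_PER_YEAR + 1)):
            raise ValueError(f"year {year}: expected days 1..{DAYS_PER_YEAR}")
        out.append(DailySeries(year=int(year), rain_mm=grp["rain_mm"].to_numpy(float)))
    return out


def write_dekadal_csv(seasons: Sequence[DekadalSeason], path) -> None:
    """Columns ``year, dekad_index, rain_mm`` (dekad_index is 1-based)."""
    rows = [(s.year if s.year is not None else i + 1, d + 1, s.rain_mm[d])
            for i, s in enumerate(seasons) for d in range(s.n_dekads)]
    pd.DataFrame(rows, columns=["year", "dekad_index", "rain_mm"]).to_csv(path, index=False)


def read_dekadal_csv(path, sowing_day: int = 1, offset_days: int = 0) -> list[DekadalSeason]:
    df = pd.read_csv(path)
    out = []
    for year, grp in df.groupby("year", sort=True):
        grp = grp.sort_values("dekad_index")
        out.append(DekadalSeason(sowing_day=sowing_day, offset_days=offset_days,
                                 rain_mm=grp["rain_mm"].to_numpy(float), year=int(year)))
    return out
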