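"""Actuarial summaries: trigger-exceedance probabilities and premiums.

Probabilities are empirical burn rates over the simulated seasons -- the
fraction whose total rainfall deficit reaches the trigger -- with no
distributional fit or tail extrapolation.  The fair premium is the mean
seasonal payout; a multiplicative loading factor (default 0) turns it
into an offered premium.  ``risk_map`` tabulates these per (pixel, soil,
trigger) over a full run table and appends the soil-averaged summary per
pixel, the tabular analogue of a probability map of 50 and 70 mm deficits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import deficit_totals
from .contract import ContractSpec
from .cropmodel import rain_matrix

__all__ = ["RiskSummary", "exceedance_probability", "price_contract",
           "risk_map", "write_risk_csv", "read_risk_csv", "SOIL_MEAN"]

#: soil id used for the soil-averaged rows of a risk map
SOIL_MEAN = "mean"

RISK_COLUMNS = ["pixel", "lat", "lon", "soil", "trigger_mm", "prob",
                "expected_payout", "fair_premium", "loaded_premium"]


@dataclass(frozen=True)
class RiskSummary:
    """Exceedance probability and premiums for one (pixel, soil, trigger)."""

    pixel: str
    soil: str
    trigger_mm: float
    prob: float
    expected_payout: float
    fair_premium: float
    loaded_premium: float
    lat: float = float("nan")
    lon: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("exceedance probability must lie in [0, 1]")
        if self.loaded_premium < self.fair_premium - 1e-12:
            raise ValueError("loaded premium cannot be below the fair premium")


def exceedance_probability(totals, trigger_mm: float) -> float:
    """Fraction of season total deficits at or below the trigger."""
    t = np.asarray(totals, dtype=float)
    if t.size == 0:
        raise ValueError("cannot estimate a probability from zero seasons")
    return float(np.mean(t <= trigger_mm))


def _payouts(spec: ContractSpec, totals: np.ndarray) -> np.ndarray:
    excess = np.maximum(0.0, spec.trigger_mm - totals)
    return spec.indemnity_rate * excess


def price_contract(spec: ContractSpec, runs: pd.DataFrame,
                   loading: float = 0.0,
                   lat: float = float("nan"),
                   lon: float = float("nan")) -> RiskSummary:
    """Burn-rate pricing of one contract over one run's simulated seasons.

    ``runs`` must hold a single (pixel, soil) cell.  Fair premium = mean
    seasonal payout; loaded premium = fair * (1 + loading).
    """
    if loading < 0:
        raise ValueError("loading must be >= 0")
    if runs.empty:
        raise ValueError("cannot price a contract on zero seasons")
    for col in ("pixel", "soil"):
        if col in runs.columns and runs[col].nunique() > 1:
            raise ValueError(f"runs span several {col}s; price one cell at a time")
    totals = deficit_totals(rain_matrix(runs), spec.mwr)
    payouts = _payouts(spec, totals)
    expected = float(payouts.mean())
    pixel = str(runs["pixel"].iloc[0]) if "pixel" in runs.columns else ""
    soil = str(runs["soil"].iloc[0]) if "soil" in runs.columns else spec.soil_name
    return RiskSummary(
        pixel=pixel, soil=soil, trigger_mm=spec.trigger_mm,
        prob=exceedance_probability(totals, spec.trigger_mm),
        expected_payout=expected, fair_premium=expected,
        loaded_premium=expected * (1.0 + loading), lat=lat, lon=lon)


def risk_map(run_table: pd.DataFrame, spec: ContractSpec,
             triggers: Sequence[float],
             mwr_by_cell: Mapping[tuple[str, str], np.ndarray] | None = None,
             loading: float = 0.0,
             coords: Mapping[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Risk summaries for every (pixel, soil, trigger) plus soil means.

    The MIN row defaults to ``spec.mwr`` for every cell; pass
    ``mwr_by_cell`` to price each (pixel, soil) with its own calibrated
    MWR vector.  The soil-averaged rows (soil id ``"mean"``) hold the
    arithmetic mean over soils of the probability and of the premiums.
    A run table with missing (pixel, soil) cells is rejected.
    """
    pixels = list(dict.fromkeys(run_table["pixel"].astype(str)))
    soils = list(dict.fromkeys(run_table["soil"].astype(str)))
    have = set(zip(run_table["pixel"].astype(str), run_table["soil"].astype(str)))
    missing = [(p, s) for p in pixels for s in soils if (p, s) not in have]
    if missing:
        raise ValueError(f"run table is missing (pixel, soil) cells: {missing}")

    rows = []
    for pix in pixels:
        lat, lon = (coords or {}).get(pix, (float("nan"), float("nan")))
        per_soil: dict[float, list[RiskSummary]] = {float(t): [] for t in triggers}
        for soil in soils:
            cell = run_table[(run_table["pixel"].astype(str) == pix)
                             & (run_table["soil"].astype(str) == soil)]
            mwr = spec.mwr if mwr_by_cell is None else mwr_by_cell[(pix, soil)]
            for trig in triggers:
                cell_spec = spec.with_(mwr=np.asarray(mwr, dtype=float),
                                       trigger_mm=float(trig), soil_name=soil)
                summary = price_contract(cell_spec, cell, loading=loading,
                                         lat=lat, lon=lon)
                per_soil[float(trig)].append(summary)
                rows.append(summary)
        for trig, summaries in per_soil.items():
            expected = float(np.mean([s.expected_payout for s in summaries]))
            rows.append(RiskSummary(
                pixel=pix, soil=SOIL_MEAN, trigger_mm=trig,
                prob=float(np.mean([s.prob for s in summaries])),
                expected_payout=expected, fair_premium=expected,
                loaded_premium=expected * (1.0 + loading), lat=lat, lon=lon))
    return pd.DataFrame([{
        "pixel": s.pixel, "lat": s.lat, "lon": s.lon, "soil": s.soil,
        "trigger_mm": s.trigger_mm, "prob": s.prob,
        "expected_payout": s.expected_payout, "fair_premium": s.fair_premium,
        "loaded_premium": s.loaded_premium} for s in rows],
        columns=RISK_COLUMNS)


def write_risk_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_risk_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not set(RISK_COLUMNS) <= set(df.columns):
        raise ValueError("risk CSV is missing required columns")
    return df


def plot_risk_map(table: pd.DataFrame, trigger_mm: float, ax=None):
    """Scatter the soil-mean exceedance probability on pixel coordinates.

    A convenience view of the risk grid; requires matplotlib.
    """
    import matplotlib.pyplot as plt

    sub = table[(table["soil"] == SOIL_MEAN)
                & (table["trigger_mm"] == trigger_mm)]
    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(sub["lon"], sub["lat"], c=sub["prob"], vmin=0, vmax=1,
                    cmap="YlOrRd", s=120, edgecolor="k")
    ax.figure.colorbar(sc, ax=ax, label=f"P(total deficit <= {trigger_mm:g} mm)")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
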