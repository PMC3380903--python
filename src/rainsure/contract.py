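"""Rainfall-deficit insurance contracts: schema, evaluation and rendering.

A contract names a reference weather station, crop and soil, a sowing
window with a transparent onset rule, the MIN row of per-dekad minimum
rainfall requirements, a trigger value (a negative total deficit, e.g.
-70 mm) and an indemnity rate.  A season is settled from the official
station rainfall alone: DEF = min(RAIN - MIN, 0) per dekad, the total
deficit is the sum, the contract triggers when the total is at or below
the trigger, and the indemnity pays the stated rate for every millimetre
of deficit beyond the trigger.  At exactly the trigger the contract is
formally triggered but the excess -- and hence the payment -- is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
import yaml

from .calibration import as_mwr, compute_deficit
from .weathergen import DekadalSeason, OnsetRule

__all__ = ["ContractSpec", "SeasonEvaluation", "evaluate_season",
           "render_contract", "contract_to_yaml", "contract_from_yaml",
           "write_contract", "read_contract"]


@dataclass(frozen=True)
class ContractSpec:
    """One rainfall insurance contract (the printed contract sheet)."""

    station: str
    crop_name: str
    soil_name: str
    sowing_window: tuple[int, int]  # inclusive day-of-year bounds
    sowing_rule: OnsetRule
    mwr: np.ndarray  # the MIN row, mm per dekad
    trigger_mm: float
    indemnity_rate: float  # currency per mm of deficit beyond the trigger
    premium: float
    currency: str = "US$"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mwr", as_mwr(self.mwr))
        if self.trigger_mm >= 0:
            raise ValueError("the trigger is a deficit and must be < 0 mm")
        if self.indemnity_rate < 0:
            raise ValueError("indemnity rate must be >= 0")
        if self.premium < 0:
            raise ValueError("premium must be >= 0")
        lo, hi = self.sowing_window
        if lo > hi:
            raise ValueError("empty sowing window")

    @property
    def n_dekads(self) -> int:
        return int(self.mwr.size)

    def with_(self, **changes) -> "ContractSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class SeasonEvaluation:
    """Settlement of one season against a contract."""

    deficits: np.ndarray  # DEF row, mm (<= 0)
    total: float  # total rainfall deficit, mm (<= 0)
    triggered: bool
    payout: float

    def __post_init__(self) -> None:
        if self.payout < 0:
            raise ValueError("payout must be >= 0")


def evaluate_season(spec: ContractSpec,
                    season: DekadalSeason | np.ndarray) -> SeasonEvaluation:
    """Settle one season: DEF row, total deficit, trigger test, payout.

    The payout is ``rate * max(0, trigger - total)`` when the total deficit
    is at or below the trigger (both are negative, so ``trigger - total``
    is the deficit in excess of the trigger), else 0.
    """
    res = compute_deficit(season, spec.mwr)
    triggered = res.total <= spec.trigger_mm
    excess = max(0.0, spec.trigger_mm - res.total)
    payout = spec.indemnity_rate * excess if triggered else 0.0
    return SeasonEvaluation(deficits=res.per_dekad, total=res.total,
                            triggered=triggered, payout=payout)


# ---------------------------------------------------------------------------
# serialization

def contract_to_yaml(spec: ContractSpec) -> str:
    d = {
        "station": spec.station,
        "crop": spec.crop_name,
        "soil": spec.soil_name,
        "sowing_window_doy": [int(spec.sowing_window[0]), int(spec.sowing_window[1])],
        "sowing_rule": {"run_length": spec.sowing_rule.run_length,
                        "threshold_mm": spec.sowing_rule.threshold_mm},
        "min_mm": [float(v) for v in spec.mwr],
        "trigger_mm": float(spec.trigger_mm),
        "indemnity_rate": float(spec.indemnity_rate),
        "premium": float(spec.premium),
        "currency": spec.currency,
    }
    return yaml.safe_dump(d, sort_keys=True, default_flow_style=False)


def contract_from_yaml(text: str) -> ContractSpec:
    d = yaml.safe_load(text)
    try:
        rule = d["sowing_rule"]
        return ContractSpec(
            station=d["station"], crop_name=d["crop"], soil_name=d["soil"],
            sowing_window=(int(d["sowing_window_doy"][0]),
                           int(d["sowing_window_doy"][1])),
            sowing_rule=OnsetRule(run_length=int(rule["run_length"]),
                                  threshold_mm=float(rule["threshold_mm"])),
            mwr=np.asarray(d["min_mm"], dtype=float),
            trigger_mm=float(d["trigger_mm"]),
            indemnity_rate=float(d["indemnity_rate"]),
            premium=float(d["premium"]),
            currency=d.get("currency", "US$"),
        )
    except KeyError as exc:
        raise ValueError(f"contract file is missing field {exc}") from exc


def write_contract(spec: ContractSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(contract_to_yaml(spec))


def read_contract(path) -> ContractSpec:
    with open(path) as fh:
        return contract_from_yaml(fh.read())


# ---------------------------------------------------------------------------
# rendering

def _fmt(x: float) -> str:
    """Print 10 as '10' and 34.9 as '34.9' (one decimal at most)."""
    return f"{x:.1f}".rstrip("0").rstrip(".")


def render_contract(spec: ContractSpec,
                    season: DekadalSeason | np.ndarray | None = None,
                    evaluation: SeasonEvaluation | None = None) -> str:
    """Plain-text contract sheet: header, MIN/RAIN/DEF table, settlement.

    With no season the RAIN and DEF rows are left blank; DEF cells are
    printed only where a deficit occurred.
    """
    if season is not None and evaluation is None:
        evaluation = evaluate_season(spec, season)
    n = spec.n_dekads
    width = 9
    headers = [f"d{10 * i + 1}-{10 * (i + 1)}" for i in range(n)]
    rain = None if season is None else np.asarray(
        getattr(season, "rain_mm", season), dtype=float)

    def row(label: str, cells) -> str:
        return (f"{label:<6}" + "".join(f"{c:>{width}}" for c in cells)).rstrip()

    lines = [
        "RAINFALL INSURANCE CONTRACT",
        f"Reference weather station: {spec.station}",
        f"Crop:                      {spec.crop_name}",
        f"Reference soil type:       {spec.soil_name}",
        f"Sowing window (day of yr): {spec.sowing_window[0]} to {spec.sowing_window[1]}",
        (f"Sowing date rule:          first day after "
         f"{spec.sowing_rule.run_length} consecutive rainy days over "
         f"{_fmt(spec.sowing_rule.threshold_mm)} mm each"),
        f"Trigger value:             {_fmt(spec.trigger_mm)} mm",
        f"Premium price:             {spec.currency}{_fmt(spec.premium)}",
        (f"Indemnity:                 {spec.currency}{_fmt(spec.indemnity_rate)} "
         f"for every mm of rainfall deficit after the trigger value"),
        "",
        row("", headers),
        row("MIN", [_fmt(v) for v in spec.mwr]),
        row("RAIN", [""] * n if rain is None else [_fmt(v) for v in rain]),
        row("DEF", [""] * n if evaluation is None else
            [_fmt(d) if d < 0 else "" for d in evaluation.deficits]),
    ]
    if evaluation is not None:
        lines += [
            f"TOTAL rainfall deficit: {_fmt(evaluation.total)} mm",
            f"Triggered: {'yes' if evaluation.triggered else 'no'}",
            f"Indemnity payment: {spec.currency}{evaluation.payout:.2f}",
        ]
    else:
        lines.append("TOTAL rainfall deficit:")
    return "\n".join(lines) + "\n"
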