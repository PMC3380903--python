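"""End-to-end driver: generate weather, simulate yields, calibrate MWRs,
write contracts and price them, from one declarative YAML config.

Every artifact records the master seed; reruns of the same config are
numerically identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import calibration, cropmodel, pricing
from .contract import ContractSpec, write_contract
from .cropmodel import CropParams, SoilProfile, default_soils
from .weathergen import ClimateParams, OnsetRule

log = logging.getLogger("rainsure")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    seed: int
    out_dir: Path
    pixels: list[dict]  # {"id": str, "lat": float, "lon": float}
    climate: ClimateParams | Mapping[str, ClimateParams]
    crop: CropParams
    n_years: int
    soils: list[SoilProfile] = field(default_factory=default_soils)
    sowing_day: int | None = 152
    onset_rule: OnsetRule | None = None
    sowing_window: tuple[int, int] | None = None
    offset_days: int = -10
    n_dekads: int = 8
    trigger_mm: float = -70.0
    indemnity_rate: float = 5.0
    premium: float = 3.0
    triggers: tuple[float, ...] = (-50.0, -70.0)
    loading: float = 0.0
    station: str = "reference station"
    crop_name: str = "drybean"
    config_hash: str = ""

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not self.pixels:
            raise ValueError("at least one pixel is required")
        ids = [p["id"] for p in self.pixels]
        if len(set(ids)) != len(ids):
            raise ValueError("pixel ids must be unique")

    @property
    def pixel_ids(self) -> list[str]:
        return [str(p["id"]) for p in self.pixels]

    @property
    def coords(self) -> dict[str, tuple[float, float]]:
        return {str(p["id"]): (float(p.get("lat", np.nan)),
                               float(p.get("lon", np.nan)))
                for p in self.pixels}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        d = yaml.safe_load(raw)
        missing = [k for k in ("seed", "out_dir", "pixels", "climate", "n_years")
                   if k not in d]
        if missing:
            raise ValueError(f"config {path} is missing fields: {missing}")

        soils_spec = d.get("soils", "default")
        if soils_spec == "default":
            soils = default_soils(slope=float(d.get("slope", 0.3)))
        elif isinstance(soils_spec, str):
            soil_path = (path.parent / soils_spec)
            if not soil_path.exists():
                raise FileNotFoundError(
                    f"soil library {soil_path} referenced by {path} does not exist")
            soils = [SoilProfile(**s) for s in yaml.safe_load(soil_path.read_text())]
        elif isinstance(soils_spec, list) and soils_spec and isinstance(soils_spec[0], str):
            soils = [cropmodel.get_soil(n, slope=float(d.get("slope", 0.3)))
                     for n in soils_spec]
        else:
            soils = [SoilProfile(**s) for s in soils_spec]

        clim = d["climate"]
        if isinstance(clim, Mapping) and "p_wet" not in clim:
            climate: ClimateParams | dict = {
                pix: ClimateParams.from_dict(c) for pix, c in clim.items()}
        else:
            climate = ClimateParams.from_dict(clim)

        rule = d.get("onset_rule")
        window = d.get("sowing_window_doy")
        return cls(
            seed=int(d["seed"]),
            out_dir=(path.parent / d["out_dir"]).resolve(),
            pixels=d["pixels"],
            climate=climate,
            crop=CropParams.from_dict(d.get("crop", {})),
            n_years=int(d["n_years"]),
            soils=soils,
            sowing_day=d.get("sowing_day", 152),
            onset_rule=OnsetRule(**rule) if rule else None,
            sowing_window=tuple(window) if window else None,
            offset_days=int(d.get("offset_days", -10)),
            n_dekads=int(d.get("n_dekads", 8)),
            trigger_mm=float(d.get("trigger_mm", -70.0)),
            indemnity_rate=float(d.get("indemnity_rate", 5.0)),
            premium=float(d.get("premium", 3.0)),
            triggers=tuple(d.get("triggers", [-50.0, -70.0])),
            loading=float(d.get("loading", 0.0)),
            station=d.get("station", "reference station"),
            crop_name=d.get("crop_name", "drybean"),
            config_hash=hashlib.sha256(raw.encode()).hexdigest()[:16],
        )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run generate -> simulate -> calibrate -> contract -> price.

    Writes, under ``config.out_dir``: ``run_table.csv``, one calibration
    JSON and one contract YAML per (pixel, soil), ``risk_grid.csv`` and
    ``pipeline.log``.  Returns the artifact paths.
    """
    out = Path(config.out_dir)
    (out / "calibration").mkdir(parents=True, exist_ok=True)
    (out / "contracts").mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("seed=%d config_hash=%s pixels=%d soils=%d years=%d",
                 config.seed, config.config_hash or "n/a",
                 len(config.pixel_ids), len(config.soils), config.n_years)

        table = cropmodel.run_grid(
            config.pixel_ids, config.soils, config.climate, config.crop,
            config.n_years, seed=config.seed, sowing_day=config.sowing_day,
            onset_rule=config.onset_rule, sowing_window=config.sowing_window,
            offset_days=config.offset_days, n_dekads=config.n_dekads)
        run_path = out / "run_table.csv"
        cropmodel.write_run_table(table, run_path)
        log.info("simulate: %d rows -> %s", len(table), run_path)

        template = ContractSpec(
            station=config.station, crop_name=config.crop_name,
            soil_name="template",
            sowing_window=config.sowing_window or (135, 166),
            sowing_rule=config.onset_rule or OnsetRule(),
            mwr=np.zeros(config.n_dekads) + 1.0,
            trigger_mm=config.trigger_mm,
            indemnity_rate=config.indemnity_rate, premium=config.premium)

        mwr_by_cell: dict[tuple[str, str], np.ndarray] = {}
        for (pix, soil), cell in table.groupby(["pixel", "soil"], sort=False):
            try:
                result = calibration.calibrate_run(cell, seed=config.seed)
            except Exception as exc:
                raise RuntimeError(
                    f"calibration failed for (pixel={pix}, soil={soil})") from exc
            result.diagnostics["seed"] = config.seed
            result.diagnostics["pixel"] = str(pix)
            result.diagnostics["soil"] = str(soil)
            result.to_json(out / "calibration" / f"{pix}_{soil}.json")
            mwr_by_cell[(str(pix), str(soil))] = result.mwr
            write_contract(
                template.with_(soil_name=str(soil), mwr=result.mwr,
                               station=f"{config.station} ({pix})"),
                out / "contracts" / f"{pix}_{soil}.yaml")
            log.info("calibrate (%s, %s): R2=%.3f index=%.1f mm",
                     pix, soil, result.r2, result.index_mm)

        grid = pricing.risk_map(table, template, config.triggers,
                                mwr_by_cell=mwr_by_cell,
                                loading=config.loading, coords=config.coords)
        risk_path = out / "risk_grid.csv"
        pricing.write_risk_csv(grid, risk_path)
        log.info("price: %d rows -> %s", len(grid), risk_path)
        return {"run_table": run_path,
                "calibration_dir": out / "calibration",
                "contracts_dir": out / "contracts",
                "risk_grid": risk_path,
                "log": out / "pipeline.log"}
    finally:
        log.removeHandler(handler)
        handler.close()
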