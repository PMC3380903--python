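"""rainsure: site-specific drought-index insurance design.

Generate stochastic tropical rainfall, simulate water-limited drybean
yields on generic soils, calibrate per-dekad minimum water requirements
(MWRs) so that the seasonal rainfall deficit tracks yield in bad years,
evaluate deficit-triggered contracts and price them from empirical
exceedance probabilities.
"""

from importlib import resources

from .calibration import (CalibrationResult, calibrate_mwr, calibrate_run,
                          compute_deficit, deficit_totals, initial_mwr,
                          lowest_quartile, r_squared, rainfall_index,
                          top_quartile)
from .contract import (ContractSpec, SeasonEvaluation, evaluate_season,
                       read_contract, render_contract, write_contract)
from .cropmodel import (CropParams, SoilProfile, default_soils,
                        expected_run_count, get_soil, rain_matrix,
                        read_run_table, run_grid, runoff_fraction,
                        simulate_yield, write_run_table)
from .pipeline import PipelineConfig, run_pipeline
from .pricing import (RiskSummary, exceedance_probability, price_contract,
                      risk_map)
from .weathergen import (Canicula, ClimateParams, DailySeries, DekadalSeason,
                         OnsetRule, aggregate_to_dekads, day_of_year,
                         determine_sowing_date, droughty_wet_season,
                         generate_daily, read_dekadal_csv, tropical_wet_season,
                         write_dekadal_csv)

__version__ = "0.1.0"


def packaged_fixture(name: str):
    """Path-like handle to a packaged example file (contract and worked
    seasons)."""
    return resources.files("rainsure.data") / name
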