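import numpy as np
import pandas as pd
import pytest

import rainsure as rs


def make_run_table(rain: np.ndarray, yields: np.ndarray,
                   pixel: str = "BS", soil: str = "deep_loam") -> pd.DataFrame:
    """Assemble a run table from a (n_seasons, n_dekads) rainfall matrix
    and a yield vector."""
    rain = np.asarray(rain, dtype=float)
    n, d = rain.shape
    out = pd.DataFrame({"pixel": pixel, "soil": soil,
                        "year": np.arange(1, n + 1), "sowing_day": 152})
    for j in range(d):
        out[f"dekad_{j + 1}"] = rain[:, j]
    out["yield"] = np.asarray(yields, dtype=float)
    return out


@pytest.fixture(scope="session")
def table3_spec() -> rs.ContractSpec:
    """The packaged sample contract: MIN row (0,10,10,25,40,40,40,30,0),
    trigger -70 mm, US$5/mm indemnity."""
    return rs.read_contract(rs.packaged_fixture("contract_example.yaml"))


@pytest.fixture(scope="session")
def season_no_payout() -> rs.DekadalSeason:
    return rs.read_dekadal_csv(rs.packaged_fixture("season_no_payout.csv"))[0]


@pytest.fixture(scope="session")
def season_payout() -> rs.DekadalSeason:
    return rs.read_dekadal_csv(rs.packaged_fixture("season_payout.csv"))[0]


@pytest.fixture(scope="session")
def droughty_loam_runs() -> pd.DataFrame:
    """One run under the study conditions: droughty climate, deep loam,
    99 years, onset-rule sowing."""
    return rs.run_grid(
        ["BS"], [rs.get_soil("deep_loam")], rs.droughty_wet_season(),
        rs.CropParams(), 99, seed=1, sowing_day=None,
        onset_rule=rs.OnsetRule(), sowing_window=(135, 166))
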