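import warnings

import numpy as np
import pandas as pd
import pytest

from psithresh import (
    SimConfig,
    SpeciesParams,
    TrueParams,
    make_default_truth,
    normalize_gs,
    simulate_campaign_dataset,
)


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    """Model-fit convergence chatter is not what the tests assert on."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def one_species() -> SpeciesParams:
    return SpeciesParams(
        species_id="sp01",
        gs_max=0.3,
        pst_predawn_true=-1.2,
        exp_rate=float(np.log(0.05 / 0.3) / -1.2),
        linear_slope=0.02,
        vpd_sensitivity=-0.35,
        tlp=-1.6,
        hydroscape_intercept=-0.5,
        hydroscape_slope_wet=1.5,
        hydroscape_slope_dry=0.4,
    )


@pytest.fixture
def noiseless_config() -> SimConfig:
    return SimConfig(
        n_species=1,
        trees_per_species=10,
        n_campaigns=35,
        noise_sd_gs=0.0,
        noise_sd_psi=0.0,
        noise_sd_psi_midday=0.0,
        vpd_mean_range=(1.0, 1.0),
        vpd_campaign_sd=0.0,
        vpd_within_campaign_sd=0.0,
        tree_intercept_sd=0.0,
        seed=5,
    )


@pytest.fixture
def noiseless_world(one_species, noiseless_config):
    truth = TrueParams(species=(one_species,))
    campaign, _ = simulate_campaign_dataset(noiseless_config, truth)
    return campaign, truth


@pytest.fixture(scope="session")
def default_world():
    """One default-scale noisy world (9 species x 10 trees x 35 campaigns)."""
    truth = make_default_truth(seed=901)
    campaign, _ = simulate_campaign_dataset(SimConfig(seed=902), truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm, ref = normalize_gs(campaign)
    return norm, ref, truth


@pytest.fixture
def small_campaign_csv(tmp_path):
    """A tiny well-formed campaign file written by hand."""
    path = tmp_path / "campaign.csv"
    rows = [
        "tree_id,species,timestamp,window,psi_leaf_mpa,gs_mol_m2_s,vpd_kpa",
        "a_t01,sp_a,2021-06-10T05:00:00+01:00,predawn,-0.5,,",
        "a_t01,sp_a,2021-06-10T13:00:00+01:00,midday,-1.1,0.21,1.4",
        "a_t02,sp_a,2021-06-10T13:30:00+01:00,midday,-1.2,0.15,1.6",
    ]
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture
def dendro_df():
    dates = pd.date_range("2021-06-01", periods=6, freq="7D")
    return pd.DataFrame(
        {
            "tree_id": ["t1"] * 6,
            "date": dates,
            "dbh_cm": [30.00, 30.02, 30.01, 30.05, 30.05, 30.08],
        }
    )
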