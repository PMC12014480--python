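"""Generator contracts: response-curve shape, determinism, physical limits."""
import numpy as np
import pandas as pd
import pytest

from psithresh import (
    SimConfig,
    TrueParams,
    growth_probability,
    gs_response,
    hydroscape_map,
    make_default_truth,
    simulate_campaign_dataset,
    simulate_dendrometer_series,
    simulate_sapflow_series,
)
from psithresh.preprocess import granier_sap_flux, zero_growth_transform
from psithresh.types import VPD_REF


class TestGsResponse:
    def test_identity_at_zero_stress(self, one_species):
        p = one_species.__class__(**{**one_species.__dict__, "linear_slope": 0.0})
        assert gs_response(0.0, VPD_REF, p) == pytest.approx(1.0)

    def test_continuity_at_join(self, one_species):
        eps = 1e-8
        lo = gs_response(one_species.pst_predawn_true - eps, 1.0, one_species)
        hi = gs_response(one_species.pst_predawn_true + eps, 1.0, one_species)
        assert abs(hi - lo) < 1e-6

    def test_matches_hand_coded_piecewise_formula(self, one_species):
        # independent re-derivation of the two branches, evaluated pointwise
        p = one_species
        grid = np.arange(-2.0, 0.0, 0.01)
        for vpd in (0.8, 1.0, 2.4):
            expected = []
            for psi in grid:
                if psi > p.pst_predawn_true:
                    base = np.exp(p.exp_rate * psi)
                else:
                    base = np.exp(p.exp_rate * p.pst_predawn_true) + p.linear_slope * (
                        psi - p.pst_predawn_true
                    )
                expected.append(min(max(base * vpd**p.vpd_sensitivity, 0.0), 1.0))
            np.testing.assert_allclose(
                gs_response(grid, vpd, p), expected, atol=1e-12
            )

    def test_rejects_nonpositive_vpd_and_positive_psi(self, one_species):
        with pytest.raises(ValueError):
            gs_response(-1.0, 0.0, one_species)
        with pytest.raises(ValueError):
            gs_response(0.5, 1.0, one_species)


class TestCampaignSimulation:
    def test_same_seed_is_byte_identical(self):
        truth = make_default_truth(seed=11, n_species=2)
        cfg = SimConfig(n_species=2, trees_per_species=3, n_campaigns=8, seed=3)
        a, _ = simulate_campaign_dataset(cfg, truth)
        b, _ = simulate_campaign_dataset(cfg, truth)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_noiseless_gs_equals_response_curve(self, noiseless_world, one_species):
        campaign, _ = noiseless_world
        md = campaign[campaign["window"] == "midday"]
        pre = campaign[campaign["window"] == "predawn"]
        merged = md.merge(
            pre[["tree_id", "timestamp"]].assign(
                date=pre["timestamp"].dt.date, psi_pd=pre["psi_leaf_mpa"].values
            )[["tree_id", "date", "psi_pd"]],
            left_on=["tree_id", md["timestamp"].dt.date],
            right_on=["tree_id", "date"],
        )
        expected = gs_response(
            merged["psi_pd"].to_numpy(), merged["vpd_kpa"].to_numpy(), one_species
        )
        observed = merged["gs_mol_m2_s"].to_numpy() / one_species.gs_max
        np.testing.assert_allclose(observed, expected, atol=1e-4)

    def test_predawn_never_drier_than_midday(self):
        truth = make_default_truth(seed=1, n_species=3)
        cfg = SimConfig(n_species=3, trees_per_species=4, n_campaigns=12, seed=9)
        campaign, _ = simulate_campaign_dataset(cfg, truth)
        df = campaign.copy()
        df["date"] = df["timestamp"].dt.date
        wide = df.pivot_table(
            index=["tree_id", "date"], columns="window", values="psi_leaf_mpa"
        )
        assert (wide["predawn"] >= wide["midday"]).all()

    def test_hydroscape_map_continuous_and_below_identity(self, one_species):
        psi = np.arange(-2.5, -0.05, 0.005)
        md = hydroscape_map(psi, one_species)
        assert np.all(np.abs(np.diff(md)) < 0.02)  # no jump at the break
        assert np.all(md <= psi)


class TestDendrometer:
    def test_wet_limit_is_nondecreasing(self):
        truth = TrueParams(species=tuple(make_default_truth(seed=0).species))
        dates = pd.date_range("2021-06-01", periods=15, freq="7D")
        psi = pd.Series(-0.3, index=dates)
        df = simulate_dendrometer_series(
            truth, psi, n_trees=3, shrink_coeff_cm_per_mpa=0.0,
            reading_noise_sd_cm=0.0, seed=4,
        )
        for _, grp in df.groupby("tree_id"):
            assert (np.diff(grp["dbh_cm"].to_numpy()) >= 0).all()

    def test_dry_limit_is_constant_after_zero_growth(self):
        truth = make_default_truth(seed=0)
        dates = pd.date_range("2021-06-01", periods=15, freq="7D")
        psi = pd.Series(-2.5, index=dates)
        df = simulate_dendrometer_series(
            truth, psi, n_trees=5, reading_noise_sd_cm=0.0, seed=8
        )
        zg = zero_growth_transform(df)
        for _, grp in zg.groupby("tree_id"):
            vals = grp["dbh_cm"].to_numpy()
            assert np.allclose(vals, vals[0])

    def test_growth_probability_half_at_logistic_midpoint(self):
        # binomial oracle: at the halt psi each weekly draw is Bernoulli(1/2)
        truth = make_default_truth(seed=0)
        dates = pd.date_range("2021-06-01", periods=11, freq="7D")
        psi = pd.Series(truth.growth_halt_psi, index=dates)
        df = simulate_dendrometer_series(
            truth, psi, n_trees=200, shrink_coeff_cm_per_mpa=0.0,
            reading_noise_sd_cm=0.0, resolution_cm=0.0, seed=12,
        )
        grew = []
        for _, grp in df.groupby("tree_id"):
            inc = np.diff(grp["dbh_cm"].to_numpy())
            grew.extend(inc > 0)
        frac = np.mean(grew)
        n = len(grew)  # 200 trees x 10 intervals
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


class TestSapflow:
    def _daily_psi(self):
        dates = pd.date_range("2021-06-01", periods=10, freq="D")
        return pd.Series(np.linspace(-0.3, -1.8, 10), index=dates)

    def test_no_flow_gives_constant_delta_t(self):
        psi = self._daily_psi()
        df = simulate_sapflow_series(psi, u_max_m3_m2_s=0.0, delta_t_max_k=9.0)
        assert np.allclose(df["delta_t_k"], 9.0)

    def test_roundtrip_recovers_intended_daily_max(self):
        psi = self._daily_psi()
        u_max = 60e-6
        df = simulate_sapflow_series(psi, u_max_m3_m2_s=u_max, flux_exponent=-0.8)
        flux = granier_sap_flux(df, delta_t_max_window_days=7)
        flux["date"] = pd.to_datetime(flux["timestamp"]).dt.date
        daily = flux.groupby("date")["flux_m3_m2_s"].max()
        intended = u_max * (psi.to_numpy() / psi.max()) ** -0.8
        np.testing.assert_allclose(daily.to_numpy(), intended, atol=1e-6)

    def test_more_flux_means_cooler_probe_at_midday(self):
        psi = self._daily_psi()
        lo = simulate_sapflow_series(psi, u_max_m3_m2_s=30e-6)
        hi = simulate_sapflow_series(psi, u_max_m3_m2_s=60e-6)
        mid = lo["timestamp"].dt.hour == 13
        assert (hi.loc[mid, "delta_t_k"].to_numpy() < lo.loc[mid, "delta_t_k"].to_numpy()).all()


def test_growth_logistic_anchors():
    """The generative logistic passes through the two printed anchor points:
    50% growth probability at -1.2 MPa and 5% at -1.5 MPa."""
    truth = make_default_truth(seed=0)
    assert growth_probability(-1.2, truth) == pytest.approx(0.5, abs=1e-12)
    assert growth_probability(-1.5, truth) == pytest.approx(0.05, abs=0.002)
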