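"""Normalization, zero-growth, season filter and Granier-transform contracts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psithresh.preprocess import (
    GranierCalibration,
    daily_max_flux_percent,
    granier_sap_flux,
    growth_rates,
    normalize_gs,
    season_filter,
    zero_growth_transform,
)


def _campaign(gs_by_species: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for sp, values in gs_by_species.items():
        for i, g in enumerate(values):
            rows.append(
                {
                    "tree_id": f"{sp}_t{i}",
                    "species": sp,
                    "timestamp": pd.Timestamp("2021-06-10T13:00:00+01:00"),
                    "window": "midday",
                    "psi_leaf_mpa": -1.0,
                    "gs_mol_m2_s": g,
                    "vpd_kpa": 1.5,
                }
            )
    return pd.DataFrame(rows)


class TestNormalizeGs:
    def test_direct_division_by_species_max(self):
        df, ref = normalize_gs(_campaign({"a": [0.1, 0.2, 0.4]}))
        assert list(df["gs_norm"]) == pytest.approx([0.25, 0.5, 1.0])
        assert ref["a"] == pytest.approx(0.4)

    def test_species_normalized_independently(self):
        df, _ = normalize_gs(_campaign({"a": [0.1, 0.3], "b": [0.05, 0.5]}))
        assert df.groupby("species")["gs_norm"].max().eq(1.0).all()

    def test_quantile_one_equals_max_method(self):
        camp = _campaign({"a": [0.12, 0.31, 0.07], "b": [0.2, 0.4]})
        a, _ = normalize_gs(camp, method="species_max")
        b, _ = normalize_gs(camp, method="species_quantile", q=1.0)
        np.testing.assert_allclose(a["gs_norm"], b["gs_norm"])

    def test_preserves_within_species_ordering(self):
        rng = np.random.default_rng(0)
        vals = list(rng.uniform(0.01, 0.5, 30))
        df, _ = normalize_gs(_campaign({"a": vals}))
        assert (df["gs_norm"].rank() == df["gs_mol_m2_s"].rank()).all()

    def test_species_without_gs_excluded_with_warning(self):
        camp = _campaign({"a": [0.1, 0.2]})
        empty = camp.iloc[:1].assign(species="b", gs_mol_m2_s=np.nan)
        with pytest.warns(UserWarning, match="excluded"):
            df, _ = normalize_gs(pd.concat([camp, empty]))
        assert set(df["species"]) == {"a"}


class TestZeroGrowth:
    def test_hand_worked_running_max(self):
        df = pd.DataFrame(
            {
                "tree_id": ["t"] * 4,
                "date": pd.date_range("2021-06-01", periods=4, freq="7D"),
                "dbh_cm": [30.00, 30.02, 30.01, 30.05],
            }
        )
        out = zero_growth_transform(df)
        assert list(out["dbh_cm"]) == [30.00, 30.02, 30.02, 30.05]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(10, 100, allow_nan=False), min_size=2, max_size=30))
    def test_equals_prefix_max_oracle_and_idempotent(self, values):
        df = pd.DataFrame(
            {
                "tree_id": "t",
                "date": pd.date_range("2021-06-01", periods=len(values), freq="D"),
                "dbh_cm": values,
            }
        )
        out = zero_growth_transform(df)
        oracle = [max(values[: i + 1]) for i in range(len(values))]
        assert list(out["dbh_cm"]) == oracle
        again = zero_growth_transform(out)
        assert list(again["dbh_cm"]) == oracle


class TestGrowthRates:
    def test_rate_arithmetic_and_zero_flag(self, dendro_df):
        out = growth_rates(zero_growth_transform(dendro_df)).intervals
        assert out["rate_cm_day"].iloc[0] == pytest.approx(0.02 / 7)
        flat = out[out["rate_cm_day"] == 0]
        assert flat["is_zero"].all() and len(flat) == 2

    def test_telescoping_conservation(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "tree_id": "t",
                "date": pd.date_range("2021-05-01", periods=20, freq="5D"),
                "dbh_cm": 30 + np.cumsum(rng.uniform(-0.01, 0.04, 20)),
            }
        )
        zg = zero_growth_transform(df)
        iv = growth_rates(zg).intervals
        total = (iv["rate_cm_day"] * iv["days"]).sum()
        assert total == pytest.approx(
            zg["dbh_cm"].iloc[-1] - zg["dbh_cm"].iloc[0], abs=1e-12
        )

    def test_duplicate_dates_error(self):
        df = pd.DataFrame(
            {
                "tree_id": ["t", "t"],
                "date": ["2021-06-01", "2021-06-01"],
                "dbh_cm": [30.0, 30.1],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            growth_rates(df)


class TestSeasonFilter:
    def test_midpoint_rule_keeps_straddling_interval(self):
        iv = pd.DataFrame({"midpoint": [pd.Timestamp("2021-06-02")]})
        assert len(season_filter(iv)) == 1  # May 30 - Jun 5 midpoint is June

    def test_winter_series_empty_with_warning(self):
        iv = pd.DataFrame({"midpoint": pd.to_datetime(["2021-01-10", "2021-02-10"])})
        with pytest.warns(UserWarning, match="removed all"):
            out = season_filter(iv)
        assert out.empty

    def test_idempotent(self):
        iv = pd.DataFrame(
            {"midpoint": pd.to_datetime(["2021-06-02", "2021-09-01", "2021-07-15"])}
        )
        once = season_filter(iv)
        twice = season_filter(once)
        pd.testing.assert_frame_equal(once, twice)


def _sapflow_df(delta_t):
    ts = pd.date_range("2021-06-01", periods=len(delta_t), freq="15min", tz="Etc/GMT-1")
    return pd.DataFrame({"tree_id": "t", "timestamp": ts, "delta_t_k": delta_t})


class TestGranier:
    def test_zero_flow_at_delta_t_max(self):
        # constant delta-T: the rolling pre-dawn max equals every sample
        df = _sapflow_df(np.full(96 * 2, 8.0))
        out = granier_sap_flux(df)
        assert np.allclose(out["flux_m3_m2_s"], 0.0)

    def test_k_equals_one_gives_calibration_constant(self):
        cal = GranierCalibration()
        # delta_t = delta_t_max / 2  =>  K = 1  =>  u = a
        dt = np.full(96, 8.0)
        dt[40:60] = 4.0
        out = granier_sap_flux(_sapflow_df(dt))
        mid = out["delta_t_k"] == 4.0
        assert np.allclose(out.loc[mid, "flux_m3_m2_s"], cal.a_m3_m2_s)

    def test_flux_strictly_increasing_in_k(self):
        cal = GranierCalibration()
        k = np.sort(np.random.default_rng(1).uniform(0, 2, 50))
        u = cal.a_m3_m2_s * k**cal.b
        assert (np.diff(u) > 0).all()


class TestDailyMaxPercent:
    def test_best_day_scores_100_and_range(self):
        rng = np.random.default_rng(2)
        ts = pd.date_range("2021-06-01", periods=96 * 5, freq="15min", tz="Etc/GMT-1")
        flux = pd.DataFrame(
            {
                "tree_id": "t",
                "timestamp": ts,
                "flux_m3_m2_s": rng.uniform(0.1, 1.0, len(ts)),
            }
        )
        out = daily_max_flux_percent(flux)
        assert out["flux_pct_of_max"].max() == pytest.approx(100.0)
        assert ((out["flux_pct_of_max"] > 0) & (out["flux_pct_of_max"] <= 100)).all()

    def test_matches_naive_per_day_scan(self):
        rng = np.random.default_rng(5)
        ts = pd.date_range("2021-06-01", periods=96 * 3, freq="15min", tz="Etc/GMT-1")
        vals = rng.uniform(0, 1, len(ts))
        flux = pd.DataFrame({"tree_id": "t", "timestamp": ts, "flux_m3_m2_s": vals})
        out = daily_max_flux_percent(flux)
        by_day = {}
        for t, v in zip(ts, vals):
            local_date = (t.tz_convert("UTC") + pd.Timedelta(hours=1)).date()
            by_day[local_date] = max(by_day.get(local_date, 0.0), v)
        season_max = max(by_day.values())
        for _, row in out.iterrows():
            assert row["flux_pct_of_max"] == pytest.approx(
                100 * by_day[row["date"]] / season_max
            )

    def test_short_days_excluded(self):
        ts = pd.date_range("2021-06-01", periods=96 + 5, freq="15min", tz="Etc/GMT-1")
        flux = pd.DataFrame(
            {"tree_id": "t", "timestamp": ts, "flux_m3_m2_s": np.ones(len(ts))}
        )
        out = daily_max_flux_percent(flux, min_samples_per_day=24)
        assert len(out) == 1  # the 5-sample second day is dropped
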