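"""Closure-point estimator chain: mixed model, projection, smooth, scans."""
import numpy as np
import pandas as pd
import pytest

from psithresh import (
    estimate_pst_fixed_threshold,
    estimate_pst_intersection,
    estimate_species_pst,
    fit_gs_model,
    fit_gs_smooth,
    normalize_gs,
    paired_axis_table,
    project_linear_regime,
    summarize_pst,
)
from psithresh.closure import LinearProjection, SmoothFit
from psithresh.types import PstEstimate


def _loglinear_campaign(slope=1.5, vpd_coef=-0.4, n_trees=4, n_days=30, noise=0.0, seed=0):
    """Exact log-linear conductance data: log gs = a + slope*psi + c*log vpd."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_trees):
        for d in range(n_days):
            day = pd.Timestamp("2021-05-01", tz="Etc/GMT-1") + pd.Timedelta(days=d)
            psi_pd = -0.2 - 1.6 * d / (n_days - 1)
            vpd = float(rng.uniform(0.8, 2.5))
            loggs = slope * psi_pd + vpd_coef * np.log(vpd)
            gs = 0.3 * np.exp(loggs + rng.normal(0, noise))
            rows.append(
                dict(tree_id=f"t{t}", species="sp", timestamp=day + pd.Timedelta(hours=5),
                     window="predawn", psi_leaf_mpa=psi_pd,
                     gs_mol_m2_s=np.nan, vpd_kpa=np.nan)
            )
            rows.append(
                dict(tree_id=f"t{t}", species="sp", timestamp=day + pd.Timedelta(hours=13),
                     window="midday", psi_leaf_mpa=psi_pd - 0.5,
                     gs_mol_m2_s=gs, vpd_kpa=vpd)
            )
    return pd.DataFrame(rows)


class TestFitGsModel:
    def test_noiseless_loglinear_slope_recovered_exactly(self):
        camp = _loglinear_campaign(slope=1.5, vpd_coef=-0.4, noise=0.0)
        norm, _ = normalize_gs(camp)
        with pytest.warns(UserWarning, match="singular"):
            fit = fit_gs_model(norm, include_vpd=True, axis="predawn")
        assert fit.singular
        assert fit.params["psi"] == pytest.approx(1.5, abs=1e-6)
        assert fit.params["log_vpd"] == pytest.approx(-0.4, abs=1e-6)

    def test_null_vpd_effect_not_detected(self):
        camp = _loglinear_campaign(vpd_coef=0.0, noise=0.15, n_trees=6, seed=3)
        norm, _ = normalize_gs(camp)
        fit = fit_gs_model(norm, include_vpd=True, axis="predawn")
        assert abs(fit.params["log_vpd"]) < 2 * fit.bse["log_vpd"]

    def test_vpd_never_reduces_marginal_r2(self, default_world):
        norm, _, _ = default_world
        without = fit_gs_model(norm, include_vpd=False, axis="predawn")
        with_vpd = fit_gs_model(norm, include_vpd=True, axis="predawn")
        assert with_vpd.r2_marginal >= without.r2_marginal - 1e-6
        assert with_vpd.tree_variance >= 0 and with_vpd.resid_variance >= 0


class TestProjection:
    def _post_closure_table(self, noise=0.0, seed=0, n=40):
        rng = np.random.default_rng(seed)
        psi = np.linspace(-1.3, -2.0, n)
        gs = 0.15 + 0.02 * (psi + 1.3) + rng.normal(0, noise, n)
        return pd.DataFrame(
            {"tree_id": "t", "species": "sp", "date": pd.NaT, "psi": psi,
             "gs_norm": gs, "vpd_kpa": np.nan}
        )

    def test_noiseless_line_gives_degenerate_band(self):
        tbl = self._post_closure_table(noise=0.0)
        proj = project_linear_regime(None, tbl, regime_rule="psi_cut", psi_cut=-1.3)
        np.testing.assert_allclose(proj.upper95 - proj.lower95, 0.0, atol=1e-8)
        np.testing.assert_allclose(proj.mean, 0.15 + 0.02 * (proj.grid + 1.3), atol=1e-9)

    def test_vpd_setting_recorded(self):
        tbl = self._post_closure_table(noise=0.01, seed=1)
        proj = project_linear_regime(None, tbl, vpd_setting=2.4,
                                     regime_rule="psi_cut", psi_cut=-1.3)
        assert proj.vpd_setting == 2.4

    def test_band_matches_hand_coded_prediction_interval(self):
        """Normal-theory 95% prediction interval recomputed from scratch."""
        from scipy import stats

        tbl = self._post_closure_table(noise=0.03, seed=2, n=25)
        proj = project_linear_regime(None, tbl, regime_rule="psi_cut", psi_cut=-1.3,
                                     vpd_adjust="none")
        x = tbl["psi"].to_numpy()
        y = tbl["gs_norm"].to_numpy()
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (len(x) - 2)
        XtX_inv = np.linalg.inv(X.T @ X)
        tcrit = stats.t.ppf(0.975, len(x) - 2)
        for i in range(0, len(proj.grid), 17):
            x0 = np.array([1.0, proj.grid[i]])
            se_pred = np.sqrt(s2 * (1.0 + x0 @ XtX_inv @ x0))
            mean = x0 @ beta
            assert proj.mean[i] == pytest.approx(mean, abs=1e-10)
            assert proj.upper95[i] == pytest.approx(mean + tcrit * se_pred, abs=1e-8)
            assert proj.lower95[i] == pytest.approx(mean - tcrit * se_pred, abs=1e-8)

    def test_small_subset_raises(self):
        tbl = self._post_closure_table(n=40)
        with pytest.raises(ValueError, match="< 8"):
            project_linear_regime(None, tbl, regime_rule="psi_cut", psi_cut=-1.99)


class TestSmooth:
    def test_linear_truth_has_low_edf_and_matches_line(self):
        rng = np.random.default_rng(4)
        psi = rng.uniform(-2.0, -0.3, 200)
        tbl = pd.DataFrame(
            {"tree_id": [f"t{i % 5}" for i in range(200)], "species": "sp",
             "psi": psi, "gs_norm": 0.9 + 0.2 * psi + rng.normal(0, 0.03, 200),
             "vpd_kpa": np.nan}
        )
        fit = fit_gs_smooth(tbl, species=None, axis="predawn")
        assert fit.edf < 4
        line = 0.9 + 0.2 * fit.grid
        assert np.all((fit.lower95 - 0.02 <= line) & (line <= fit.upper95 + 0.02))
        assert np.all(fit.lower95 <= fit.mean) and np.all(fit.mean <= fit.upper95)

    def test_insufficient_span_errors_with_span_named(self):
        tbl = pd.DataFrame(
            {"tree_id": "t", "species": "sp", "psi": np.linspace(-1.0, -1.3, 30),
             "gs_norm": np.linspace(0.4, 0.3, 30), "vpd_kpa": np.nan}
        )
        with pytest.raises(ValueError, match="span"):
            fit_gs_smooth(tbl, species=None, axis="predawn")


def _synthetic_pair(seed=0, n_grid=150, inside_from=60):
    """A smooth/projection pair with a known entry structure."""
    rng = np.random.default_rng(seed)
    grid = np.round(np.arange(-0.3, -0.3 - 0.01 * n_grid, -0.01), 10)[:n_grid]
    mean = 0.1 + 0.01 * rng.standard_normal(n_grid).cumsum() * 0
    line = np.full(n_grid, 0.1)
    width = rng.uniform(0.01, 0.05)
    smooth_mean = np.where(
        np.arange(n_grid) < inside_from,
        line + width + rng.uniform(0.01, 0.3, n_grid),
        line + rng.uniform(-0.5, 0.9, 1) * 0 + rng.uniform(0, 1) * width * 0.05,
    )
    proj = LinearProjection(
        grid=grid, mean=line, lower95=line - width, upper95=line + width,
        vpd_setting=2.4, n_subset=20, regime_rule="test", slope=-0.02,
    )
    smo = SmoothFit(
        grid=grid, mean=smooth_mean, lower95=smooth_mean - 0.01,
        upper95=smooth_mean + 0.01, edf=5.0, species="sp", axis="predawn",
        n=100, psi_span=1.5,
    )
    return smo, proj


def _oracle_scan(smooth, projection, k=15, atol=1e-3, entry_atol=5e-3, entry_level=0.1):
    """Independent linear scan re-implementing the published rule."""
    grid = smooth.grid
    above = smooth.mean > projection.upper95 + entry_atol
    start = 0
    for i, a in enumerate(above):
        if a:
            start = i
            break
    else:
        return 0  # never above: degenerate, first grid point
    i = start
    n = len(grid)
    entry = None
    while i < n:
        if not above[i]:
            j = i
            while j < n and not above[j]:
                j += 1
            if (j - i) >= k or j == n:
                entry = i
                break
            i = j
        else:
            i += 1
    if entry is None:
        return None
    level = projection.mean + entry_level * (projection.upper95 - projection.mean)
    for j in range(entry, n):
        if smooth.mean[j] <= level[j] + atol:
            return j
    return entry


class TestIntersectionScan:
    def test_smooth_identical_to_projection_mean_returns_first_point(self):
        smo, proj = _synthetic_pair(seed=1)
        smo.mean = proj.mean.copy()
        est = estimate_pst_intersection(smo, proj)
        assert est.detected and est.pst == pytest.approx(proj.grid[0])

    def test_equals_independent_scan_on_random_pairs(self):
        for seed in range(50):
            smo, proj = _synthetic_pair(seed=seed, inside_from=int(30 + seed))
            est = estimate_pst_intersection(smo, proj)
            oracle_idx = _oracle_scan(smo, proj)
            if oracle_idx is None:
                assert not est.detected
            else:
                assert est.detected
                assert est.pst == pytest.approx(smo.grid[oracle_idx])

    def test_never_entering_reports_gap(self):
        smo, proj = _synthetic_pair(seed=2, inside_from=10**9)
        est = estimate_pst_intersection(smo, proj)
        assert not est.detected and est.pst is None and est.min_gap > 0

    def test_noiseless_species_recovered_within_two_grid_steps(
        self, noiseless_world, one_species
    ):
        campaign, _ = noiseless_world
        norm, ref = normalize_gs(campaign)
        est = estimate_species_pst(norm, ref, axis="predawn")[0]
        assert est.detected
        assert est.pst == pytest.approx(one_species.pst_predawn_true, abs=0.0201)


class TestFixedThreshold:
    def test_monotone_smooth_matches_bisection_oracle(self):
        grid = np.round(np.arange(-0.3, -2.0, -0.01), 10)
        mean = np.exp(1.4 * grid)  # strictly decreasing
        smo = SmoothFit(grid=grid, mean=mean, lower95=mean, upper95=mean,
                        edf=3, species="sp", axis="predawn", n=100, psi_span=1.7)
        gs_max = 0.3
        est = estimate_pst_fixed_threshold(smo, gs_max, gs_threshold=0.05)
        # bisection on the continuous curve
        from scipy.optimize import brentq

        root = brentq(lambda p: np.exp(1.4 * p) - 0.05 / gs_max, -2.0, -0.3)
        assert est.pst == pytest.approx(root, abs=0.011)
        assert est.diagnostics["gs_threshold"] == 0.05

    def test_threshold_equal_to_species_max_crosses_at_wet_edge(self):
        grid = np.round(np.arange(-0.3, -2.0, -0.01), 10)
        mean = np.exp(1.4 * grid)
        smo = SmoothFit(grid=grid, mean=mean, lower95=mean, upper95=mean,
                        edf=3, species="sp", axis="predawn", n=100, psi_span=1.7)
        est = estimate_pst_fixed_threshold(smo, species_gs_max=1.0, gs_threshold=1.0)
        assert est.pst == pytest.approx(grid[0])  # mean < 1 everywhere

    def test_never_crossing_reports_no_closure(self):
        grid = np.round(np.arange(-0.3, -2.0, -0.01), 10)
        mean = np.full_like(grid, 0.8)
        smo = SmoothFit(grid=grid, mean=mean, lower95=mean, upper95=mean,
                        edf=1, species="sp", axis="predawn", n=100, psi_span=1.7)
        est = estimate_pst_fixed_threshold(smo, 0.3, 0.05)
        assert not est.detected


class TestSummaries:
    def _est(self, sp, pst):
        return PstEstimate(species=sp, axis="predawn", pst=pst, method="ci_intersection")

    def test_two_point_arithmetic(self):
        s = summarize_pst([self._est("a", -1.0), self._est("b", -1.4)], "predawn")
        assert s.mean == pytest.approx(-1.2)
        assert s.sd == pytest.approx(np.sqrt(0.08), abs=1e-6)

    def test_identical_estimates_have_zero_sd(self):
        s = summarize_pst([self._est(f"s{i}", -1.1) for i in range(4)], "predawn")
        assert s.sd == 0.0

    def test_matches_hand_computed_moments(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(-2, -0.5, 9)
        ests = [self._est(f"s{i}", v) for i, v in enumerate(vals)]
        s = summarize_pst(ests, "predawn")
        assert s.mean == pytest.approx(float(np.mean(vals)))
        assert s.sd == pytest.approx(float(np.std(vals, ddof=1)))

    def test_single_species_errors(self):
        with pytest.raises(ValueError, match=">= 2"):
            summarize_pst([self._est("a", -1.0)], "predawn")


class TestInvariance:
    def test_estimates_invariant_to_row_order_and_tree_labels(self, default_world):
        norm, ref, _ = default_world
        base = {
            e.species: e.pst for e in estimate_species_pst(norm, ref, axis="predawn")
        }
        shuffled = norm.sample(frac=1.0, random_state=5).reset_index(drop=True)
        relabeled = shuffled.assign(
            tree_id=shuffled["tree_id"].map(lambda t: f"zz_{t}")
        )
        alt = {
            e.species: e.pst
            for e in estimate_species_pst(relabeled, ref, axis="predawn")
        }
        assert base == alt


def test_paired_axis_table_requires_normalization(default_world):
    norm, _, _ = default_world
    with pytest.raises(ValueError, match="gs_norm"):
        paired_axis_table(norm.drop(columns=["gs_norm"]), "predawn")
    with pytest.raises(ValueError, match="axis"):
        paired_axis_table(norm, "noon")
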