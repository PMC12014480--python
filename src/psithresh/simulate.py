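"""Forward simulation of multi-species tree water-relations campaigns.

The generator is phenomenological: it encodes the empirical regularities of
temperate-forest campaign data — a negative-exponential stomatal response to
pre-dawn water potential that turns into a shallow linear decline at a
species closure point, a two-slope hydroscape mapping pre-dawn to midday
water potential, growth whose probability falls off logistically with
pre-dawn water potential, and thermal-dissipation sap-flow signals — with
every generative parameter retained so that the estimation pipeline can be
checked by parameter recovery. It is not a mechanistic soil-plant-atmosphere
hydraulic model.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import VPD_REF, SimConfig, SpeciesParams, TrueParams

__all__ = [
    "gs_response",
    "hydroscape_map",
    "growth_probability",
    "make_default_truth",
    "simulate_campaign_dataset",
    "simulate_dendrometer_series",
    "simulate_sapflow_series",
]

#: Fixed UTC+1 offset: campaign clock times are defined on the CET wall clock.
CET = "Etc/GMT-1"

# Granier-style probe constants used when synthesizing delta-T signals; the
# preprocessing inverse uses the same classical calibration by default.
GRANIER_A = 118.99e-6  # m3 m-2 s-1
GRANIER_B = 1.231


def gs_response(
    psi: np.ndarray | float, vpd: np.ndarray | float, params: SpeciesParams
) -> np.ndarray | float:
    """Normalized stomatal conductance at leaf water potential ``psi`` (MPa).

    For ``psi`` above (less negative than) the species closure point the
    response declines as ``exp(exp_rate * psi)``; below it the decline is
    linear with slope ``linear_slope``, continuous at the join. The whole
    curve is multiplied by ``(vpd / VPD_REF) ** vpd_sensitivity`` and clipped
    to [0, 1].
    """
    psi_arr = np.asarray(psi, dtype=float)
    vpd_arr = np.asarray(vpd, dtype=float)
    if np.any(psi_arr > 0):
        raise ValueError("psi must be <= 0 MPa")
    if np.any(vpd_arr <= 0):
        raise ValueError("vpd must be > 0 kPa")

    pst = params.pst_predawn_true
    g_join = np.exp(params.exp_rate * pst)
    exp_branch = np.exp(params.exp_rate * psi_arr)
    lin_branch = g_join + params.linear_slope * (psi_arr - pst)
    g = np.where(psi_arr > pst, exp_branch, lin_branch)
    g = g * (vpd_arr / VPD_REF) ** params.vpd_sensitivity
    out = np.clip(g, 0.0, 1.0)
    if np.isscalar(psi) and np.isscalar(vpd):
        return float(out)
    return out


def hydroscape_map(psi_pd: np.ndarray | float, params: SpeciesParams) -> np.ndarray:
    """Midday water potential implied by pre-dawn water potential.

    Continuous two-segment line with its break at the species closure point:
    the wet slope applies above the break, the shallower dry slope below.
    """
    psi_pd = np.asarray(psi_pd, dtype=float)
    pst = params.pst_predawn_true
    md_break = params.hydroscape_intercept + params.hydroscape_slope_wet * pst
    wet = params.hydroscape_intercept + params.hydroscape_slope_wet * psi_pd
    dry = md_break + params.hydroscape_slope_dry * (psi_pd - pst)
    return np.where(psi_pd > pst, wet, dry)


def growth_probability(psi_pd: np.ndarray | float, truth: TrueParams) -> np.ndarray:
    """Probability of non-zero weekly stem growth at pre-dawn psi (MPa)."""
    x = truth.growth_logistic_steepness * (
        np.asarray(psi_pd, dtype=float) - truth.growth_halt_psi
    )
    return 1.0 / (1.0 + np.exp(-x))


def make_default_truth(
    seed: int | np.random.Generator = 0,
    n_species: int = 9,
    pst_mean: float = -1.2,
    pst_sd: float = 0.2,
    tree_threshold_sd: float = 0.0,
) -> TrueParams:
    """Draw a species ensemble emulating a temperate mixed-forest site.

    Species closure points are drawn around ``pst_mean`` (default -1.2 MPa)
    with across-species spread ``pst_sd`` (default 0.2 MPa). The exponential
    rate of each species is set so that its absolute conductance crosses the
    conventional 0.05 mol m-2 s-1 closure level near its own closure point,
    and the hydroscape wet slope (mean 1.5, intercept -0.5 MPa) places the
    midday-axis closure point near -2.3 MPa with a wider across-species
    spread than on the pre-dawn axis.

    ``tree_threshold_sd`` is exposed because the within-species spread of
    tree-level thresholds is not empirically constrained; the default of 0
    makes the species curve exact for every tree.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    species = []
    for i in range(n_species):
        pst = float(np.clip(rng.normal(pst_mean, pst_sd), -1.75, -0.75))
        gs_max = float(rng.uniform(0.2, 0.4))
        # place the absolute 0.05 crossing close to the closure point
        psi_cross = pst + float(rng.uniform(-0.15, 0.10))
        exp_rate = float(np.log(0.05 / gs_max) / psi_cross)
        slope_wet = float(np.clip(rng.normal(1.5, 0.40), 0.95, 2.4))
        slope_dry = float(np.clip(rng.normal(0.4, 0.10), 0.10, slope_wet - 0.3))
        species.append(
            SpeciesParams(
                species_id=f"sp{i + 1:02d}",
                gs_max=gs_max,
                pst_predawn_true=pst,
                exp_rate=exp_rate,
                linear_slope=float(rng.uniform(0.01, 0.03)),
                vpd_sensitivity=float(rng.uniform(-0.65, -0.25)),
                tlp=pst - float(rng.uniform(0.2, 0.6)),
                hydroscape_intercept=float(rng.normal(-0.5, 0.15)),
                hydroscape_slope_wet=slope_wet,
                hydroscape_slope_dry=slope_dry,
            )
        )
    return TrueParams(species=tuple(species))


def _campaign_schedule(config: SimConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.season_start, tz=CET)
    if config.n_campaigns == 1:
        offsets = np.array([0.0])
    else:
        # whole days: sampling clock times must stay inside the diurnal windows
        offsets = np.round(np.linspace(0, config.season_days - 1, config.n_campaigns))
    return pd.DatetimeIndex([start + pd.Timedelta(days=float(d)) for d in offsets])


def _site_psi_trajectory(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Seasonal site-level pre-dawn psi: drying ramp with campaign jitter."""
    wet, dry = config.predawn_psi_range
    n = config.n_campaigns
    f = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    psi = wet + (dry - wet) * f**1.15
    psi = psi + rng.normal(0.0, 0.06, size=n)
    return np.clip(psi, dry, min(wet, -0.01))


def simulate_campaign_dataset(
    config: SimConfig, truth: TrueParams
) -> tuple[pd.DataFrame, TrueParams]:
    """Simulate a full multi-species campaign table.

    Per campaign the site dries along a seasonal trajectory; each tree's
    pre-dawn psi scatters around the site value, midday psi follows the
    species hydroscape (never wetter than pre-dawn, by construction), and
    midday conductance follows :func:`gs_response` driven by the tree's
    pre-dawn psi, with multiplicative lognormal tree effects and additive
    truncated-Gaussian measurement noise. Pre-dawn rows carry psi only;
    midday rows carry psi, conductance and VPD.

    Returns the tidy observation table (campaign.csv schema) and the truth
    object, which is passed through untouched for recovery bookkeeping.
    """
    if len(truth.species) != config.n_species:
        raise ValueError(
            f"truth has {len(truth.species)} species but config expects {config.n_species}"
        )
    rng = np.random.default_rng(config.seed)
    dates = _campaign_schedule(config)
    site_psi = _site_psi_trajectory(config, rng)
    f_season = np.linspace(0.0, 1.0, config.n_campaigns) if config.n_campaigns > 1 else np.array([0.5])

    rows: list[dict] = []
    for sp in truth.species:
        tree_ids = [f"{sp.species_id}_t{j + 1:02d}" for j in range(config.trees_per_species)]
        tree_eff = np.exp(rng.normal(0.0, config.tree_intercept_sd, size=len(tree_ids)))
        for ci, (day, psi_site) in enumerate(zip(dates, site_psi)):
            # campaign-level midday VPD rises as the season dries
            v_lo, v_hi = config.vpd_mean_range
            vpd_mu = np.log(v_lo + (v_hi - v_lo) * f_season[ci])
            vpd_campaign = np.exp(rng.normal(vpd_mu, config.vpd_campaign_sd))
            for tj, tree in enumerate(tree_ids):
                psi_pd = min(psi_site + rng.normal(0.0, config.noise_sd_psi), -0.01)
                psi_md = hydroscape_map(psi_pd, sp) + rng.normal(
                    0.0, config.noise_sd_psi_midday
                )
                psi_md = min(float(psi_md), psi_pd)
                vpd = float(
                    np.clip(
                        vpd_campaign
                        * np.exp(rng.normal(0.0, config.vpd_within_campaign_sd)),
                        0.4,
                        3.5,
                    )
                )
                g_norm = gs_response(psi_pd, vpd, sp) * tree_eff[tj]
                g_norm = max(g_norm + rng.normal(0.0, config.noise_sd_gs), 0.0)
                rows.append(
                    {
                        "tree_id": tree,
                        "species": sp.species_id,
                        "timestamp": day + pd.Timedelta(hours=5),
                        "window": "predawn",
                        "psi_leaf_mpa": round(psi_pd, 4),
                        "gs_mol_m2_s": np.nan,
                        "vpd_kpa": np.nan,
                    }
                )
                rows.append(
                    {
                        "tree_id": tree,
                        "species": sp.species_id,
                        "timestamp": day + pd.Timedelta(hours=13),
                        "window": "midday",
                        "psi_leaf_mpa": round(psi_md, 4),
                        "gs_mol_m2_s": round(g_norm * sp.gs_max, 5),
                        "vpd_kpa": round(vpd, 3),
                    }
                )
    df = pd.DataFrame(rows)
    df = df.sort_values(["species", "tree_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return df, truth


def simulate_dendrometer_series(
    truth: TrueParams,
    psi_pd_series: pd.Series,
    n_trees: int = 10,
    dbh0_cm: float = 35.0,
    base_increment_cm: float = 0.03,
    shrink_coeff_cm_per_mpa: float = 0.005,
    reading_noise_sd_cm: float = 0.0005,
    resolution_cm: float = 0.005,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Weekly band-dendrometer readings for ``n_trees`` trees.

    ``psi_pd_series`` is a date-indexed pre-dawn psi trajectory (MPa) at the
    reading dates. Each week a tree adds an irreversible increment with
    probability given by the growth logistic of ``truth`` (gamma-distributed
    size, mean ``base_increment_cm``); the observed diameter superimposes a
    reversible elastic shrinkage proportional to psi plus reading noise, so
    raw series can decrease even while cumulative growth never does.
    Readings are quantized to ``resolution_cm`` (manual girth-band tapes
    resolve ~0.01 cm); without quantization sub-resolution reading noise
    would register as spurious weekly growth after the running-maximum
    transform.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    psi = psi_pd_series.to_numpy(dtype=float)
    # growth during an interval responds to the interval's mean water status
    psi_interval = np.concatenate([[psi[0]], 0.5 * (psi[1:] + psi[:-1])])
    p_grow = growth_probability(psi_interval, truth)
    rows = []
    for t in range(n_trees):
        dbh = dbh0_cm + rng.normal(0.0, 2.0)
        for k, date in enumerate(psi_pd_series.index):
            if k > 0:
                grows = rng.random() < p_grow[k]
                if grows:
                    dbh += rng.gamma(4.0, base_increment_cm / 4.0)
            observed = (
                dbh
                + shrink_coeff_cm_per_mpa * psi[k]
                + (rng.normal(0.0, reading_noise_sd_cm) if reading_noise_sd_cm > 0 else 0.0)
            )
            if resolution_cm > 0:
                observed = round(observed / resolution_cm) * resolution_cm
            rows.append({"tree_id": f"t{t + 1:02d}", "date": pd.Timestamp(date).date(), "dbh_cm": round(observed, 6)})
    return pd.DataFrame(rows)


def simulate_sapflow_series(
    psi_pd_daily: pd.Series,
    flux_exponent: float = -0.8,
    u_max_m3_m2_s: float = 60e-6,
    delta_t_max_k: float = 10.0,
    samples_per_day: int = 96,
    noise_sd_k: float = 0.0,
    tree_id: str = "t01",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Thermal-dissipation delta-T series whose implied daily maximum flux
    follows a power law in pre-dawn psi.

    The intended daily maximum flux density is
    ``u_max * ((-psi) / (-psi_wettest)) ** flux_exponent`` (a log-log linear
    decline toward more negative psi); the diel course is a half-sine between
    06:00 and 20:00 with zero night flow. Delta-T is the exact inverse of the
    classical thermal-dissipation calibration, so the preprocessing transform
    recovers the intended flux to numerical precision.
    """
    if np.any(psi_pd_daily.to_numpy() >= 0):
        raise ValueError("psi_pd_daily must be < 0 MPa")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    psi = psi_pd_daily.to_numpy(dtype=float)
    psi_wet = psi.max()
    u_day = u_max_m3_m2_s * (psi / psi_wet) ** flux_exponent  # psi/psi_wet = (-psi)/(-psi_wet)

    step_h = 24.0 / samples_per_day
    hours = np.arange(0.0, 24.0, step_h)
    day_mask = (hours >= 6.0) & (hours <= 20.0)
    shape = np.zeros_like(hours)
    shape[day_mask] = np.sin(np.pi * (hours[day_mask] - 6.0) / 14.0)

    rows = []
    for d, date in enumerate(psi_pd_daily.index):
        flux = u_day[d] * shape
        k_index = (flux / GRANIER_A) ** (1.0 / GRANIER_B)
        delta_t = delta_t_max_k / (1.0 + k_index)
        if noise_sd_k > 0:
            delta_t = delta_t + rng.normal(0.0, noise_sd_k, size=delta_t.size)
        base = pd.Timestamp(date).tz_localize(CET) if pd.Timestamp(date).tz is None else pd.Timestamp(date)
        for h, dt in zip(hours, delta_t):
            rows.append(
                {
                    "tree_id": tree_id,
                    "timestamp": base + pd.Timedelta(hours=float(h)),
                    "delta_t_k": round(float(dt), 6),
                }
            )
    return pd.DataFrame(rows)
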