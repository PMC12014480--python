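"""Transforms from raw records to estimator-ready variables.

Covers species-max conductance normalization, the zero-growth treatment of
dendrometer series (reversible shrinkage is not negative growth), interval
growth rates, the summer season filter, and the thermal-dissipation
(Granier-type) delta-T to sap-flux-density conversion.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "normalize_gs",
    "zero_growth_transform",
    "growth_rates",
    "season_filter",
    "granier_sap_flux",
    "daily_max_flux_percent",
    "GranierCalibration",
]


def normalize_gs(
    records: pd.DataFrame, method: str = "species_max", q: float = 1.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize conductance to a species-specific reference.

    method="species_max" divides by each species' maximum observed
    conductance (so the species maximum of ``gs_norm`` is exactly 1);
    method="species_quantile" divides by the q-quantile instead, a robust
    option for outlier-contaminated data (q=1.0 reduces to the max).

    Returns the augmented table (new column ``gs_norm``) and the per-species
    reference used, for back-conversion to absolute units. Species with no
    non-missing conductance are excluded with a warning.
    """
    if method not in ("species_max", "species_quantile"):
        raise ValueError(f"unknown method {method!r}")
    if method == "species_max":
        q = 1.0
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    df = records.copy()
    has_gs = df.groupby("species")["gs_mol_m2_s"].transform(lambda s: s.notna().any())
    dropped = sorted(df.loc[~has_gs, "species"].unique())
    if dropped:
        warnings.warn(f"species with no conductance data excluded: {dropped}")
        df = df[has_gs].copy()
    ref = df.groupby("species")["gs_mol_m2_s"].quantile(q)
    ref.name = "species_gs_max"
    df["gs_norm"] = df["gs_mol_m2_s"] / df["species"].map(ref)
    return df, ref


def zero_growth_transform(series: pd.DataFrame) -> pd.DataFrame:
    """Replace each DBH reading by the running maximum within its tree.

    Under the zero-growth concept, reversible stem shrinkage (drought-driven
    water depletion of bark tissues) is not growth: only irreversible
    expansion beyond the previous maximum counts. Output is monotone
    nondecreasing per tree; the transform is idempotent.
    """
    df = series.sort_values(["tree_id", "date"], kind="mergesort").copy()
    df["dbh_cm"] = df.groupby("tree_id")["dbh_cm"].cummax()
    return df.reset_index(drop=True)


@dataclass
class GrowthRateSeries:
    """Per-interval growth rates for one or more trees.

    intervals columns: tree_id, start, end, midpoint, days, rate_cm_day,
    is_zero.
    """

    intervals: pd.DataFrame


def growth_rates(series: pd.DataFrame) -> GrowthRateSeries:
    """Interval growth rates from (zero-growth-transformed) DBH readings.

    rate = delta-DBH / delta-days per consecutive reading pair; ``is_zero``
    marks intervals with no irreversible expansion. Input should already be
    zero-growth transformed so rates are >= 0. Duplicate reading dates within
    a tree are an error.
    """
    rows = []
    for tree, grp in series.sort_values(["tree_id", "date"], kind="mergesort").groupby("tree_id"):
        if grp["date"].duplicated().any():
            raise ValueError(f"duplicate reading dates for tree {tree}")
        d = pd.to_datetime(grp["date"]).to_numpy()
        dbh = grp["dbh_cm"].to_numpy(dtype=float)
        for i in range(1, len(grp)):
            days = (d[i] - d[i - 1]) / np.timedelta64(1, "D")
            rate = (dbh[i] - dbh[i - 1]) / days
            rows.append(
                {
                    "tree_id": tree,
                    "start": d[i - 1],
                    "end": d[i],
                    "midpoint": d[i - 1] + (d[i] - d[i - 1]) / 2,
                    "days": days,
                    "rate_cm_day": rate,
                    "is_zero": rate == 0.0,
                }
            )
    return GrowthRateSeries(intervals=pd.DataFrame(rows))


def season_filter(
    intervals: pd.DataFrame,
    months: tuple[int, ...] = (6, 7, 8),
    date_column: str = "midpoint",
) -> pd.DataFrame:
    """Keep records whose (midpoint) date falls in the configured months.

    Default June-August: restricting to high summer avoids counting winter
    cambial dormancy as water-limited growth halt. Idempotent. Works on any
    dated table; for interval tables the midpoint decides membership.
    """
    dates = pd.to_datetime(intervals[date_column])
    out = intervals[dates.dt.month.isin(months)].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("season filter removed all records")
    return out


@dataclass(frozen=True)
class GranierCalibration:
    """Classical thermal-dissipation calibration u = a * K**b."""

    a_m3_m2_s: float = 118.99e-6
    b: float = 1.231


def granier_sap_flux(
    series: pd.DataFrame,
    delta_t_max_window_days: int = 7,
    calibration: GranierCalibration = GranierCalibration(),
    predawn_hours: tuple[float, float] = (0.0, 6.0),
    utc_offset_hours: float = 1.0,
) -> pd.DataFrame:
    """Convert a delta-T series to sap flux density (m3 m-2 s-1).

    The zero-flow reference delta-T-max is the maximum pre-dawn delta-T in a
    rolling window (default 7 days) per tree, which accommodates slow probe
    baseline drift. K = (delta_t_max - delta_t) / delta_t, clipped at 0, and
    u = a * K**b with the classical calibration constants.
    """
    if delta_t_max_window_days < 1:
        raise ValueError("delta_t_max_window_days must be >= 1")
    df = series.sort_values(["tree_id", "timestamp"], kind="mergesort").copy()
    ts = pd.to_datetime(df["timestamp"])
    local = ts.dt.tz_convert("UTC") + pd.Timedelta(hours=utc_offset_hours) if ts.dt.tz is not None else ts
    df["_date"] = local.dt.date
    hour = local.dt.hour + local.dt.minute / 60.0
    is_predawn = (hour >= predawn_hours[0]) & (hour < predawn_hours[1])

    out = []
    for tree, grp in df.groupby("tree_id", sort=False):
        night_max = (
            grp.loc[is_predawn.loc[grp.index]]
            .groupby("_date")["delta_t_k"]
            .max()
        )
        if night_max.empty:
            raise ValueError(f"no pre-dawn samples to define delta_t_max for tree {tree}")
        rolling = night_max.rolling(delta_t_max_window_days, min_periods=1).max()
        if (rolling <= 0).any():
            raise ValueError("delta_t_max must be > 0")
        dt_max = grp["_date"].map(rolling)
        # days before the first pre-dawn reference use the first available one
        dt_max = dt_max.fillna(rolling.iloc[0])
        k = (dt_max - grp["delta_t_k"]) / grp["delta_t_k"]
        k = k.clip(lower=0.0)
        g = grp.copy()
        g["k_index"] = k
        g["flux_m3_m2_s"] = calibration.a_m3_m2_s * k**calibration.b
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    return res.drop(columns=["_date"])


def daily_max_flux_percent(
    flux: pd.DataFrame, min_samples_per_day: int = 24, utc_offset_hours: float = 1.0
) -> pd.DataFrame:
    """Daily maximum sap flux density per tree, as % of the tree's seasonal
    maximum.

    Days with fewer than ``min_samples_per_day`` samples are excluded and
    flagged in the ``excluded`` column of the returned table's attrs. Values
    lie in (0, 100]; the day attaining the tree maximum scores exactly 100
    (ties share the score).
    """
    df = flux.copy()
    ts = pd.to_datetime(df["timestamp"])
    local = ts.dt.tz_convert("UTC") + pd.Timedelta(hours=utc_offset_hours) if ts.dt.tz is not None else ts
    df["date"] = local.dt.date
    counts = df.groupby(["tree_id", "date"])["flux_m3_m2_s"].size()
    daily = df.groupby(["tree_id", "date"])["flux_m3_m2_s"].max()
    ok = counts >= min_samples_per_day
    excluded = daily[~ok].reset_index()[["tree_id", "date"]]
    daily = daily[ok]
    res = daily.reset_index().rename(columns={"flux_m3_m2_s": "daily_max_flux"})
    tree_max = res.groupby("tree_id")["daily_max_flux"].transform("max")
    if (tree_max <= 0).any():
        raise ValueError("tree seasonal maximum flux is zero; cannot normalize")
    res["flux_pct_of_max"] = 100.0 * res["daily_max_flux"] / tree_max
    res.attrs["excluded_days"] = excluded
    return res
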