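"""Tidy delimited-text schemas, validation and diurnal-window tagging.

All tables are comma-separated UTF-8 with "." decimals and unit-suffixed
headers. Water potential is stored negative (MPa): any positive value is a
validation error, never auto-negated — silent sign flips are a classic
corruption source in water-potential datasets.

Canonical schemas
-----------------
campaign.csv : tree_id, species, timestamp, window, psi_leaf_mpa,
               gs_mol_m2_s, vpd_kpa
dendro.csv   : tree_id, date, dbh_cm
sapflow.csv  : tree_id, timestamp, delta_t_k
meteo.csv    : timestamp, air_temp_c, rh_pct, solar_w_m2, precip_mm
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CAMPAIGN_COLUMNS = [
    "tree_id",
    "species",
    "timestamp",
    "window",
    "psi_leaf_mpa",
    "gs_mol_m2_s",
    "vpd_kpa",
]
DENDRO_COLUMNS = ["tree_id", "date", "dbh_cm"]
SAPFLOW_COLUMNS = ["tree_id", "timestamp", "delta_t_k"]
METEO_COLUMNS = ["timestamp", "air_temp_c", "rh_pct", "solar_w_m2", "precip_mm"]


class SchemaError(ValueError):
    """A file does not match the documented schema (e.g. missing column)."""


@dataclass(frozen=True)
class WindowsConfig:
    """Half-open local-clock measurement windows, on a fixed UTC offset.

    Defaults follow the campaign protocol: pre-dawn 04:00-06:00 and midday
    12:00-14:00 on the CET wall clock (UTC+1, no daylight shift). Boundaries
    are [start, end): 06:00 itself is no longer pre-dawn.
    """

    predawn: tuple[float, float] = (4.0, 6.0)
    midday: tuple[float, float] = (12.0, 14.0)
    utc_offset_hours: float = 1.0

    def __post_init__(self) -> None:
        for name, (a, b) in (("predawn", self.predawn), ("midday", self.midday)):
            if not 0 <= a < b <= 24:
                raise ValueError(f"{name} window must satisfy 0 <= start < end <= 24")
        a1, b1 = self.predawn
        a2, b2 = self.midday
        if max(a1, a2) < min(b1, b2):
            raise ValueError("predawn and midday windows overlap")


def tag_window(timestamp: pd.Timestamp, windows: WindowsConfig | None = None) -> str:
    """Label a timestamp as predawn / midday / other by its local clock hour."""
    windows = windows or WindowsConfig()
    ts = pd.Timestamp(timestamp)
    if ts.tz is not None:
        ts = ts.tz_convert("UTC") + pd.Timedelta(hours=windows.utc_offset_hours)
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    if windows.predawn[0] <= hour < windows.predawn[1]:
        return "predawn"
    if windows.midday[0] <= hour < windows.midday[1]:
        return "midday"
    return "other"


@dataclass
class ReadResult:
    """Validated records plus a row-indexed account of rejected rows."""

    records: pd.DataFrame
    rejected: pd.DataFrame  # columns: row (0-based data row), reason
    n_read: int = 0

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _reject(reasons: dict[int, list[str]], idx: int, reason: str) -> None:
    reasons.setdefault(idx, []).append(reason)


def read_campaign_table(
    path: str | Path,
    windows: WindowsConfig | None = None,
    column_map: dict[str, str] | None = None,
) -> ReadResult:
    """Read and validate a campaign table.

    ``column_map`` renames source columns onto the canonical schema (useful
    for externally deposited files whose headers differ). Rows violating an
    invariant (positive psi, negative conductance, non-positive VPD,
    unparseable timestamp) are collected into the rejection report, not
    silently dropped. The window column, if absent or inconsistent, is
    recomputed from the timestamp.
    """
    windows = windows or WindowsConfig()
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = {"tree_id", "species", "timestamp", "psi_leaf_mpa"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
    for col in ("gs_mol_m2_s", "vpd_kpa", "window"):
        if col not in df.columns:
            df[col] = np.nan

    reasons: dict[int, list[str]] = {}
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    for idx in np.flatnonzero(ts.isna().to_numpy()):
        _reject(reasons, int(idx), f"unparseable timestamp: {df['timestamp'].iloc[idx]!r}")
    psi = pd.to_numeric(df["psi_leaf_mpa"], errors="coerce")
    for idx in np.flatnonzero((psi > 0).to_numpy()):
        _reject(reasons, int(idx), f"psi_leaf_mpa must be <= 0, got {psi.iloc[idx]}")
    for idx in np.flatnonzero(psi.isna().to_numpy()):
        _reject(reasons, int(idx), "psi_leaf_mpa missing or non-numeric")
    gs = pd.to_numeric(df["gs_mol_m2_s"], errors="coerce")
    for idx in np.flatnonzero((gs < 0).to_numpy()):
        _reject(reasons, int(idx), f"gs_mol_m2_s must be >= 0, got {gs.iloc[idx]}")
    vpd = pd.to_numeric(df["vpd_kpa"], errors="coerce")
    for idx in np.flatnonzero((vpd <= 0).to_numpy()):
        _reject(reasons, int(idx), f"vpd_kpa must be > 0, got {vpd.iloc[idx]}")

    bad = sorted(reasons)
    rejected = pd.DataFrame(
        {"row": bad, "reason": ["; ".join(reasons[i]) for i in bad]}
    )
    keep = df.index.difference(bad)
    out = df.loc[keep].copy()
    out["timestamp"] = ts.loc[keep]
    out["psi_leaf_mpa"] = psi.loc[keep]
    out["gs_mol_m2_s"] = gs.loc[keep]
    out["vpd_kpa"] = vpd.loc[keep]
    out["window"] = [tag_window(t, windows) for t in out["timestamp"]]
    out = out[CAMPAIGN_COLUMNS].reset_index(drop=True)
    return ReadResult(records=out, rejected=rejected, n_read=len(df))


def write_campaign_table(path: str | Path, records: pd.DataFrame) -> None:
    """Write a campaign table: canonical column order, rows sorted by
    (species, tree_id, timestamp), ISO-8601 timestamps. Bit-stable for a
    fixed record set."""
    df = records.copy()
    missing = set(CAMPAIGN_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"records missing column(s): {sorted(missing)}")
    df = df[CAMPAIGN_COLUMNS].sort_values(
        ["species", "tree_id", "timestamp"], kind="mergesort"
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"]).map(_iso)
    df.to_csv(path, index=False)


def _iso(ts: pd.Timestamp) -> str:
    # canonical on-disk clock is the fixed UTC+1 campaign zone
    if ts.tz is not None:
        ts = ts.tz_convert("Etc/GMT-1")
    return ts.isoformat()


def write_series(path: str | Path, records: pd.DataFrame, kind: str) -> None:
    """Write a dendrometer / sap-flow / meteo series in its canonical schema."""
    columns = {"dendro": DENDRO_COLUMNS, "sapflow": SAPFLOW_COLUMNS, "meteo": METEO_COLUMNS}[kind]
    df = records.copy()
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"records missing column(s): {sorted(missing)}")
    df = df[columns].sort_values(columns[: 2 if "tree_id" in columns else 1], kind="mergesort")
    for tcol in ("timestamp",):
        if tcol in df.columns:
            df[tcol] = pd.to_datetime(df[tcol]).map(_iso)
    df.to_csv(path, index=False)


def read_dendro_table(path: str | Path) -> ReadResult:
    """Read dated DBH readings; rejects non-positive DBH and bad dates."""
    df = pd.read_csv(path)
    missing = set(DENDRO_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
    reasons: dict[int, list[str]] = {}
    dates = pd.to_datetime(df["date"], errors="coerce")
    for idx in np.flatnonzero(dates.isna().to_numpy()):
        _reject(reasons, int(idx), f"unparseable date: {df['date'].iloc[idx]!r}")
    dbh = pd.to_numeric(df["dbh_cm"], errors="coerce")
    for idx in np.flatnonzero(~(dbh > 0).to_numpy()):
        _reject(reasons, int(idx), "dbh_cm must be > 0")
    bad = sorted(reasons)
    rejected = pd.DataFrame({"row": bad, "reason": ["; ".join(reasons[i]) for i in bad]})
    keep = df.index.difference(bad)
    out = df.loc[keep, DENDRO_COLUMNS].copy()
    out["date"] = dates.loc[keep]
    out["dbh_cm"] = dbh.loc[keep]
    out = out.sort_values(["tree_id", "date"], kind="mergesort").reset_index(drop=True)
    for tree, grp in out.groupby("tree_id"):
        if grp["date"].duplicated().any():
            raise SchemaError(f"duplicate reading dates for tree {tree}")
    return ReadResult(records=out, rejected=rejected, n_read=len(df))


def read_sapflow_table(path: str | Path) -> ReadResult:
    """Read a delta-T series; rejects non-positive delta-T."""
    df = pd.read_csv(path)
    missing = set(SAPFLOW_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
    reasons: dict[int, list[str]] = {}
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    for idx in np.flatnonzero(ts.isna().to_numpy()):
        _reject(reasons, int(idx), "unparseable timestamp")
    dt = pd.to_numeric(df["delta_t_k"], errors="coerce")
    for idx in np.flatnonzero(~(dt > 0).to_numpy()):
        _reject(reasons, int(idx), "delta_t_k must be > 0")
    bad = sorted(reasons)
    rejected = pd.DataFrame({"row": bad, "reason": ["; ".join(reasons[i]) for i in bad]})
    keep = df.index.difference(bad)
    out = df.loc[keep, SAPFLOW_COLUMNS].copy()
    out["timestamp"] = ts.loc[keep]
    out["delta_t_k"] = dt.loc[keep]
    out = out.sort_values(["tree_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return ReadResult(records=out, rejected=rejected, n_read=len(df))


@dataclass
class SchemaConfig:
    """Structured run configuration loaded from YAML: windows, season months
    and source-column mappings."""

    windows: WindowsConfig = field(default_factory=WindowsConfig)
    season_months: tuple[int, ...] = (6, 7, 8)
    column_map: dict[str, str] = field(default_factory=dict)


def load_schema_config(path: str | Path) -> SchemaConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    wraw = raw.get("windows", {})
    windows = WindowsConfig(
        predawn=tuple(wraw.get("predawn", (4.0, 6.0))),
        midday=tuple(wraw.get("midday", (12.0, 14.0))),
        utc_offset_hours=float(wraw.get("utc_offset_hours", 1.0)),
    )
    return SchemaConfig(
        windows=windows,
        season_months=tuple(raw.get("season_months", (6, 7, 8))),
        column_map=dict(raw.get("column_map", {})),
    )
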