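"""Estimation of the point of stomatal closure (P_st).

The estimator chain mirrors the campaign analysis: species-normalized
midday conductance is modelled against leaf water potential on a chosen
axis (pre-dawn or midday); the shallow linear post-closure regime is
projected at a fixed high VPD (2.4 kPa) with a pointwise 95% confidence
band; a penalized-spline smooth (with tree-level intercept adjustment)
summarizes the mean response; and P_st is the least-negative grid point at
which the smooth enters the projection band and stays there. A
fixed-conductance-threshold variant (g_s < 0.05 mol m-2 s-1) provides the
robustness check.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .smoothing import PenalizedSpline
from .types import Axis, PstEstimate, PstSummary

__all__ = [
    "paired_axis_table",
    "fit_gs_model",
    "project_linear_regime",
    "fit_gs_smooth",
    "estimate_pst_intersection",
    "estimate_pst_fixed_threshold",
    "estimate_species_pst",
    "summarize_pst",
    "GsModelFit",
    "LinearProjection",
    "SmoothFit",
]

DEFAULT_VPD_SETTING = 2.4  # kPa: high-VPD condition for the linear projection
DEFAULT_GS_THRESHOLD = 0.05  # mol m-2 s-1: conventional closure level
DEFAULT_GRID_STEP = 0.01  # MPa


def paired_axis_table(records: pd.DataFrame, axis: Axis) -> pd.DataFrame:
    """Pair midday conductance with leaf water potential on the chosen axis.

    axis="midday" uses the midday rows directly; axis="predawn" joins each
    midday conductance measurement to the same tree's pre-dawn water
    potential from the same campaign day. Requires a ``gs_norm`` column
    (see :func:`psithresh.preprocess.normalize_gs`).
    """
    if "gs_norm" not in records.columns:
        raise ValueError("records must carry gs_norm; run normalize_gs first")
    df = records.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    md = df[(df["window"] == "midday") & df["gs_norm"].notna()]
    if axis == "midday":
        out = md.rename(columns={"psi_leaf_mpa": "psi"})
    elif axis == "predawn":
        pd_rows = df[df["window"] == "predawn"][["tree_id", "date", "psi_leaf_mpa"]]
        pd_rows = pd_rows.rename(columns={"psi_leaf_mpa": "psi"})
        out = md.drop(columns=["psi_leaf_mpa"]).merge(
            pd_rows, on=["tree_id", "date"], how="inner"
        )
    else:
        raise ValueError(f"axis must be 'predawn' or 'midday', got {axis!r}")
    return out[["tree_id", "species", "date", "psi", "gs_norm", "vpd_kpa"]].reset_index(
        drop=True
    )


@dataclass
class GsModelFit:
    """Mixed-model fit of log normalized conductance on psi (+ log VPD)."""

    params: pd.Series  # fixed-effect coefficients
    bse: pd.Series
    tree_variance: float
    resid_variance: float
    r2_marginal: float
    r2_conditional: float
    n: int
    axis: Axis
    include_vpd: bool
    log_offset: float  # added to gs_norm before the log when zeros occur
    singular: bool = False  # True when downgraded to a fixed-effects fit


def fit_gs_model(
    records: pd.DataFrame, include_vpd: bool = True, axis: Axis = "predawn"
) -> GsModelFit:
    """Linear mixed model: log(gs_norm) ~ psi [+ log VPD] + species, with a
    tree random intercept.

    Zeros in normalized conductance are handled by adding half the smallest
    positive value before the log; the offset is recorded in the fit. A
    singular or degenerate random-effects fit (single tree, zero residual
    variance) downgrades to ordinary least squares with a warning.
    """
    tbl = paired_axis_table(records, axis)
    tbl = tbl.dropna(subset=["psi", "gs_norm"] + (["vpd_kpa"] if include_vpd else []))
    offset = 0.0
    if (tbl["gs_norm"] <= 0).any():
        offset = 0.5 * tbl.loc[tbl["gs_norm"] > 0, "gs_norm"].min()
    y = np.log(tbl["gs_norm"] + offset)
    X = pd.DataFrame({"Intercept": 1.0, "psi": tbl["psi"]}, index=tbl.index)
    if include_vpd:
        X["log_vpd"] = np.log(tbl["vpd_kpa"])
    for sp in sorted(tbl["species"].unique())[1:]:
        X[f"species[{sp}]"] = (tbl["species"] == sp).astype(float)

    n_trees = tbl["tree_id"].nunique()
    ols = sm.OLS(y, X).fit()
    resid_var_ols = float(ols.mse_resid) if ols.df_resid > 0 else 0.0

    def _r2(params, re_var, resid_var):
        var_fixed = float(np.var(X.to_numpy() @ params.to_numpy(), ddof=0))
        denom = var_fixed + re_var + resid_var
        return var_fixed / denom, (var_fixed + re_var) / denom

    if n_trees < 2 or resid_var_ols < 1e-12:
        warnings.warn(
            "random-intercept fit is singular (single tree or zero residual "
            "variance); downgraded to fixed-effects OLS"
        )
        r2m, r2c = _r2(ols.params, 0.0, resid_var_ols)
        return GsModelFit(
            params=ols.params, bse=ols.bse, tree_variance=0.0,
            resid_variance=resid_var_ols, r2_marginal=r2m, r2_conditional=r2c,
            n=len(tbl), axis=axis, include_vpd=include_vpd,
            log_offset=offset, singular=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=tbl["tree_id"])
        try:
            mm = model.fit(reml=True)
        except np.linalg.LinAlgError:
            mm = model.fit(reml=True, method="powell")
    tree_var = float(mm.cov_re.iloc[0, 0])
    resid_var = float(mm.scale)
    r2m, r2c = _r2(mm.params[X.columns], tree_var, resid_var)
    return GsModelFit(
        params=mm.params[X.columns], bse=mm.bse[X.columns], tree_variance=tree_var,
        resid_variance=resid_var, r2_marginal=r2m, r2_conditional=r2c,
        n=len(tbl), axis=axis, include_vpd=include_vpd, log_offset=offset,
    )


@dataclass
class LinearProjection:
    """Post-closure linear regime projected at a fixed VPD, with 95% band."""

    grid: np.ndarray  # MPa, ordered least- to most-negative
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    vpd_setting: float
    n_subset: int
    regime_rule: str
    slope: float = np.nan

    def __post_init__(self) -> None:
        if not (np.diff(self.grid) < 0).all():
            raise ValueError("grid must be strictly ordered toward more negative psi")


@dataclass
class SmoothFit:
    """Penalized-spline smooth of normalized conductance against psi."""

    grid: np.ndarray
    mean: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    edf: float
    species: str
    axis: Axis
    n: int
    psi_span: float
    tree_intercepts: pd.Series | None = None
    diagnostics: dict = field(default_factory=dict)


def species_grid(psi: np.ndarray, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Shared psi grid over the observed range, wettest first."""
    hi = np.floor(np.max(psi) / step) * step
    lo = np.ceil(np.min(psi) / step) * step
    return np.round(np.arange(hi, lo - step / 2, -step), 10)


def project_linear_regime(
    fit: GsModelFit | None,
    table: pd.DataFrame,
    vpd_setting: float = DEFAULT_VPD_SETTING,
    regime_rule: str = "gs_quantile",
    q: float = 0.10,
    grid: np.ndarray | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    psi_cut: float | None = None,
    vpd_adjust: str = "standardize",
    interval: str = "prediction",
) -> LinearProjection:
    """Project the post-closure linear decline at high VPD.

    ``table`` is a single-species paired axis table. The post-closure subset
    is chosen by ``regime_rule``:

    - "gs_quantile": observations with gs_norm at or below the species
      q-quantile (default q = 0.10);
    - "psi_cut": observations with psi more negative than ``psi_cut``
      (used by the iterated rule seeded from the fixed-threshold estimate).

    When VPD is available, subset conductances are first standardized to the
    VPD setting with a species-level multiplicative factor
    ``(vpd_setting / vpd) ** b``, where ``b`` is the log-log VPD coefficient
    estimated from the species' full table (the subset alone spans too
    little VPD to identify it); the straight line in psi is then refitted on
    the standardized subset and its mean and pointwise normal-theory 95%
    interval are evaluated on the grid. Standardizing, rather than carrying
    a VPD regressor into the refit, keeps VPD-driven scatter out of the
    projection band. ``fit`` may supply nothing here — the refit is
    self-contained — but is accepted to mirror the two-stage workflow
    (full-data mixed model, then regime refit).
    """
    if regime_rule == "gs_quantile":
        cut = table["gs_norm"].quantile(q)
        sub = table[table["gs_norm"] <= cut]
        rule = f"gs_quantile(q={q})"
    elif regime_rule == "psi_cut":
        if psi_cut is None:
            raise ValueError("psi_cut rule requires psi_cut")
        sub = table[table["psi"] <= psi_cut]
        rule = f"psi_cut({psi_cut:.3f})"
    else:
        raise ValueError(f"unknown regime_rule {regime_rule!r}")
    if len(sub) < 8:
        raise ValueError(
            f"post-closure subset has {len(sub)} < 8 observations; increase q "
            "or pool species"
        )
    if grid is None:
        grid = species_grid(table["psi"].to_numpy(), grid_step)

    y = sub["gs_norm"].to_numpy(dtype=float)
    use_vpd = (
        vpd_adjust != "none"
        and table["vpd_kpa"].notna().all()
        and table["vpd_kpa"].nunique() > 1
    )
    X = pd.DataFrame({"Intercept": 1.0, "psi": sub["psi"]})
    Xg = pd.DataFrame({"Intercept": 1.0, "psi": grid})
    if use_vpd and vpd_adjust == "standardize":
        b_vpd = _species_vpd_coefficient(table)
        y = y * (vpd_setting / sub["vpd_kpa"].to_numpy()) ** b_vpd
    elif use_vpd and vpd_adjust == "regressor":
        X["log_vpd"] = np.log(sub["vpd_kpa"].to_numpy())
        Xg["log_vpd"] = np.log(vpd_setting)
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(Xg)
    ci = pred.conf_int(obs=(interval == "prediction"), alpha=0.05)
    return LinearProjection(
        grid=grid,
        mean=np.asarray(pred.predicted_mean, dtype=float),
        lower95=ci[:, 0],
        upper95=ci[:, 1],
        vpd_setting=vpd_setting,
        n_subset=len(sub),
        regime_rule=rule,
        slope=float(res.params["psi"]),
    )


def _species_vpd_coefficient(table: pd.DataFrame) -> float:
    """Log-log VPD coefficient of conductance for one species' full table."""
    tbl = table.dropna(subset=["psi", "gs_norm", "vpd_kpa"])
    pos = tbl["gs_norm"] > 0
    tbl = tbl[pos]
    X = pd.DataFrame(
        {"Intercept": 1.0, "psi": tbl["psi"], "log_vpd": np.log(tbl["vpd_kpa"])}
    )
    res = sm.OLS(np.log(tbl["gs_norm"].to_numpy()), X).fit()
    return float(res.params["log_vpd"])


def fit_gs_smooth(
    table: pd.DataFrame,
    species: str | None = None,
    axis: Axis = "predawn",
    df_basis: int = 25,
    backfit_passes: int = 2,
    grid: np.ndarray | None = None,
    grid_step: float = DEFAULT_GRID_STEP,
    min_obs: int = 20,
    min_span: float = 0.8,
    undersmooth: float = 1.0,
) -> SmoothFit:
    """Penalized smooth of normalized conductance against psi for one species.

    Tree-level intercepts are absorbed by iterated backfitting between the
    smooth and centred tree-mean residuals (default two passes), a
    desk-scale stand-in for a joint smooth-plus-random-intercept fit. The
    smoothing parameter is chosen by GCV and then divided by ``undersmooth``:
    GCV minimizes global prediction error, which over-smooths localized
    features; when the smooth is used to locate the closure kink, deliberate
    undersmoothing trades a little variance for much less rounding bias at
    the kink (the standard remedy for feature localization).
    """
    if species is not None and "species" in table.columns:
        tbl = table[table["species"] == species]
    else:
        tbl = table
        species = species or (tbl["species"].iloc[0] if "species" in tbl.columns else "?")
    tbl = tbl.dropna(subset=["psi", "gs_norm"])
    span = float(tbl["psi"].max() - tbl["psi"].min()) if len(tbl) else 0.0
    if len(tbl) < min_obs or span < min_span:
        raise ValueError(
            f"species {species}: need >= {min_obs} observations spanning >= "
            f"{min_span} MPa on the {axis} axis; have n={len(tbl)}, span={span:.2f} MPa"
        )
    x = tbl["psi"].to_numpy(dtype=float)
    y = tbl["gs_norm"].to_numpy(dtype=float)
    trees = tbl["tree_id"].to_numpy()

    adj = np.zeros_like(y)
    spline = PenalizedSpline(df=df_basis)
    tree_int = pd.Series(0.0, index=np.unique(trees))
    for _ in range(max(backfit_passes, 1)):
        spline = PenalizedSpline(df=df_basis).fit(x, y - adj)
        resid = (y - adj) - spline.predict(x)
        means = pd.Series(resid + adj).groupby(trees).mean()
        tree_int = means - means.mean()
        adj = tree_int.reindex(trees).to_numpy()
    if undersmooth != 1.0:
        spline = PenalizedSpline(df=df_basis, alpha=spline.alpha_ / undersmooth).fit(
            x, y - adj
        )

    if grid is None:
        grid = species_grid(x, grid_step)
    mean, lo, hi = spline.predict_band(grid)
    return SmoothFit(
        grid=grid, mean=mean, lower95=lo, upper95=hi, edf=float(spline.edf_),
        species=str(species), axis=axis, n=len(tbl), psi_span=span,
        tree_intercepts=tree_int,
        diagnostics={"alpha": spline.alpha_, "sigma2": spline.sigma2_},
    )


def estimate_pst_intersection(
    smooth: SmoothFit,
    projection: LinearProjection,
    k: int = 15,
    atol: float = 1e-3,
    entry_atol: float = 5e-3,
    entry_level: float = 0.1,
) -> PstEstimate:
    """P_st as the entry of the smooth into the projection's 95% band.

    Scanning from least- to most-negative psi, detection requires the
    smooth mean to fall to or below the band's upper limit (tolerance
    ``atol`` in normalized-conductance units) and remain there for at least
    ``k`` consecutive grid points (0.15 MPa at the default 0.01-MPa grid;
    shorter runs are noise dips of the smooth, whose wiggle scale is the
    spline knot spacing). Because the projection is an extrapolation of the
    dry-regime subset, its band can be arbitrarily wide at the wet end of
    the grid and trivially contain the smooth there; an entry therefore only
    counts after the smooth has first been above the band (when the smooth
    never leaves the band the first grid point is returned — the degenerate
    smooth-equals-projection case).

    The reported closure point is the first grid point within the entered
    run at which the smooth reaches ``mean + entry_level * (upper95 - mean)``
    of the projection. The first touch of the upper limit itself precedes
    the closure point systematically (at entry the smooth is still half a
    band width above the line), while the literal line crossing is unstable
    (beyond closure the smooth and line are nearly parallel, so small level
    errors displace it arbitrarily far dry); a crossing level just above the
    band centre removes the entry bias without inheriting that instability.
    The raw band entry is kept in the diagnostics.

    A smooth that never enters yields a "no closure detected" result
    carrying the minimum gap to the band.
    """
    if smooth.grid.shape != projection.grid.shape or not np.allclose(
        smooth.grid, projection.grid
    ):
        raise ValueError("smooth and projection must share the psi grid")
    grid = smooth.grid
    above = smooth.mean > projection.upper95 + entry_atol
    inside = ~above
    step = float(abs(np.median(np.diff(grid))))
    if above.any():
        start = int(np.flatnonzero(above)[0])
        inside = inside.copy()
        inside[:start] = False
    idx = _first_run(inside, k)
    if idx is None:
        gap = float(np.min(smooth.mean - projection.upper95))
        return PstEstimate(
            species=smooth.species, axis=smooth.axis, pst=None,
            method="ci_intersection", detected=False, grid_step=step,
            min_gap=gap,
        )
    level = projection.mean + entry_level * (projection.upper95 - projection.mean)
    rest = np.flatnonzero(smooth.mean[idx:] <= level[idx:] + atol)
    j = idx + int(rest[0]) if rest.size else idx
    width = float(projection.upper95[j] - projection.lower95[j])
    return PstEstimate(
        species=smooth.species, axis=smooth.axis, pst=float(grid[j]),
        method="ci_intersection", grid_step=step, band_width_at_pst=width,
        diagnostics={"k": k, "entry_level": entry_level,
                     "n_subset": projection.n_subset,
                     "regime_rule": projection.regime_rule,
                     "band_entry_psi": float(grid[idx])},
    )


def _first_run(mask: np.ndarray, k: int) -> int | None:
    """Index of the first True that starts a run of >= k Trues (a terminal
    run shorter than k counts if it reaches the end of the grid)."""
    n = mask.size
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if (j - i) >= k or j == n:
                return i
            i = j
        else:
            i += 1
    return None


def estimate_pst_fixed_threshold(
    smooth: SmoothFit,
    species_gs_max: float,
    gs_threshold: float = DEFAULT_GS_THRESHOLD,
) -> PstEstimate:
    """P_st as the first grid psi where the smooth falls below a fixed
    absolute conductance threshold (default 0.05 mol m-2 s-1), mapped onto
    the normalized scale by the species' reference conductance."""
    if species_gs_max <= 0:
        raise ValueError("species_gs_max must be > 0")
    thr = gs_threshold / species_gs_max
    below = smooth.mean < thr
    idx = np.flatnonzero(below)
    step = float(abs(np.median(np.diff(smooth.grid))))
    if idx.size == 0:
        return PstEstimate(
            species=smooth.species, axis=smooth.axis, pst=None,
            method="fixed_gs_threshold", detected=False, grid_step=step,
            min_gap=float(np.min(smooth.mean - thr)),
            diagnostics={"gs_threshold": gs_threshold},
        )
    return PstEstimate(
        species=smooth.species, axis=smooth.axis, pst=float(smooth.grid[idx[0]]),
        method="fixed_gs_threshold", grid_step=step,
        diagnostics={"gs_threshold": gs_threshold, "threshold_norm": thr},
    )


def _psi_cut_subset_floor(tbl: pd.DataFrame, cut: float) -> float:
    """Clamp a psi cut so the post-closure subset is a dry tail of sane size.

    The cut is confined between the 10% and 55% psi quantiles (fraction of
    observations drier than the cut between 10% and 55%): a seed estimate
    that is badly off would otherwise select either almost no observations
    (an uninformative, arbitrarily wide band) or almost all of them (a
    projection contaminated by the exponential regime).
    """
    psi = np.sort(tbl["psi"].to_numpy())
    q_dry = float(np.quantile(psi, 0.10))
    q_wet = float(np.quantile(psi, 0.55))
    cut = min(max(cut, q_dry), q_wet)
    if (psi <= cut).sum() >= 8:
        return cut
    return float(psi[min(7, psi.size - 1)])


def _standardize_to_vpd(table: pd.DataFrame, vpd_setting: float) -> pd.DataFrame:
    """Rescale conductance to a common VPD with the species' log-log VPD
    coefficient; pass-through when VPD is absent."""
    if not (table["vpd_kpa"].notna().all() and table["vpd_kpa"].nunique() > 1):
        return table
    b_vpd = _species_vpd_coefficient(table)
    out = table.copy()
    out["gs_norm"] = table["gs_norm"] * (
        vpd_setting / table["vpd_kpa"].to_numpy()
    ) ** b_vpd
    return out


def _pooled_projections(
    tables_std: dict[str, pd.DataFrame],
    cuts: dict[str, float],
    grids: dict[str, np.ndarray],
    vpd_setting: float,
) -> dict[str, LinearProjection]:
    """Post-closure projections with a common (pooled) psi slope.

    The shallow post-closure slope is a cross-species property of the
    campaign design, so it is estimated from all species' post-closure
    subsets jointly (species-specific intercepts, one psi slope): pooling
    multiplies the data behind the slope roughly by the number of species
    and correspondingly narrows the projection band relative to independent
    per-species refits.
    """
    frames = []
    for spid, tbl in tables_std.items():
        sub = tbl[tbl["psi"] <= cuts[spid]].copy()
        sub["_sp"] = spid
        frames.append(sub)
    allsub = pd.concat(frames, ignore_index=True)
    if len(allsub) < 8:
        raise ValueError(
            f"pooled post-closure subset has {len(allsub)} < 8 observations"
        )
    sps = sorted(tables_std)
    y = allsub["gs_norm"].to_numpy()
    X = pd.DataFrame({"psi": allsub["psi"].to_numpy()})
    Xsep = pd.DataFrame(index=allsub.index)
    for spid in sps:
        ind = (allsub["_sp"] == spid).astype(float).to_numpy()
        X[f"i[{spid}]"] = ind
        Xsep[f"i[{spid}]"] = ind
        Xsep[f"psi[{spid}]"] = ind * allsub["psi"].to_numpy()
    pooled = sm.OLS(y, X).fit()
    separate = sm.OLS(y, Xsep).fit()
    # The common slope is a variance saver, not an article of faith: when the
    # species-specific slopes fit decisively better (noise small relative to
    # between-species slope differences), use them.
    use_pooled = len(sps) < 2 or pooled.bic <= separate.bic + 2
    res = pooled if use_pooled else separate
    rule = "pooled" if use_pooled else "per_species"
    out = {}
    for spid in sps:
        grid = grids[spid]
        if use_pooled:
            Xg = pd.DataFrame({"psi": grid})
            for s2 in sps:
                Xg[f"i[{s2}]"] = 1.0 if s2 == spid else 0.0
            slope = float(res.params["psi"])
        else:
            Xg = pd.DataFrame(index=range(len(grid)))
            for s2 in sps:
                Xg[f"i[{s2}]"] = 1.0 if s2 == spid else 0.0
                Xg[f"psi[{s2}]"] = grid if s2 == spid else 0.0
            slope = float(res.params[f"psi[{spid}]"])
        pred = res.get_prediction(Xg)
        ci = pred.conf_int(obs=True, alpha=0.05)
        out[spid] = LinearProjection(
            grid=grid,
            mean=np.asarray(pred.predicted_mean, dtype=float),
            lower95=ci[:, 0],
            upper95=ci[:, 1],
            vpd_setting=vpd_setting,
            n_subset=int((allsub["_sp"] == spid).sum()),
            regime_rule=f"psi_cut_{rule}({cuts[spid]:.3f})",
            slope=slope,
        )
    return out


def estimate_species_pst(
    records: pd.DataFrame,
    species_gs_max: pd.Series,
    axis: Axis = "predawn",
    method: str = "ci_intersection",
    vpd_setting: float = DEFAULT_VPD_SETTING,
    gs_threshold: float = DEFAULT_GS_THRESHOLD,
    regime_rule: str = "fixed_iterated",
    q: float = 0.10,
    grid_step: float = DEFAULT_GRID_STEP,
    df_basis: int = 25,
    k: int = 15,
    undersmooth: float = 30.0,
    entry_level: float = 0.1,
    cut_margin: float = 0.1,
) -> list[PstEstimate]:
    """Run the per-species P_st estimation chain on a normalized dataset.

    For the intersection method the post-closure regime is selected by
    ``regime_rule``:

    - "fixed_iterated" (default): observations with psi more negative than
      the fixed-conductance-threshold estimate minus ``cut_margin`` MPa,
      updated once from the resulting intersection estimate. Selecting on
      the regressor keeps the projection unbiased, and the projections use
      the pooled cross-species slope (see :func:`_pooled_projections`).
    - "gs_quantile": observations with gs_norm below the species q-quantile,
      refitted per species. Selecting on the noisy outcome shifts the
      projection low (the chosen points are disproportionately negative
      noise draws), which can leave the smooth permanently above the band;
      retained as a config option.

    The smooth used for the intersection is VPD-standardized to
    ``vpd_setting`` and deliberately undersmoothed (see
    :func:`fit_gs_smooth`); the fixed-threshold method uses the raw
    GCV-smoothed fit at ambient VPD.
    """
    table = paired_axis_table(records, axis)
    if method not in ("ci_intersection", "fixed_gs_threshold"):
        raise ValueError(f"unknown method {method!r}")

    smooths_raw: dict[str, SmoothFit] = {}
    smooths_std: dict[str, SmoothFit] = {}
    tables_std: dict[str, pd.DataFrame] = {}
    grids: dict[str, np.ndarray] = {}
    estimates: list[PstEstimate] = []
    for sp, tbl in table.groupby("species"):
        sp = str(sp)
        try:
            grid = species_grid(tbl["psi"].to_numpy(), grid_step)
            smooths_raw[sp] = fit_gs_smooth(
                tbl, species=sp, axis=axis, grid=grid,
                df_basis=df_basis, grid_step=grid_step,
            )
            if method == "ci_intersection":
                tbl_std = _standardize_to_vpd(tbl, vpd_setting)
                smooths_std[sp] = fit_gs_smooth(
                    tbl_std, species=sp, axis=axis, grid=grid,
                    df_basis=df_basis, grid_step=grid_step,
                    undersmooth=undersmooth,
                )
                tables_std[sp] = tbl_std
                grids[sp] = grid
        except ValueError as err:
            warnings.warn(f"species {sp}: {err}")
            continue

    if method == "fixed_gs_threshold":
        for sp, smo in smooths_raw.items():
            estimates.append(
                estimate_pst_fixed_threshold(smo, float(species_gs_max[sp]), gs_threshold)
            )
        return estimates

    if regime_rule == "gs_quantile":
        for sp, smo in smooths_std.items():
            try:
                proj = project_linear_regime(
                    None, tables_std[sp], vpd_setting=vpd_setting,
                    regime_rule="gs_quantile", q=q, grid=grids[sp],
                    vpd_adjust="none",
                )
                estimates.append(
                    estimate_pst_intersection(smo, proj, k=k, entry_level=entry_level)
                )
            except ValueError as err:
                warnings.warn(f"species {sp}: {err}")
        return estimates
    if regime_rule != "fixed_iterated":
        raise ValueError(f"unknown regime_rule {regime_rule!r}")

    if not smooths_std:
        warnings.warn("no species met the smoothing preconditions")
        return estimates

    cuts: dict[str, float] = {}
    for sp in smooths_std:
        # seed the regime cut from the fixed-threshold crossing; when the
        # absolute threshold lies below the smooth's dry-end plateau (no
        # crossing), relax it in 25% steps — the relaxed crossing is still a
        # far better cut locator than any fixed psi quantile
        cut = None
        thr = gs_threshold
        for _ in range(4):
            seed = estimate_pst_fixed_threshold(
                smooths_raw[sp], float(species_gs_max[sp]), thr
            )
            if seed.detected and seed.pst is not None:
                cut = seed.pst - cut_margin
                break
            thr *= 1.25
        if cut is None:  # last resort: driest 15% of psi observations
            cut = float(tables_std[sp]["psi"].quantile(0.15))
        cuts[sp] = _psi_cut_subset_floor(tables_std[sp], cut)

    ests: dict[str, PstEstimate] = {}
    for _pass in range(2):
        projections = _pooled_projections(tables_std, cuts, grids, vpd_setting)
        changed = False
        for sp, smo in smooths_std.items():
            est = estimate_pst_intersection(
                smo, projections[sp], k=k, entry_level=entry_level
            )
            ests[sp] = est
            if est.detected and est.pst is not None:
                new_cut = _psi_cut_subset_floor(tables_std[sp], est.pst - cut_margin)
                if abs(new_cut - cuts[sp]) > 1e-12:
                    cuts[sp] = new_cut
                    changed = True
        if not changed:
            break
    return [ests[sp] for sp in sorted(ests)]


def summarize_pst(estimates: list[PstEstimate], axis: Axis) -> PstSummary:
    """Across-species mean and sample s.d. of detected closure points."""
    det = [e for e in estimates if e.axis == axis and e.detected and e.pst is not None]
    missing = [e.species for e in estimates if e.axis == axis and not e.detected]
    if len(det) < 2:
        raise ValueError(
            f"need >= 2 species with detected closure on the {axis} axis, have {len(det)}"
        )
    vals = np.array([e.pst for e in det], dtype=float)
    return PstSummary(
        axis=axis, mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
        n_species=len(det), undetected=missing,
    )
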