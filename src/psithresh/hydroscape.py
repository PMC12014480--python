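"""Hydroscape breakpoint fitting and across-site stress-response models.

The hydroscape is the empirical relationship between pre-dawn and midday
leaf water potential; its inflection (a shallower decline of midday psi
below a pre-dawn breakpoint) marks a shift in hydraulic regulation. The
breakpoint is located by continuous two-segment least squares with a grid
search, compared against a single line by a BIC-style criterion. The same
module fits the across-site log-log mixed models of daily maximum sap flux
density (or stomatal conductance) against pre-dawn psi.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "fit_hydroscape",
    "fit_flux_response",
    "fit_gs_predawn_response",
    "HydroscapeFit",
    "FluxResponseFit",
]


@dataclass
class HydroscapeFit:
    """Continuous two-segment fit of midday on pre-dawn psi."""

    breakpoint: float | None  # MPa; None when no breakpoint is supported
    slope_wet: float
    slope_dry: float
    intercept: float  # of the wet segment
    sse: float
    sse_linear: float
    delta_bic: float  # BIC(linear) - BIC(segmented); > 2 supports the break
    n: int
    has_breakpoint: bool
    diagnostics: dict = field(default_factory=dict)

    def predict(self, psi_pd: np.ndarray) -> np.ndarray:
        psi_pd = np.asarray(psi_pd, dtype=float)
        if not self.has_breakpoint:
            return self.intercept + self.slope_wet * psi_pd
        wet = self.intercept + self.slope_wet * psi_pd
        at_break = self.intercept + self.slope_wet * self.breakpoint
        dry = at_break + self.slope_dry * (psi_pd - self.breakpoint)
        return np.where(psi_pd > self.breakpoint, wet, dry)


def _segmented_sse(x: np.ndarray, y: np.ndarray, brk: float) -> tuple[float, np.ndarray]:
    """Least-squares fit of y = a + b*x + c*(x - brk)*1[x < brk]."""
    z = np.where(x < brk, x - brk, 0.0)
    X = np.column_stack([np.ones_like(x), x, z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def fit_hydroscape(
    pairs: pd.DataFrame,
    x_col: str = "psi_pd",
    y_col: str = "psi_md",
    grid_step: float = 0.01,
    interior_exclude: float = 0.10,
    delta_criterion: float = 2.0,
    orientation_check: bool = True,
    min_pairs: int = 15,
    min_span: float = 1.0,
) -> HydroscapeFit:
    """Continuous two-segment least-squares fit with grid-searched breakpoint.

    Candidate breakpoints run at ``grid_step`` resolution over the pre-dawn
    range excluding the outer ``interior_exclude`` fraction on each side
    (boundary breakpoints are unidentifiable). The two-segment model is
    retained only when its BIC improves on the single straight line by more
    than ``delta_criterion``; otherwise a "no breakpoint" fit is returned
    with the single-line coefficients.
    """
    df = pairs.dropna(subset=[x_col, y_col])
    x = df[x_col].to_numpy(dtype=float)
    y = df[y_col].to_numpy(dtype=float)
    n = x.size
    if n < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs, have {n}")
    span = float(x.max() - x.min())
    if span < min_span:
        raise ValueError(f"pre-dawn span {span:.2f} MPa < required {min_span} MPa")
    if orientation_check and y_col == "psi_md":
        frac = float(np.mean(y <= x))
        if frac < 0.95:
            raise ValueError(
                f"only {frac:.0%} of pairs have midday <= pre-dawn psi; "
                "columns are probably swapped"
            )

    X1 = np.column_stack([np.ones_like(x), x])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid1 = y - X1 @ beta1
    sse1 = float(resid1 @ resid1)

    lo = x.min() + interior_exclude * span
    hi = x.max() - interior_exclude * span
    candidates = np.arange(np.ceil(lo / grid_step), np.floor(hi / grid_step) + 1) * grid_step
    best_sse, best_brk, best_beta = np.inf, None, None
    for brk in candidates:
        sse, beta = _segmented_sse(x, y, brk)
        if sse < best_sse:
            best_sse, best_brk, best_beta = sse, float(brk), beta

    # BIC with Gaussian errors; the breakpoint itself counts as a parameter
    bic1 = n * np.log(max(sse1, 1e-300) / n) + 2 * np.log(n)
    bic2 = n * np.log(max(best_sse, 1e-300) / n) + 4 * np.log(n)
    delta = float(bic1 - bic2)
    if best_brk is None or delta <= delta_criterion:
        return HydroscapeFit(
            breakpoint=None, slope_wet=float(beta1[1]), slope_dry=float(beta1[1]),
            intercept=float(beta1[0]), sse=sse1, sse_linear=sse1,
            delta_bic=delta, n=n, has_breakpoint=False,
        )
    a, b, c = best_beta
    return HydroscapeFit(
        breakpoint=best_brk, slope_wet=float(b), slope_dry=float(b + c),
        intercept=float(a), sse=best_sse, sse_linear=sse1, delta_bic=delta,
        n=n, has_breakpoint=True,
        diagnostics={"n_candidates": int(candidates.size), "grid_step": grid_step},
    )


@dataclass
class FluxResponseFit:
    """Log-log mixed model of a positive stress response on pre-dawn psi.

    The response (daily maximum sap flux as % of tree maximum, or stomatal
    conductance) and the sign-flipped water potential are both
    log-transformed: log(response) = intercept + slope * log(-psi_pd).
    A negative slope is the stress-decline signature.
    """

    intercept: float
    slope: float
    slope_se: float
    r2: float
    species_re_sd: float
    site_re_sd: float
    n: int
    response: str
    random_effects_dropped: bool = False

    def predict(self, psi_pd: np.ndarray) -> np.ndarray:
        psi_pd = np.asarray(psi_pd, dtype=float)
        return np.exp(self.intercept + self.slope * np.log(-psi_pd))


def fit_flux_response(
    pairs: pd.DataFrame,
    response_col: str = "flux_pct_of_max",
    psi_col: str = "psi_pd",
    species_col: str = "species",
    site_col: str = "site",
) -> FluxResponseFit:
    """Across-site log-log mixed model of a stress response on pre-dawn psi.

    Water potential is negative, so the log is taken of -psi (MPa); the
    transform is recorded in the fit. Species enters as a random intercept
    (grouping factor) with site as a variance component nested within it;
    with a single species/site the random effects are dropped with a
    warning and an ordinary regression is returned.
    """
    df = pairs.dropna(subset=[response_col, psi_col]).copy()
    if (df[response_col] <= 0).any():
        raise ValueError("responses must be > 0 for the log transform")
    if (df[psi_col] >= 0).any():
        raise ValueError("psi_pd must be < 0 MPa")
    y = np.log(df[response_col].to_numpy(dtype=float))
    lx = np.log(-df[psi_col].to_numpy(dtype=float))
    df["_logx"] = lx

    n_species = df[species_col].nunique() if species_col in df else 1
    n_sites = df[site_col].nunique() if site_col in df else 1
    X = pd.DataFrame({"Intercept": 1.0, "log_neg_psi": lx}, index=df.index)

    if n_species < 2 and n_sites < 2:
        warnings.warn("single species and site: random effects dropped")
        res = sm.OLS(y, X).fit()
        return FluxResponseFit(
            intercept=float(res.params["Intercept"]),
            slope=float(res.params["log_neg_psi"]),
            slope_se=float(res.bse["log_neg_psi"]),
            r2=float(res.rsquared), species_re_sd=0.0, site_re_sd=0.0,
            n=len(df), response=response_col, random_effects_dropped=True,
        )

    group_col = species_col if n_species >= 2 else site_col
    vc = {}
    if group_col == species_col and n_sites >= 2:
        vc = {"site": f"0 + C({site_col})"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM.from_formula(
            "resp ~ _logx", groups=group_col, re_formula="1",
            vc_formula=vc or None, data=df.assign(resp=y),
        )
        res = model.fit(reml=True)
    var_group = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    var_site = float(np.mean(list(res.vcomp))) if len(res.vcomp) else 0.0
    var_fixed = float(np.var(res.params["Intercept"] + res.params["_logx"] * lx))
    r2 = var_fixed / (var_fixed + var_group + var_site + float(res.scale))
    return FluxResponseFit(
        intercept=float(res.params["Intercept"]),
        slope=float(res.params["_logx"]),
        slope_se=float(res.bse["_logx"]),
        r2=r2,
        species_re_sd=float(np.sqrt(max(var_group, 0.0))),
        site_re_sd=float(np.sqrt(max(var_site, 0.0))),
        n=len(df),
        response=response_col,
    )


def fit_gs_predawn_response(
    pairs: pd.DataFrame,
    gs_col: str = "gs_mol_m2_s",
    psi_col: str = "psi_pd",
    species_col: str = "species",
    site_col: str = "site",
    reference_psi: float = -1.2,
) -> tuple[FluxResponseFit, HydroscapeFit | None]:
    """Stomatal-conductance analogue of :func:`fit_flux_response`.

    Returns the log-log mixed fit plus a two-segment shift detection on the
    (psi_pd, gs) pairs around ``reference_psi`` (the fit is attempted on raw
    conductance; None when the segmented preconditions are not met). The
    reference line at -1.2 MPa is the conventional pre-dawn threshold and
    is included in exported curve tables by the pipeline.
    """
    fit = fit_flux_response(
        pairs, response_col=gs_col, psi_col=psi_col,
        species_col=species_col, site_col=site_col,
    )
    shift = None
    try:
        shift = fit_hydroscape(
            pairs.rename(columns={psi_col: "psi_pd", gs_col: "response"}),
            x_col="psi_pd", y_col="response", orientation_check=False,
        )
    except ValueError as err:
        warnings.warn(f"segmented shift detection skipped: {err}")
    return fit, shift
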