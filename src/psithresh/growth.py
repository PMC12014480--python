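"""Stem-growth probability and rate as functions of pre-dawn water potential.

Weekly dendrometer-derived growth intervals are matched to the nearest
pre-dawn water-potential campaign, a binomial mixed model estimates the
probability of any (irreversible) growth as a logistic in pre-dawn psi, and
the fitted population-level logistic is inverted in closed form for
cessation thresholds such as the psi at 5% growth probability.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import logit as _logit

from .preprocess import GrowthRateSeries
from .smoothing import PenalizedSpline

__all__ = [
    "build_growth_table",
    "fit_growth_probability",
    "psi_at_probability",
    "rate_response_curve",
    "GrowthProbabilityFit",
]


class SeparationError(ValueError):
    """The binary outcome is perfectly separated (or single-class)."""


def build_growth_table(
    rates: GrowthRateSeries,
    campaigns: pd.DataFrame,
    tree_species: pd.Series | None = None,
    window_days: float = 7.0,
) -> pd.DataFrame:
    """Pair each growth interval with the nearest pre-dawn campaign psi.

    ``campaigns`` carries one pre-dawn psi per tree and campaign date
    (columns tree_id, date, psi_leaf_mpa). An interval is paired with the
    campaign whose date lies closest to the interval midpoint, provided the
    gap is at most ``window_days``; unmatched intervals are dropped and
    counted in the result's ``attrs["n_unmatched"]``.
    """
    iv = rates.intervals.copy()
    if iv.empty:
        raise ValueError("no growth intervals to match")
    camp = campaigns.copy()
    camp["date"] = pd.to_datetime(camp["date"])
    rows, unmatched = [], 0
    for tree, grp in iv.groupby("tree_id"):
        cg = camp[camp["tree_id"] == tree]
        if cg.empty:
            unmatched += len(grp)
            continue
        cdates = cg["date"].to_numpy()
        cpsi = cg["psi_leaf_mpa"].to_numpy(dtype=float)
        for _, r in grp.iterrows():
            mid = pd.Timestamp(r["midpoint"])
            gaps = np.abs((cdates - np.datetime64(mid)) / np.timedelta64(1, "D"))
            # on ties (midpoint equidistant from two campaigns) prefer the later
            j = int(np.flatnonzero(gaps <= gaps.min() + 1e-9)[-1])
            if gaps[j] > window_days:
                unmatched += 1
                continue
            rows.append(
                {
                    "tree_id": tree,
                    "midpoint": mid,
                    "psi_pd": cpsi[j],
                    "gap_days": float(gaps[j]),
                    "rate_cm_day": r["rate_cm_day"],
                    "is_growing": not bool(r["is_zero"]),
                }
            )
    if not rows:
        raise ValueError(
            f"no interval could be matched to a campaign within {window_days} days"
        )
    out = pd.DataFrame(rows)
    if tree_species is not None:
        out["species"] = out["tree_id"].map(tree_species)
    out.attrs["n_unmatched"] = unmatched
    return out


@dataclass
class GrowthProbabilityFit:
    """Population-level logistic of growth occurrence on pre-dawn psi."""

    intercept: float  # log-odds at psi = 0
    slope: float  # log-odds per MPa (positive: wetter -> likelier growth)
    species_re_sd: float
    tree_re_sd: float
    n: int
    method: str  # "vb_glmm" or "logit"
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


def fit_growth_probability(
    table: pd.DataFrame, penalized_fallback: bool = False
) -> GrowthProbabilityFit:
    """Binomial mixed model of the growth indicator on pre-dawn psi.

    Random intercepts for species and tree nested in species are fitted by
    variational Bayes (the closest available machinery for a binomial GLMM
    with this structure); when species labels are absent or the variational
    fit fails, the model falls back to a plain logistic regression with a
    warning. Requires both outcome classes; perfect separation raises
    :class:`SeparationError` (set ``penalized_fallback`` to refit with a
    small L2 penalty instead).
    """
    tbl = table.dropna(subset=["psi_pd", "is_growing"]).copy()
    y = tbl["is_growing"].astype(float)
    if y.nunique() < 2:
        raise SeparationError(
            "growth outcome is single-class; probability model is undefined"
        )
    has_groups = "species" in tbl.columns and tbl["species"].notna().all()
    if has_groups and tbl["species"].nunique() > 1:
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        tbl["_y"] = y
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = BinomialBayesMixedGLM.from_formula(
                    "_y ~ psi_pd",
                    {"species": "0 + C(species)", "tree": "0 + C(tree_id)"},
                    tbl,
                )
                res = model.fit_vb()
            fe = dict(zip(res.model.exog_names, res.fe_mean))
            vc_sd = dict(zip(res.model.vcp_names, np.exp(res.vcp_mean)))
            if fe["psi_pd"] <= 0:
                # growth probability must rise toward wetter psi; a
                # wrong-signed variational fit signals a degenerate dataset
                raise ValueError("non-positive psi slope from variational fit")
            return GrowthProbabilityFit(
                intercept=float(fe["Intercept"]),
                slope=float(fe["psi_pd"]),
                species_re_sd=float(vc_sd.get("species", np.nan)),
                tree_re_sd=float(vc_sd.get("tree", np.nan)),
                n=len(tbl),
                method="vb_glmm",
            )
        except Exception as err:  # noqa: BLE001 - VB failure falls back
            warnings.warn(f"variational GLMM failed ({err}); falling back to Logit")

    X = sm.add_constant(tbl[["psi_pd"]])
    try:
        if penalized_fallback:
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, disp=False)
        else:
            res = sm.Logit(y, X).fit(disp=False)
    except Exception as err:  # PerfectSeparation and kin
        raise SeparationError(
            f"logistic fit failed ({err}); consider penalized_fallback=True"
        ) from err
    if not penalized_fallback and np.abs(res.params).max() > 1e3:
        raise SeparationError(
            "coefficients diverged (perfect separation); consider "
            "penalized_fallback=True"
        )
    return GrowthProbabilityFit(
        intercept=float(res.params["const"]),
        slope=float(res.params["psi_pd"]),
        species_re_sd=0.0,
        tree_re_sd=0.0,
        n=len(tbl),
        method="logit",
    )


def psi_at_probability(fit: GrowthProbabilityFit, p: float) -> float:
    """Pre-dawn psi at which growth probability equals ``p``.

    Closed-form inversion of the population logistic:
    psi = (logit(p) - intercept) / slope. Monotone and continuous in p.
    """
    if not 0 < p < 1:
        raise ValueError("p must be strictly between 0 and 1")
    if abs(fit.slope) < 1e-10:
        raise ValueError("slope is ~0; threshold psi is undefined")
    return float((_logit(p) - fit.intercept) / fit.slope)


def rate_response_curve(
    table: pd.DataFrame, min_intervals: int = 30, min_nonzero: int = 10
) -> pd.DataFrame:
    """Nonparametric smooth of non-zero growth rates against pre-dawn psi.

    Returns a grid table (psi_pd, rate_mean, rate_lower95, rate_upper95).
    Omitted (with a warning, returning an empty table) when too few non-zero
    rates exist to support a curve.
    """
    if len(table) < min_intervals:
        raise ValueError(f"need >= {min_intervals} intervals, have {len(table)}")
    nz = table[table["rate_cm_day"] > 0]
    if len(nz) < min_nonzero:
        warnings.warn(
            f"only {len(nz)} non-zero rates (< {min_nonzero}); rate curve omitted"
        )
        return pd.DataFrame(columns=["psi_pd", "rate_mean", "rate_lower95", "rate_upper95"])
    x = nz["psi_pd"].to_numpy(dtype=float)
    y = nz["rate_cm_day"].to_numpy(dtype=float)
    spline = PenalizedSpline(df=min(12, max(4, x.size // 5))).fit(x, y)
    grid = np.linspace(x.max(), x.min(), 101)
    mean, lo, hi = spline.predict_band(grid)
    return pd.DataFrame(
        {"psi_pd": grid, "rate_mean": mean, "rate_lower95": lo, "rate_upper95": hi}
    )
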