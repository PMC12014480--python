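"""End-to-end orchestration: simulate -> preprocess -> estimate -> report.

A run is driven by a fully serializable :class:`RunConfig`; every output
directory receives the exact config and seed that produced it (manifest),
so re-running from the manifest reproduces all CSVs byte-identically.
:func:`recovery_experiment` wraps the pipeline in replicate synthetic
worlds and tabulates bias / RMSE of every threshold estimate against the
retained generative truth.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .closure import estimate_species_pst, fit_gs_model, summarize_pst
from .growth import build_growth_table, fit_growth_probability, psi_at_probability
from .hydroscape import fit_hydroscape
from .io import write_campaign_table, write_series
from .preprocess import (
    growth_rates,
    normalize_gs,
    season_filter,
    zero_growth_transform,
)
from .simulate import (
    make_default_truth,
    simulate_campaign_dataset,
    simulate_dendrometer_series,
)
from .types import SimConfig, TrueParams


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream of a single global seed.

    Stages draw from independent streams keyed by a fixed label, so the
    randomness of one stage never depends on whether another ran first.
    """
    label = int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "little")
    ss = np.random.SeedSequence([seed, label])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    outdir: str = "run_out"
    seed: int = 0
    simulate: bool = True
    # simulation block (ignored when simulate=False)
    n_species: int = 9
    trees_per_species: int = 10
    n_campaigns: int = 35
    pst_mean: float = -1.2
    pst_sd: float = 0.2
    # input paths (used when simulate=False)
    campaign_csv: str | None = None
    dendro_csv: str | None = None
    # method parameters
    axes: tuple[str, ...] = ("predawn", "midday")
    vpd_setting: float = 2.4
    gs_threshold: float = 0.05
    grid_step: float = 0.01
    season_months: tuple[int, ...] = (6, 7, 8)
    matching_window_days: float = 7.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("axes", "season_months"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    pst_table: pd.DataFrame
    pst_summaries: pd.DataFrame
    growth_psi_p50: float | None
    growth_psi_p05: float | None
    hydroscape_breakpoint: float | None
    hydroscape_slopes: tuple[float, float] | None
    gs_model_r2: float | None
    outdir: Path
    truth: TrueParams | None = None
    log: list[str] = field(default_factory=list)


def _simulate_world(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, TrueParams]:
    truth = make_default_truth(
        seed=stage_seed(config.seed, "truth"),
        n_species=config.n_species,
        pst_mean=config.pst_mean,
        pst_sd=config.pst_sd,
    )
    sim = SimConfig(
        n_species=config.n_species,
        trees_per_species=config.trees_per_species,
        n_campaigns=config.n_campaigns,
        seed=stage_seed(config.seed, "campaign"),
    )
    campaign, _ = simulate_campaign_dataset(sim, truth)

    # dendrometer readings: each tree driven by its own pre-dawn trajectory
    pre = campaign[campaign["window"] == "predawn"]
    rng_seed = stage_seed(config.seed, "dendro")
    rng = np.random.default_rng(rng_seed)
    frames = []
    for tree, grp in pre.groupby("tree_id"):
        psi = pd.Series(
            grp["psi_leaf_mpa"].to_numpy(),
            index=pd.to_datetime(grp["timestamp"]).dt.date,
        )
        dd = simulate_dendrometer_series(truth, psi, n_trees=1, seed=rng)
        dd["tree_id"] = tree
        frames.append(dd)
    dendro = pd.concat(frames, ignore_index=True)
    return campaign, dendro, truth


def run_full_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and write per-stage CSVs plus a manifest.

    Stage failures abort with a stage-named diagnostic; partial outputs are
    retained in the output directory.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    truth = None

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulate:
            campaign, dendro, truth = _simulate_world(config)
            write_campaign_table(out / "campaign.csv", campaign)
            write_series(out / "dendro.csv", dendro, "dendro")
            with open(out / "truth.yaml", "w") as fh:
                yaml.safe_dump(truth.to_dict(), fh, sort_keys=True)
        else:
            if not config.campaign_csv:
                raise ValueError("simulate=False requires campaign_csv")
            from .io import read_campaign_table, read_dendro_table

            rr = read_campaign_table(config.campaign_csv)
            campaign = rr.records
            log.append(f"inputs: {rr.n_read} rows read, {rr.n_rejected} rejected")
            dendro = (
                read_dendro_table(config.dendro_csv).records
                if config.dendro_csv
                else pd.DataFrame(columns=["tree_id", "date", "dbh_cm"])
            )
    except Exception as err:
        raise RuntimeError(f"stage 'inputs' failed: {err}") from err
    log.append(f"inputs: {len(campaign)} campaign rows, {len(dendro)} dendro rows")

    # ---- stage: normalize ----------------------------------------------
    try:
        if campaign["gs_mol_m2_s"].notna().sum() == 0 and any(
            a in config.axes for a in ("predawn", "midday")
        ):
            raise ValueError(
                "closure-point estimation requested but the campaign table "
                "has no conductance (gs_mol_m2_s) values"
            )
        norm, gs_ref = normalize_gs(campaign)
        gs_ref.rename("species_gs_max").to_csv(out / "species_gs_max.csv")
    except Exception as err:
        raise RuntimeError(f"stage 'normalize' failed: {err}") from err
    log.append(f"normalize: references for {len(gs_ref)} species")

    # ---- stage: closure point ------------------------------------------
    pst_rows, summary_rows = [], []
    r2 = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = fit_gs_model(norm, include_vpd=True, axis="predawn").r2_marginal
            for axis in config.axes:
                for method in ("ci_intersection", "fixed_gs_threshold"):
                    ests = estimate_species_pst(
                        norm, gs_ref, axis=axis, method=method,
                        vpd_setting=config.vpd_setting,
                        gs_threshold=config.gs_threshold,
                        grid_step=config.grid_step,
                    )
                    for e in ests:
                        pst_rows.append(
                            {
                                "species": e.species, "axis": e.axis,
                                "method": e.method, "pst_mpa": e.pst,
                                "detected": e.detected,
                            }
                        )
                    if sum(e.detected for e in ests) >= 2:
                        s = summarize_pst(ests, axis)
                        summary_rows.append(
                            {
                                "axis": axis, "method": method,
                                "mean_mpa": s.mean, "sd_mpa": s.sd,
                                "n_species": s.n_species,
                            }
                        )
        pst_table = pd.DataFrame(pst_rows)
        pst_summaries = pd.DataFrame(summary_rows)
        pst_table.to_csv(out / "pst_estimates.csv", index=False)
        pst_summaries.to_csv(out / "pst_summary.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"stage 'closure' failed: {err}") from err
    log.append(f"closure: {len(pst_rows)} species-axis-method estimates")

    # ---- stage: growth --------------------------------------------------
    growth_p50 = growth_p05 = None
    try:
        if len(dendro):
            rates = growth_rates(zero_growth_transform(dendro))
            rates.intervals = season_filter(
                rates.intervals, months=tuple(config.season_months)
            )
            pre = campaign[campaign["window"] == "predawn"].copy()
            pre["date"] = pd.to_datetime(pre["timestamp"]).dt.date
            camp = pre[["tree_id", "date", "psi_leaf_mpa"]]
            tree_species = campaign.groupby("tree_id")["species"].first()
            tbl = build_growth_table(
                rates, camp, tree_species=tree_species,
                window_days=config.matching_window_days,
            )
            log.append(
                f"growth: {len(tbl)} matched intervals, "
                f"{tbl.attrs['n_unmatched']} unmatched"
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gfit = fit_growth_probability(tbl)
            growth_p50 = psi_at_probability(gfit, 0.5)
            growth_p05 = psi_at_probability(gfit, 0.05)
            tbl.to_csv(out / "growth_table.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"stage 'growth' failed: {err}") from err

    # ---- stage: hydroscape ----------------------------------------------
    brk = None
    slopes = None
    try:
        md = campaign[campaign["window"] == "midday"].copy()
        pre = campaign[campaign["window"] == "predawn"].copy()
        for d in (md, pre):
            d["date"] = pd.to_datetime(d["timestamp"]).dt.date
        pairs = md.merge(
            pre[["tree_id", "date", "psi_leaf_mpa"]],
            on=["tree_id", "date"], suffixes=("_md", "_pd"),
        ).rename(columns={"psi_leaf_mpa_md": "psi_md", "psi_leaf_mpa_pd": "psi_pd"})
        hfit = fit_hydroscape(pairs)
        brk = hfit.breakpoint
        slopes = (hfit.slope_wet, hfit.slope_dry)
        pd.DataFrame(
            [
                {
                    "breakpoint_mpa": hfit.breakpoint,
                    "slope_wet": hfit.slope_wet,
                    "slope_dry": hfit.slope_dry,
                    "delta_bic": hfit.delta_bic,
                    "n": hfit.n,
                }
            ]
        ).to_csv(out / "hydroscape.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"stage 'hydroscape' failed: {err}") from err
    log.append(f"hydroscape: breakpoint {brk}")

    # ---- manifest --------------------------------------------------------
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "seed": config.seed,
                "package_version": __version__,
                "stages": log,
            },
            fh, sort_keys=True,
        )
    return RunReport(
        pst_table=pst_table, pst_summaries=pst_summaries,
        growth_psi_p50=growth_p50, growth_psi_p05=growth_p05,
        hydroscape_breakpoint=brk, hydroscape_slopes=slopes,
        gs_model_r2=r2, outdir=out, truth=truth, log=log,
    )


@dataclass
class RecoveryReport:
    """Bias / RMSE / interval-style summaries over replicate worlds."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame


def recovery_experiment(
    config: RunConfig,
    n_replicates: int = 100,
    axes: tuple[str, ...] = ("predawn",),
    include_growth: bool = False,
    include_hydroscape: bool = True,
) -> RecoveryReport:
    """Replicate synthetic worlds, run the estimators, compare with truth.

    A light-weight loop around the pipeline stages (no file output): each
    replicate draws a fresh species ensemble and campaign dataset from a
    derived seed, estimates species closure points on the requested axes
    (plus optionally the growth threshold and hydroscape breakpoint), and
    records errors against the retained generative parameters.
    """
    if not config.simulate:
        raise ValueError("recovery_experiment requires a simulation-mode config")
    rows = []
    for rep in range(n_replicates):
        rep_cfg = dataclasses.replace(config, seed=stage_seed(config.seed, f"rep{rep}"))
        truth = make_default_truth(
            seed=stage_seed(rep_cfg.seed, "truth"),
            n_species=rep_cfg.n_species,
            pst_mean=rep_cfg.pst_mean,
            pst_sd=rep_cfg.pst_sd,
        )
        sim = SimConfig(
            n_species=rep_cfg.n_species,
            trees_per_species=rep_cfg.trees_per_species,
            n_campaigns=rep_cfg.n_campaigns,
            seed=stage_seed(rep_cfg.seed, "campaign"),
        )
        campaign, _ = simulate_campaign_dataset(sim, truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm, gs_ref = normalize_gs(campaign)
            for axis in axes:
                ests = estimate_species_pst(
                    norm, gs_ref, axis=axis,
                    vpd_setting=config.vpd_setting,
                    gs_threshold=config.gs_threshold,
                    grid_step=config.grid_step,
                )
                for e in ests:
                    if not e.detected:
                        continue
                    sp = truth.species_by_id(e.species)
                    true_val = (
                        sp.pst_predawn_true if axis == "predawn" else sp.pst_midday_true
                    )
                    rows.append(
                        {
                            "replicate": rep, "estimand": f"pst_{axis}",
                            "species": e.species, "estimate": e.pst,
                            "truth": true_val, "error": e.pst - true_val,
                        }
                    )
            if include_hydroscape:
                md = campaign[campaign["window"] == "midday"].copy()
                pre = campaign[campaign["window"] == "predawn"].copy()
                for d in (md, pre):
                    d["date"] = pd.to_datetime(d["timestamp"]).dt.date
                pairs = md.merge(
                    pre[["tree_id", "date", "psi_leaf_mpa"]],
                    on=["tree_id", "date"], suffixes=("_md", "_pd"),
                ).rename(
                    columns={"psi_leaf_mpa_md": "psi_md", "psi_leaf_mpa_pd": "psi_pd"}
                )
                # single-species worlds have a single true break; multi-species
                # worlds target the across-species mean closure point
                true_brk = float(
                    np.mean([sp.pst_predawn_true for sp in truth.species])
                )
                hfit = fit_hydroscape(pairs)
                if hfit.has_breakpoint:
                    rows.append(
                        {
                            "replicate": rep, "estimand": "hydroscape_breakpoint",
                            "species": "all", "estimate": hfit.breakpoint,
                            "truth": true_brk, "error": hfit.breakpoint - true_brk,
                        }
                    )
            if include_growth:
                rep_report = _growth_recovery(rep_cfg, truth, campaign)
                if rep_report is not None:
                    est05, true05 = rep_report
                    rows.append(
                        {
                            "replicate": rep, "estimand": "growth_psi_p05",
                            "species": "all", "estimate": est05,
                            "truth": true05, "error": est05 - true05,
                        }
                    )
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby("estimand")["error"]
        .agg(
            bias="mean",
            rmse=lambda e: float(np.sqrt(np.mean(np.square(e)))),
            mae=lambda e: float(np.mean(np.abs(e))),
            n="size",
        )
        .reset_index()
    )
    return RecoveryReport(per_replicate=per_rep, summary=summary)


def _growth_recovery(
    config: RunConfig, truth: TrueParams, campaign: pd.DataFrame
) -> tuple[float, float] | None:
    pre = campaign[campaign["window"] == "predawn"].copy()
    pre["date"] = pd.to_datetime(pre["timestamp"]).dt.date
    rng = np.random.default_rng(stage_seed(config.seed, "dendro"))
    frames = []
    for tree, grp in pre.groupby("tree_id"):
        psi = pd.Series(grp["psi_leaf_mpa"].to_numpy(), index=grp["date"])
        dd = simulate_dendrometer_series(truth, psi, n_trees=1, seed=rng)
        dd["tree_id"] = tree
        frames.append(dd)
    dendro = pd.concat(frames, ignore_index=True)
    rates = growth_rates(zero_growth_transform(dendro))
    rates.intervals = season_filter(rates.intervals)
    if rates.intervals.empty:
        return None
    tree_species = campaign.groupby("tree_id")["species"].first()
    tbl = build_growth_table(
        rates, pre[["tree_id", "date", "psi_leaf_mpa"]], tree_species=tree_species
    )
    gfit = fit_growth_probability(tbl)
    return psi_at_probability(gfit, 0.05), float(truth.growth_psi_at(0.05))
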