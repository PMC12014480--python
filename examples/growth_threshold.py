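"""Stem-growth cessation thresholds from weekly band-dendrometer readings.

Weekly DBH readings pass through the zero-growth transform (running maximum
per tree: reversible shrinkage is not growth), become interval growth
rates, are restricted to June-August, matched to the nearest pre-dawn
water-potential campaign, and fitted with a binomial mixed model. Inverting
the population logistic gives the psi of growth halt (p = 0.5) and the psi
beyond which growth is nearly impossible (p = 0.05) — the generative world
places these at -1.2 and -1.5 MPa.
"""
import warnings

import pandas as pd

from psithresh import (
    RunConfig,
    build_growth_table,
    fit_growth_probability,
    growth_rates,
    psi_at_probability,
    season_filter,
    zero_growth_transform,
)
from psithresh.pipeline import _simulate_world

warnings.simplefilter("ignore")

campaign, dendro, truth = _simulate_world(RunConfig(seed=7))

rates = growth_rates(zero_growth_transform(dendro))
rates.intervals = season_filter(rates.intervals)
pre = campaign[campaign["window"] == "predawn"].copy()
pre["date"] = pd.to_datetime(pre["timestamp"]).dt.date
table = build_growth_table(
    rates, pre[["tree_id", "date", "psi_leaf_mpa"]],
    tree_species=campaign.groupby("tree_id")["species"].first(),
)
fit = fit_growth_probability(table)

print(f"{len(table)} summer growth intervals matched to campaigns "
      f"({table.attrs['n_unmatched']} unmatched)")
print(f"logistic slope {fit.slope:.1f} per MPa ({fit.method})")
p50 = psi_at_probability(fit, 0.5)
p05 = psi_at_probability(fit, 0.05)
print(f"growth halts (p=0.5) at {p50:.2f} MPa   [generator: {truth.growth_halt_psi}]")
print(f"5% growth probability at {p05:.2f} MPa  [generator: {truth.growth_psi_at(0.05):.2f}]")
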