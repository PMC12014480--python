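"""Estimate each species' point of stomatal closure (P_st) on both psi axes.

Chain: species-max normalization of midday conductance -> penalized smooth
of the response against leaf water potential -> linear projection of the
post-closure regime at VPD = 2.4 kPa -> entry of the smooth into the
projection's 95% band. The pre-dawn axis should give tightly clustered
closure points near -1.2 MPa; the midday axis more negative, more variable
ones — the study's central contrast.
"""
import warnings

from psithresh import (
    SimConfig,
    estimate_species_pst,
    make_default_truth,
    normalize_gs,
    simulate_campaign_dataset,
    summarize_pst,
)

warnings.simplefilter("ignore")

truth = make_default_truth(seed=1)
campaign, _ = simulate_campaign_dataset(SimConfig(seed=2), truth)
norm, gs_ref = normalize_gs(campaign)

for axis in ("predawn", "midday"):
    ests = estimate_species_pst(norm, gs_ref, axis=axis)
    s = summarize_pst(ests, axis)
    true_vals = {
        sp.species_id: (sp.pst_predawn_true if axis == "predawn" else sp.pst_midday_true)
        for sp in truth.species
    }
    print(f"\n{axis} axis: P_st = {s.mean:.2f} +/- {s.sd:.2f} MPa "
          f"({s.n_species} species)")
    for e in sorted(ests, key=lambda e: e.species):
        print(f"  {e.species}: estimated {e.pst:+.2f}  true {true_vals[e.species]:+.2f}")
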