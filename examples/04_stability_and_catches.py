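"""Stability of total ecosystem biomass and catch responses across arms.

Computes the coefficient of variation of total biomass over 10-year sliding
windows (mid-season and end-of-season record days) and the percent change of
per-stage annual catches between stocking arms.
"""

import numpy as np

import atnsim as a

web = a.make_lc_like_web(a.WebRecipe(seed=1))
cfg = a.ScenarioConfig(harvest=a.HarvestPolicy(), years_unfished=40, years_fished=30)
arms = a.run_experiment(web, config=cfg)

print("total-biomass CV (10-year windows, fished period):")
for name, res in arms.items():
    for day, label in zip(cfg.record_days, ("mid-season", "end-of-season")):
        total = res.total_biomass(day)[cfg.years_unfished:]
        cv = np.nanmean(a.stability_cv(total, 10))
        print(f"  {name:14s} {label:14s} CV = {cv:.2e}")

print("\ncatch changes, Wht300 vs Wht200 (fished period):")
for sid, pc in a.catch_comparison(arms["wht300"], arms["wht200"]).items():
    if not np.isnan(pc):
        print(f"  {sid:20s} {pc:+7.3f}%")

# The CV quantifies year-to-year fluctuation of the whole system at a fixed
# point of the season; catch changes track the adult biomass responses —
# higher whitefish stocking yields only a few percent more catch.
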