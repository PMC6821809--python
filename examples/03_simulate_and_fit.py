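"""Simulate a small camera-trap survey and fit the community occupancy
model.

Generates one landscape (2 sites x 15 stations, 10 units) whose occupancy
is driven by canopy closure, fits the hierarchical model by MCMC at a
reduced scale, and prints the recovered community-mean covariate effects
next to the values used to generate the data.
"""

import warnings

from defaunation import (MCMCConfig, ScenarioConfig, build_detection_history,
                         effect_sizes, fit)
from defaunation.simulate import (generate_community, generate_covariates,
                                  generate_stations, generate_villages,
                                  simulate_detections)

cfg = ScenarioConfig(landscapes=("degraded",), sites_per_landscape=2,
                     stations_per_site=15, n_units=10, seed=3)
stations = generate_stations(cfg)
covariates = generate_covariates(stations,
                                 generate_villages(cfg, stations), cfg)
truth = generate_community(cfg, "degraded")
records, truth = simulate_detections(truth, stations, covariates, cfg)
history = build_detection_history(records, stations, units=truth.units)
print(f"{len(records)} detection records at {history.n_stations} stations, "
      f"{history.n_occasions} ten-day occasions")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    samples = fit(history, covariates,
                  mcmc=MCMCConfig(chains=3, iterations=12_000, burn_in=3_000,
                                  thin=5, seed=3))
print(f"3 chains, {samples.n_draws} retained draws each; "
      f"converged: {samples.converged}")

eff = effect_sizes(samples)
community = eff[eff["unit"] == "(community mean)"]
hyp = cfg.hypers["degraded"]
print("\ncommunity-mean covariate effects (logit scale):")
for _, row in community.iterrows():
    name = row["covariate"]
    true = hyp.mu_beta1 if name == "canopy_z" else hyp.mu_beta2
    print(f"  {name:<18} {row['mean']:+.2f} "
          f"[{row['q2.5']:+.2f}, {row['q97.5']:+.2f}] 95% BCI "
          f"(generating value {true:+.2f})")
print("\nA 95% BCI that excludes zero marks a community-level driver of"
      "\noccupancy; here canopy drives occurrence and village density"
      "\ndoes not, by construction.")
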