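"""The whole analysis end to end on a synthetic survey.

Writes a synthetic input bundle (records, stations, traits, villages),
then runs the full pipeline: detection histories, covariates, historical
defaunation per site, per-landscape occupancy fits, and the
occupancy-based defaunation index against the first site as reference.
Outputs land in ./pipeline_out.
"""

import tempfile
import warnings
from pathlib import Path

from defaunation import PipelineConfig, ScenarioConfig, run
from defaunation.simulate import survey_scale_fixture

workdir = Path(tempfile.mkdtemp(prefix="defaunation_"))
cfg_sim = ScenarioConfig(stations_per_site=12, n_units=10, seed=11)
bundle = survey_scale_fixture(seed=11, outdir=workdir, config=cfg_sim)

# the pipeline reads canopy from the station table
st = bundle["stations"].copy()
st["canopy"] = bundle["covariates"]["canopy"].to_numpy()
st["deploy_start"] = [d.isoformat() for d in st["deploy_start"]]
st["deploy_end"] = [d.isoformat() for d in st["deploy_end"]]
st.to_csv(workdir / "stations.csv", index=False)

config = PipelineConfig(
    records=str(workdir / "records.csv"),
    stations=str(workdir / "stations.csv"),
    traits=str(workdir / "traits.csv"),
    villages=str(workdir / "villages.csv"),
    outdir="pipeline_out", seed=11)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run(config)

print("historical defaunation (site x weight scheme):")
print(result.historical.round(3).to_string())
print("\noccupancy-based defaunation vs", result.manifest["reference_site"])
for site, r in result.occupancy_defaunation.items():
    print(f"  {site:<18} D = {r.mean:+.3f} [{r.ci_low:+.3f}, {r.ci_high:+.3f}]")
print("\nOutputs (CSV summaries, manifest.json) are in ./pipeline_out."
      "\nHistorical D compares recorded vs expected assemblages per site;"
      "\nthe occupancy-based D propagates posterior uncertainty.")
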