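"""End-to-end orchestration: inputs -> histories -> covariates ->
historical defaunation -> occupancy fits -> occupancy-based defaunation.

Each stage writes its outputs under the configured output directory along
with a JSON run manifest (package version, seed, configuration hash), so a
run is auditable and repeatable. Stage failures abort with the stage name
attached. One occupancy model is fitted per landscape, with site-indexed
random intercepts; the occupancy-based defaunation index then compares
every site against the reference site over the units recorded in all
landscapes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import covariates as cov_mod
from . import histories as hist_mod
from . import index as index_mod
from . import io as io_mod
from . import montecarlo as mc_mod
from . import occupancy as occ_mod
from .errors import ConfigurationError, DefaunationError

log = logging.getLogger("defaunation")


@dataclass
class PipelineConfig:
    """Paths, analysis settings and defaults for a full run.

    Defaults equal the study design values: 10-day occasions, 2.5%
    functional-extinction threshold, 15 km kernel radius, 30,000
    Monte-Carlo draws; MCMC defaults to desk scale (use
    ``mcmc_scale: full`` for 3 chains x 250,000 / 20,000 / 20).
    """

    records: str = "records.csv"
    stations: str = "stations.csv"
    traits: str = "traits.csv"
    villages: str = "villages.csv"
    outdir: str = "out"
    occasion_length: int = 10
    extinction_threshold: float = 0.025
    weight_schemes: tuple[str, ...] = ("equal", "conservation", "size")
    kernel_radius: float = 15_000.0
    mcmc_scale: str = "desk"            # "desk" or "full"
    reference_site: str | None = None   # default: first site of first landscape
    n_draws: int = 30_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "weight_schemes" in raw:
            raw["weight_schemes"] = tuple(raw["weight_schemes"])
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    historical: pd.DataFrame
    occupancy_summaries: dict
    occupancy_defaunation: dict
    manifest: dict
    samples: dict = field(default_factory=dict)


def load_inputs(config: PipelineConfig):
    """Read and validate the four input tables."""
    for p in (config.records, config.stations, config.traits, config.villages):
        if not Path(p).exists():
            raise ConfigurationError(f"[stage load] input file not found: {p}")
    records = io_mod.read_detection_records(config.records)
    stations = io_mod.read_stations(config.stations)
    traits = io_mod.read_species_traits(config.traits)
    villages = io_mod.read_villages(config.villages)
    log.info("loaded %d records, %d stations, %d units, %d villages",
             len(records), len(stations), len(traits), len(villages))
    return records, stations, traits, villages


def historical_defaunation(history, stations, traits, config) -> pd.DataFrame:
    """Per-site presence/absence defaunation under each weight scheme.

    The reference assemblage is the full trait-table unit list (the
    historically expected community); sites' focal assemblages come from
    the functional-extinction rule."""
    presence = hist_mod.station_presence(history)
    site_of = dict(zip(stations["station_id"], stations["site_id"]))
    presence_by_site = {
        s: presence.loc[:, [c for c in presence.columns if site_of[c] == s]]
        for s in pd.unique(stations["site_id"])}
    reference = pd.Series(1, index=pd.Index(traits["unit_id"]))
    return index_mod.site_defaunation(
        presence_by_site, reference, traits, schemes=config.weight_schemes,
        threshold=config.extinction_threshold)


def fit_landscapes(history, stations, cov, config):
    """Fit one community occupancy model per landscape.

    Returns dict landscape -> PosteriorSamples; seeds are offset per
    landscape so chains are independent."""
    factory = (occ_mod.MCMCConfig.full if config.mcmc_scale == "full"
               else occ_mod.MCMCConfig.desk)
    fits = {}
    for li, land in enumerate(pd.unique(stations["landscape_id"])):
        st_ids = list(stations.loc[stations["landscape_id"] == land,
                                   "station_id"])
        sub_idx = [history.station_index[s] for s in st_ids]
        sub = hist_mod.DetectionHistory(
            y=history.y[:, sub_idx], effort=history.effort[sub_idx],
            units=history.units, stations=st_ids,
            occasion_length=history.occasion_length)
        log.info("fitting landscape %s: %d stations, %d detections",
                 land, len(st_ids), int(sub.y.sum()))
        fits[land] = occ_mod.fit(sub, cov, mcmc=factory(seed=config.seed + li))
    return fits


def combined_site_occupancy(fits: dict, stations, cov):
    """Site-level psi draws for units recorded in every landscape.

    Returns (psi array (draws, n_shared_units, n_sites), units, sites).
    The cross-landscape index is defined only for shared units (species or
    species pairs present in both regions)."""
    shared = None
    for samples in fits.values():
        s = set(samples.units)
        shared = s if shared is None else shared & s
    shared = sorted(shared)
    if not shared:
        raise ConfigurationError(
            "no unit was recorded in every landscape; the occupancy-based "
            "index compares shared units only")
    blocks, sites = [], []
    n_draws = min(s.n_chains * s.n_draws for s in fits.values())
    for land, samples in fits.items():
        st_ids = list(stations.loc[stations["landscape_id"] == land,
                                   "station_id"])
        psi = occ_mod.species_site_occupancy(samples, cov, stations=st_ids)
        rows = [samples.units.index(u) for u in shared]
        blocks.append(psi[:n_draws][:, rows])
        sites.extend(samples.sites)
    return np.concatenate(blocks, axis=2), shared, sites


def run(config: PipelineConfig, canopy: np.ndarray | None = None,
        keep_samples: bool = False) -> PipelineResult:
    """Execute the full analysis and write all stage outputs.

    Parameters
    ----------
    config : PipelineConfig
    canopy : array, optional
        Per-station canopy-closure fractions in station-table order. When
        absent, a ``canopy`` column is expected in the station table (the
        photograph-processing step happens upstream of a pipeline run).
    keep_samples : bool
        Retain raw posterior draws on the result object.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, stations, traits, villages = load_inputs(config)

    unit_records = io_mod.merge_to_analysis_units(records, traits)
    history = hist_mod.build_detection_history(
        unit_records, stations, occasion_length=config.occasion_length,
        units=list(traits["unit_id"]))
    log.info("history: %d units x %d stations x %d occasions, %d detections",
             history.n_units, history.n_stations, history.n_occasions,
             int(history.y.sum()))

    if canopy is None:
        if "canopy" not in stations:
            raise ConfigurationError(
                "[stage covariates] no canopy values: pass `canopy=` or add "
                "a canopy column to the station table")
        canopy = stations["canopy"].to_numpy(dtype=float)
    cov = cov_mod.covariate_table(stations, canopy, villages,
                                  radius=config.kernel_radius)
    cov.to_csv(outdir / "covariates.csv", index=False)

    historical = historical_defaunation(history, stations, traits, config)
    historical.to_csv(outdir / "historical_defaunation.csv")

    fits = fit_landscapes(history, stations, cov, config)
    summaries = {}
    for land, samples in fits.items():
        summaries[land] = occ_mod.summarize(samples)
        summaries[land].to_csv(outdir / f"posterior_{land}.csv")
        occ_mod.effect_sizes(samples).to_csv(
            outdir / f"effect_sizes_{land}.csv", index=False)

    psi, shared_units, sites = combined_site_occupancy(fits, stations, cov)
    ref_site = config.reference_site or sites[0]
    occ_def = mc_mod.occupancy_defaunation(
        psi, sites, ref_site, n_draws=config.n_draws, seed=config.seed)
    pd.DataFrame([
        {"site": r.site, "reference": r.reference, "mean": r.mean, "sd": r.sd,
         "ci_low": r.ci_low, "ci_high": r.ci_high}
        for r in occ_def.values()
    ]).to_csv(outdir / "occupancy_defaunation.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": {k: str(v) for k, v in asdict(config).items()},
        "n_stations": int(len(stations)),
        "n_units": int(len(traits)),
        "n_records": int(len(records)),
        "n_shared_units": len(shared_units),
        "reference_site": ref_site,
        "converged": {land: bool(s.converged) for land, s in fits.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return PipelineResult(historical=historical,
                          occupancy_summaries=summaries,
                          occupancy_defaunation=occ_def,
                          manifest=manifest,
                          samples=fits if keep_samples else {})
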