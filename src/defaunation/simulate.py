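"""Synthetic camera-trap survey generator.

Emulates the sampling design and statistical structure the analysis
assumes, so every pipeline stage can be exercised without field data:
two landscapes (one degraded, one hunted) of three sites each, stations on
a jittered ~2.5 km grid deployed for >= 60 days, a species community whose
logit-scale occupancy and detection parameters are drawn from
community-level normal distributions, canopy closure from a smooth spatial
field, village density from generated village points, and dated detection
records produced by the same occupancy/detection process the model fits.

Default study conditions
------------------------
* 3 sites x 80 stations per landscape, 2.5 km target spacing, deployments
  of 60 days (the design minimum) plus a uniform 0-10 day overrun before
  camera collection, pooled into up to seven 10-day occasions with a
  variable-effort trailing occasion.
* 30 analysis units per landscape (the surveyed communities held roughly
  15-45 camera-trappable units).
* Canopy closure mean/sd 0.77/0.12 in the degraded landscape and
  0.83/0.05 in the hunted landscape, mirroring the published contrast of a
  structurally varied logged forest against intact but hunted forest.
* Occupancy driven by canopy in the degraded landscape (mu_beta1 = 1,
  mu_beta2 = 0) and by village density in the hunted landscape
  (mu_beta1 = 0, mu_beta2 = -1, villages depressing occupancy), the
  qualitative contrast the analysis is designed to detect.
* Detection intercept mu_p = -1 (p ~ 0.27 per 10-day occasion, a typical
  camera-trap value) with a positive effort effect mu_e = 0.5.

All randomness flows from one seed through named sub-streams per stage, so
each stage is independently reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from . import covariates as _cov
from . import io as _io
from .histories import station_effort
from .occupancy import _normalize_effort
from scipy.special import expit

# stage identifiers for the named seed sub-streams
_STAGES = {"stations": 0, "villages": 1, "canopy": 2, "community": 3,
           "detections": 4, "traits": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage of one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES[stage],)))


@dataclass
class CommunityHyperparams:
    """Community-level means/sds of the logit-scale parameter distributions."""

    mu_alpha: float = 0.0       # occupancy intercept (psi ~ 0.5)
    sigma_alpha: float = 1.0
    mu_beta1: float = 1.0       # canopy effect
    sigma_beta1: float = 0.5
    mu_beta2: float = 0.0       # village-density effect
    sigma_beta2: float = 0.25
    mu_p: float = -1.0          # detection intercept (p ~ 0.27/occasion)
    sigma_p: float = 0.5
    mu_e: float = 0.5           # effort effect on detection
    sigma_e: float = 0.25


#: Canopy-driven community (degraded landscape) and village-driven
#: community (hunted landscape; villages depress occupancy).
DEGRADED_HYPERS = CommunityHyperparams()
HUNTED_HYPERS = CommunityHyperparams(mu_beta1=0.0, sigma_beta1=0.25,
                                     mu_beta2=-1.0, sigma_beta2=0.5)


@dataclass
class ScenarioConfig:
    """Full description of a synthetic survey."""

    landscapes: tuple[str, ...] = ("degraded", "hunted")
    sites_per_landscape: int = 3
    stations_per_site: int = 80
    spacing: float = 2_500.0            # meters between neighboring stations
    jitter_frac: float = 0.08           # station jitter as fraction of spacing
    max_site_extent: float = 40_000.0   # meters; spacing feasibility bound
    n_units: int = 30
    deployment_days: int = 60        # design minimum
    deployment_extra_days: int = 10  # per-station uniform 0..extra overrun
    occasion_length: int = 10
    base_date: _dt.date = _dt.date(2015, 1, 1)
    hypers: dict = field(default_factory=lambda: {
        "degraded": DEGRADED_HYPERS, "hunted": HUNTED_HYPERS})
    canopy_moments: dict = field(default_factory=lambda: {
        "degraded": (0.77, 0.12), "hunted": (0.83, 0.05)})
    villages_per_landscape: dict = field(default_factory=lambda: {
        "degraded": 8, "hunted": 40})
    kernel_radius: float = 15_000.0
    seed: int = 0

    def __post_init__(self):
        if min(self.sites_per_landscape, self.stations_per_site,
               self.n_units, self.deployment_days) < 1:
            raise ValueError("all scenario counts must be positive")


@dataclass
class GroundTruth:
    """Generating parameters and latent states for one landscape."""

    landscape: str
    units: list[str]
    stations: list[str]
    sites: list[str]
    hypers: CommunityHyperparams
    alpha: np.ndarray          # (n_units, n_sites)
    beta1: np.ndarray          # (n_units,)
    beta2: np.ndarray
    alpha_p: np.ndarray
    beta_eff: np.ndarray
    psi: np.ndarray = None     # (n_units, n_stations)
    z: np.ndarray = None
    y: np.ndarray = None       # (n_units, n_stations, n_occasions)

    def to_jsonable(self) -> dict:
        d = {"landscape": self.landscape, "units": self.units,
             "stations": self.stations, "sites": self.sites,
             "hypers": asdict(self.hypers)}
        for k in ("alpha", "beta1", "beta2", "alpha_p", "beta_eff", "psi", "z"):
            v = getattr(self, k)
            if v is not None:
                d[k] = np.asarray(v).tolist()
        return d


# ---------------------------------------------------------------------------
# stations and villages

def _site_layout(n: int, spacing: float, jitter_frac: float,
                 max_extent: float, rng: np.random.Generator) -> np.ndarray:
    side = math.ceil(math.sqrt(n))
    if (side - 1) * spacing > max_extent:
        raise ValueError(
            f"{n} stations at {spacing:.0f} m spacing need a grid of "
            f"{(side - 1) * spacing:.0f} m, exceeding the site extent "
            f"{max_extent:.0f} m")
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    xy = np.column_stack([gx.ravel(), gy.ravel()])[:n] * spacing
    xy = xy + rng.uniform(-jitter_frac, jitter_frac, size=xy.shape) * spacing
    return xy


def generate_stations(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Lay out stations on jittered grids, one grid per site.

    Sites within a landscape are placed side by side with a gap; the two
    landscapes are offset far apart (they are different regions).
    Deployment windows are staggered by site, with small per-station
    start jitter. Coordinates are offset to UTM-like magnitudes so they are
    unambiguously planar meters.
    """
    rng = stage_rng(config.seed if seed is None else seed, "stations")
    side_extent = (math.ceil(math.sqrt(config.stations_per_site))) * config.spacing
    rows = []
    for li, land in enumerate(config.landscapes):
        for si in range(config.sites_per_landscape):
            xy = _site_layout(config.stations_per_site, config.spacing,
                              config.jitter_frac, config.max_site_extent, rng)
            offset = np.array([500_000.0 + li * 400_000.0
                               + si * (side_extent + 8_000.0),
                               500_000.0 + li * 150_000.0])
            site_id = f"{land}_site{si + 1}"
            start0 = config.base_date + _dt.timedelta(days=20 * si + 120 * li)
            for j, (x, y) in enumerate(xy + offset):
                start = start0 + _dt.timedelta(days=int(rng.integers(0, 4)))
                # cameras are collected some days past the design minimum,
                # giving stations unequal trailing-occasion effort
                days = config.deployment_days + int(
                    rng.integers(0, config.deployment_extra_days + 1))
                rows.append({
                    "station_id": f"{site_id}_st{j + 1:03d}",
                    "site_id": site_id,
                    "landscape_id": land,
                    "x": float(x), "y": float(y),
                    "deploy_start": start,
                    "deploy_end": start + _dt.timedelta(days=days - 1),
                })
    return pd.DataFrame(rows)


def generate_villages(config: ScenarioConfig, stations: pd.DataFrame,
                      seed: int | None = None) -> pd.DataFrame:
    """Scatter villages uniformly in a 10 km buffer around each landscape."""
    rng = stage_rng(config.seed if seed is None else seed, "villages")
    buffer = 10_000.0
    frames = []
    for land in config.landscapes:
        st = stations[stations["landscape_id"] == land]
        n = config.villages_per_landscape.get(land, 0)
        if n == 0 or len(st) == 0:
            continue
        x = rng.uniform(st["x"].min() - buffer, st["x"].max() + buffer, n)
        y = rng.uniform(st["y"].min() - buffer, st["y"].max() + buffer, n)
        frames.append(pd.DataFrame({"x": x, "y": y, "landscape_id": land}))
    if not frames:
        return pd.DataFrame({"x": [], "y": [], "landscape_id": []})
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# covariates

def _smooth_field_at(xy: np.ndarray, rng: np.random.Generator,
                     n_grid: int = 40, smooth_sigma: float = 3.0) -> np.ndarray:
    """Standardized values of a Gaussian-smoothed noise field at points.

    Any smooth spatial field serves; the analysis only needs canopy to vary
    smoothly in space with controllable moments.
    """
    lo = xy.min(axis=0) - 1.0
    hi = xy.max(axis=0) + 1.0
    gx = np.linspace(lo[0], hi[0], n_grid)
    gy = np.linspace(lo[1], hi[1], n_grid)
    noise = gaussian_filter(rng.standard_normal((n_grid, n_grid)),
                            smooth_sigma, mode="wrap")
    interp = RegularGridInterpolator((gx, gy), noise)
    v = interp(xy)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros(len(v))


def generate_covariates(stations: pd.DataFrame, villages: pd.DataFrame,
                        config: ScenarioConfig,
                        seed: int | None = None) -> pd.DataFrame:
    """Canopy from a smooth spatial field; village density from points.

    Canopy is rescaled to the configured per-landscape mean/sd and clipped
    into [0, 1]; village density comes from the covariates module's quartic
    kernel, so simulation and analysis share one definition.
    """
    rng = stage_rng(config.seed if seed is None else seed, "canopy")
    canopy = np.empty(len(stations))
    for land in config.landscapes:
        m = (stations["landscape_id"] == land).to_numpy()
        mean, sd = config.canopy_moments[land]
        zfield = _smooth_field_at(stations.loc[m, ["x", "y"]].to_numpy(), rng)
        canopy[m] = np.clip(mean + sd * zfield, 0.0, 1.0)
    return _cov.covariate_table(stations, canopy, villages,
                                radius=config.kernel_radius)


# ---------------------------------------------------------------------------
# community and detections

def unit_labels(n_units: int) -> list[str]:
    return [f"unit{i + 1:02d}" for i in range(n_units)]


def generate_community(config: ScenarioConfig, landscape: str,
                       seed: int | None = None) -> GroundTruth:
    """Draw species-level parameters from the community distributions."""
    # a distinct sub-stream per landscape: the two communities differ but
    # each remains individually reproducible
    li = list(config.landscapes).index(landscape)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed if seed is None else seed,
                               spawn_key=(_STAGES["community"], li)))
    h = config.hypers[landscape]
    n, s = config.n_units, config.sites_per_landscape
    sites = [f"{landscape}_site{k + 1}" for k in range(s)]
    return GroundTruth(
        landscape=landscape,
        units=unit_labels(n),
        stations=[], sites=sites, hypers=h,
        alpha=rng.normal(h.mu_alpha, h.sigma_alpha, size=(n, s)),
        beta1=rng.normal(h.mu_beta1, h.sigma_beta1, size=n),
        beta2=rng.normal(h.mu_beta2, h.sigma_beta2, size=n),
        alpha_p=rng.normal(h.mu_p, h.sigma_p, size=n),
        beta_eff=rng.normal(h.mu_e, h.sigma_e, size=n),
    )


def simulate_detections(truth: GroundTruth, stations: pd.DataFrame,
                        covariate_table: pd.DataFrame, config: ScenarioConfig,
                        seed: int | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate dated detection records from the occupancy process.

    Draws z ~ Bern(psi) per (unit, station), then per active occasion a
    detection with probability z * p where logit(p) uses the normalized
    effort covariate. Each detected (unit, station, occasion) becomes one
    record dated to the occasion's first active day — the pipeline only
    uses occasion-level presence, so finer timing would be invented detail.
    """
    rng = stage_rng(config.seed if seed is None else seed, "detections")
    st = stations[stations["landscape_id"] == truth.landscape].reset_index(drop=True)
    cov = covariate_table.set_index("station_id").loc[st["station_id"]]
    x1 = cov["canopy_z"].to_numpy(dtype=float)
    x2 = cov["village_density_z"].to_numpy(dtype=float)
    site_index = np.array([truth.sites.index(s) for s in st["site_id"]])

    lpsi = (truth.alpha[:, site_index] + truth.beta1[:, None] * x1[None]
            + truth.beta2[:, None] * x2[None])
    psi = expit(lpsi)
    z = (rng.random(psi.shape) < psi).astype(np.uint8)

    dep_days = np.array([(e - s).days + 1 for s, e in
                         zip(st["deploy_start"], st["deploy_end"])])
    n_occ = int(np.ceil(dep_days / config.occasion_length).max())
    effort = np.zeros((len(st), n_occ))
    for j, days in enumerate(dep_days):
        e = station_effort(int(days), config.occasion_length)
        effort[j, :len(e)] = e
    eff_z = _normalize_effort(effort)
    mask = effort > 0

    lp = truth.alpha_p[:, None, None] + truth.beta_eff[:, None, None] * eff_z[None]
    p = expit(lp)
    y = ((rng.random(p.shape) < p) & (z[:, :, None] == 1) & mask[None]).astype(np.uint8)

    units, stations_i, occs = np.nonzero(y)
    starts = list(st["deploy_start"])
    st_ids = list(st["station_id"])
    records = pd.DataFrame({
        "station_id": [st_ids[j] for j in stations_i],
        "unit_id": [truth.units[i] for i in units],
        "date": [starts[j] + _dt.timedelta(days=int(k) * config.occasion_length)
                 for j, k in zip(stations_i, occs)],
    })
    truth.stations = list(st["station_id"])
    truth.psi, truth.z, truth.y = psi, z, y
    return records, truth


def generate_traits(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Trait table for the synthetic units: IUCN category, body mass, pair.

    Masses are log-normal above the 500 g camera-trappability floor; IUCN
    categories are drawn with threatened classes rarer than Least Concern,
    and heavier units more likely threatened (as in real assemblages).
    """
    rng = stage_rng(config.seed if seed is None else seed, "traits")
    units = unit_labels(config.n_units)
    mass = 500.0 + np.exp(rng.normal(np.log(4_000.0), 1.2, config.n_units))
    order = np.argsort(np.argsort(mass))  # 0 = lightest
    cats = []
    for r in order / max(config.n_units - 1, 1):
        pvals = np.array([3.5 - 2.5 * r, 1.0, 0.6 + r, 0.4 + r, 0.2 + r, 0.3])
        cats.append(rng.choice(["LC", "NT", "VU", "EN", "CR", "DD"],
                               p=pvals / pvals.sum()))
    return pd.DataFrame({
        "unit_id": units,
        "member_species": [(u,) for u in units],
        "iucn": cats,
        "body_mass_g": mass,
        "pair_id": units,
    })


# ---------------------------------------------------------------------------

def survey_scale_fixture(seed: int = 0, outdir=None,
                        config: ScenarioConfig | None = None) -> dict:
    """Full synthetic input bundle at survey scale.

    Two landscapes x 3 sites x 80 stations, 30 units, 70-day deployments
    (seven 10-day occasions), canopy-driven occupancy in the degraded
    landscape and village-driven occupancy in the hunted landscape.

    Returns a dict with ``stations``, ``villages``, ``covariates``,
    ``traits``, ``records`` (unit-level, both landscapes) and ``truth``
    (dict landscape -> :class:`GroundTruth`). With ``outdir``, also writes
    the standard CSV bundle plus ``truth.json``.
    """
    config = config or ScenarioConfig(seed=seed)
    stations = generate_stations(config, seed)
    villages = generate_villages(config, stations, seed)
    cov = generate_covariates(stations, villages, config, seed)
    traits = generate_traits(config, seed)

    records, truth = [], {}
    for land in config.landscapes:
        t = generate_community(config, land, seed)
        rec, t = simulate_detections(t, stations, cov, config, seed)
        records.append(rec)
        truth[land] = t
    records = pd.concat(records, ignore_index=True)

    bundle = {"config": config, "stations": stations, "villages": villages,
              "covariates": cov, "traits": traits, "records": records,
              "truth": truth}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rec_out = records.rename(columns={"unit_id": "species"})
        _io.write_detection_records(rec_out, outdir / "records.csv")
        _io.write_stations(stations, outdir / "stations.csv")
        _io.write_species_traits(traits, outdir / "traits.csv")
        _io.write_villages(villages, outdir / "villages.csv")
        cov.to_csv(outdir / "covariates.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump({k: v.to_jsonable() for k, v in truth.items()}, fh)
    return bundle
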