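"""Hierarchical Bayesian community occupancy model for camera-trap data.

The model follows the Royle–Dorazio multispecies occupancy formulation.
For species (analysis unit) i at station j in occasion k:

    z_ij ~ Bernoulli(psi_ij)
    logit(psi_ij) = alpha_{i, site[j]} + beta1_i * x1_j + beta2_i * x2_j
    y_ijk ~ Bernoulli(z_ij * p_ijk)
    logit(p_ijk) = alpha.p_i + beta.e_i * effort_jk

with z the latent true occupancy state and y the detections. Detection is
conditioned on the latent state (the z factor): a species absent from a
station cannot be detected there. Species-level parameters are draws from
community-level normal distributions,

    alpha_{i,s} ~ N(mu_alpha[s], sigma_alpha[s])     per site s
    beta1_i    ~ N(mu_beta1, sigma_beta1)            (canopy effect)
    beta2_i    ~ N(mu_beta2, sigma_beta2)            (village-density effect)
    alpha.p_i  ~ N(mu_p, sigma_p)
    beta.e_i   ~ N(mu_e, sigma_e)

which shares strength across species: rarely detected species borrow
information from the community. Hyperpriors are weakly informative:
community means ~ N(0, 2.25) on the logit scale, community standard
deviations ~ Uniform(0, 5).

Sampling is Metropolis-within-Gibbs:

* z from its exact full conditional (z_ij = 1 with certainty wherever the
  unit was detected; otherwise a Bernoulli on the posterior odds of
  presence given no detection in any active occasion);
* species-level parameters by adaptive random-walk Metropolis, proposed and
  accepted independently per species (their likelihoods are independent
  given the hyperparameters, so the whole community updates in one
  vectorized step);
* community means by their conjugate normal full conditionals;
* community standard deviations by shrinkage slice sampling on (0, upper).

Any sampler targeting the same posterior is equivalent; this one is chosen
for having no gradient requirements and exact z updates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit  # noqa: F401  (logit re-exported)

from ._kernels import det_scan
from .errors import ConfigurationError, ConvergenceWarning
from .histories import DetectionHistory

__all__ = [
    "OccupancyModelSpec", "MCMCConfig", "PosteriorSamples",
    "fit", "log_likelihood", "gelman_rubin", "summarize",
    "species_site_occupancy", "effect_sizes",
]

RHAT_THRESHOLD = 1.1


@dataclass
class OccupancyModelSpec:
    """Structure and priors of the community occupancy model.

    Parameters
    ----------
    covariates : tuple of str
        Names of the (normalized) station covariate columns on occupancy.
    prior_mean_sd : float
        Standard deviation of the N(0, .) hyperprior on community means
        (logit scale). 2.25 keeps induced probabilities near-uniform.
    sigma_upper : float
        Upper bound of the Uniform(0, .) hyperprior on community sds.
    hierarchical : bool
        If False, species-level parameters get independent N(0,
        prior_mean_sd) priors and no community level is fitted (used for
        single-species models and oracle checks).
    fix_detection : (float, float), optional
        Fix (alpha.p, beta.e) for all species to these values instead of
        sampling them (used for oracle checks).
    """

    covariates: tuple[str, str] = ("canopy_z", "village_density_z")
    prior_mean_sd: float = 2.25
    sigma_upper: float = 5.0
    hierarchical: bool = True
    fix_detection: tuple[float, float] | None = None


@dataclass
class MCMCConfig:
    """Chain settings. ``full()`` gives the full-scale run (3 chains of
    250,000 iterations, 20,000 burn-in, thinned by 20); ``desk()`` gives a
    settings block sized for workstation iteration and testing."""

    chains: int = 3
    iterations: int = 250_000
    burn_in: int = 20_000
    thin: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 1:
            raise ValueError("need at least one chain")

    @classmethod
    def full(cls, seed: int = 0) -> "MCMCConfig":
        return cls(chains=3, iterations=250_000, burn_in=20_000, thin=20, seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "MCMCConfig":
        return cls(chains=3, iterations=4_000, burn_in=1_000, thin=2, seed=seed)

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws, organized by chain.

    ``params`` maps parameter names to arrays with leading axes
    (chain, draw): species-level parameters have a trailing unit axis
    (``alpha`` additionally a site axis), hyperparameters are scalar per
    draw (``mu_alpha``/``sigma_alpha`` have a site axis).
    """

    params: dict[str, np.ndarray]
    units: list[str]
    sites: list[str]
    config: MCMCConfig
    spec: OccupancyModelSpec
    rhat: dict[str, np.ndarray] = field(default_factory=dict)
    converged: bool | None = None

    def stacked(self, name: str) -> np.ndarray:
        """Draws with chains concatenated: shape (chains*draws, ...)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]


def _softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)) = -log(1 - sigmoid(x)), overflow-safe."""
    return np.logaddexp(0.0, x)


def log_likelihood(z: np.ndarray, params: dict, history: DetectionHistory) -> float:
    """Joint detection log-likelihood of the data given a latent state.

    Sums, over every (unit, station, occasion) cell with positive effort,
    the Bernoulli log-mass of ``y`` under success probability
    ``z_ij * p_ijk`` with ``logit(p) = alpha_p + beta_eff * effort``.
    A detection at a station where ``z = 0`` is impossible and returns
    ``-inf``. Occasions with zero effort contribute nothing.

    Parameters
    ----------
    z : (n_units, n_stations) binary array
    params : dict with ``alpha_p`` and ``beta_eff`` per-unit arrays, and
        optionally ``effort`` overriding the (normalized) effort matrix.
    """
    y = history.y.astype(float)
    eff = np.asarray(params.get("effort", history.effort), dtype=float)
    mask = history.effort > 0
    z = np.asarray(z, dtype=float)
    if np.any((y == 1) & (z[:, :, None] == 0) & mask[None]):
        return -np.inf
    ap = np.asarray(params["alpha_p"], dtype=float)[:, None, None]
    be = np.asarray(params["beta_eff"], dtype=float)[:, None, None]
    lp = ap + be * eff[None]
    ll = y * lp - _softplus(lp)          # log Bern(y | p), z = 1
    ll = np.where(z[:, :, None] == 1, ll, 0.0)   # z = 0, y = 0 -> log 1
    return float(np.sum(ll * mask[None]))


def _normalize_effort(effort: np.ndarray) -> np.ndarray:
    """Z-score effort over active (effort > 0) cells; inactive cells 0."""
    mask = effort > 0
    vals = effort[mask]
    sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
    out = np.zeros_like(effort, dtype=float)
    if sd > 0:
        out[mask] = (vals - vals.mean()) / sd
    # constant positive effort carries no information; leave centered at 0
    return out


# ---------------------------------------------------------------------------
# sampler internals

class _AdaptiveScale:
    """Per-block random-walk scales tuned during burn-in to ~35% acceptance."""

    def __init__(self, shape, window: int = 50):
        self.scale = np.full(shape, 0.5)
        self.accepts = np.zeros(shape)
        self.window = window
        self.count = 0

    def record(self, accepted: np.ndarray) -> None:
        self.accepts += accepted
        self.count += 1
        if self.count >= self.window:
            rate = self.accepts / self.count
            self.scale *= np.exp(1.2 * (rate - 0.35))
            np.clip(self.scale, 1e-3, 20.0, out=self.scale)
            self.accepts[:] = 0.0
            self.count = 0


def _slice_sigma(sigma: float, theta: np.ndarray, mu: float, upper: float,
                 rng: np.random.Generator) -> float:
    """Shrinkage slice sample of a community sd with Uniform(0, upper) prior."""
    n = len(theta)
    ss = float(np.sum((theta - mu) ** 2))

    def logf(s):
        return -n * np.log(s) - ss / (2.0 * s * s)

    log_u = logf(sigma) - rng.exponential()
    lo, hi = 1e-8, upper
    for _ in range(100):
        prop = rng.uniform(lo, hi)
        if logf(prop) >= log_u:
            return prop
        if prop < sigma:
            lo = prop
        else:
            hi = prop
    return sigma


def _conjugate_mean(theta: np.ndarray, sigma: float, prior_sd: float,
                    rng: np.random.Generator) -> float:
    n = len(theta)
    prec = n / sigma ** 2 + 1.0 / prior_sd ** 2
    mean = (theta.sum() / sigma ** 2) / prec
    return rng.normal(mean, 1.0 / np.sqrt(prec))


def _run_chain(y, effort_z, mask, x1, x2, site_index, n_sites, spec, cfg,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    n_units, n_stations, n_occ = y.shape
    det_any = y.any(axis=2)
    yf = np.ascontiguousarray(y, dtype=np.float64)
    effort_z = np.ascontiguousarray(effort_z, dtype=np.float64)
    site_onehot = np.eye(n_sites)[site_index]             # (J, S)

    # --- state ---------------------------------------------------------
    alpha = rng.normal(0.0, 0.5, size=(n_units, n_sites))
    beta1 = rng.normal(0.0, 0.5, size=n_units)
    beta2 = rng.normal(0.0, 0.5, size=n_units)
    if spec.fix_detection is not None:
        ap = np.full(n_units, spec.fix_detection[0])
        be = np.full(n_units, spec.fix_detection[1])
    else:
        ap = rng.normal(-1.0, 0.5, size=n_units)
        be = rng.normal(0.0, 0.5, size=n_units)
    hyp = {"mu_alpha": np.zeros(n_sites), "sigma_alpha": np.ones(n_sites),
           "mu_beta1": 0.0, "sigma_beta1": 1.0,
           "mu_beta2": 0.0, "sigma_beta2": 1.0,
           "mu_p": 0.0, "sigma_p": 1.0,
           "mu_e": 0.0, "sigma_e": 1.0}
    z = det_any.astype(float)
    z[~det_any] = rng.random(size=(~det_any).sum()) < 0.5

    sc_alpha = _AdaptiveScale((n_units, n_sites))
    sc_b1 = _AdaptiveScale(n_units)
    sc_b2 = _AdaptiveScale(n_units)
    sc_det = _AdaptiveScale(n_units)

    def lpsi_of(a, b1, b2):
        return a[:, site_index] + b1[:, None] * x1[None] + b2[:, None] * x2[None]

    lpsi = lpsi_of(alpha, beta1, beta2)
    # detection scan for the current (ap, be); rows are refreshed in place
    # when a unit's proposal is accepted, so one fused scan per sweep
    # suffices. s_det[i, j] is the summed Bernoulli log-mass at station j
    # if the unit is present; log_q[i, j] is log P(no detection | present).
    s_det, log_q = det_scan(ap, be, effort_z, mask, yf)

    n_draws = cfg.n_draws
    store = {
        "alpha": np.empty((n_draws, n_units, n_sites)),
        "beta1": np.empty((n_draws, n_units)),
        "beta2": np.empty((n_draws, n_units)),
        "alpha_p": np.empty((n_draws, n_units)),
        "beta_eff": np.empty((n_draws, n_units)),
        "mu_alpha": np.empty((n_draws, n_sites)),
        "sigma_alpha": np.empty((n_draws, n_sites)),
    }
    for h in ("mu_beta1", "sigma_beta1", "mu_beta2", "sigma_beta2",
              "mu_p", "sigma_p", "mu_e", "sigma_e"):
        store[h] = np.empty(n_draws)

    kept = 0
    for it in range(cfg.iterations):
        adapting = it < cfg.burn_in

        # --- z | rest (exact full conditional) ---------------------------
        psi = expit(lpsi)
        with np.errstate(over="ignore"):
            odds = psi * np.exp(log_q)
        pz = odds / (odds + (1.0 - psi))
        z = np.where(det_any, 1.0,
                     (rng.random(size=psi.shape) < pz).astype(float))

        # --- detection parameters (alpha.p_i, beta.e_i jointly) ----------
        if spec.fix_detection is None:
            ll_cur = (s_det * z).sum(axis=1)
            ap_prop = ap + sc_det.scale * rng.standard_normal(n_units)
            be_prop = be + sc_det.scale * rng.standard_normal(n_units)
            s_prop, logq_prop = det_scan(ap_prop, be_prop, effort_z, mask, yf)
            ll_prop = (s_prop * z).sum(axis=1)
            if spec.hierarchical:
                pr_cur = (-(ap - hyp["mu_p"]) ** 2 / (2 * hyp["sigma_p"] ** 2)
                          - (be - hyp["mu_e"]) ** 2 / (2 * hyp["sigma_e"] ** 2))
                pr_prop = (-(ap_prop - hyp["mu_p"]) ** 2 / (2 * hyp["sigma_p"] ** 2)
                           - (be_prop - hyp["mu_e"]) ** 2 / (2 * hyp["sigma_e"] ** 2))
            else:
                s2 = 2 * spec.prior_mean_sd ** 2
                pr_cur = -(ap ** 2 + be ** 2) / s2
                pr_prop = -(ap_prop ** 2 + be_prop ** 2) / s2
            acc = np.log(rng.random(n_units)) < (ll_prop + pr_prop - ll_cur - pr_cur)
            ap = np.where(acc, ap_prop, ap)
            be = np.where(acc, be_prop, be)
            s_det[acc] = s_prop[acc]
            log_q[acc] = logq_prop[acc]
            if adapting:
                sc_det.record(acc)

        # --- occupancy parameters ----------------------------------------
        occ_cur = z * lpsi - _softplus(lpsi)              # (U, J)

        # alpha, blocked per (unit, site)
        d_alpha = sc_alpha.scale * rng.standard_normal((n_units, n_sites))
        lpsi_p = lpsi + d_alpha[:, site_index]
        occ_p = z * lpsi_p - _softplus(lpsi_p)
        d_ll = (occ_p - occ_cur) @ site_onehot            # (U, S)
        if spec.hierarchical:
            a_prop = alpha + d_alpha
            d_pr = ((alpha - hyp["mu_alpha"]) ** 2
                    - (a_prop - hyp["mu_alpha"]) ** 2) / (2 * hyp["sigma_alpha"] ** 2)
        else:
            a_prop = alpha + d_alpha
            d_pr = (alpha ** 2 - a_prop ** 2) / (2 * spec.prior_mean_sd ** 2)
        acc = np.log(rng.random((n_units, n_sites))) < (d_ll + d_pr)
        alpha = np.where(acc, a_prop, alpha)
        lpsi = lpsi + np.where(acc, d_alpha, 0.0)[:, site_index]
        if adapting:
            sc_alpha.record(acc)
        occ_cur = z * lpsi - _softplus(lpsi)

        # beta1, beta2 — one scalar block per unit each
        for bname, bvec, scale, xcov, mu_k, sd_k in (
                ("beta1", beta1, sc_b1, x1, "mu_beta1", "sigma_beta1"),
                ("beta2", beta2, sc_b2, x2, "mu_beta2", "sigma_beta2")):
            d_b = scale.scale * rng.standard_normal(n_units)
            lpsi_p = lpsi + d_b[:, None] * xcov[None]
            occ_p = z * lpsi_p - _softplus(lpsi_p)
            d_ll = (occ_p - occ_cur).sum(axis=1)
            b_prop = bvec + d_b
            if spec.hierarchical:
                d_pr = ((bvec - hyp[mu_k]) ** 2
                        - (b_prop - hyp[mu_k]) ** 2) / (2 * hyp[sd_k] ** 2)
            else:
                d_pr = (bvec ** 2 - b_prop ** 2) / (2 * spec.prior_mean_sd ** 2)
            acc = np.log(rng.random(n_units)) < (d_ll + d_pr)
            bvec[:] = np.where(acc, b_prop, bvec)
            lpsi = lpsi + np.where(acc, d_b, 0.0)[:, None] * xcov[None]
            occ_cur = z * lpsi - _softplus(lpsi)
            if adapting:
                scale.record(acc)

        # --- hyperparameters ---------------------------------------------
        if spec.hierarchical and n_units > 1:
            for s in range(n_sites):
                hyp["mu_alpha"][s] = _conjugate_mean(
                    alpha[:, s], hyp["sigma_alpha"][s], spec.prior_mean_sd, rng)
                hyp["sigma_alpha"][s] = _slice_sigma(
                    hyp["sigma_alpha"][s], alpha[:, s], hyp["mu_alpha"][s],
                    spec.sigma_upper, rng)
            for mu_k, sd_k, vec in (("mu_beta1", "sigma_beta1", beta1),
                                    ("mu_beta2", "sigma_beta2", beta2),
                                    ("mu_p", "sigma_p", ap),
                                    ("mu_e", "sigma_e", be)):
                if spec.fix_detection is not None and mu_k in ("mu_p", "mu_e"):
                    continue
                hyp[mu_k] = _conjugate_mean(vec, hyp[sd_k], spec.prior_mean_sd, rng)
                hyp[sd_k] = _slice_sigma(hyp[sd_k], vec, hyp[mu_k],
                                         spec.sigma_upper, rng)

        # guard against incremental drift in the maintained predictor
        if (it + 1) % 500 == 0:
            lpsi = lpsi_of(alpha, beta1, beta2)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_draws:
            store["alpha"][kept] = alpha
            store["beta1"][kept] = beta1
            store["beta2"][kept] = beta2
            store["alpha_p"][kept] = ap
            store["beta_eff"][kept] = be
            store["mu_alpha"][kept] = hyp["mu_alpha"]
            store["sigma_alpha"][kept] = hyp["sigma_alpha"]
            for h in ("mu_beta1", "sigma_beta1", "mu_beta2", "sigma_beta2",
                      "mu_p", "sigma_p", "mu_e", "sigma_e"):
                store[h][kept] = hyp[h]
            kept += 1

    return store


def fit(history: DetectionHistory,
        covariates: pd.DataFrame,
        spec: OccupancyModelSpec | None = None,
        mcmc: MCMCConfig | None = None,
        check_convergence: bool = True) -> PosteriorSamples:
    """Fit the community occupancy model by MCMC.

    Parameters
    ----------
    history : DetectionHistory
        Detection/effort tensors. Units never detected anywhere are
        excluded from the fit (the community model is fit to recorded
        species) with a warning.
    covariates : DataFrame
        Per-station table carrying ``station_id``, ``site_id`` and the
        normalized covariate columns named in ``spec.covariates``; aligned
        to ``history.stations`` by station_id.
    spec, mcmc : optional
        Model structure/priors and chain settings (defaults:
        :class:`OccupancyModelSpec` and ``MCMCConfig.desk()``).

    Returns
    -------
    PosteriorSamples
        With Gelman-Rubin diagnostics attached; a
        :class:`~defaunation.errors.ConvergenceWarning` is issued (never a
        silent pass) when any hyperparameter has R-hat >= 1.1.
    """
    spec = spec or OccupancyModelSpec()
    mcmc = mcmc or MCMCConfig.desk()

    cov = covariates.set_index("station_id").loc[history.stations]
    for name in spec.covariates:
        if name not in cov:
            raise ConfigurationError(f"covariate column {name!r} missing")
        col = cov[name].to_numpy(dtype=float)
        if np.unique(col).size < 2:
            raise ConfigurationError(
                f"covariate {name!r} is constant across stations")
    x1 = cov[spec.covariates[0]].to_numpy(dtype=float)
    x2 = cov[spec.covariates[1]].to_numpy(dtype=float)
    sites = list(pd.unique(cov["site_id"]))
    site_index = np.array([sites.index(s) for s in cov["site_id"]])

    det_any = history.y.any(axis=(1, 2))
    if not det_any.any():
        raise ConfigurationError("no unit has any detection; nothing to fit")
    if not det_any.all():
        dropped = [u for u, d in zip(history.units, det_any) if not d]
        warnings.warn(f"excluding {len(dropped)} never-detected unit(s) "
                      f"from the fit: {dropped}", stacklevel=2)
    y = history.y[det_any]
    units = [u for u, d in zip(history.units, det_any) if d]

    mask = history.effort > 0
    effort_z = _normalize_effort(history.effort)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [
        _run_chain(y, effort_z, mask, x1, x2, site_index, len(sites),
                   spec, mcmc, np.random.default_rng(s))
        for s in seeds
    ]
    params = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    samples = PosteriorSamples(params=params, units=units, sites=sites,
                               config=mcmc, spec=spec)
    if check_convergence and mcmc.chains >= 2:
        hyper_names = [k for k in params if k.startswith(("mu_", "sigma_"))]
        samples.rhat = gelman_rubin(samples, names=hyper_names)
        worst = max(float(np.max(v)) for v in samples.rhat.values())
        samples.converged = worst < RHAT_THRESHOLD
        if not samples.converged:
            warnings.warn(
                f"chains not converged: max R-hat {worst:.3f} >= "
                f"{RHAT_THRESHOLD}; run longer chains",
                ConvergenceWarning, stacklevel=2)
    return samples


# ---------------------------------------------------------------------------
# diagnostics and summaries

def _psrf(draws: np.ndarray) -> float:
    """Classic potential scale reduction factor for one scalar parameter.

    ``draws`` has shape (chains, n). Defined as 1 when the pooled draws
    have zero variance.
    """
    m, n = draws.shape
    chain_means = draws.mean(axis=1)
    w = draws.var(axis=1, ddof=1).mean()
    b_over_n = chain_means.var(ddof=1)
    var_plus = (n - 1) / n * w + b_over_n
    if var_plus == 0.0:
        return 1.0
    if w == 0.0:
        return np.inf
    return float(np.sqrt(var_plus / w))


def gelman_rubin(samples: PosteriorSamples | dict,
                 names: list[str] | None = None) -> dict[str, np.ndarray]:
    """Gelman-Rubin R-hat per scalar element of each parameter.

    Requires at least two chains and ten retained draws. Values near 1
    indicate the chains are sampling the same distribution; the package
    flags R-hat >= 1.1 as non-convergence.
    """
    params = samples.params if isinstance(samples, PosteriorSamples) else samples
    out = {}
    for name in (names or params):
        a = np.asarray(params[name], dtype=float)
        if a.ndim < 2 or a.shape[0] < 2:
            raise ValueError("gelman_rubin needs >= 2 chains of draws")
        if a.shape[1] < 10:
            raise ValueError("gelman_rubin needs >= 10 draws per chain")
        flat = a.reshape(a.shape[0], a.shape[1], -1)
        r = np.array([_psrf(flat[:, :, p]) for p in range(flat.shape[2])])
        out[name] = r.reshape(a.shape[2:]) if a.ndim > 2 else r[0]
    return out


PERCENTILES = (2.5, 12.5, 87.5, 97.5)


def _summary_row(draws: np.ndarray) -> dict:
    qs = np.percentile(draws, PERCENTILES)
    return {"mean": draws.mean(), "sd": draws.std(ddof=1),
            "q2.5": qs[0], "q12.5": qs[1], "q87.5": qs[2], "q97.5": qs[3]}


def summarize(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean, sd, and 75%/95% credible intervals per parameter.

    Intervals are percentile BCIs: (12.5, 87.5) and (2.5, 97.5) percentiles
    of the pooled draws (linear-interpolation percentile convention).
    Rows are indexed by parameter element, e.g. ``beta1[Manis spp.]`` or
    ``mu_alpha[site2]``.
    """
    rows = {}
    for name, a in samples.params.items():
        flat = samples.stacked(name)
        if flat.ndim == 1:
            rows[name] = _summary_row(flat)
        elif flat.ndim == 2:
            labels = samples.sites if flat.shape[1] == len(samples.sites) and \
                name.endswith("alpha") else samples.units
            for idx in range(flat.shape[1]):
                rows[f"{name}[{labels[idx]}]"] = _summary_row(flat[:, idx])
        else:  # alpha: unit x site
            for i, u in enumerate(samples.units):
                for s, site in enumerate(samples.sites):
                    rows[f"{name}[{u},{site}]"] = _summary_row(flat[:, i, s])
    df = pd.DataFrame(rows).T
    df.index.name = "parameter"
    return df


def species_site_occupancy(samples: PosteriorSamples,
                           covariates: pd.DataFrame,
                           stations: list[str] | None = None,
                           chunk: int = 500) -> np.ndarray:
    """Posterior draws of site-level occupancy per unit.

    For each retained draw, evaluates psi at every station from that draw's
    species parameters and the station's covariates, then averages stations
    within each site: the site-level occupancy of a unit is its mean
    station-level occupancy probability. Returns an array of shape
    (total_draws, n_units, n_sites) ordered as ``samples.sites``.
    """
    cov = covariates.set_index("station_id")
    if stations is not None:
        cov = cov.loc[stations]
    x1 = cov[samples.spec.covariates[0]].to_numpy(dtype=float)
    x2 = cov[samples.spec.covariates[1]].to_numpy(dtype=float)
    site_index = np.array([samples.sites.index(s) for s in cov["site_id"]])
    counts = np.bincount(site_index, minlength=len(samples.sites))
    if np.any(counts == 0):
        empty = [s for s, c in zip(samples.sites, counts) if c == 0]
        raise ValueError(f"site(s) with zero stations: {empty}")
    # (J, S) averaging matrix: column s has weight 1/n_s on site-s stations
    onehot = np.eye(len(samples.sites))[site_index] / counts[None, :]

    alpha = samples.stacked("alpha")          # (D, U, S)
    beta1 = samples.stacked("beta1")          # (D, U)
    beta2 = samples.stacked("beta2")
    n_draws = alpha.shape[0]
    out = np.empty((n_draws, alpha.shape[1], len(samples.sites)))
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        lpsi = (alpha[lo:hi][:, :, site_index]
                + beta1[lo:hi, :, None] * x1[None, None]
                + beta2[lo:hi, :, None] * x2[None, None])
        out[lo:hi] = expit(lpsi) @ onehot
    return out


def effect_sizes(samples: PosteriorSamples) -> pd.DataFrame:
    """Covariate effect-size summaries per unit plus community averages.

    For each unit's beta1 (canopy) and beta2 (village density): posterior
    mean, sd, 75% and 95% BCIs, and flags for whether each interval
    excludes zero — the criterion used to call an effect. Community rows
    summarize the community means mu_beta1 / mu_beta2 the same way.
    """
    rows = []
    for name, label in (("beta1", samples.spec.covariates[0]),
                        ("beta2", samples.spec.covariates[1])):
        flat = samples.stacked(name)
        for i, u in enumerate(samples.units):
            r = _summary_row(flat[:, i])
            rows.append({"covariate": label, "unit": u, **r,
                         "excludes_zero_75": _excludes(r, "q12.5", "q87.5"),
                         "excludes_zero_95": _excludes(r, "q2.5", "q97.5")})
        mu = samples.stacked(f"mu_{name}")
        r = _summary_row(mu)
        rows.append({"covariate": label, "unit": "(community mean)", **r,
                     "excludes_zero_75": _excludes(r, "q12.5", "q87.5"),
                     "excludes_zero_95": _excludes(r, "q2.5", "q97.5")})
    return pd.DataFrame(rows)


def _excludes(row: dict, lo: str, hi: str) -> bool:
    return bool(row[lo] > 0.0 or row[hi] < 0.0)
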