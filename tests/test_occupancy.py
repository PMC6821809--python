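import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from defaunation.histories import DetectionHistory
from defaunation.occupancy import (MCMCConfig, OccupancyModelSpec,
                                   PosteriorSamples, effect_sizes, fit,
                                   gelman_rubin, log_likelihood,
                                   species_site_occupancy, summarize)


def make_history(y, effort, occasion_length=10):
    y = np.asarray(y, dtype=np.uint8)
    return DetectionHistory(
        y=y, effort=np.asarray(effort, dtype=float),
        units=[f"u{i}" for i in range(y.shape[0])],
        stations=[f"s{j}" for j in range(y.shape[1])],
        occasion_length=occasion_length)


class TestLogLikelihood:
    def test_single_cell_half(self):
        hist = make_history([[[1]]], [[10.0]])
        ll = log_likelihood(np.array([[1]]),
                            {"alpha_p": [0.0], "beta_eff": [0.0],
                             "effort": np.array([[0.0]])}, hist)
        assert ll == pytest.approx(math.log(0.5))

    def test_absent_station_contributes_zero(self):
        hist = make_history([[[0, 0, 0]]], [[10.0, 10.0, 5.0]])
        ll = log_likelihood(np.array([[0]]),
                            {"alpha_p": [0.3], "beta_eff": [1.0]}, hist)
        assert ll == 0.0

    def test_detection_with_z_zero_impossible(self):
        hist = make_history([[[1]]], [[10.0]])
        ll = log_likelihood(np.array([[0]]),
                            {"alpha_p": [0.0], "beta_eff": [0.0]}, hist)
        assert ll == -np.inf

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        y = (rng.random((3, 4, 5)) < 0.3).astype(np.uint8)
        effort = rng.uniform(1, 10, size=(4, 5))
        effort[2, 4] = 0.0
        y[:, 2, 4] = 0
        z = np.ones((3, 4), dtype=int)
        z[y.any(axis=2) == 0] = rng.integers(0, 2, size=(z[y.any(axis=2) == 0]).shape)
        y[z == 0] = 0
        ap, be = rng.normal(size=3), rng.normal(size=3)
        hist = make_history(y, effort)
        expected = 0.0
        for i in range(3):
            for j in range(4):
                for k in range(5):
                    if effort[j, k] <= 0:
                        continue
                    p = expit(ap[i] + be[i] * effort[j, k]) * z[i, j]
                    expected += math.log(p if y[i, j, k] else 1 - p)
        got = log_likelihood(z, {"alpha_p": ap, "beta_eff": be}, hist)
        assert got == pytest.approx(expected)


class TestGelmanRubin:
    def test_identical_chains_unity(self):
        draws = np.tile(np.random.default_rng(0).normal(size=1000), (3, 1))
        r = gelman_rubin({"x": draws})["x"]
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        r = gelman_rubin({"x": chains})["x"]
        assert r > 1.5
        # direct formula evaluation as the oracle
        w = chains.var(axis=1, ddof=1).mean()
        b_over_n = chains.mean(axis=1).var(ddof=1)
        expected = math.sqrt((999 / 1000) * w / w + b_over_n / w)
        assert r == pytest.approx(expected)

    def test_well_mixed_chains_near_unity(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 5000))
        assert gelman_rubin({"x": chains})["x"] < 1.05

    def test_single_chain_error(self):
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin({"x": np.zeros((1, 100))})

    def test_zero_variance_defined_as_one(self):
        assert gelman_rubin({"x": np.zeros((3, 100))})["x"] == 1.0


def make_samples(params, units=("u0",), sites=("A",)):
    return PosteriorSamples(
        params=params, units=list(units), sites=list(sites),
        config=MCMCConfig(chains=2, iterations=40, burn_in=20, thin=1, seed=0),
        spec=OccupancyModelSpec())


class TestSummarize:
    def test_constant_draws(self):
        s = make_samples({"mu_beta1": np.full((2, 50), 3.5)})
        row = summarize(s).loc["mu_beta1"]
        assert row["mean"] == 3.5 and row["sd"] == 0.0
        assert row["q2.5"] == row["q97.5"] == 3.5

    def test_percentile_convention(self):
        draws = np.arange(1.0, 101.0).reshape(2, 50)
        row = summarize(make_samples({"mu_beta1": draws})).loc["mu_beta1"]
        assert row["q2.5"] == pytest.approx(3.475)
        assert row["q97.5"] == pytest.approx(97.525)

    def test_bci75_nested_in_bci95(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(size=(2, 400))
        row = summarize(make_samples({"mu_beta1": draws})).loc["mu_beta1"]
        assert row["q2.5"] <= row["q12.5"] <= row["q87.5"] <= row["q97.5"]


class TestSpeciesSiteOccupancy:
    def cov_frame(self, x1, x2, sites):
        return pd.DataFrame({
            "station_id": [f"s{j}" for j in range(len(x1))],
            "site_id": sites, "canopy_z": x1, "village_density_z": x2})

    def test_point_mass_zero_covariates(self):
        a = 0.7
        s = make_samples({
            "alpha": np.full((2, 30, 1, 1), a),
            "beta1": np.zeros((2, 30, 1)), "beta2": np.zeros((2, 30, 1))})
        cov = self.cov_frame([0.0, 0.0], [0.0, 0.0], ["A", "A"])
        psi = species_site_occupancy(s, cov)
        np.testing.assert_allclose(psi, expit(a))

    def test_single_station_site(self):
        rng = np.random.default_rng(7)
        s = make_samples({
            "alpha": rng.normal(size=(2, 20, 1, 1)),
            "beta1": rng.normal(size=(2, 20, 1)),
            "beta2": rng.normal(size=(2, 20, 1))})
        cov = self.cov_frame([0.8], [-0.3], ["A"])
        psi = species_site_occupancy(s, cov)
        flat_a = s.stacked("alpha")[:, 0, 0]
        expected = expit(flat_a + s.stacked("beta1")[:, 0] * 0.8
                         + s.stacked("beta2")[:, 0] * -0.3)
        np.testing.assert_allclose(psi[:, 0, 0], expected)

    def test_matches_brute_force_station_average(self):
        rng = np.random.default_rng(8)
        s = make_samples({
            "alpha": rng.normal(size=(2, 10, 2, 2)),
            "beta1": rng.normal(size=(2, 10, 2)),
            "beta2": rng.normal(size=(2, 10, 2))},
            units=("u0", "u1"), sites=("A", "B"))
        x1 = [0.1, -0.4, 0.9, 0.0]
        x2 = [1.0, 0.2, -0.7, 0.3]
        sites = ["A", "A", "B", "B"]
        cov = self.cov_frame(x1, x2, sites)
        psi = species_site_occupancy(s, cov)
        alpha, b1, b2 = (s.stacked(k) for k in ("alpha", "beta1", "beta2"))
        for d in range(alpha.shape[0]):
            for i in range(2):
                per_station = [
                    expit(alpha[d, i, ("A", "B").index(sites[j])]
                          + b1[d, i] * x1[j] + b2[d, i] * x2[j])
                    for j in range(4)]
                assert psi[d, i, 0] == pytest.approx(
                    np.mean(per_station[:2]))
                assert psi[d, i, 1] == pytest.approx(
                    np.mean(per_station[2:]))

    def test_empty_site_error(self):
        s = make_samples({"alpha": np.zeros((2, 5, 1, 2)),
                          "beta1": np.zeros((2, 5, 1)),
                          "beta2": np.zeros((2, 5, 1))}, sites=("A", "B"))
        cov = self.cov_frame([0.0, 1.0], [0.0, 1.0], ["A", "A"])
        with pytest.raises(ValueError, match="zero stations"):
            species_site_occupancy(s, cov)


class TestEffectSizes:
    def params(self, b1, b2):
        return {"beta1": b1, "beta2": b2,
                "mu_beta1": b1[:, :, 0], "mu_beta2": b2[:, :, 0]}

    def test_all_positive_flags(self):
        b1 = np.abs(np.random.default_rng(0).normal(2, 0.1, (2, 100, 1)))
        b2 = np.random.default_rng(1).normal(0, 1, (2, 100, 1))
        out = effect_sizes(make_samples(self.params(b1, b2)))
        row = out[(out["unit"] == "u0")
                  & (out["covariate"] == "canopy_z")].iloc[0]
        assert row["excludes_zero_95"] and row["excludes_zero_75"]

    def test_symmetric_draws_no_flags(self):
        rng = np.random.default_rng(3)
        b = rng.normal(0, 1, (2, 300, 1))
        out = effect_sizes(make_samples(self.params(b, b)))
        assert not out["excludes_zero_75"].any()

    def test_flags_equal_brute_force_percentiles(self):
        rng = np.random.default_rng(4)
        b1 = rng.normal(0.4, 0.5, (2, 200, 1))
        b2 = rng.normal(-0.2, 0.3, (2, 200, 1))
        out = effect_sizes(make_samples(self.params(b1, b2)))
        for name, draws in (("canopy_z", b1), ("village_density_z", b2)):
            row = out[(out["unit"] == "u0") & (out["covariate"] == name)].iloc[0]
            lo75, hi75 = np.percentile(draws.ravel(), [12.5, 87.5])
            lo95, hi95 = np.percentile(draws.ravel(), [2.5, 97.5])
            assert row["excludes_zero_75"] == (lo75 > 0 or hi75 < 0)
            assert row["excludes_zero_95"] == (lo95 > 0 or hi95 < 0)


class TestFit:
    """Sampler behavior on small problems; full-scale accuracy checks live
    with the acceptance suite."""

    def small_inputs(self, seed=0, n_units=4, n_stations=16):
        rng = np.random.default_rng(seed)
        x1 = rng.standard_normal(n_stations)
        x2 = rng.standard_normal(n_stations)
        psi = expit(0.3 + 0.8 * x1)
        z = rng.random((n_units, n_stations)) < psi
        p = 0.4
        y = ((rng.random((n_units, n_stations, 5)) < p)
             & z[:, :, None]).astype(np.uint8)
        effort = np.full((n_stations, 5), 10.0)
        effort[:, -1] = rng.integers(1, 11, n_stations)
        hist = make_history(y, effort)
        cov = pd.DataFrame({"station_id": hist.stations, "site_id": "A",
                            "canopy_z": x1, "village_density_z": x2})
        return hist, cov

    def test_never_detected_units_excluded(self):
        hist, cov = self.small_inputs()
        hist.y[1] = 0
        with pytest.warns(UserWarning, match="never-detected"):
            s = fit(hist, cov, mcmc=MCMCConfig(chains=2, iterations=200,
                                               burn_in=100, thin=1, seed=0),
                    check_convergence=False)
        assert s.units == ["u0", "u2", "u3"]

    def test_constant_covariate_rejected(self):
        hist, cov = self.small_inputs()
        cov["canopy_z"] = 0.0
        from defaunation.errors import ConfigurationError
        with pytest.raises(ConfigurationError, match="constant"):
            fit(hist, cov)

    def test_fixed_seed_reproducible(self):
        hist, cov = self.small_inputs()
        cfg = MCMCConfig(chains=2, iterations=300, burn_in=100, thin=2, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(hist, cov, mcmc=cfg, check_convergence=False)
            b = fit(hist, cov, mcmc=cfg, check_convergence=False)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_station_permutation_leaves_posterior_invariant(self):
        """Station order is arbitrary; posterior summaries must agree up to
        Monte-Carlo error between the original and a permuted dataset."""
        hist, cov = self.small_inputs(seed=3, n_units=3, n_stations=12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(hist.n_stations)
        hist_p = DetectionHistory(
            y=hist.y[:, perm], effort=hist.effort[perm],
            units=hist.units, stations=[hist.stations[j] for j in perm],
            occasion_length=hist.occasion_length)
        cfg = MCMCConfig(chains=3, iterations=4000, burn_in=1000, thin=2, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s_a = fit(hist, cov, mcmc=cfg, check_convergence=False)
            s_b = fit(hist_p, cov, mcmc=cfg, check_convergence=False)
        for k in ("beta1", "alpha"):
            ma = s_a.stacked(k).mean(axis=0)
            mb = s_b.stacked(k).mean(axis=0)
            sa = s_a.stacked(k).std(axis=0)
            np.testing.assert_array_less(np.abs(ma - mb), 0.35 * sa + 0.05)

    def test_psi_probabilities_in_open_unit_interval(self):
        hist, cov = self.small_inputs()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = fit(hist, cov, mcmc=MCMCConfig(chains=2, iterations=400,
                                               burn_in=200, thin=2, seed=1),
                    check_convergence=False)
        psi = species_site_occupancy(s, cov)
        assert np.all((psi > 0) & (psi < 1))

    def test_logit_logistic_round_trip(self):
        x = np.linspace(-20, 20, 101)
        np.testing.assert_allclose(logit(expit(x)), x, atol=1e-9)
        p = np.linspace(1e-9, 1 - 1e-9, 101)
        np.testing.assert_allclose(expit(logit(p)), p, atol=1e-12)
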