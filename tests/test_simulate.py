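import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from defaunation.histories import build_detection_history
from defaunation.simulate import (ScenarioConfig, generate_community,
                                  generate_covariates, generate_stations,
                                  generate_traits, generate_villages,
                                  survey_scale_fixture, simulate_detections)


def nn_mean(xy):
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1).mean()


class TestGenerateStations:
    def test_nearest_neighbor_spacing(self):
        cfg = ScenarioConfig(landscapes=("degraded",), sites_per_landscape=1,
                             stations_per_site=80, seed=0)
        st = generate_stations(cfg)
        m = nn_mean(st[["x", "y"]].to_numpy())
        assert 0.9 * cfg.spacing <= m <= 1.1 * cfg.spacing

    def test_four_station_spacing(self):
        cfg = ScenarioConfig(landscapes=("degraded",), sites_per_landscape=1,
                             stations_per_site=4, seed=1)
        m = nn_mean(generate_stations(cfg)[["x", "y"]].to_numpy())
        assert 2_250 <= m <= 2_750

    def test_deterministic_under_seed(self):
        cfg = ScenarioConfig(seed=3)
        pd.testing.assert_frame_equal(generate_stations(cfg),
                                      generate_stations(cfg))

    def test_single_station_fine(self):
        cfg = ScenarioConfig(landscapes=("degraded",), sites_per_landscape=1,
                             stations_per_site=1, seed=0)
        assert len(generate_stations(cfg)) == 1

    def test_infeasible_spacing_raises(self):
        cfg = ScenarioConfig(stations_per_site=400, max_site_extent=10_000.0)
        with pytest.raises(ValueError, match="extent"):
            generate_stations(cfg)

    def test_deployments_cover_design_minimum(self):
        st = generate_stations(ScenarioConfig(seed=2))
        days = [(e - s).days + 1
                for s, e in zip(st["deploy_start"], st["deploy_end"])]
        assert min(days) >= 60


class TestGenerateCovariates:
    def test_canopy_moments_hit_target(self):
        cfg = ScenarioConfig(landscapes=("degraded",), seed=4,
                             canopy_moments={"degraded": (0.8, 0.05)})
        st = generate_stations(cfg)
        v = generate_villages(cfg, st)
        cov = generate_covariates(st, v, cfg)
        assert cov["canopy"].mean() == pytest.approx(0.8, abs=0.03)

    def test_canopy_bounded(self):
        cfg = ScenarioConfig(seed=5)
        st = generate_stations(cfg)
        cov = generate_covariates(st, generate_villages(cfg, st), cfg)
        assert cov["canopy"].between(0, 1).all()

    def test_zero_villages_zero_density(self):
        cfg = ScenarioConfig(landscapes=("degraded",), seed=6,
                             villages_per_landscape={"degraded": 0})
        st = generate_stations(cfg)
        villages = generate_villages(cfg, st)
        assert len(villages) == 0
        from defaunation.covariates import village_density
        assert np.all(village_density(st, villages) == 0.0)


class TestGenerateCommunity:
    def test_zero_sigma_collapses_to_mean(self):
        from defaunation.simulate import CommunityHyperparams
        h = CommunityHyperparams(sigma_alpha=0, sigma_beta1=0, sigma_beta2=0,
                                 sigma_p=0, sigma_e=0)
        cfg = ScenarioConfig(landscapes=("degraded",), hypers={"degraded": h},
                             seed=7)
        t = generate_community(cfg, "degraded")
        assert np.all(t.alpha == h.mu_alpha)
        assert np.all(t.beta1 == h.mu_beta1)

    def test_clt_check_on_community_mean(self):
        cfg = ScenarioConfig(n_units=400, landscapes=("degraded",), seed=8)
        t = generate_community(cfg, "degraded")
        h = cfg.hypers["degraded"]
        tol = 3 * h.sigma_beta1 / np.sqrt(cfg.n_units)
        assert abs(t.beta1.mean() - h.mu_beta1) < tol

    def test_reproducible(self):
        cfg = ScenarioConfig(seed=9)
        a = generate_community(cfg, "hunted")
        b = generate_community(cfg, "hunted")
        np.testing.assert_array_equal(a.beta2, b.beta2)


class TestSimulateDetections:
    def small_cfg(self, **kw):
        kw.setdefault("landscapes", ("degraded",))
        kw.setdefault("sites_per_landscape", 1)
        kw.setdefault("stations_per_site", 20)
        kw.setdefault("n_units", 5)
        kw.setdefault("seed", 10)
        return ScenarioConfig(**kw)

    def build(self, cfg):
        st = generate_stations(cfg)
        cov = generate_covariates(st, generate_villages(cfg, st), cfg)
        truth = generate_community(cfg, cfg.landscapes[0])
        return st, cov, truth

    def test_impossible_occupancy_no_records(self):
        cfg = self.small_cfg()
        st, cov, truth = self.build(cfg)
        truth.alpha[:] = -50.0
        truth.beta1[:] = 0.0
        truth.beta2[:] = 0.0
        rec, _ = simulate_detections(truth, st, cov, cfg)
        assert len(rec) == 0

    def test_certain_detection_fills_tensor(self):
        cfg = self.small_cfg()
        st, cov, truth = self.build(cfg)
        truth.alpha[:] = 50.0
        truth.beta1[:] = 0.0
        truth.beta2[:] = 0.0
        truth.alpha_p[:] = 50.0
        truth.beta_eff[:] = 0.0
        rec, t = simulate_detections(truth, st, cov, cfg)
        # every active (station, occasion) cell is detected for every unit
        from defaunation.histories import station_effort
        active = (np.stack([np.pad(station_effort(
            (e - s).days + 1, cfg.occasion_length),
            (0, t.y.shape[2] - len(station_effort((e - s).days + 1,
                                                  cfg.occasion_length))))
            for s, e in zip(st["deploy_start"], st["deploy_end"])]) > 0)
        expected = np.broadcast_to(active, t.y.shape)
        np.testing.assert_array_equal(t.y, expected.astype(np.uint8))

    def test_records_respect_deployment_windows(self):
        cfg = self.small_cfg(seed=11)
        st, cov, truth = self.build(cfg)
        rec, _ = simulate_detections(truth, st, cov, cfg)
        windows = {r.station_id: (r.deploy_start, r.deploy_end)
                   for r in st.itertuples(index=False)}
        for row in rec.itertuples(index=False):
            lo, hi = windows[row.station_id]
            assert lo <= row.date <= hi

    def test_round_trip_reproduces_tensor(self):
        cfg = self.small_cfg(seed=12)
        st, cov, truth = self.build(cfg)
        rec, t = simulate_detections(truth, st, cov, cfg)
        hist = build_detection_history(rec, st, units=t.units,
                                       occasion_length=cfg.occasion_length)
        np.testing.assert_array_equal(hist.y, t.y)

    def test_presence_frequency_matches_closed_form(self):
        """At many stations, the fraction of stations where a unit is seen
        at least once converges to psi * (1 - (1-p)^K)."""
        cfg = ScenarioConfig(
            landscapes=("degraded",), sites_per_landscape=1,
            stations_per_site=500, n_units=6, seed=13,
            deployment_extra_days=0,  # constant effort: closed form exact
            max_site_extent=100_000.0)
        st = generate_stations(cfg)
        cov = generate_covariates(st, generate_villages(cfg, st), cfg)
        truth = generate_community(cfg, "degraded")
        # flat covariate response so every station shares psi and p
        truth.beta1[:] = 0.0
        truth.beta2[:] = 0.0
        truth.beta_eff[:] = 0.0
        truth.alpha[:] = truth.alpha[:, :1]
        rec, t = simulate_detections(truth, st, cov, cfg)
        from scipy.special import expit
        n_occ = t.y.shape[2]
        for i in range(cfg.n_units):
            psi = expit(t.alpha[i, 0])
            p = expit(t.alpha_p[i])
            expect = psi * (1 - (1 - p) ** n_occ)
            observed = t.y[i].any(axis=1).mean()
            tol = 3 * np.sqrt(expect * (1 - expect) / 500)
            assert abs(observed - expect) < tol


class TestPaperScaleFixture:
    def test_bundle_loads_through_io(self, tmp_path, small_scenario):
        import defaunation.io as dio
        survey_scale_fixture(seed=7, outdir=tmp_path, config=small_scenario)
        rec = dio.read_detection_records(tmp_path / "records.csv")
        st = dio.read_stations(tmp_path / "stations.csv")
        tr = dio.read_species_traits(tmp_path / "traits.csv")
        vil = dio.read_villages(tmp_path / "villages.csv")
        assert len(st) == 24 and len(tr) == 8
        merged = dio.merge_to_analysis_units(rec, tr)
        assert set(merged["unit_id"]) <= set(tr["unit_id"])
        assert len(vil) == 5

    def test_traits_valid(self):
        tr = generate_traits(ScenarioConfig(seed=14))
        assert (tr["body_mass_g"] > 500).all()
        assert tr["iucn"].isin(["LC", "NT", "VU", "EN", "CR", "DD"]).all()
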