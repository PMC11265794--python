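"""Ground-truth generator: determinism, internal consistency, physical scales."""

import numpy as np
import pytest

from mechwarp import mechanics as mech
from mechwarp import optics, synthetic
from mechwarp.erism import DisplacementMap
from mechwarp.synthetic import CrawlScenario, ScenarioError


class TestScenarioValidation:
    def test_overlapping_protopodia_rejected(self):
        with pytest.raises(ScenarioError):
            CrawlScenario(spacing_um=10.0)

    def test_wave_before_settling_rejected(self):
        with pytest.raises(ScenarioError):
            CrawlScenario(wave_start_s=0.2)

    def test_depth_list_length_checked(self):
        with pytest.raises(ScenarioError):
            CrawlScenario(peak_depths_nm=(500.0, 600.0)).depths


class TestSimulateCrawl:
    def test_deterministic_for_fixed_seed(self):
        sc = CrawlScenario(n_protopodia=2, shape=(48, 96), seed=9, intensity_noise=0.01)
        b1 = synthetic.simulate_crawl(sc)
        b2 = synthetic.simulate_crawl(sc)
        assert np.array_equal(b1.displacement, b2.displacement)
        assert np.array_equal(b1.grf, b2.grf)

    def test_zero_depth_produces_nothing(self):
        sc = CrawlScenario(n_protopodia=1, peak_depths_nm=(0.0,), shape=(48, 64),
                           tripod_enabled=False)
        b = synthetic.simulate_crawl(sc)
        assert np.abs(b.displacement).max() == 0.0
        assert len(b.events) == 0

    def test_single_footfall_grf_matches_forward_load(self):
        # the inverted stress map must integrate back to the generating load
        sc = CrawlScenario(n_protopodia=1, shape=(64, 64), peak_depths_nm=(800.0,),
                           tripod_enabled=False)
        b = synthetic.simulate_crawl(sc)
        grf = b.grf[:, 0]
        peak = grf.max()
        f = int(0.85 * sc.map_rate)  # fully settled stance
        m = mech.SubstrateMechanics(sc.substrate_E_pa, 0.495, sc.rest_thickness_nm, 1.0)
        d = DisplacementMap(b.displacement[f].astype(float), 1.0, (0, 0, 0),
                            np.ones(sc.shape, bool))
        inverted = mech.integrate_grf(
            mech.stress_from_displacement(d, m, 1e-3), b.rois[0]
        )
        assert inverted == pytest.approx(b.grf[f, 0], rel=0.02)
        # single footfall: dips to zero during swing, returns to stance level
        wv = synthetic.scenario_waves(sc)[0]
        mid_swing = int((wv["si"][0] + 0.3) * sc.map_rate)
        assert grf[mid_swing] < 0.05 * peak

    def test_default_scenario_grfs_in_micronewton_range(self):
        b = synthetic.simulate_crawl(CrawlScenario())
        peaks = b.grf.max(axis=0)
        assert np.all(peaks >= 1000.0) and np.all(peaks <= 7000.0)  # 1-7 uN in nN

    def test_truth_consistency_with_mechanics_roi_integrals(self):
        sc = CrawlScenario(n_protopodia=2, shape=(48, 96))
        b = synthetic.simulate_crawl(sc)
        f = int(0.5 * sc.map_rate)  # during initial stance
        d = DisplacementMap(
            b.displacement[f].astype(float), sc.pixel_size_um, (0, 0, 0),
            np.ones(sc.shape, bool),
        )
        for i in range(2):
            area, _ = mech.contact_area(d, b.rois[i], sc.contact_threshold_nm)
            vol = mech.displaced_volume(d, b.rois[i])
            assert area == b.area[f, i]
            assert vol == pytest.approx(b.volume[f, i], rel=1e-6)

    def test_quadratic_grf_area_law_recovered(self):
        law = (0.02, 1.0, 0.0)
        sc = CrawlScenario(n_protopodia=2, shape=(48, 96), grf_area_law=law)
        b = synthetic.simulate_crawl(sc)
        pts = np.column_stack([b.area.ravel(), b.grf.ravel()])
        pts = pts[pts[:, 0] > 0]
        _, adj = mech.fit_grf_area_polynomial(pts)
        assert adj > 0.95

    def test_droplet_ring_adds_upward_annulus(self):
        sc = CrawlScenario(n_protopodia=1, shape=(64, 64), droplet_enabled=True,
                           tripod_enabled=False, peak_depths_nm=(300.0,),
                           droplet_radius_um=25.0)
        b = synthetic.simulate_crawl(sc)
        assert b.displacement.max() >= 0.9 * sc.droplet_amplitude_nm

    def test_events_and_tripod_timing(self):
        sc = CrawlScenario()
        b = synthetic.simulate_crawl(sc)
        assert len(b.events) == sc.n_protopodia
        a7_si = b.events[b.events.protopodium == 1].si_time.iloc[0]
        assert b.tripod_contacts[0] == pytest.approx(a7_si - sc.tripod_lead_s)


class TestHertzProfile:
    def test_continuous_at_contact_edge(self):
        depth, R = 900.0, 100.0
        a = np.sqrt(R * depth * 1e-3)
        u_in = synthetic.hertz_indentation_profile(np.array([a - 1e-6]), depth, R)
        u_out = synthetic.hertz_indentation_profile(np.array([a + 1e-6]), depth, R)
        assert u_in[0] == pytest.approx(u_out[0], abs=0.01)
        assert u_in[0] == pytest.approx(-depth / 2, abs=0.01)

    def test_peak_equals_depth(self):
        u = synthetic.hertz_indentation_profile(np.array([0.0]), 700.0, 50.0)
        assert u[0] == pytest.approx(-700.0, abs=1e-9)

    def test_compact_support_with_taper(self):
        depth, R, w = 700.0, 50.0, 3.0
        a = np.sqrt(R * depth * 1e-3)
        u = synthetic.hertz_indentation_profile(np.array([a + 3 * w + 0.1]), depth, R, w)
        assert u[0] == 0.0


class TestRenderInterference:
    def test_uniform_scene_minima_match_model(self, stack, grid, lookup):
        s = synthetic.render_interference(np.full((8, 8), 9000.0), stack, grid=grid)
        spec = s.frames[:, 4, 4] / 1000.0
        got = optics.find_resonance_minima(np.column_stack([grid.wavelengths, spec]))
        model = optics.reflectance_spectrum(stack, grid, 9000.0)
        expect = optics.find_resonance_minima(np.column_stack([grid.wavelengths, model]))
        assert np.allclose(got, expect, atol=1e-9)
        # every pixel identical
        assert np.ptp(s.frames, axis=(1, 2)).max() == 0.0

    def test_static_two_wavelength_ratio_constant(self, stack):
        video = synthetic.render_interference(
            np.full((6, 8, 8), 9500.0), stack, mode="two_wavelength"
        )
        lam, theta = video.frames[0::2], video.frames[1::2]
        W = (lam - theta) / (lam + theta)
        assert np.ptp(W, axis=0).max() < 1e-12

    def test_lambda_frame_first(self, stack):
        video = synthetic.render_interference(
            np.full((2, 4, 4), 9500.0), stack, mode="two_wavelength"
        )
        r_lam = optics.compute_reflectance(stack, 633.0, 9500.0) * 1000
        assert video.frames[0, 0, 0] == pytest.approx(r_lam, rel=1e-12)
        assert video.first_frame_label == "lambda"

    def test_render_deterministic_with_seed(self, stack, grid):
        a = synthetic.render_interference(
            np.full((6, 6), 9000.0), stack, grid=grid, noise_fraction=0.02, seed=3
        )
        b = synthetic.render_interference(
            np.full((6, 6), 9000.0), stack, grid=grid, noise_fraction=0.02, seed=3
        )
        assert np.array_equal(a.frames, b.frames)

    def test_mode_grid_mismatch_rejected(self, stack):
        with pytest.raises(ValueError):
            synthetic.render_interference(np.full((4, 4), 9000.0), stack, mode="spectral")
        with pytest.raises(ValueError):
            synthetic.render_interference(
                np.full((4, 4), 9000.0), stack, mode="two_wavelength"
            )


class TestSimulateAfmCurve:
    def test_reaches_maximum_force_monotonically(self):
        c = synthetic.simulate_afm_curve(28000.0, 8.0, 10.0, 30.0)
        f_contact = c.force[c.indentation >= 0]
        assert np.all(np.diff(f_contact) >= 0)
        assert c.force[-1] == pytest.approx(30.0, rel=1e-6)

    def test_force_linear_in_modulus(self):
        c1 = synthetic.simulate_afm_curve(10000.0, 8.0, 10.0, 30.0)
        f1 = mech.hertz_force_bonded(c1.indentation, 10000.0, 8.0, 10.0)
        f2 = mech.hertz_force_bonded(c1.indentation, 20000.0, 8.0, 10.0)
        assert np.allclose(f2, 2.0 * f1)

    def test_noise_reproducible(self):
        a = synthetic.simulate_afm_curve(28000.0, 8.0, 10.0, 30.0, 0.02, seed=1)
        b = synthetic.simulate_afm_curve(28000.0, 8.0, 10.0, 30.0, 0.02, seed=1)
        assert np.array_equal(a.force, b.force)


class TestSimulateTracks:
    def test_zero_latency_rows_move_together(self):
        sc = CrawlScenario(si_latency_fraction=0.0, st_latency_fraction=0.0)
        t = synthetic.simulate_tracks(sc)
        post = t.data[t.data.point_id == "p1_post"]["x_um"].to_numpy()
        ant = t.data[t.data.point_id == "p1_ant"]["x_um"].to_numpy()
        assert np.allclose(post - post[0], ant - ant[0], atol=1e-9)

    def test_tracks_deterministic(self):
        sc = CrawlScenario()
        a = synthetic.simulate_tracks(sc, noise_um=0.5, seed=2)
        b = synthetic.simulate_tracks(sc, noise_um=0.5, seed=2)
        assert a.data.equals(b.data)

    def test_minimum_two_rows(self):
        with pytest.raises(ValueError):
            synthetic.simulate_tracks(CrawlScenario(), points_per_band=1)
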