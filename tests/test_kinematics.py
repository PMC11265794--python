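"""Footfall segmentation, AP latencies, kymographs and event timing."""

import numpy as np
import pandas as pd
import pytest

from mechwarp import kinematics as kin
from mechwarp import synthetic
from mechwarp.kinematics import FootfallEvent, TrackTable, WaveAnnotation


def table(points, frame_rate=60.0):
    rows = []
    for pid, (t, x, y) in points.items():
        rows.append(pd.DataFrame({"time_s": t, "point_id": pid, "x_um": x, "y_um": y}))
    return TrackTable(pd.concat(rows, ignore_index=True), frame_rate)


def recover_events(scenario, pid, v_on=20.0, v_off=10.0, **track_kw):
    tracks = synthetic.simulate_tracks(scenario, **track_kw)
    speeds = kin.point_velocities(tracks)
    g = speeds[speeds.point_id == pid]
    return kin.segment_footfalls(
        g["time_s"].to_numpy(), g["speed_um_s"].to_numpy(), v_on, v_off, 0.05, pid
    )


class TestPointVelocities:
    def test_stationary_point_zero_speed(self):
        t = np.arange(0, 1, 1 / 60)
        v = kin.point_velocities(table({"p": (t, np.full_like(t, 5.0), np.full_like(t, 2.0))}))
        assert np.abs(v["speed_um_s"]).max() < 1e-9

    def test_uniform_motion(self):
        t = np.arange(0, 1, 1 / 60)
        v = kin.point_velocities(table({"p": (t, 100.0 * t, np.zeros_like(t))}))
        assert np.abs(v["speed_um_s"] - 100.0).max() < 1e-9

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.arange(0, 2, 1 / 60)  # 60 samples per 1 s cycle
        x = 50.0 * np.sin(2 * np.pi * t)
        v = kin.point_velocities(table({"p": (t, x, np.zeros_like(t))}))
        expect = np.abs(50.0 * 2 * np.pi * np.cos(2 * np.pi * t))
        core = slice(2, -2)
        err = np.abs(v["speed_um_s"].to_numpy()[core] - expect[core])
        assert np.max(err / expect.max()) < 0.02

    def test_duplicate_timestamps_rejected(self):
        t = np.array([0.0, 0.1, 0.1, 0.2])
        with pytest.raises(ValueError):
            table({"p": (t, t, t)})


class TestSegmentFootfalls:
    def test_zero_speed_no_events(self):
        t = np.arange(0, 1, 1 / 60)
        assert kin.segment_footfalls(t, np.zeros_like(t)) == []

    def test_rectangular_pulse_single_event(self):
        t = np.arange(0, 2, 1 / 60)
        v = np.where((t >= 0.5) & (t < 1.1), 40.0, 0.0)
        events = kin.segment_footfalls(t, v, 20.0, 10.0, 0.1)
        assert len(events) == 1
        assert events[0].si_time == pytest.approx(0.5, abs=1 / 60)
        assert events[0].st_time == pytest.approx(1.1, abs=1 / 60)
        assert events[0].swing_duration == pytest.approx(0.6, abs=2 / 60)

    def test_short_swings_discarded(self):
        t = np.arange(0, 2, 1 / 60)
        v = np.where((t >= 0.5) & (t < 0.55), 40.0, 0.0)
        assert kin.segment_footfalls(t, v, 20.0, 10.0, 0.2) == []

    def test_hysteresis_prevents_chatter(self):
        t = np.arange(0, 1, 1 / 60)
        v = 15.0 + 2.0 * np.sin(2 * np.pi * 10 * t)  # wobbles between thresholds
        assert kin.segment_footfalls(t, v, 20.0, 10.0) == []

    def test_simulator_events_recovered_within_one_frame(self):
        sc = synthetic.CrawlScenario()
        wv = synthetic.scenario_waves(sc)[0]
        events = recover_events(sc, "p2_post")
        assert len(events) == 1
        assert events[0].si_time == pytest.approx(wv["si"][2], abs=1 / sc.map_rate)
        assert events[0].st_time == pytest.approx(wv["st"][2], abs=1 / sc.map_rate)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            kin.segment_footfalls(np.arange(5.0), np.zeros(5), 10.0, 20.0)


class TestApLatency:
    def wave(self, duration=2.0, direction="forward"):
        return WaveAnnotation(0, direction, duration)

    def test_identical_events_zero(self):
        e = [FootfallEvent("p", 1.0, 1.5)]
        lat = kin.ap_latency(e, e, self.wave())
        assert lat == (0.0, 0.0, 0.0, 0.0)

    def test_posterior_led_arithmetic(self):
        post = [FootfallEvent("p", 1.0, 1.8)]
        ant = [FootfallEvent("a", 1.2, 2.0)]
        lat = kin.ap_latency(post, ant, self.wave(2.0))
        assert lat.si_latency == pytest.approx(0.2)
        assert lat.si_pct == pytest.approx(10.0)

    def test_antisymmetry(self):
        post = [FootfallEvent("p", 1.0, 1.8)]
        ant = [FootfallEvent("a", 1.3, 2.1)]
        a = kin.ap_latency(post, ant, self.wave())
        b = kin.ap_latency(ant, post, self.wave())
        assert a.si_latency == -b.si_latency
        assert a.st_latency == -b.st_latency

    def test_simulator_forward_wave_posterior_led(self):
        sc = synthetic.CrawlScenario()
        post = recover_events(sc, "p2_post")
        ant = recover_events(sc, "p2_ant")
        lat = kin.ap_latency(post, ant, self.wave(sc.wave_duration_s))
        assert lat.si_latency == pytest.approx(
            sc.si_latency_fraction * sc.wave_duration_s, abs=1 / sc.map_rate
        )

    def test_simulator_backward_wave_flips_sign(self):
        sc = synthetic.CrawlScenario(direction="backward")
        post = recover_events(sc, "p2_post", track_step_um=20.0)
        ant = recover_events(sc, "p2_ant", track_step_um=20.0)
        lat = kin.ap_latency(post, ant, self.wave(sc.wave_duration_s, "backward"))
        assert lat.si_latency == pytest.approx(
            -sc.si_latency_fraction * sc.wave_duration_s, abs=1 / sc.map_rate
        )

    def test_unmatched_events_warn(self):
        post = [FootfallEvent("p", 1.0, 1.5), FootfallEvent("p", 3.0, 3.5)]
        ant = [FootfallEvent("a", 1.1, 1.6)]
        with pytest.warns(UserWarning):
            kin.ap_latency(post, ant, self.wave())


class TestLatencyDurationRegression:
    def test_exact_line(self):
        d = np.linspace(0.5, 3.0, 10)
        slope, icpt, r2 = kin.latency_duration_regression(np.column_stack([d, 0.1 * d]))
        assert slope == pytest.approx(0.1)
        assert icpt == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_permuted_pairs_decorrelate(self):
        rng = np.random.default_rng(5)
        d = np.linspace(0.5, 3.0, 200)
        lat = 0.1 * d
        r2s = []
        for _ in range(30):
            r2s.append(
                kin.latency_duration_regression(
                    np.column_stack([d, rng.permutation(lat)])
                )[2]
            )
        assert np.mean(r2s) < 0.03

    def test_r2_equals_brute_force_definition(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0.5, 3.0, 40)
        lat = 0.08 * d + rng.normal(0, 0.02, 40)
        slope, icpt, r2 = kin.latency_duration_regression(np.column_stack([d, lat]))
        resid = lat - (slope * d + icpt)
        brute = 1.0 - (resid**2).sum() / ((lat - lat.mean()) ** 2).sum()
        assert r2 == pytest.approx(brute, abs=1e-12)

    def test_zero_duration_variance_rejected(self):
        with pytest.raises(ValueError):
            kin.latency_duration_regression(np.array([[1.0, 0.1]] * 5))


class TestKymograph:
    @staticmethod
    def travelling_dimple(n_frames=30, shape=(40, 120), speed_px=2.0):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        frames = []
        for f in range(n_frames):
            cx = 20.0 + speed_px * f
            frames.append(-200.0 * np.exp(-(((xx - cx) ** 2 + (yy - 20) ** 2) / 30.0)))
        return np.stack(frames)

    def test_static_scene_identical_columns(self):
        arr = np.tile(self.travelling_dimple(1)[0], (5, 1, 1))
        kymo, pos = kin.kymograph(arr, [(0, 20), (119, 20)])
        assert np.allclose(kymo, kymo[:, :1])

    def test_travelling_dimple_ridge_slope(self):
        speed = 2.0
        arr = self.travelling_dimple(speed_px=speed)
        kymo, pos = kin.kymograph(arr, [(0, 20), (119, 20)])
        troughs = np.argmin(kymo, axis=0)
        slopes = np.diff(troughs.astype(float))
        assert np.median(slopes) == pytest.approx(speed, abs=0.5)

    def test_translation_shifts_position_axis(self):
        arr = self.travelling_dimple(8)
        shifted = np.roll(arr, 5, axis=2)
        k1, _ = kin.kymograph(arr, [(0, 20), (119, 20)])
        k2, _ = kin.kymograph(shifted, [(0, 20), (119, 20)])
        assert np.allclose(k2[10:-10], k1[5:-15], atol=1e-9)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            kin.kymograph(np.zeros((2, 10, 10)), [(3, 3), (3, 3)])


class TestContactOnsetLatency:
    def test_simultaneous_crossing_all_zero(self):
        arr = np.zeros((10, 20, 20))
        arr[5:] = -50.0
        lat = kin.contact_onset_latency(arr, [(5, 5), (10, 10)], (15, 15), 0.0, 60.0)
        assert np.allclose(lat, 0.0)

    def test_programmed_posterior_first_row_delays(self):
        sc = synthetic.CrawlScenario(n_protopodia=1, shape=(64, 64), tripod_enabled=False,
                                     peak_depths_nm=(800.0,))
        b = synthetic.simulate_crawl(sc)
        wv = synthetic.scenario_waves(sc)[0]
        x_new = sc.centres[0][0] + sc.step_length_um
        y0 = sc.centres[0][1]
        a = np.sqrt(sc.indenter_radius_um * 0.8)
        post_edge = x_new - a
        probes = [(post_edge + 3.0, y0), (post_edge + 6.0, y0), (post_edge + 9.0, y0)]
        # start after lift-off so the initial settling contact is not seen
        k0 = int(np.ceil((wv["si"][0] + sc.release_time_s + 0.03) * sc.map_rate))
        lat = kin.contact_onset_latency(
            b.displacement[k0:].astype(float), probes, (post_edge + 0.5, y0), -1.0, sc.map_rate
        )
        per_um = sc.ap_landing_delay_s / sc.ap_row_spacing_um
        expect = np.array([2.5, 5.5, 8.5]) * per_um
        assert np.all(np.diff(lat) > 0)  # strictly posterior-first ordering
        assert np.abs(lat - expect).max() < 1.5 / sc.map_rate

    def test_midline_first_ml_ordering(self):
        sc = synthetic.CrawlScenario(n_protopodia=1, shape=(64, 64), tripod_enabled=False,
                                     peak_depths_nm=(800.0,))
        b = synthetic.simulate_crawl(sc)
        wv = synthetic.scenario_waves(sc)[0]
        x_new = sc.centres[0][0] + sc.step_length_um
        y0 = sc.centres[0][1]
        probes = [(x_new, y0 + 3.0), (x_new, y0 + 6.0), (x_new, y0 - 6.0)]
        k0 = int(np.ceil((wv["si"][0] + sc.release_time_s + 0.03) * sc.map_rate))
        lat = kin.contact_onset_latency(
            b.displacement[k0:].astype(float), probes, (x_new, y0), -1.0, sc.map_rate
        )
        assert lat[0] > 0 and lat[1] > lat[0]
        assert lat[1] == pytest.approx(lat[2], abs=1.5 / sc.map_rate)  # left/right symmetric

    def test_never_crossing_probe_is_nan(self):
        arr = np.zeros((10, 20, 20))
        arr[5:, 10, 10] = -50.0
        lat = kin.contact_onset_latency(arr, [(0, 0)], (10, 10), -1.0, 60.0)
        assert np.isnan(lat[0])

    def test_never_crossing_reference_rejected(self):
        with pytest.raises(ValueError):
            kin.contact_onset_latency(np.zeros((5, 10, 10)), [(1, 1)], (2, 2), -1.0, 60.0)


class TestEventDelay:
    def test_identical_sequences(self):
        d = kin.event_delay([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0)
        assert np.allclose(d.delays, 0.0) and d.n_unmatched == 0

    def test_matching_arithmetic(self):
        d = kin.event_delay([0.0, 10.0], [0.5, 10.7], 2.0)
        assert np.allclose(d.delays, [0.5, 0.7])
        assert d.mean == pytest.approx(0.6)

    def test_unmatched_events_counted(self):
        d = kin.event_delay([0.0, 5.0, 20.0], [0.3], 2.0)
        assert d.n_unmatched == 2

    def test_tripod_lead_recovered_from_simulator(self):
        sc = synthetic.CrawlScenario(n_waves=3, timing_jitter_s=0.05, seed=4)
        b = synthetic.simulate_crawl(sc)
        a7_si = b.events[b.events.protopodium == 1].si_time.to_numpy()
        d = kin.event_delay(b.tripod_contacts, a7_si, 2.0)
        assert d.mean == pytest.approx(sc.tripod_lead_s, abs=2 * 0.05)
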