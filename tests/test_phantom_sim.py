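"""The in-silico circulation phantom: geometry, flow, transport, rendering."""

from dataclasses import replace

import numpy as np
import pytest

from ccia.errors import ValidationError
from ccia import phantom_sim as ps
from ccia.phantom_sim import (FlowWaveform, SimConfig, StenosisGeometry,
                              advect_bolus, diameter_profile, lesion_roi,
                              pressure_traces, pulsatile_flow, render_frames,
                              simulate_invivo, stenosis_pressure_drop,
                              synthetic_ecg, table1_geometries)
from ccia.hemodynamics import ffr


class TestGeometry:
    @pytest.mark.parametrize("h_over_r,expected_ds", [(0.3, 70), (0.5, 50),
                                                      (0.7, 30)])
    def test_severity_pairing(self, h_over_r, expected_ds):
        g = StenosisGeometry(h_over_r, li=3, xs=12, lo=3)
        assert g.percent_ds == pytest.approx(expected_ds)
        assert g.total_length == pytest.approx(18)

    def test_bench_set_has_nine_models(self):
        geoms = table1_geometries()
        assert len(geoms) == 9
        assert sorted({g.total_length for g in geoms}) == [6, 18, 30]
        assert sorted({round(g.percent_ds) for g in geoms}) == [30, 50, 70]

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValidationError):
            StenosisGeometry(h_over_r=0.0)
        with pytest.raises(ValidationError):
            StenosisGeometry.from_severity(50.0, total_length=4.0)


class TestDiameterProfile:
    def test_normal_segment_is_three_mm(self):
        g = StenosisGeometry(0.5, li=3, xs=12, lo=3)
        assert diameter_profile(g, -5.0, lesion_start=0.0) == pytest.approx(3.0)
        assert diameter_profile(g, 25.0, lesion_start=0.0) == pytest.approx(3.0)

    def test_throat_diameter(self):
        g = StenosisGeometry(0.3, li=3, xs=12, lo=3)
        assert diameter_profile(g, 9.0, lesion_start=0.0) == pytest.approx(0.9)

    def test_identity_geometry_is_uniform(self):
        g = StenosisGeometry(1.0, li=3, xs=12, lo=3)
        x = np.linspace(0, 18, 50)
        np.testing.assert_allclose(diameter_profile(g, x, 0.0), 3.0)

    def test_taper_is_linear(self):
        g = StenosisGeometry(0.5, li=4, xs=0, lo=4)
        assert diameter_profile(g, 2.0, 0.0) == pytest.approx(2.25)


class TestPulsatileFlow:
    def test_period_mean_flow_matches_bench_setting(self):
        flow = FlowWaveform()  # 25 cm/s, 60 bpm, 3 mm tube
        t = np.linspace(0, 1.0, 100_001)[:-1]
        q = np.asarray(pulsatile_flow(flow, t))
        assert q.mean() == pytest.approx(25.0 * np.pi * 0.15 ** 2, rel=1e-4)

    def test_sixty_bpm_period_is_one_second(self):
        assert FlowWaveform(heart_rate=60).period == pytest.approx(1.0)

    def test_zero_pulse_amplitude_is_steady(self):
        flow = FlowWaveform(pulse_amp=0.0)
        q = np.asarray(pulsatile_flow(flow, np.linspace(0, 2, 100)))
        assert np.ptp(q) == pytest.approx(0.0)

    def test_waveform_nonnegative(self):
        flow = FlowWaveform(pulse_amp=2.0)
        assert np.all(flow.velocity(np.linspace(0, 1, 1000)) >= 0)


class TestBolusTransport:
    def test_no_injection_stays_zero(self, steady_flow_config):
        cfg = replace(steady_flow_config,
                      injection=ps.Injection(1e-12, 16.0, 100.0))
        b = advect_bolus(cfg)
        assert np.all(b.conc <= 1e-12)

    def test_mass_conservation_ledger(self, steady_bolus):
        balance = steady_bolus.mass_injected - (
            steady_bolus.mass_in_domain() + steady_bolus.mass_out)
        assert np.max(np.abs(balance)) < 1e-3 * 4.0

    def test_plug_flow_centroid_speed(self):
        cfg = SimConfig(geometry=StenosisGeometry(1.0),
                        flow=FlowWaveform(mean_velocity=5.0, pulse_amp=0.0),
                        injection=ps.Injection(4.0, 16.0, 0.0),
                        upstream_length_mm=0.0, inlet_spread_s=0.05,
                        dispersion_coeff=0.0, duration=3.0, noise_sd=0.0)
        b = advect_bolus(cfg)

        def centroid(f):
            w = b.conc[f] * b.area
            return np.sum(w * b.x) / np.sum(w)

        i1, i2 = 15, 60  # 0.5 s and 2.0 s
        v = (centroid(i2) - centroid(i1)) / (b.times[i2] - b.times[i1])
        assert v == pytest.approx(50.0, rel=0.01)  # Q/A in mm/s

    def test_station_auc_invariant_to_dispersion(self, steady_flow_config):
        aucs = [advect_bolus(replace(steady_flow_config, dispersion_coeff=d)
                             ).station_auc(60.0) for d in (0.0, 1.0, 5.0)]
        assert np.ptp(aucs) / np.mean(aucs) < 0.02


class TestRendering:
    def test_zero_concentration_gives_background(self, steady_flow_config):
        cfg = replace(steady_flow_config,
                      injection=ps.Injection(1e-12, 16.0, 100.0))
        stack = render_frames(advect_bolus(cfg), cfg)
        assert np.all(stack.frames == cfg.background)

    def test_fixed_seed_is_bit_deterministic(self, steady_flow_config,
                                             steady_bolus):
        cfg = replace(steady_flow_config, noise_sd=8.0, seed=42)
        s1 = render_frames(steady_bolus, cfg)
        s2 = render_frames(steady_bolus, cfg)
        np.testing.assert_array_equal(s1.frames, s2.frames)

    def test_noise_free_projection_matches_closed_form(self,
                                                       steady_flow_config,
                                                       steady_bolus):
        cfg = steady_flow_config
        stack = render_frames(steady_bolus, cfg)
        # center-row pixel over the vessel axis: chord equals the diameter
        f = 100  # well inside the bolus passage
        col = int(60.0 / cfg.mm_per_px)
        c = np.interp((col + 0.5) * cfg.mm_per_px, steady_bolus.x,
                      steady_bolus.conc[f])
        nrows = stack.frames.shape[1]
        center = stack.frames[f, nrows // 2 - 1:nrows // 2 + 1, col].mean()
        # the two center rows straddle the axis; chord there is within 1% of d
        expected = cfg.background - cfg.gain * c * 3.0
        assert center == pytest.approx(expected, rel=0.01)


class TestPressures:
    def test_no_lesion_ffr_near_unity(self, steady_flow_config):
        traces = pressure_traces(steady_flow_config)
        assert ffr(traces, period=1.0, n_cycles=10).ffr >= 0.99

    def test_drop_increases_with_severity_and_length(self):
        q = np.array([1.767])
        drops_ds = [stenosis_pressure_drop(
            StenosisGeometry.from_severity(ds, 18.0), q)[0]
            for ds in (30, 50, 70)]
        assert drops_ds == sorted(drops_ds)
        assert drops_ds[0] < drops_ds[1] < drops_ds[2]
        drops_len = [stenosis_pressure_drop(
            StenosisGeometry.from_severity(50.0, L), q)[0]
            for L in (6, 18, 30)]
        assert drops_len[0] < drops_len[1] < drops_len[2]

    def test_ffr_monotone_in_severity(self):
        cfgs = [SimConfig(geometry=StenosisGeometry.from_severity(ds, 18.0))
                for ds in (30, 50, 70)]
        vals = [ffr(pressure_traces(c), 1.0, 10).ffr for c in cfgs]
        assert vals[0] > vals[1] > vals[2]


class TestInVivoMode:
    def test_zero_amplitude_keeps_static_render(self):
        cfg = SimConfig(duration=2.0, noise_sd=0.0)
        moving, ecg, disp = simulate_invivo(cfg, motion_amplitude_px=0.0,
                                            background_texture_sd=0.0)
        static = render_frames(advect_bolus(cfg), cfg)
        np.testing.assert_array_equal(moving.frames, static.frames)
        np.testing.assert_allclose(disp, 0.0)

    def test_ecg_r_peaks_at_cycle_boundaries(self):
        from ccia.motion_stabilize import detect_r_peaks
        ecg = synthetic_ecg(6.0, heart_rate=60.0, noise_sd=0.01)
        peaks = detect_r_peaks(ecg)
        expected = np.arange(len(peaks.peak_times), dtype=float)
        np.testing.assert_allclose(peaks.peak_times, expected, atol=0.01)

    def test_ground_truth_motion_range(self, invivo_bundle):
        disp = invivo_bundle["true_disp"]
        assert np.abs(disp[:, 0]).max() == pytest.approx(5.0, abs=0.05)


class TestBenchGrid:
    def test_grid_shape(self, bench_grid):
        assert len(bench_grid) == 27
        assert set(bench_grid["replicate"]) == {0, 1, 2}

    def test_noise_free_replicates_are_identical(self, bench_grid):
        sd = bench_grid.groupby(["length", "percent_ds"])["ccia"].std()
        assert np.allclose(sd, 0.0)

    def test_ccia_decreasing_in_severity_at_each_length(self, bench_grid):
        means = bench_grid.groupby(["length", "percent_ds"])["ccia"].mean()
        for length in (6.0, 18.0, 30.0):
            col = means[length]
            assert col[30.0] > col[50.0] > col[70.0]

    def test_lesion_roi_intersects_centerline(self):
        roi = lesion_roi(SimConfig())
        assert roi.stenotic_mask.sum() > 0


class TestYamlConfig:
    def test_nested_fields_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "geometry: {h_over_r: 0.3, li: 3, xs: 24, lo: 3}\n"
            "flow: {mean_velocity: 25, heart_rate: 60}\n"
            "injection: {amount: 4, rate: 16, start_time: 1.0}\n"
            "noise_sd: 0.0\nseed: 7\n")
        cfg = ps.config_from_yaml(p)
        assert cfg.geometry.percent_ds == pytest.approx(70)
        assert cfg.geometry.total_length == pytest.approx(30)
        assert cfg.seed == 7 and cfg.noise_sd == 0.0
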