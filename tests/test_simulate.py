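"""Synthetic-survey generator: dive profiles, placement, multipath, clips."""

import numpy as np
import pytest

from cachalot import signal as sg
from cachalot import simulate as sim


class TestDiveProfile:
    def test_u_dive_duration_and_max_depth(self):
        # 800 m at 1.2 m/s down and up plus 20 min bottom: ~42.2 min total
        w = sim.simulate_dive_profile(
            sim.DiveParams(1.2, 800.0, 1200.0, 1.2), seed=0
        )
        assert w.max_depth_m == 800.0
        assert w.dive_duration_s == pytest.approx(800 / 1.2 * 2 + 1200)
        assert w.dive_duration_s / 60 == pytest.approx(42.22, abs=0.01)

    def test_surface_whale_zero_length_dive(self):
        w = sim.simulate_dive_profile(sim.DiveParams(1.2, 0.0, 0.0, 1.2), seed=0)
        assert w.max_depth_m == 0.0
        assert w.dive_duration_s == 0.0
        assert w.click_times_s.size == 0

    def test_icis_respect_configured_band(self):
        w = sim.simulate_dive_profile(
            sim.DiveParams(1.2, 600.0, 600.0, 1.2, ici_s=(0.5, 1.0)), seed=1
        )
        icis = np.diff(np.concatenate([[0.0], w.click_times_s]))
        assert np.all(icis >= 0.5) and np.all(icis <= 1.0)

    def test_depth_profile_bounds(self):
        w = sim.simulate_dive_profile(sim.DiveParams(1.0, 500.0, 300.0, 1.0), seed=2)
        t = np.linspace(-10, w.dive_duration_s + 10, 500)
        z = w.depth_at(t)
        assert np.all(z >= 0) and np.all(z <= 500.0)

    def test_bottom_at_seafloor_rejected(self):
        with pytest.raises(ValueError, match="seafloor"):
            sim.simulate_dive_profile(
                sim.DiveParams(1.2, 2000.0, 600.0, 1.2), seed=0,
                seafloor_depth_m=1800.0,
            )


class TestPlacement:
    def test_expected_count_matches_poisson_mean(self):
        # density 0.00833/km2 over a 2x6.5 km strip, 5661 km of effort
        cfg = sim.SimConfig(
            effort_length_km=5661.0, whale_density_per_km2=0.00833, seed=3
        )
        counts = [len(sim.place_whales(cfg, seed=s)) for s in range(5)]
        mean = 0.00833 * 2 * 6.5 * 5661
        assert mean == pytest.approx(613, abs=1)
        assert abs(np.mean(counts) - mean) < 4 * np.sqrt(mean / 5)

    def test_zero_density_empty(self):
        cfg = sim.SimConfig(whale_density_per_km2=0.0)
        assert sim.place_whales(cfg, seed=0) == []

    def test_fixed_seed_reproducible(self):
        cfg = sim.SimConfig(effort_length_km=50.0, whale_density_per_km2=0.05)
        a = sim.place_whales(cfg, seed=7)
        b = sim.place_whales(cfg, seed=7)
        assert len(a) == len(b)
        for wa, wb in zip(a, b):
            assert wa.perpendicular_distance_m == wb.perpendicular_distance_m
            np.testing.assert_array_equal(wa.click_times_s, wb.click_times_s)

    def test_perpendicular_distances_uniform(self):
        # K-S against Uniform(0, w) at alpha=0.01 on |y|
        from scipy import stats

        cfg = sim.SimConfig(
            effort_length_km=300.0, whale_density_per_km2=1.45, seed=11
        )
        ys = np.abs([w.perpendicular_distance_m for w in sim.place_whales(cfg)])
        assert ys.size >= 5000
        p = stats.kstest(ys[:5000], "uniform", args=(0, cfg.truncation_m)).pvalue
        assert p > 0.01


class TestPropagation:
    def test_image_source_closed_form(self):
        # whale 620 m deep, 2000 m horizontal, array at 7.5 m, c=1500
        d, e, _ = sim.propagate_click([0, 2000, 620], [0, 0, 7.5], 1500.0)
        assert d * 1500 == pytest.approx(2091.69, abs=0.01)
        assert (d + e) * 1500 == pytest.approx(2096.13, abs=0.01)
        assert e == pytest.approx(2.961e-3, rel=1e-3)

    def test_surface_whale_zero_echo_delay(self):
        _, e, _ = sim.propagate_click([0, 1500, 0], [0, 0, 7.5], 1500.0)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_whale_below_gives_two_way_array_depth(self):
        _, e, _ = sim.propagate_click([0, 0, 1000], [0, 0, 7.5], 1500.0)
        assert e == pytest.approx(2 * 7.5 / 1500.0, rel=1e-12)

    def test_echo_delay_monotone_in_depth(self):
        z = np.linspace(10, 3000, 200)
        pos = np.column_stack([np.zeros_like(z), np.full_like(z, 1500.0), z])
        _, e, _ = sim.propagate_click(pos, np.array([0.0, 0.0, 7.5]), 1500.0)
        assert np.all(np.diff(e) > 0)

    def test_invalid_sound_speed(self):
        with pytest.raises(ValueError):
            sim.propagate_click([0, 100, 50], [0, 0, 7.5], -1.0)


class TestClips:
    def test_echo_recoverable_at_constructed_delay(self):
        clip, truth = sim.synthesize_clip(0.0, 0.003, snr_db=30, fs=96000, seed=1)
        assert clip.shape[1] == 2
        m = sg.measure_slant_delay(sg.ClickClip(clip, 96000))
        assert m.accepted
        assert m.tau_s == pytest.approx(0.003, abs=1.5 / 96000)
        assert not truth["echo_merged"]

    def test_noise_only_clip_yields_no_echo(self):
        clip, _ = sim.synthesize_clip(0.0, 0.003, snr_db=-np.inf, fs=96000, seed=2)
        m = sg.measure_slant_delay(sg.ClickClip(clip, 96000))
        assert not m.accepted

    def test_strong_second_pulse_creates_false_peak_at_ipi(self):
        # multi-pulse structure: a 0.9-amplitude pulse at the IPI beats a
        # 0.3-amplitude echo — the known confound of delay measurement
        clip, _ = sim.synthesize_clip(
            0.0, 0.003, ipi_s=0.004, ipi_amplitude=0.9, echo_amplitude=0.3,
            snr_db=30, fs=96000, seed=3,
        )
        m = sg.measure_slant_delay(sg.ClickClip(clip, 96000))
        # the selected envelope peak sits at the IPI, not the echo delay
        # (sub-sample refinement resolves within half a carrier period)
        assert m.tau_s == pytest.approx(0.004, abs=0.6 / 10_000)
        assert abs(m.tau_s - 0.003) > 0.0005

    def test_sub_sample_echo_flagged_merged(self):
        _, truth = sim.synthesize_clip(0.0, 0.5 / 96000, fs=96000, seed=0)
        assert truth["echo_merged"]

    def test_clip_determinism(self):
        a, _ = sim.synthesize_clip(0.0, 0.004, snr_db=20, fs=96000, seed=9)
        b, _ = sim.synthesize_clip(0.0, 0.004, snr_db=20, fs=96000, seed=9)
        np.testing.assert_array_equal(a, b)


class TestBathymetry:
    def test_flat(self):
        g = sim.make_bathymetry("flat", depth_m=2000.0)
        assert np.all(g.depths_m == 2000.0)
        assert g.depth_at(5000.0, 0.0) == 2000.0

    def test_slope_monotone(self):
        g = sim.make_bathymetry("slope", depth_range_m=(500.0, 3000.0), axis="y")
        col = g.depths_m[:, 0]
        assert col[0] == 500.0 and col[-1] == 3000.0
        assert np.all(np.diff(col) >= 0)

    def test_query_outside_grid(self):
        g = sim.make_bathymetry("flat", depth_m=1000.0)
        with pytest.raises(ValueError, match="outside"):
            g.depth_at(1e9, 0.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            sim.make_bathymetry("flat", depth_m=-5.0)


class TestFileIO:
    def test_wav_roundtrip(self, tmp_path):
        clip, _ = sim.synthesize_clip(0.0, 0.002, fs=96000, seed=4)
        p = tmp_path / "clip.wav"
        sim.write_clip_wav(p, clip, 96000)
        data, fs = sim.read_clip_wav(p)
        assert fs == 96000
        np.testing.assert_allclose(data, clip, atol=1e-6)

    def test_esri_ascii_roundtrip(self, tmp_path):
        g = sim.make_bathymetry(
            "slope", x_extent_m=(0, 5000), y_extent_m=(-3000, 3000),
            cell_size_m=1000.0, depth_range_m=(800.0, 1600.0),
        )
        p = tmp_path / "bathy.asc"
        sim.write_esri_ascii(g, p)
        g2 = sim.read_esri_ascii(p)
        np.testing.assert_allclose(g2.depths_m, g.depths_m, atol=1e-3)
        assert g2.cell_size_m == g.cell_size_m
        assert g2.origin_xy == g.origin_xy


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sound_speed_ms": 1400.0},
            {"vessel_speed_kmh": 25.0},
            {"array_depth_m": 20.0},
            {"effort_length_km": -1.0},
            {"truncation_m": 5.0},
            {"ici_s": (0.05, 1.0)},
        ],
    )
    def test_out_of_range_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sim.SimConfig(**kwargs)
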