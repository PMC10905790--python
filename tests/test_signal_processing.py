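"""Noise / temperature / baseline separation pipeline."""

import numpy as np
import pytest

from rootfos import (
    ElasticParams,
    ProcessingConfig,
    ProcessingError,
    StrainRecord,
    TemperatureSeries,
    extract_temperature,
    notch_diurnal,
    process_pipeline,
    spatial_smooth,
    subtract_pregermination_baseline,
    subtract_spatial_average,
)
from rootfos.simulator import rice_scenario, simulate_recording, Scenario

HOUR = 3600.0
DAY = 24.0 * HOUR


def make_record(n_days=4.0, dt=600.0, n_pos=32, fill=0.0, dx=10.0):
    times = np.arange(0.0, n_days * DAY - dt / 2, dt)
    arc = np.arange(n_pos) * dx
    strain = np.full((times.size, arc.size), fill)
    return StrainRecord(times=times, arc_positions=arc, strain=strain)


class TestNotchDiurnal:
    def test_pure_diurnal_sinusoid_removed(self):
        rec = make_record()
        sine = 50.0 * np.sin(2 * np.pi * rec.times / DAY)
        rec = rec.with_strain(np.tile(sine[:, None], (1, rec.n_positions)))
        filtered, background = notch_diurnal(rec)
        assert np.abs(filtered.strain).max() <= 0.01 * 50.0
        # attenuation of the diurnal line is at least 40 dB
        atten = 20 * np.log10(np.abs(filtered.strain).max() / 50.0 + 1e-300)
        assert atten <= -40.0

    def test_dc_preserved(self):
        rec = make_record(fill=17.0)
        filtered, background = notch_diurnal(rec)
        np.testing.assert_allclose(filtered.strain, 17.0, atol=1e-9)
        np.testing.assert_allclose(background.strain, 0.0, atol=1e-9)

    def test_exact_decomposition(self, rng):
        rec = make_record()
        rec = rec.with_strain(rng.normal(0, 10, rec.strain.shape))
        filtered, background = notch_diurnal(rec)
        np.testing.assert_allclose(
            filtered.strain + background.strain, rec.strain, atol=1e-9
        )

    def test_fast_transient_barely_touched(self):
        rec = make_record()
        bump = 80.0 * np.exp(-0.5 * ((rec.times - 2 * DAY) / (0.5 * HOUR)) ** 2)
        rec = rec.with_strain(np.tile(bump[:, None], (1, rec.n_positions)))
        filtered, _ = notch_diurnal(rec)
        assert filtered.strain.max() == pytest.approx(80.0, rel=0.10)

    def test_short_record_rejected(self):
        rec = make_record(n_days=1.5)
        with pytest.raises(ProcessingError):
            notch_diurnal(rec)


class TestSpatialSmooth:
    def test_median_rejects_single_spike(self):
        rec = make_record(n_days=2.1)
        strain = rec.strain.copy()
        strain[:, 10] = 100.0
        rec = rec.with_strain(strain)
        cfg = ProcessingConfig(spatial_filter_kind="median")
        out = spatial_smooth(rec, cfg)
        assert np.abs(out.strain[:, 10]).max() <= 1e-9

    @pytest.mark.parametrize("kind", ["fft", "butterworth"])
    def test_long_wavelength_preserved(self, kind):
        rec = make_record(n_days=2.1, n_pos=64)
        wave = 40.0 * np.sin(2 * np.pi * rec.arc_positions / 120.0)
        rec = rec.with_strain(np.tile(wave[None, :], (rec.n_times, 1)))
        out = spatial_smooth(rec, ProcessingConfig(spatial_filter_kind=kind))
        mid = slice(8, -8)  # away from boundary effects
        ratio = out.strain[0, mid] / np.where(np.abs(wave[mid]) < 1, 1, wave[mid])
        amp = np.abs(out.strain[0, mid]).max() / 40.0
        assert amp == pytest.approx(1.0, abs=0.05)

    def test_noise_variance_reduced(self, rng):
        rec = make_record(n_days=2.1, n_pos=64)
        rec = rec.with_strain(rng.normal(0, 10, rec.strain.shape))
        out = spatial_smooth(rec)
        assert out.strain.var(axis=1).mean() < rec.strain.var(axis=1).mean()

    def test_too_few_positions(self):
        rec = make_record(n_pos=4)
        with pytest.raises(ProcessingError):
            spatial_smooth(rec)


class TestBaseline:
    def test_constant_record_zeroed(self):
        rec = make_record(fill=42.0)
        out = subtract_pregermination_baseline(rec)
        np.testing.assert_allclose(out.strain, 0.0, atol=1e-9)

    def test_step_after_window_survives(self):
        rec = make_record()
        strain = np.where(rec.times[:, None] > 30 * HOUR, 25.0, 0.0) + 7.0
        rec = rec.with_strain(np.broadcast_to(strain, rec.strain.shape).copy())
        out = subtract_pregermination_baseline(rec)
        late = rec.times > 30 * HOUR
        np.testing.assert_allclose(out.strain[late], 25.0, atol=1e-9)
        np.testing.assert_allclose(out.strain[rec.times <= 24 * HOUR], 0.0, atol=1e-9)

    def test_window_mean_is_zero(self, rng):
        rec = make_record()
        rec = rec.with_strain(rng.normal(5, 20, rec.strain.shape))
        out = subtract_pregermination_baseline(rec)
        window = rec.times <= 24 * HOUR
        np.testing.assert_allclose(out.strain[window].mean(axis=0), 0.0, atol=1e-9)

    def test_missing_window_rejected(self):
        times = np.arange(2 * DAY, 5 * DAY, 600.0)
        rec = StrainRecord(times, np.arange(8) * 30.0, np.zeros((times.size, 8)))
        with pytest.raises(ProcessingError):
            subtract_pregermination_baseline(rec)


class TestSpatialAverage:
    def test_uniform_record_fully_removed(self):
        rec = make_record()
        trace = 30.0 * np.sin(2 * np.pi * rec.times / DAY)
        rec = rec.with_strain(np.tile(trace[:, None], (1, rec.n_positions)))
        residual, common = subtract_spatial_average(rec)
        np.testing.assert_allclose(residual.strain, 0.0, atol=1e-9)
        np.testing.assert_allclose(common.values, trace, atol=1e-9)

    def test_shift_equivariance(self, rng):
        rec = make_record()
        base = rng.normal(0, 5, rec.strain.shape)
        r1, c1 = subtract_spatial_average(rec.with_strain(base))
        r2, c2 = subtract_spatial_average(rec.with_strain(base + 11.0))
        np.testing.assert_allclose(r1.strain, r2.strain, atol=1e-9)
        np.testing.assert_allclose(c2.values - c1.values, 11.0, atol=1e-9)

    def test_additivity(self, rng):
        rec = make_record()
        rec = rec.with_strain(rng.normal(0, 5, rec.strain.shape))
        residual, common = subtract_spatial_average(rec)
        np.testing.assert_allclose(
            residual.strain + common.values[:, None], rec.strain, atol=1e-9
        )


class TestExtractTemperature:
    def test_definitional_inversion(self):
        times = np.arange(10.0)
        common = TemperatureSeries(times, np.full(10, 125.0))
        out = extract_temperature(common, mounting="ptfe")
        np.testing.assert_allclose(out.values, 1.0)
        assert out.unit == "degC"

    def test_film_to_bare_ratio_approx_220(self):
        cfg = ProcessingConfig()
        ratio = cfg.alpha_ptfe / cfg.alpha_silica
        assert ratio >= 220.0
        assert ratio == pytest.approx(227.3, rel=0.01)

    def test_zero_strain_zero_delta_t(self):
        common = TemperatureSeries(np.arange(4.0), np.zeros(4))
        out = extract_temperature(common, mounting="bare")
        np.testing.assert_allclose(out.values, 0.0)


class TestPipeline:
    def _simulate(self, geometry, layout, seed=1, noise=1.0, tips=0):
        scenario = rice_scenario(
            n_tips=tips, seed=seed, noise_sigma_ue=noise, duration_h=96.0
        ) if tips else Scenario(
            species="none", noise_sigma_ue=noise, seed=seed, duration_h=96.0
        )
        return simulate_recording(scenario, geometry, layout, ElasticParams())

    def test_exact_decomposition_of_components(self, geometry, layout):
        rec, _ = self._simulate(geometry, layout)
        result = process_pipeline(rec)
        np.testing.assert_allclose(result.reassemble(), rec.strain, atol=1e-8)

    def test_null_scenario_residual_within_noise(self, geometry, layout):
        """Temperature + baseline + noise only: processing leaves < 3 sigma."""
        sigma = 1.0
        rec, _ = self._simulate(geometry, layout, noise=sigma)
        result = process_pipeline(rec)
        late = rec.times > 36 * HOUR
        rms = float(np.sqrt(np.mean(result.processed.strain[late] ** 2)))
        assert rms <= 3.0 * sigma

    def test_root_event_creates_local_maximum(self, geometry, layout):
        rec_root, truth = self._simulate(geometry, layout, tips=1, noise=0.5)
        rec_null, _ = self._simulate(geometry, layout, tips=0, noise=0.5)
        p_root = process_pipeline(rec_root).processed
        p_null = process_pipeline(rec_null).processed
        snap_root = p_root.strain[-1]
        snap_null = p_null.strain[-1]
        tip = truth.tips_at(rec_root.times[-1])[0]
        dist = np.linalg.norm(layout.xyz - tip.position, axis=1)
        # strongest response sits in the tip's neighbourhood and dwarfs the null
        strongest = int(np.argmax(np.abs(snap_root)))
        assert dist[strongest] <= 35.0
        assert np.abs(snap_root[strongest]) > 5 * np.abs(snap_null).max()
        assert np.abs(snap_null).max() < 5.0

    def test_linearity(self, geometry, layout, rng):
        rec, _ = self._simulate(geometry, layout, noise=0.0)
        x = rec.strain
        y = rng.normal(0, 3, x.shape)
        a, b = 1.7, -0.6
        combo = rec.with_strain(a * x + b * y)
        px = process_pipeline(rec).processed.strain
        py = process_pipeline(rec.with_strain(y)).processed.strain
        pc = process_pipeline(combo).processed.strain
        np.testing.assert_allclose(pc, a * px + b * py, atol=1e-7)

    def test_idempotence(self, geometry, layout):
        rec, _ = self._simulate(geometry, layout, tips=2, noise=1.0)
        once = process_pipeline(rec).processed
        twice = process_pipeline(once).processed
        rms1 = float(np.sqrt(np.mean(once.strain**2)))
        rms2 = float(np.sqrt(np.mean(twice.strain**2)))
        assert abs(rms2 - rms1) / rms1 < 0.05
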