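"""Phantom simulator: waveform, velocity field, acquisition physics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcmri import (
    AcquisitionParams,
    ConfigurationError,
    DomainError,
    PhantomSpec,
    default_acquisition,
    phase_to_velocity,
    protocol_timing,
    simulate_series,
    velocity_field,
    velocity_waveform,
)
from pcmri.phantom import pixel_centers


class TestWaveform:
    def test_constant_when_systole_equals_diastole(self):
        spec = PhantomSpec(v_systolic=50, v_diastolic=50)
        t = np.linspace(0, spec.rr_period, 50, endpoint=False)
        assert np.allclose(velocity_waveform(spec, t), 50.0)

    def test_peak_attained_at_pulse_center(self):
        spec = PhantomSpec()
        assert velocity_waveform(spec, 0.25 * spec.rr_period) == pytest.approx(
            spec.v_systolic
        )

    def test_cycle_mean_matches_quadrature(self):
        """Cycle mean equals v_dia + (v_sys - v_dia) * mean(g), trapezoid oracle."""
        spec = PhantomSpec(v_systolic=80, v_diastolic=20, systolic_fraction=0.3)
        t = np.linspace(0, spec.rr_period, 10_001)
        quad_mean = np.trapezoid(velocity_waveform(spec, t), t) / spec.rr_period
        # raised-cosine pulse of width w has mean w/2 over the cycle
        analytic = 20 + 60 * spec.systolic_fraction / 2
        assert quad_mean == pytest.approx(analytic, rel=1e-6)

    def test_negative_or_nonfinite_time_rejected(self):
        spec = PhantomSpec()
        with pytest.raises(DomainError):
            velocity_waveform(spec, -1.0)
        with pytest.raises(DomainError):
            velocity_waveform(spec, np.nan)

    @settings(max_examples=50, derandomize=True)
    @given(t=st.floats(min_value=0.0, max_value=1e4))
    def test_periodic_and_bounded(self, t):
        spec = PhantomSpec()
        v = velocity_waveform(spec, t)
        assert spec.v_diastolic - 1e-9 <= v <= spec.v_systolic + 1e-9
        assert v == pytest.approx(
            velocity_waveform(spec, t + spec.rr_period), abs=1e-9
        )


class TestVelocityField:
    def test_centerline_and_wall(self):
        spec = PhantomSpec()
        t = 0.25 * spec.rr_period
        cx, cy = spec.center
        assert velocity_field(spec, t, cx, cy) == pytest.approx(spec.v_systolic)
        assert velocity_field(spec, t, cx + spec.lumen_radius, cy) == 0.0

    def test_poiseuille_flux_matches_closed_form(self):
        """Supersampled sum of the parabolic field reproduces pi R^2 vmax / 2."""
        spec = PhantomSpec(v_systolic=60, v_diastolic=60)
        n = 256 * 8
        c = pixel_centers(40.0, n)
        x, y = np.meshgrid(c, c)
        v = velocity_field(spec, 0.0, x, y)
        flux = v.sum() * (40.0 / n / 10.0) ** 2  # mL/s
        assert flux == pytest.approx(0.235619, rel=5e-3)

    def test_plug_profile_with_infinite_exponent(self):
        spec = PhantomSpec(v_systolic=60, v_diastolic=60, profile_exponent=np.inf)
        cx, cy = spec.center
        assert velocity_field(spec, 0.0, cx + 0.45, cy) == pytest.approx(60.0)


class TestSimulateSeries:
    def test_zero_velocity_gives_zero_phase_and_flat_magnitude(self):
        spec = PhantomSpec(v_systolic=0, v_diastolic=0, snr=np.inf)
        series = simulate_series(spec, default_acquisition(spec))
        assert np.allclose(series.phase, 0.0, atol=1e-12)
        assert set(np.round(np.unique(series.magnitude), 6)) <= {
            round(v, 6)
            for v in np.linspace(spec.tissue_magnitude, spec.blood_magnitude, 65)
        }

    def test_wrapped_plug_flow_reads_aliased_velocity(self):
        """130 cm/s at VENC 120 appears as -110 cm/s (phase -0.9167 pi)."""
        spec = PhantomSpec(
            v_systolic=130,
            v_diastolic=130,
            profile_exponent=np.inf,
            snr=np.inf,
            supersample_factor=1,
        )
        params = default_acquisition(spec, venc=120.0, matrix_size=201)
        series = simulate_series(spec, params)
        center = series.phase[0, 100, 100]  # pixel center coincides with axis
        assert center == pytest.approx(-0.91667 * np.pi, abs=1e-4)
        vmap = phase_to_velocity(series)
        assert vmap.velocity[0, 100, 100] == pytest.approx(-110.0, abs=1e-9)

    @pytest.mark.parametrize("v_true", [150.0, 200.0, 300.0, 355.0])
    def test_wrap_consistency_within_single_wrap_budget(self, v_true):
        """For venc < v < 3 venc the apparent velocity is exactly v - 2 venc."""
        spec = PhantomSpec(
            v_systolic=v_true,
            v_diastolic=v_true,
            profile_exponent=np.inf,
            snr=np.inf,
            supersample_factor=1,
        )
        params = default_acquisition(spec, venc=120.0, matrix_size=201)
        vmap = phase_to_velocity(simulate_series(spec, params))
        assert vmap.velocity[0, 100, 100] == pytest.approx(v_true - 240.0, abs=1e-9)

    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec(seed=11)
        params = default_acquisition(spec)
        a = simulate_series(spec, params)
        b = simulate_series(spec, params)
        assert np.array_equal(a.magnitude, b.magnitude)
        assert np.array_equal(a.phase, b.phase)
        c = simulate_series(dataclasses.replace(spec, seed=12), params)
        assert not np.array_equal(a.phase, c.phase)

    def test_phase_always_in_principal_interval(self):
        spec = PhantomSpec(seed=3)
        series = simulate_series(spec, default_acquisition(spec, venc=60.0))
        assert series.phase.min() >= -np.pi
        assert series.phase.max() < np.pi

    def test_nongated_underestimates_pulsatile_mean(self):
        """Complex cycle averaging biases the non-gated lumen mean low."""
        for v_sys, v_dia, frac in [(80, 20, 0.3), (100, 10, 0.2), (60, 30, 0.5)]:
            spec = PhantomSpec(
                v_systolic=v_sys, v_diastolic=v_dia, systolic_fraction=frac, snr=np.inf
            )
            params = default_acquisition(spec, gated=False)
            series = simulate_series(spec, params, n_avg=64)
            vmap = phase_to_velocity(series)
            c = pixel_centers(params.fov, params.matrix_size)
            x, y = np.meshgrid(c, c)
            lumen = (
                np.hypot(x - 20, y - 20)
                < spec.lumen_radius - 0.75 * params.pixel_spacing
            )
            t = np.linspace(0, spec.rr_period, 2000, endpoint=False)
            true_mean_profile = np.trapezoid(
                velocity_waveform(spec, t), t
            ) / spec.rr_period
            apparent = vmap.velocity[0][lumen]
            true_vals = velocity_field(spec, 0.25 * spec.rr_period, x, y)[lumen]
            true_mean = true_vals / v_sys * true_mean_profile
            assert apparent.mean() <= true_mean.mean() + 1e-6

    def test_flux_conserved_by_complex_box_averaging(self):
        """Whole-FOV velocity x magnitude sum tracks the supersampled flux < 1%."""
        spec = PhantomSpec(snr=np.inf)
        for matrix in (64, 128, 192, 256):
            params = default_acquisition(spec, matrix_size=matrix)
            series = simulate_series(spec, params)
            vmap = phase_to_velocity(series)
            n = matrix * spec.supersample_factor
            c = pixel_centers(params.fov, n)
            x, y = np.meshgrid(c, c)
            for k in range(params.n_frames):
                t = (k + 0.5) * 2.0 * params.tr
                v_true = velocity_field(spec, t, x, y)
                flux_true = v_true.sum() * (params.fov / n / 10.0) ** 2
                weights = series.magnitude[k] / spec.blood_magnitude
                flux_est = (vmap.velocity[k] * weights).sum() * (
                    params.pixel_spacing / 10.0
                ) ** 2
                assert flux_est == pytest.approx(flux_true, rel=0.01)

    def test_invalid_configurations_rejected(self):
        spec = PhantomSpec()
        with pytest.raises(DomainError):
            PhantomSpec(snr=0.0)
        with pytest.raises(DomainError):
            PhantomSpec(v_systolic=10, v_diastolic=20)
        with pytest.raises(ConfigurationError):
            # cardiac period shorter than one temporal-resolution slot
            short = PhantomSpec(rr_period=20.0)
            simulate_series(short, AcquisitionParams(venc=120, gated=True, n_frames=1))
        with pytest.raises(ConfigurationError):
            off = PhantomSpec(center=(0.4, 20.0))
            simulate_series(off, default_acquisition(off))
        with pytest.raises(ConfigurationError):
            coarse = PhantomSpec(supersample_factor=2)
            simulate_series(coarse, default_acquisition(coarse, matrix_size=64))


class TestProtocolTiming:
    def test_temporal_resolution_from_tr(self):
        params = default_acquisition(PhantomSpec(), tr=15.55)
        timing = protocol_timing(params, rr_period=150.0)
        assert timing["temporal_resolution"] == pytest.approx(31.1)

    def test_nongated_scan_duration(self):
        spec = PhantomSpec()
        params = default_acquisition(spec, matrix_size=128, gated=False, nex=8)
        timing = protocol_timing(params, rr_period=150.0)
        assert timing["scan_duration"] == pytest.approx(15.9232)
        assert timing["scan_duration"] == pytest.approx(16.0, abs=0.5)

    def test_gated_frame_count(self):
        params = default_acquisition(PhantomSpec(rr_period=150.0))
        timing = protocol_timing(params, rr_period=150.0)
        assert timing["n_frames"] == 4  # floor(0.9 * 150 / 31.1)
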