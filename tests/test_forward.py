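import numpy as np
import pytest
from scipy.integrate import solve_ivp

import twinpeak as tp
from twinpeak.exceptions import UnsupportedModelError, ValidationError


class TestModalOscillator:
    @pytest.mark.parametrize("k,tau", [(200.0, 0.1e-3), (800.0, 0.5e-3),
                                       (3000.0, 1.0e-3)])
    def test_root_invariants(self, k, tau):
        osc = tp.ModalOscillator(rho=1000.0, cs=np.sqrt(2.0), tau=tau, k=k)
        l1, l2 = osc.roots
        wn, z = osc.natural_frequency, osc.damping_ratio
        assert l1 * l2 == pytest.approx(wn ** 2, rel=1e-9)
        assert l1 + l2 == pytest.approx(-2 * z * wn, rel=1e-9)

    def test_velocity_zero_at_onset(self):
        osc = tp.ModalOscillator(rho=1000.0, cs=1.414, tau=0.5e-3, k=800.0)
        assert tp.modal_velocity(osc, 1.0, 400e-6, 0.0) == 0.0

    def test_rigid_mode_limit(self):
        osc = tp.ModalOscillator(rho=1000.0, cs=1.414, tau=0.5e-3, k=0.0)
        T = 400e-6
        assert tp.modal_velocity(osc, 3.0, T, 2e-4) == pytest.approx(3.0 * 2e-4 / 1000.0)
        # after the pulse the rigid mode coasts at F*T/rho
        assert tp.modal_velocity(osc, 3.0, T, 5e-3) == pytest.approx(3.0 * T / 1000.0)

    def test_against_ode_integration_oracle(self):
        """Closed form vs direct numerical integration of the damped
        oscillator driven by a rectangular force pulse."""
        rho, cs, tau, k, T = 1000.0, np.sqrt(2.0), 0.5e-3, 800.0, 400e-6
        osc = tp.ModalOscillator(rho=rho, cs=cs, tau=tau, k=k)
        M, C, K = osc.mass, osc.damping, osc.stiffness

        def rhs(t, y):
            force = 1.0 if t <= T else 0.0
            return [y[1], (force - C * y[1] - K * y[0]) / M]

        sol = solve_ivp(rhs, (0.0, 2e-3), [0.0, 0.0], rtol=1e-11, atol=1e-16,
                        max_step=T / 50, dense_output=True)
        v_ode = sol.sol(2e-3)[1]
        v_closed = tp.modal_velocity(osc, 1.0, T, 2e-3)
        assert v_closed == pytest.approx(v_ode, rel=1e-6)

    def test_near_critical_damping_is_finite(self):
        rho, cs = 1000.0, np.sqrt(2.0)
        k = 1000.0
        tau = 2.0 / (cs * k)  # zeta exactly 1
        osc = tp.ModalOscillator(rho=rho, cs=cs, tau=tau, k=k)
        v = tp.modal_velocity(osc, 1.0, 400e-6, np.linspace(0, 5e-3, 40))
        assert np.all(np.isfinite(v))
        # continuity against slightly off-critical neighbours
        for eps in (1e-4, -1e-4):
            osc2 = tp.ModalOscillator(rho=rho, cs=cs, tau=tau * (1 + eps), k=k)
            v2 = tp.modal_velocity(osc2, 1.0, 400e-6, np.linspace(0, 5e-3, 40))
            np.testing.assert_allclose(v, v2, rtol=1e-2, atol=1e-12)


class TestSimulators:
    def test_zero_amplitude_source_gives_zero_field(self, medium, small_grid):
        src = tp.ARFSource(amplitude=0.0)
        kv = tp.KelvinVoigtParams(2000.0, 0.5e-3)
        f = tp.simulate_time_kv(kv, medium, src, small_grid, dims=2,
                                observe=tp.Observation())
        np.testing.assert_array_equal(f.velocity, 0.0)

    def test_linearity_and_peak_invariance(self, medium, small_grid):
        kv = tp.KelvinVoigtParams(2000.0, 0.5e-3)
        a = tp.simulate_time_kv(kv, medium, tp.ARFSource(amplitude=1.0),
                                small_grid, dims=2, observe=tp.Observation())
        b = tp.simulate_time_kv(kv, medium, tp.ARFSource(amplitude=7.5),
                                small_grid, dims=2, observe=tp.Observation())
        np.testing.assert_allclose(b.velocity, 7.5 * a.velocity, rtol=1e-9,
                                   atol=1e-12 * np.abs(a.velocity).max())
        pr = tp.PeakRange(100.0, 900.0, 300.0, 2000.0)
        ta = tp.extract_twin_peaks(tp.fk_transform(a, 2), pr)
        tb = tp.extract_twin_peaks(tp.fk_transform(b, 2), pr)
        np.testing.assert_array_equal(ta.f_of_k, tb.f_of_k)
        np.testing.assert_array_equal(ta.k_of_f, tb.k_of_f)

    def test_time_kv_rejects_other_rheologies(self, medium, small_grid, source):
        sp = tp.RheologyModel.spring_pot(2000.0, 0.4, 2 * np.pi * 200.0)
        with pytest.raises(UnsupportedModelError, match="simulate_freq"):
            tp.simulate_time_kv(sp, medium, source, small_grid)

    def test_spatial_symmetry_of_full_field(self, medium, source, small_grid):
        kv = tp.KelvinVoigtParams(2000.0, 0.5e-3)
        f = tp.simulate_time_kv(kv, medium, source, small_grid, dims=2)
        iy = np.argmin(np.abs(f.y))
        # y -> -y symmetry about the push axis
        np.testing.assert_allclose(f.velocity[:, iy + 3, :], f.velocity[:, iy - 3, :],
                                   atol=1e-12 * np.abs(f.velocity).max())

    def test_causality_time_solver(self, kv_field_2d):
        """No response before first arrival: far-field early samples are at
        the round-off floor (spatial wrap-around excluded by expansion)."""
        v = kv_field_2d.velocity
        assert np.abs(v[-8:, :3]).max() <= 1e-6 * np.abs(v).max()

    def test_causality_freq_solver(self, kv_model, medium, source, default_grid):
        """The periodic-in-time solver keeps wrap-around ringing well below
        signal level at the default expansion."""
        f = tp.simulate_freq(kv_model, medium, source, default_grid, dims=2,
                             observe=tp.Observation())
        assert np.abs(f.velocity[-8:, :3]).max() <= 2e-3 * np.abs(f.velocity).max()

    def test_attenuation_monotonic_beyond_footprint(self, kv_field_2d):
        env = np.abs(kv_field_2d.velocity).max(axis=1)
        x = kv_field_2d.x
        sel = x > 2e-3  # beyond the source footprint
        assert np.all(np.diff(env[sel]) <= 1e-12)

    def test_elastic_limit_dispersion(self, medium, source, default_grid):
        """tau = 0: the f(k) ridge follows 2*pi*f = cs*k within one bin."""
        kv0 = tp.KelvinVoigtParams(2000.0, 0.0)
        f = tp.simulate_time_kv(kv0, medium, source, default_grid, dims=2,
                                observe=tp.Observation())
        spec = tp.fk_transform(f, 4)
        tk = tp.extract_twin_peaks(spec, tp.PeakRange(100, 500, 500, 1500))
        fpred = np.sqrt(2.0) * tk.k_grid / (2 * np.pi)
        assert np.nanmax(np.abs(tk.f_of_k - fpred)) <= spec.df * (1 + 1e-9)

    def test_solvers_cross_check_pointwise(self, kv_field_2d, kv_model, medium,
                                           source, default_grid):
        """Time- and frequency-domain Kelvin-Voigt fields agree to < 1% of
        peak after the force pulse ends (band-limiting of the rectangular
        pulse only affects the source samples themselves)."""
        ff = tp.simulate_freq(kv_model, medium, source, default_grid, dims=2,
                              observe=tp.Observation())
        late = kv_field_2d.t > source.duration + 2 * default_grid.dt
        d = np.abs(kv_field_2d.velocity[:, late] - ff.velocity[:, late])
        assert d.max() <= 0.01 * np.abs(kv_field_2d.velocity).max()


class TestFusedVsFullField:
    def test_time_kv_2d(self, medium, source, small_grid):
        kv = tp.KelvinVoigtParams(2000.0, 0.5e-3)
        full = tp.simulate_time_kv(kv, medium, source, small_grid, dims=2)
        line = tp.extract_observation(full)
        fused = tp.simulate_time_kv(kv, medium, source, small_grid, dims=2,
                                    observe=tp.Observation(), n_kappa_bins=20000)
        scale = np.abs(line.velocity).max()
        np.testing.assert_allclose(fused.velocity, line.velocity, atol=2e-4 * scale)

    def test_time_kv_3d_with_strip(self, medium, source, small_grid):
        kv = tp.KelvinVoigtParams(2000.0, 0.5e-3)
        full = tp.simulate_time_kv(kv, medium, source, small_grid, dims=3)
        strip = tp.extract_observation(full, strip_halfwidth=2e-3)
        fused = tp.simulate_time_kv(kv, medium, source, small_grid, dims=3,
                                    observe=tp.Observation(strip_halfwidth=2e-3),
                                    n_kappa_bins=20000)
        scale = np.abs(strip.velocity).max()
        np.testing.assert_allclose(fused.velocity, strip.velocity, atol=5e-4 * scale)

    def test_freq_2d(self, medium, source, small_grid):
        sp = tp.RheologyModel.spring_pot(2000.0, 0.4, 2 * np.pi * 200.0)
        full = tp.simulate_freq(sp, medium, source, small_grid, dims=2)
        line = tp.extract_observation(full)
        fused = tp.simulate_freq(sp, medium, source, small_grid, dims=2,
                                 observe=tp.Observation(), n_kappa_bins=20000)
        scale = np.abs(line.velocity).max()
        np.testing.assert_allclose(fused.velocity, line.velocity, atol=2e-4 * scale)


class TestObservation:
    def test_strip_zero_is_center_slice(self, medium, source, small_grid):
        kv = tp.KelvinVoigtParams(2000.0, 0.5e-3)
        full = tp.simulate_time_kv(kv, medium, source, small_grid, dims=3)
        obs = tp.extract_observation(full, 0.0)
        iy = np.argmin(np.abs(full.y))
        iz = np.argmin(np.abs(full.z))
        np.testing.assert_array_equal(obs.velocity, full.velocity[:, iy, iz, :])

    def test_field_constant_in_z(self, small_grid):
        x, y, z, t = small_grid.x, small_grid.y, small_grid.z, small_grid.t
        rng = np.random.default_rng(0)
        base = rng.standard_normal((x.size, y.size, 1, t.size))
        field = tp.MotionField(np.repeat(base, z.size, axis=2), x, t, y=y, z=z)
        obs = tp.extract_observation(field, strip_halfwidth=2e-3)
        iy = np.argmin(np.abs(y))
        np.testing.assert_allclose(obs.velocity, base[:, iy, 0, :])

    def test_strip_vs_slice_peaks_within_one_bin(self, medium, source, default_grid,
                                                 kv_model):
        strip = tp.generate_insilico(kv_model, medium, source, default_grid,
                                     dims=3, strip_halfwidth=1.5e-3)
        slice_ = tp.generate_insilico(kv_model, medium, source, default_grid, dims=3)
        pr = tp.PeakRange(100, 500, 500, 1500)
        ta = tp.extract_twin_peaks(tp.fk_transform(strip, 4), pr)
        tb = tp.extract_twin_peaks(tp.fk_transform(slice_, 4), pr)
        spec = tp.fk_transform(strip, 4)
        assert np.nanmax(np.abs(ta.f_of_k - tb.f_of_k)) <= spec.df * (1 + 1e-9)
        assert np.nanmax(np.abs(ta.k_of_f - tb.k_of_f)) <= spec.dk * (1 + 1e-9)

    def test_strip_wider_than_domain(self, medium, source, small_grid):
        kv = tp.KelvinVoigtParams(2000.0, 0.5e-3)
        full = tp.simulate_time_kv(kv, medium, source, small_grid, dims=3)
        with pytest.raises(ValidationError):
            tp.extract_observation(full, strip_halfwidth=1.0)


class TestGridAndProvenance:
    def test_sample_counts(self):
        g = tp.SamplingGrid()
        assert g.x.size == 121 and g.t.size == 151
        assert g.x[0] == 0.0 and g.t[0] == 0.0
        assert g.y[0] == -g.y[-1]

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValidationError):
            tp.SamplingGrid(dx=-1.0)
        with pytest.raises(ValidationError):
            tp.SamplingGrid(expansion_factor=0.5)

    def test_provenance_records_configuration(self, kv_field_2d):
        meta = kv_field_2d.meta
        assert meta["solver"] == "time_kv"
        assert meta["model"]["parameters"] == [2000.0, 0.5e-3]
        assert meta["grid"]["dx"] == 0.25e-3

    def test_motion_field_axis_validation(self):
        with pytest.raises(ValidationError):
            tp.MotionField(np.zeros((3, 4)), np.array([0.0, 1.0, 0.5]),
                           np.arange(4.0))
        with pytest.raises(ValidationError):
            tp.MotionField(np.zeros((3, 5)), np.arange(3.0), np.arange(4.0))
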