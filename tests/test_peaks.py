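import numpy as np
import pytest

import twinpeak as tp
from twinpeak.exceptions import ValidationError


def _make_field(nx=32, nt=64, dx=0.5e-3, dt=0.2e-3, fill=None):
    x = np.arange(nx) * dx
    t = np.arange(nt) * dt
    v = np.ones((nx, nt)) if fill is None else fill(x[:, None], t[None, :])
    return tp.MotionField(v, x, t)


class TestTruncateWindow:
    def test_full_extents_identity(self):
        f = _make_field()
        g = tp.truncate_window(f, (f.x[0], f.x[-1]), (f.t[0], f.t[-1]))
        np.testing.assert_array_equal(g.velocity, f.velocity)
        np.testing.assert_array_equal(g.x, f.x)

    def test_ones_field_any_window(self):
        f = _make_field()
        g = tp.truncate_window(f, (2e-3, 8e-3), (1e-3, 5e-3))
        assert np.all(g.velocity == 1.0)
        assert g.x[0] >= 2e-3 and g.x[-1] <= 8e-3  # coordinates preserved

    def test_acquisition_window_sample_counts(self):
        """Index arithmetic for a 4-10 mm, 0.535-10 ms window at the default
        sampling: floor((10-4)/0.25)+1 by floor((10-0.535)/0.1)+1 samples."""
        g = tp.SamplingGrid()
        f = tp.MotionField(np.ones((g.x.size, g.t.size)), g.x, g.t)
        w = tp.truncate_window(f, (4e-3, 10e-3), (0.535e-3, 10e-3))
        assert w.velocity.shape == (25, 95)

    def test_empty_window_rejected(self):
        with pytest.raises(ValidationError):
            tp.truncate_window(_make_field(), (1.0, 2.0), None)


class TestFKTransform:
    def test_on_grid_sinusoid_peak_location(self):
        dx, dt = 0.5e-3, 0.2e-3
        nx, nt = 64, 128
        f0 = 10 / (nt * dt)              # exactly on the unpadded grid
        k0 = 2 * np.pi * 6 / (nx * dx)
        fld = _make_field(nx, nt, dx, dt,
                          fill=lambda x, t: np.cos(2 * np.pi * f0 * t - k0 * x))
        spec = tp.fk_transform(fld, pad_factor=1)
        i, j = np.unravel_index(np.argmax(np.abs(spec.values)), spec.values.shape)
        assert spec.f[i] == pytest.approx(f0)
        assert spec.k[j] == pytest.approx(k0)

    def test_linearity(self):
        fld = _make_field(fill=lambda x, t: np.sin(3e3 * t) * np.exp(-x / 5e-3))
        a = tp.fk_transform(fld, 2)
        fld10 = tp.MotionField(10 * fld.velocity, fld.x, fld.t)
        b = tp.fk_transform(fld10, 2)
        np.testing.assert_allclose(b.values, 10 * a.values, rtol=1e-12)

    def test_single_sample_axis_rejected(self):
        x = np.array([0.0])
        f = tp.MotionField(np.ones((1, 8)), x, np.arange(8.0))
        with pytest.raises(ValidationError):
            tp.fk_transform(f)

    def test_padded_sizes(self):
        fld = _make_field(nx=20, nt=40)
        spec = tp.fk_transform(fld, pad_factor=4)
        assert spec.pad == {"nt": 256, "nx": 128, "pad_factor": 4}


class TestExtractTwinPeaks:
    def _delta_spectrum(self):
        f = np.linspace(0, 1000, 201)
        k = np.linspace(0, 3000, 301)
        vals = np.zeros((f.size, k.size), dtype=complex)
        vals[80, 120] = 1.0  # f = 400 Hz, k = 1200 rad/m
        return tp.FKSpectrum(vals, f, k, pad={})

    def test_single_bin_collapse(self):
        spec = self._delta_spectrum()
        tk = tp.extract_twin_peaks(spec, tp.PeakRange(100, 900, 300, 2500))
        assert np.nanmax(np.abs(tk.f_of_k[tk.fk_valid] - 400.0)) == 0.0
        assert np.nanmax(np.abs(tk.k_of_f[tk.kf_valid] - 1200.0)) == 0.0

    def test_amplitude_invariance_bitwise(self, kv_field_2d):
        pr = tp.PeakRange(100, 500, 500, 1500)
        a = tp.extract_twin_peaks(tp.fk_transform(kv_field_2d, 4), pr)
        scaled = tp.MotionField(3.7 * kv_field_2d.velocity, kv_field_2d.x,
                                kv_field_2d.t)
        b = tp.extract_twin_peaks(tp.fk_transform(scaled, 4), pr)
        np.testing.assert_array_equal(a.f_of_k, b.f_of_k)
        np.testing.assert_array_equal(a.k_of_f, b.k_of_f)
        np.testing.assert_array_equal(a.fk_valid, b.fk_valid)

    def test_pad_doubling_moves_peaks_at_most_one_coarse_bin(self, kv_field_2d):
        pr = tp.PeakRange(100, 500, 500, 1500)
        s4 = tp.fk_transform(kv_field_2d, 4)
        s8 = tp.fk_transform(kv_field_2d, 8)
        t4 = tp.extract_twin_peaks(s4, pr)
        t8 = tp.extract_twin_peaks(s8, pr)
        # compare k(f) on the shared frequency rows
        shared, i4, i8 = np.intersect1d(np.round(t4.f_grid, 9),
                                        np.round(t8.f_grid, 9),
                                        return_indices=True)
        dev = np.abs(t4.k_of_f[i4] - t8.k_of_f[i8])
        assert np.nanmax(dev) <= s4.dk * (1 + 1e-9)

    def test_empty_rows_marked_invalid(self):
        spec = self._delta_spectrum()
        tk = tp.extract_twin_peaks(spec, tp.PeakRange(100, 900, 300, 2500))
        assert tk.n_invalid > 0
        assert np.all(np.isnan(tk.f_of_k[~tk.fk_valid]))

    def test_refinement_stays_within_one_bin(self, kv_field_2d):
        pr = tp.PeakRange(100, 500, 500, 1500)
        spec = tp.fk_transform(kv_field_2d, 4)
        a = tp.extract_twin_peaks(spec, pr, refine=False)
        b = tp.extract_twin_peaks(spec, pr, refine=True)
        assert np.nanmax(np.abs(a.k_of_f - b.k_of_f)) <= spec.dk / 2 * (1 + 1e-9)

    def test_range_outside_support_rejected(self):
        spec = self._delta_spectrum()
        with pytest.raises(ValidationError):
            tp.extract_twin_peaks(spec, tp.PeakRange(2000, 3000, 100, 200))


class TestNormalizeForDisplay:
    def test_columns_reach_unity(self, kv_field_2d):
        spec = tp.fk_transform(kv_field_2d, 2)
        norm = tp.normalize_for_display(spec, axis="k")
        np.testing.assert_allclose(norm.max(axis=0), 1.0)
        assert norm.min() >= 0.0

    def test_constant_spectrum_all_ones(self):
        f = np.linspace(0, 10, 5)
        k = np.linspace(0, 10, 7)
        spec = tp.FKSpectrum(np.ones((5, 7), dtype=complex), f, k, pad={})
        np.testing.assert_array_equal(tp.normalize_for_display(spec, "f"), 1.0)

    def test_ridge_traces_peak_curve(self, kv_field_2d):
        pr = tp.PeakRange(100, 500, 500, 1500)
        spec = tp.fk_transform(kv_field_2d, 4)
        tk = tp.extract_twin_peaks(spec, pr)
        norm = tp.normalize_for_display(spec, axis="k")
        # at each retained k column the normalized value at the peak f is 1
        for kval, fval, ok in zip(tk.k_grid, tk.f_of_k, tk.fk_valid):
            if not ok:
                continue
            i = np.argmin(np.abs(spec.f - fval))
            j = np.argmin(np.abs(spec.k - kval))
            assert norm[i, j] == pytest.approx(1.0)


class TestMethodContracts:
    def test_spread_between_curves_increases_with_tau(self, medium, source,
                                                      default_grid):
        """The area between the f(k) and k(f) curves over a fixed band grows
        strictly with relaxation time — the observable the inversion exploits."""
        areas = []
        for tau in (0.1e-3, 0.3e-3, 0.5e-3, 0.7e-3, 1.0e-3):
            kv = tp.KelvinVoigtParams(2000.0, tau)
            fld = tp.simulate_time_kv(kv, medium, source, default_grid, dims=2,
                                      observe=tp.Observation())
            tk = tp.extract_twin_peaks(tp.fk_transform(fld, 4),
                                       tp.PeakRange(50, 800, 200, 1600))
            ok = ~np.isnan(tk.k_of_f)
            f_kf = np.interp(tk.k_grid, tk.k_of_f[ok], tk.f_grid[ok])
            band = (tk.k_grid >= 500) & (tk.k_grid <= 1200)
            areas.append(np.trapezoid(np.abs(tk.f_of_k - f_kf)[band],
                                      tk.k_grid[band]))
        assert np.all(np.diff(areas) > 0)

    def test_split_directions_symmetric_field(self):
        dx, dt = 0.5e-3, 0.2e-3
        x = (np.arange(41) - 20) * dx
        t = np.arange(64) * dt
        v = np.cos(2e3 * t[None, :] - 900 * np.abs(x)[:, None]) * \
            np.exp(-np.abs(x)[:, None] / 8e-3)
        fld = tp.MotionField(v, x, t)
        right, left = tp.split_directions(fld)
        np.testing.assert_allclose(right.velocity, left.velocity, atol=1e-14)
        assert right.x[0] == 0.0 and left.x[0] == 0.0
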