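"""Transfer-matrix optics: closed-form oracles and physical invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from guanoptics import tmm


class TestFresnel:
    def test_normal_incidence_closed_form(self):
        r, t = tmm.fresnel_coefficients(1.34, 1.83, 0.0, "s")
        assert r == pytest.approx((1.34 - 1.83) / (1.34 + 1.83), abs=1e-12)
        rp, tp = tmm.fresnel_coefficients(1.34, 1.83, 0.0, "p")
        # p convention differs only in sign at normal incidence
        assert abs(rp) == pytest.approx(abs(r), abs=1e-12)

    @pytest.mark.parametrize("pol", ["s", "p"])
    @pytest.mark.parametrize("theta", [0.0, 25.0, 60.0])
    def test_index_matched_interface(self, pol, theta):
        r, t = tmm.fresnel_coefficients(1.5, 1.5, theta, pol)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert t == pytest.approx(1.0, abs=1e-12)

    def test_brewster_angle_kills_p_reflection(self):
        theta_b = np.degrees(np.arctan(1.83 / 1.34))
        r, _ = tmm.fresnel_coefficients(1.34, 1.83, theta_b, "p")
        assert abs(r) < 1e-9

    def test_stokes_relations(self):
        # r' = -r and t t' = 1 - r^2 across one interface
        r, t = tmm.fresnel_coefficients(1.34, 1.83, 20.0, "s")
        th2 = np.degrees(np.arcsin(1.34 * np.sin(np.radians(20.0)) / 1.83))
        rp, tp = tmm.fresnel_coefficients(1.83, 1.34, th2, "s")
        assert rp == pytest.approx(-r, abs=1e-12)
        assert t * tp == pytest.approx(1 - r**2, abs=1e-12)

    def test_evanescent_regime_is_an_explicit_error(self):
        with pytest.raises(tmm.EvanescentWaveError):
            tmm.fresnel_coefficients(1.83, 1.34, 60.0, "s")


class TestStackReflectance:
    def test_homogeneous_medium_reflects_nothing(self, wavelengths):
        opt = tmm.OpticalConstants(n_platelet=1.34, n_gap=1.34, n_ambient=1.34)
        stack = tmm.StackGeometry((53.0,) * 6, (70.0,) * 5)
        spec = tmm.stack_reflectance(stack, opt, wavelengths)
        assert np.allclose(spec.reflectance, 0.0, atol=1e-12)

    @pytest.mark.parametrize("theta,pol", [(0.0, "s"), (0.0, "p"), (30.0, "s"), (30.0, "p")])
    def test_single_film_matches_airy_formula(self, optics, wavelengths, theta, pol):
        # independent closed-form thin-film oracle
        stack = tmm.StackGeometry((53.0,), ())
        spec = tmm.stack_reflectance(stack, optics, wavelengths, theta=theta, polarization=pol)
        n0, n1 = optics.n_ambient, optics.n_platelet
        th0 = np.radians(theta)
        c0 = np.cos(th0)
        s1 = n0 * np.sin(th0) / n1
        c1 = np.sqrt(1 - s1**2)
        if pol == "s":
            r01 = (n0 * c0 - n1 * c1) / (n0 * c0 + n1 * c1)
        else:
            r01 = (n1 * c0 - n0 * c1) / (n1 * c0 + n0 * c1)
        r10 = -r01
        delta = 2 * np.pi * n1 * 53.0 * c1 / wavelengths
        r = (r01 + r10 * np.exp(2j * delta)) / (1 + r01 * r10 * np.exp(2j * delta))
        assert np.max(np.abs(spec.reflectance - np.abs(r) ** 2)) < 1e-9

    def test_quarter_wave_stack_matches_admittance_formula(self, optics):
        # admittance closed form at the design wavelength
        lam0 = 2 * (53 * 1.83 + 70 * 1.34)
        nH, nL, m = 1.83, 1.34, 6
        stack = tmm.StackGeometry((lam0 / 4 / nH,) * m, (lam0 / 4 / nL,) * (m - 1))
        Y = (nH**2 / nL**2) ** (m - 1) * nH**2 / nL
        expected = ((nL - Y) / (nL + Y)) ** 2
        spec = tmm.stack_reflectance(stack, optics, np.array([lam0 - 1.0, lam0, lam0 + 1.0]))
        assert spec.reflectance[1] == pytest.approx(expected, abs=1e-9)

    def test_mean_stack_peak(self, mean_stack_spectrum):
        # bright blue-violet reflector: peak in the measured single-stack band
        pm = tmm.peak_metrics(mean_stack_spectrum)
        assert 350.0 <= pm.peak_wavelength <= 500.0
        assert pm.peak_reflectance >= 0.73

    @pytest.mark.parametrize("theta", [0.0, 15.0, 30.0, 45.0, 60.0])
    @pytest.mark.parametrize("pol", ["s", "p", "unpolarized"])
    def test_energy_conservation(self, mean_stack, optics, wavelengths, theta, pol):
        spec = tmm.stack_reflectance(mean_stack, optics, wavelengths, theta, pol)
        assert np.max(np.abs(spec.reflectance + spec.transmittance - 1.0)) < 1e-9
        assert np.all(spec.reflectance >= 0) and np.all(spec.reflectance <= 1)

    def test_reciprocity_layer_order_reversal(self, optics, wavelengths):
        rng = np.random.default_rng(0)
        t = tuple(rng.uniform(40, 70, 5))
        g = tuple(rng.uniform(50, 100, 4))
        a = tmm.StackGeometry(t, g)
        spec_a = tmm.stack_reflectance(a, optics, wavelengths, theta=20.0)
        spec_b = tmm.stack_reflectance(a.reversed(), optics, wavelengths, theta=20.0)
        assert np.max(np.abs(spec_a.reflectance - spec_b.reflectance)) < 1e-9

    def test_blue_shift_with_angle(self, mean_stack, optics):
        # iridescence of a single stack: peak non-increasing in theta
        wl = tmm.default_wavelengths(250.0, 800.0)
        peaks = [
            tmm.peak_metrics(tmm.stack_reflectance(mean_stack, optics, wl, theta=th)).peak_wavelength
            for th in np.arange(0.0, 61.0, 10.0)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(peaks, peaks[1:]))

    def test_bragg_consistency_of_tmm_peak(self, mean_stack, optics):
        # TMM peak vs volume-averaged-index Bragg prediction within 5 %
        wl = tmm.default_wavelengths(250.0, 800.0, 0.5)
        n_avg = tmm.volume_averaged_index(53.0, 70.0, optics)
        for theta in (0.0, 15.0, 30.0, 45.0):
            internal = np.degrees(
                np.arcsin(optics.n_ambient * np.sin(np.radians(theta)) / n_avg)
            )
            lam_bragg = tmm.bragg_peak_wavelength(n_avg, 123.0, internal)
            pm = tmm.peak_metrics(tmm.stack_reflectance(mean_stack, optics, wl, theta=theta))
            assert abs(pm.peak_wavelength - lam_bragg) / lam_bragg < 0.05

    def test_bad_grid_rejected(self, mean_stack, optics):
        with pytest.raises(ValueError):
            tmm.stack_reflectance(mean_stack, optics, np.array([]))
        with pytest.raises(ValueError):
            tmm.stack_reflectance(mean_stack, optics, np.array([500.0, 400.0]))


class TestBraggLaw:
    def test_mean_geometry_prediction(self):
        n_avg = tmm.volume_averaged_index(53.0, 70.0)
        assert n_avg == pytest.approx(1.55114, abs=1e-4)
        assert tmm.bragg_peak_wavelength(n_avg, 123.0, 0.0) == pytest.approx(381.6, abs=0.1)

    def test_sixty_degrees_halves_the_wavelength(self):
        assert tmm.bragg_peak_wavelength(1.55, 123.0, 60.0) == pytest.approx(
            0.5 * tmm.bragg_peak_wavelength(1.55, 123.0, 0.0)
        )

    @given(st.floats(0.0, 89.0), st.floats(0.0, 89.0))
    @settings(max_examples=50, deadline=None)
    def test_cosine_monotonicity(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert tmm.bragg_peak_wavelength(1.55, 123.0, hi) <= tmm.bragg_peak_wavelength(
            1.55, 123.0, lo
        ) + 1e-9

    def test_volume_average_limits(self):
        assert tmm.volume_averaged_index(10.0, 10.0) == pytest.approx((1.83 + 1.34) / 2)
        assert tmm.volume_averaged_index(10.0, 0.0) == pytest.approx(1.83)
        with pytest.raises(ValueError):
            tmm.volume_averaged_index(0.0, 0.0)


class TestPeakMetrics:
    def test_gaussian_fwhm_identity(self):
        wl = np.arange(300.0, 800.5, 0.5)
        sigma = 30.0
        spec = tmm.ReflectanceSpectrum(
            wl, 0.9 * np.exp(-((wl - 450.0) ** 2) / (2 * sigma**2)),
            1 - 0.9 * np.exp(-((wl - 450.0) ** 2) / (2 * sigma**2)),
        )
        pm = tmm.peak_metrics(spec)
        assert pm.peak_wavelength == pytest.approx(450.0, abs=0.5)
        assert pm.fwhm == pytest.approx(2.3548 * sigma, abs=1.0)

    def test_mean_stack_fwhm_in_reported_band(self, mean_stack_spectrum):
        pm = tmm.peak_metrics(mean_stack_spectrum)
        assert 80.0 <= pm.fwhm <= 120.0

    def test_flat_top_ties_break_to_lowest_wavelength(self):
        wl = np.arange(400.0, 501.0, 1.0)
        r = np.zeros_like(wl)
        r[30:60] = 0.5
        spec = tmm.ReflectanceSpectrum(wl, r, 1 - r)
        assert tmm.peak_metrics(spec).peak_wavelength == wl[30]

    def test_zero_spectrum_flags_undefined(self):
        wl = np.arange(400.0, 501.0, 1.0)
        spec = tmm.ReflectanceSpectrum(wl, np.zeros_like(wl), np.ones_like(wl))
        pm = tmm.peak_metrics(spec)
        assert not pm.defined

    def test_missing_half_crossing_gives_none(self):
        wl = np.arange(400.0, 501.0, 1.0)
        r = np.linspace(0.6, 1.0, wl.size)  # monotone: no left half-crossing region
        spec = tmm.ReflectanceSpectrum(wl, r, 1 - r)
        assert tmm.peak_metrics(spec).fwhm is None


class TestTypes:
    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            tmm.StackGeometry((), ())
        with pytest.raises(ValueError):
            tmm.StackGeometry((53.0, 53.0), ())
        with pytest.raises(ValueError):
            tmm.StackGeometry((53.0,), (), orientation_polar=120.0)
        with pytest.raises(ValueError):
            tmm.StackGeometry((-5.0,), ())

    def test_optical_constants_invariants(self):
        with pytest.raises(ValueError):
            tmm.OpticalConstants(n_platelet=0.5)

    def test_spectrum_round_trips_to_csv(self, mean_stack_spectrum, tmp_path):
        import pandas as pd

        path = tmp_path / "spec.csv"
        mean_stack_spectrum.to_csv(path, {"note": "test"})
        df = pd.read_csv(path)
        assert list(df.columns) == ["wavelength_nm", "reflectance", "transmittance"]
        assert len(df) == mean_stack_spectrum.wavelengths.size
        assert path.with_suffix(".csv.meta.json").exists()
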