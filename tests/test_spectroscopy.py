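"""Focal spots, wavelength fits, dispersion assembly, central frequency."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselwave import synthesize as syn
from vesselwave.geometry import CurvilinearSignal
from vesselwave.spectroscopy import (
    FitError,
    central_frequency,
    dispersion_curve,
    fit_wavelength,
    focal_spot,
    polychromatic_focal_spot,
    spectral_peaks,
    temporal_spectrum,
)
from vesselwave.theory import v_fpw_lowfreq


def plane_wave_signal(lam=2e-3, f0=3.0, aperture=5.3e-3, n_x=200, fs=38.0, duration=2.0, phases=(0.0,)):
    """Single unidirectional plane wave on a uniform curvilinear grid."""
    x = np.linspace(0.0, aperture, n_x)
    t = np.arange(int(fs * duration)) / fs
    v = lam * f0
    u = syn.propagate(syn.SourceSpectrum(f0, (1.0,), phases=phases), syn.ModeSpec("antisymmetric", v), x, t)
    return CurvilinearSignal(x=x, t=t, phi=u)


class TestTemporalSpectrum:
    def test_pure_tone_single_bin(self):
        sig = plane_wave_signal(f0=3.0)
        field = temporal_spectrum(sig)
        spec = field.mean_spectrum
        assert field.f[np.argmax(spec)] == pytest.approx(3.0)
        others = spec[np.abs(field.f - 3.0) > 1e-9]
        assert others.max() < 1e-9 * spec.max()

    def test_constant_signal_detrended_is_silent(self):
        x = np.linspace(0, 1e-3, 20)
        t = np.arange(32) / 38.0
        sig = CurvilinearSignal(x=x, t=t, phi=np.ones((20, 32)) * 3.7)
        field = temporal_spectrum(sig, detrend=True)
        assert np.abs(field.phi_hat[:, 1:]).max() < 1e-10

    def test_two_tone_amplitude_ratio(self):
        x = np.linspace(0, 5e-3, 50)
        t = np.arange(76) / 38.0
        u = syn.propagate(syn.SourceSpectrum(1.5, (1.0, 0.0, 0.4)), syn.ModeSpec("antisymmetric", 5e-3), x, t)
        field = temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=u))
        a1 = field.mean_spectrum[np.argmin(np.abs(field.f - 1.5))]
        a3 = field.mean_spectrum[np.argmin(np.abs(field.f - 4.5))]
        assert a3 / a1 == pytest.approx(0.4, rel=1e-6)

    def test_too_short_record_rejected(self):
        x = np.linspace(0, 1e-3, 4)
        t = np.arange(8) / 38.0
        with pytest.raises(ValueError, match="16"):
            temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=np.zeros((4, 8))))


class TestFocalSpot:
    def test_plane_wave_gives_exact_cosine(self):
        lam = 2e-3
        sig = plane_wave_signal(lam=lam, phases=(0.7,))
        spot = focal_spot(temporal_spectrum(sig), 3.0)
        assert np.max(np.abs(spot.C - np.cos(2 * math.pi * spot.r / lam))) <= 1e-10

    def test_zero_lag_unity(self):
        spot = focal_spot(temporal_spectrum(plane_wave_signal()), 3.0)
        assert spot.C[np.argmin(np.abs(spot.r))] == 1.0

    def test_counterpropagating_waves_give_even_spot(self):
        x = np.linspace(0.0, 5.3e-3, 150)
        t = np.arange(76) / 38.0
        spec = syn.SourceSpectrum(3.0, (1.0,), phases=(0.4,))
        u = syn.propagate(spec, syn.ModeSpec("antisymmetric", 6e-3, direction=1), x, t)
        u += syn.propagate(spec, syn.ModeSpec("antisymmetric", 6e-3, direction=-1), x, t)
        spot = focal_spot(temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=u)), 3.0)
        assert np.allclose(spot.C, spot.C[::-1], atol=1e-12)

    def test_single_position_rejected(self):
        x = np.array([0.0])
        t = np.arange(32) / 38.0
        field = temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=np.random.default_rng(0).normal(size=(1, 32))))
        with pytest.raises(ValueError, match="positions"):
            focal_spot(field, 3.0)

    def test_off_grid_frequency_warns(self):
        field = temporal_spectrum(plane_wave_signal())
        with pytest.warns(UserWarning, match="snapped"):
            focal_spot(field, 3.1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0), slope=st.floats(-0.5, 0.5))
    def test_amplitude_envelope_invariance(self, scale, slope):
        # the phase-only correlation must ignore any positive envelope
        sig = plane_wave_signal()
        env = scale * (1.0 + slope * np.linspace(-1, 1, sig.x.size))
        assert np.all(env > 0)
        scaled = CurvilinearSignal(x=sig.x, t=sig.t, phi=env[:, None] * sig.phi)
        c0 = focal_spot(temporal_spectrum(sig), 3.0).C
        c1 = focal_spot(temporal_spectrum(scaled), 3.0).C
        assert np.allclose(c0, c1, atol=1e-10)


class TestFitWavelength:
    def synthetic_spot(self, lam, aperture, n=200, f=1.0):
        from vesselwave.spectroscopy import FocalSpot

        r = np.linspace(-aperture, aperture, 2 * n + 1)
        return FocalSpot(r=r, C=np.cos(2 * math.pi * r / lam), f_center=f)

    def test_exact_cosine_recovered_to_4_digits(self):
        spot = self.synthetic_spot(2e-3, 5.3e-3)
        lam, sigma = fit_wavelength(spot)
        assert lam == pytest.approx(2e-3, rel=1e-4)
        assert sigma < 1e-5 * lam

    def test_quarter_wavelength_aperture_still_recovers(self):
        # only part of the central lobe visible: noiseless fit within 10%
        lam0 = 16e-3
        spot = self.synthetic_spot(lam0, aperture=lam0 / 4)
        lam, _ = fit_wavelength(spot)
        assert lam == pytest.approx(lam0, rel=0.10)

    def test_flat_correlation_raises(self):
        from vesselwave.spectroscopy import FocalSpot

        r = np.linspace(-1e-3, 1e-3, 41)
        with pytest.raises(FitError, match="flat"):
            fit_wavelength(FocalSpot(r=r, C=np.ones_like(r), f_center=1.0))

    def test_too_few_lags_raises(self):
        from vesselwave.spectroscopy import FocalSpot

        r = np.linspace(-1e-3, 1e-3, 5)
        with pytest.raises(FitError, match="lags"):
            fit_wavelength(FocalSpot(r=r, C=np.cos(2 * math.pi * r / 1e-3), f_center=1.0))


class TestDispersionCurve:
    def test_flexural_law_recovered_with_half_power_exponent(self):
        geom = syn.RETINAL_GEOMETRY
        x = np.linspace(0.0, 5.3e-3, 300)
        t = np.arange(304) / 38.0
        src = syn.SourceSpectrum(1.5, (1.0,) * 7, phases=tuple(np.random.default_rng(3).uniform(0, 2 * np.pi, 7)))
        u = syn.propagate(src, syn.ModeSpec("antisymmetric", lambda f: v_fpw_lowfreq(f, geom)), x, t)
        field = temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=u))
        curve = dispersion_curve(field, src.frequencies)
        assert curve.fit_ok.all()
        slope = np.polyfit(np.log(curve.f * geom.d), np.log(curve.v_phase), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.02)

    def test_nondispersive_curve_flat(self):
        x = np.linspace(0.0, 5.3e-3, 200)
        t = np.arange(152) / 38.0
        src = syn.SourceSpectrum(1.5, (1.0, 0.8, 0.6))
        u = syn.propagate(src, syn.ModeSpec("antisymmetric", 8e-3), x, t)
        curve = dispersion_curve(temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=u)), src.frequencies)
        assert np.all(np.abs(curve.v_phase / 8e-3 - 1.0) < 0.02)

    def test_velocity_is_exactly_lambda_times_f(self):
        sig = plane_wave_signal()
        curve = dispersion_curve(temporal_spectrum(sig), [3.0])
        assert curve.v_phase[0] == curve.lam[0] * curve.f[0]

    def test_failed_fits_flagged_not_dropped(self):
        sig = plane_wave_signal()
        # add a spatially uniform tone at 1.5 Hz: its focal spot is flat
        # (C = 1 everywhere), which carries no wavelength information
        phi = sig.phi + np.cos(2 * np.pi * 1.5 * sig.t)[None, :]
        curve = dispersion_curve(
            temporal_spectrum(CurvilinearSignal(x=sig.x, t=sig.t, phi=phi)), [3.0, 1.5]
        )
        assert curve.fit_ok[0]
        assert not curve.fit_ok[1]
        assert np.isnan(curve.lam[1])
        assert curve.f.size == 2

    def test_empty_frequency_list_rejected(self):
        with pytest.raises(ValueError):
            dispersion_curve(temporal_spectrum(plane_wave_signal()), [])


class TestPolychromatic:
    def test_single_tone_band_equals_monochromatic(self):
        field = temporal_spectrum(plane_wave_signal(f0=3.0))
        mono = focal_spot(field, 3.0)
        poly = polychromatic_focal_spot(field, (2.0, 4.0))
        assert np.allclose(poly.C, mono.C, atol=1e-9)
        assert poly.f_center == pytest.approx(3.0)

    def test_narrowband_wave_poly_wavelength_near_band_center(self):
        x = np.linspace(0.0, 0.04, 64)
        t = np.arange(1000) / 500.0
        src = syn.SourceSpectrum(1.5, (0.0, 0.0, 0.0, 0.8, 1.0, 0.8))
        u = syn.propagate(src, syn.ModeSpec("antisymmetric", 0.5), x, t)
        field = temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=u))
        lam_mono, _ = fit_wavelength(focal_spot(field, 7.5))
        lam_poly, _ = fit_wavelength(polychromatic_focal_spot(field, (5.5, 9.5)))
        assert lam_poly == pytest.approx(lam_mono, rel=0.05)

    def test_diffuse_field_central_peak_narrows_with_band(self, rng):
        # standing diffuse field: many counter-propagating random waves;
        # averaging over a wider band sharpens the correlation peak
        x = np.linspace(0.0, 0.04, 96)
        t = np.arange(1000) / 500.0
        v = 0.5
        u = np.zeros((x.size, t.size))
        for k in range(2, 41):
            f = 0.5 * k
            for direction in (1, -1):
                a = rng.uniform(0.5, 1.0)
                ph = rng.uniform(0, 2 * np.pi)
                u += a * np.cos(2 * np.pi * f * t[None, :] - direction * 2 * np.pi * f / v * x[:, None] + ph)
        field = temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=u))

        def first_zero(spot):
            i0 = np.argmin(np.abs(spot.r))
            neg = np.nonzero(spot.C[i0:] < 0)[0]
            return spot.r[i0:][neg[0]] if neg.size else np.inf

        widths = [first_zero(polychromatic_focal_spot(field, band)) for band in [(4, 6), (2, 12), (1, 20)]]
        assert widths[0] > widths[1] > widths[2]

    def test_empty_band_rejected(self):
        field = temporal_spectrum(plane_wave_signal())
        with pytest.raises(ValueError, match="band"):
            polychromatic_focal_spot(field, (20.0, 25.0))


class TestCentralFrequency:
    def test_pure_tone(self):
        t = np.arange(1000) / 500.0
        f = central_frequency(np.cos(2 * np.pi * 7.5 * t), frame_rate=500.0)
        # one lag quantum at the 7.5 Hz period corresponds to ~0.12 Hz
        assert f == pytest.approx(7.5, abs=0.12)

    def test_bandlimited_noise_estimate_inside_band(self, rng):
        # 6-19 Hz band-limited noise: the autocorrelation period must fall
        # inside the band for every trial
        n, fs = 2000, 500.0
        freqs = np.fft.rfftfreq(n, 1 / fs)
        for _ in range(5):
            shape = ((freqs >= 6.0) & (freqs <= 19.0)).astype(float)
            spec = shape * np.exp(2j * np.pi * rng.uniform(size=freqs.size))
            x = np.fft.irfft(spec, n=n)
            f = central_frequency(x, frame_rate=fs)
            assert 6.0 <= f <= 19.0

    def test_dc_signal_raises(self):
        with pytest.raises(ValueError):
            central_frequency(np.ones(100), frame_rate=500.0)

    def test_matrix_input_averages_positions(self):
        sig = plane_wave_signal(f0=3.0, duration=4.0)
        assert central_frequency(sig) == pytest.approx(3.0, abs=0.06)


class TestSpectralPeaks:
    def test_harmonic_comb_found(self):
        x = np.linspace(0.0, 5.3e-3, 100)
        t = np.arange(304) / 38.0
        src = syn.SourceSpectrum(1.5, (1.0, 0.9, 0.8))
        u = syn.propagate(src, syn.ModeSpec("antisymmetric", 8e-3), x, t)
        field = temporal_spectrum(CurvilinearSignal(x=x, t=t, phi=u))
        assert np.allclose(spectral_peaks(field, prominence=0.2), [1.5, 3.0, 4.5])
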