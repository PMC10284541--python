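"""Passive spectroscopy: per-frequency focal spots, wavelengths, dispersion.

Instead of correlating raw traces (which yields a group velocity), the
signal is Fourier-transformed in time and a phase-only spatial
correlation is formed at each frequency,

    C(f, r) = < cos( arg phi_hat_s(f) - arg phi_hat_{s+r}(f) ) >_s ,

the average running over every source abscissa ``s`` such that both ends
of the lag ``r`` lie on the vessel.  Discarding the Fourier modulus
normalizes the correlation and whitens the spectrum, so any positive
amplitude envelope along the vessel drops out.  For a single
unidirectional plane wave the focal spot is exactly ``cos(2 pi r /
lambda)``; a sinusoidal fit of the central peak therefore measures the
wavelength, and ``v = lambda * f`` gives the phase velocity, frequency
by frequency — a dispersion curve from entirely uncontrolled wave
sources.  A band-averaged (polychromatic) focal spot and an
autocorrelation central-frequency estimator cover broadband traces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .geometry import CurvilinearSignal

__all__ = [
    "SpectralField",
    "FocalSpot",
    "DispersionCurve",
    "FitError",
    "temporal_spectrum",
    "spectral_peaks",
    "focal_spot",
    "fit_wavelength",
    "dispersion_curve",
    "polychromatic_focal_spot",
    "central_frequency",
]

MIN_TIME_SAMPLES = 16


class FitError(RuntimeError):
    """Raised when a wavelength fit cannot be performed or did not converge."""


@dataclass
class SpectralField:
    """Per-position temporal Fourier transform of a curvilinear signal."""

    x: np.ndarray
    f: np.ndarray
    phi_hat: np.ndarray  # (n_positions, n_frequencies), complex
    mean_spectrum: np.ndarray  # magnitude averaged over positions

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])


@dataclass
class FocalSpot:
    """Normalized spatial correlation ``C(r)`` at one frequency or band."""

    r: np.ndarray
    C: np.ndarray
    f_center: float
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        i0 = int(np.argmin(np.abs(self.r)))
        if abs(self.r[i0]) > 1e-15 or abs(self.C[i0] - 1.0) > 1e-12:
            raise ValueError("focal spot must satisfy C(0) = 1")
        if np.any(np.abs(self.C) > 1.0 + 1e-12):
            raise ValueError("|C(r)| must not exceed 1")


@dataclass
class DispersionCurve:
    """Wavelength and phase velocity per analysis frequency, with 1-sigma errors."""

    f: np.ndarray
    lam: np.ndarray
    lam_sigma: np.ndarray
    fit_ok: np.ndarray

    @property
    def v_phase(self) -> np.ndarray:
        """Phase velocity ``lambda * f`` — enforced exactly, no independent rounding."""
        return self.lam * self.f

    @property
    def v_sigma(self) -> np.ndarray:
        return self.lam_sigma * self.f

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f_hz": self.f,
                "lambda_m": self.lam,
                "lambda_sigma_m": self.lam_sigma,
                "v_m_per_s": self.v_phase,
                "v_sigma_m_per_s": self.v_sigma,
                "fit_ok": self.fit_ok,
            }
        )


def temporal_spectrum(sig: CurvilinearSignal, detrend: bool = False, pad_factor: int = 1) -> SpectralField:
    """Per-position FFT over the full record (rectangular window).

    With ``detrend=True`` a per-trace linear drift is removed first.
    ``pad_factor > 1`` zero-pads the record before the FFT to refine the
    frequency sampling of the magnitude spectrum for peak localization;
    phases at bin-aligned harmonics are unaffected.
    """
    phi = sig.phi
    if phi.shape[1] < MIN_TIME_SAMPLES:
        raise ValueError(f"need at least {MIN_TIME_SAMPLES} time samples, got {phi.shape[1]}")
    if detrend:
        phi = signal.detrend(phi, axis=1, type="linear")
    else:
        phi = phi - phi.mean(axis=1, keepdims=True)
    n = phi.shape[1] * int(pad_factor)
    phi_hat = np.fft.rfft(phi, n=n, axis=1)
    f = np.fft.rfftfreq(n, d=sig.dt)
    return SpectralField(x=sig.x.copy(), f=f, phi_hat=phi_hat, mean_spectrum=np.abs(phi_hat).mean(axis=0))


def spectral_peaks(field: SpectralField, prominence: float = 0.1, f_min: float = 0.0) -> np.ndarray:
    """Frequencies of local maxima of the mean magnitude spectrum.

    ``prominence`` is relative to the largest spectral value; peaks at or
    below ``f_min`` (and DC) are discarded.
    """
    spec = field.mean_spectrum
    idx, _ = signal.find_peaks(spec, prominence=prominence * spec.max())
    f = field.f[idx]
    return f[f > max(f_min, 0.0)]


def focal_spot(field: SpectralField, f: float) -> FocalSpot:
    """Monochromatic focal spot: phase-only spatial correlation at frequency ``f``.

    ``f`` is snapped to the nearest frequency bin (with a warning when
    not exact).  For every spatial lag ``r = m * dx`` the correlation
    averages ``cos(delta arg)`` over all valid position pairs; the result
    is extended symmetrically to negative lags (the pair set is
    identical, so ``C`` is even by construction).
    """
    if field.x.size < 2:
        raise ValueError("need at least 2 positions for a focal spot")
    j = int(np.argmin(np.abs(field.f - f)))
    if abs(field.f[j] - f) > 1e-9 * max(1.0, abs(f)):
        warnings.warn(
            f"frequency {f} Hz snapped to nearest bin {field.f[j]:.6g} Hz",
            stacklevel=2,
        )
    ph = np.angle(field.phi_hat[:, j])
    n = ph.size
    C_pos = np.empty(n)
    C_pos[0] = 1.0
    for m in range(1, n):
        C_pos[m] = np.cos(ph[: n - m] - ph[m:]).mean()
    r_pos = np.arange(n) * field.dx
    r = np.concatenate([-r_pos[:0:-1], r_pos])
    C = np.concatenate([C_pos[:0:-1], C_pos])
    return FocalSpot(r=r, C=C, f_center=float(field.f[j]))


def polychromatic_focal_spot(sig: CurvilinearSignal | SpectralField, band: tuple[float, float]) -> FocalSpot:
    """Band-averaged focal spot, weighted by the mean spectral magnitude.

    Monochromatic focal spots of every frequency bin inside ``band``
    (inclusive) are averaged with weights proportional to the mean
    spectrum, emphasising the frequencies that actually carry energy.
    """
    field = temporal_spectrum(sig) if isinstance(sig, CurvilinearSignal) else sig
    f_lo, f_hi = band
    if f_hi < f_lo:
        raise ValueError("band must be (f_low, f_high) with f_low <= f_high")
    mask = (field.f >= f_lo) & (field.f <= f_hi) & (field.f > 0)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    idx = np.nonzero(mask)[0]
    weights = field.mean_spectrum[idx]
    if weights.sum() == 0:
        weights = np.ones_like(weights)
    C_sum = None
    for j, w in zip(idx, weights):
        spot = focal_spot(field, field.f[j])
        C_sum = w * spot.C if C_sum is None else C_sum + w * spot.C
    C = C_sum / weights.sum()
    f_center = float(np.sum(weights * field.f[idx]) / weights.sum())
    return FocalSpot(r=spot.r, C=C, f_center=f_center, band=(float(f_lo), float(f_hi)))


def _central_window(r: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, float]:
    """Mask of the central-peak fit window and the initial wavelength guess.

    The window runs from the first negative-going zero crossing left of
    ``r = 0`` to the first one on the right when both are visible;
    otherwise the whole aperture is used (the carotid regime, where the
    wavelength far exceeds the aperture and the fit extrapolates from the
    central-lobe curvature).  The initial guess is four times the
    zero-crossing lag, or eight times the aperture when no crossing is
    visible.
    """
    i0 = int(np.argmin(np.abs(r)))
    right = np.nonzero(C[i0:] < 0.0)[0]
    left = np.nonzero(C[: i0 + 1][::-1] < 0.0)[0]
    aperture = r.max()
    if right.size and left.size:
        hi = i0 + int(right[0])
        lo = i0 - int(left[0])
        window = np.zeros(r.size, dtype=bool)
        window[lo : hi + 1] = True
        lam0 = 4.0 * abs(r[hi])
    else:
        window = np.ones(r.size, dtype=bool)
        lam0 = 8.0 * aperture
    return window, lam0


def fit_wavelength(spot: FocalSpot) -> tuple[float, float]:
    """Wavelength and 1-sigma uncertainty from a sinusoidal central-peak fit.

    Nonlinear least squares of ``C(r) = cos(2 pi r / lambda)`` on the
    central-peak window.  Requires at least 8 lags; raises
    :class:`FitError` when the correlation is flat (no wavelength
    information), the fit does not converge, or the wavelength runs into
    its search bounds.
    """
    r, C = spot.r, spot.C
    if r.size < 8:
        raise FitError("focal spot has fewer than 8 lags")
    if float(np.ptp(C)) < 1e-12:
        raise FitError("flat correlation: no wavelength information (single position or zero signal)")
    window, lam0 = _central_window(r, C)
    r_w, C_w = r[window], C[window]
    dr = np.min(np.diff(np.unique(r)))
    lo_bound, hi_bound = dr, 1e4 * r.max()
    try:
        popt, pcov = optimize.curve_fit(
            lambda rr, lam: np.cos(2.0 * math.pi * rr / lam),
            r_w,
            C_w,
            p0=[np.clip(lam0, lo_bound, hi_bound)],
            bounds=([lo_bound], [hi_bound]),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"wavelength fit failed to converge: {exc}") from exc
    lam = float(popt[0])
    if lam <= lo_bound * 1.01 or lam >= hi_bound * 0.99:
        raise FitError(f"fitted wavelength {lam:.3g} m hit the search bounds")
    sigma = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return lam, sigma


def dispersion_curve(field: SpectralField, f_list) -> DispersionCurve:
    """Fit the wavelength at each requested frequency and assemble ``v = lambda f``.

    Frequencies whose fit fails are flagged (``fit_ok = False``, NaN
    wavelength) rather than silently dropped.  The velocity uncertainty
    is ``f * sigma_lambda`` (the frequency error of bin-aligned harmonics
    is negligible).
    """
    f_list = np.atleast_1d(np.asarray(f_list, dtype=float))
    if f_list.size == 0:
        raise ValueError("f_list must not be empty")
    lam = np.full(f_list.shape, np.nan)
    lam_sigma = np.full(f_list.shape, np.nan)
    ok = np.zeros(f_list.shape, dtype=bool)
    for i, f in enumerate(f_list):
        try:
            lam[i], lam_sigma[i] = fit_wavelength(focal_spot(field, f))
            ok[i] = True
        except (FitError, ValueError):
            continue
    return DispersionCurve(f=f_list, lam=lam, lam_sigma=lam_sigma, fit_ok=ok)


def central_frequency(sig, frame_rate: float | None = None) -> float:
    """Central frequency from the first period of the temporal autocorrelation.

    The normalized autocorrelation of each (zero-meaned) trace is
    averaged over positions; the period is the lag of the first local
    maximum after the first zero crossing, refined by three-point
    parabolic interpolation, and the central frequency is its inverse.
    Accepts a :class:`~vesselwave.geometry.CurvilinearSignal`, or a 1-D /
    (positions x time) array together with ``frame_rate``.
    """
    if isinstance(sig, CurvilinearSignal):
        phi = sig.phi
        dt = sig.dt
    else:
        phi = np.atleast_2d(np.asarray(sig, dtype=float))
        if frame_rate is None:
            raise ValueError("frame_rate is required for array input")
        dt = 1.0 / frame_rate
    phi = phi - phi.mean(axis=1, keepdims=True)
    n = phi.shape[1]
    nfft = 2 * n
    spec = np.abs(np.fft.rfft(phi, n=nfft, axis=1)) ** 2
    ac = np.fft.irfft(spec, n=nfft, axis=1)[:, :n]
    norm = ac[:, 0].copy()
    if np.all(norm <= 0):
        raise ValueError("zero signal: central frequency undefined")
    ac = (ac[norm > 0] / norm[norm > 0, None]).mean(axis=0)

    below = np.nonzero(ac <= 0.0)[0]
    if below.size == 0:
        raise ValueError("autocorrelation has no zero crossing (DC-like signal)")
    z = int(below[0])
    peaks, _ = signal.find_peaks(ac[z:])
    if peaks.size == 0:
        raise ValueError("no autocorrelation maximum after the first zero crossing")
    p = z + int(peaks[0])
    if 0 < p < ac.size - 1:  # parabolic refinement
        denom = ac[p - 1] - 2.0 * ac[p] + ac[p + 1]
        delta = 0.5 * (ac[p - 1] - ac[p + 1]) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    period = (p + delta) * dt
    return 1.0 / period
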