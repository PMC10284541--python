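"""Correlation-based time-of-flight velocimetry.

The classical time-of-flight method follows one wavefront across the
aperture.  Here every position serves as a source: for each spatial
separation ``dx`` the time cross-correlation between the traces at
``x0`` and ``x0 + dx`` is computed, normalized per pair, and averaged
over all ``x0``,

    ToF(dx, dt) = < phi(x0, t) (x)_dt phi(x0 + dx, t) >_x0 ,

so every realisation of a wave crossing the vessel contributes.  A
travelling wave produces a correlation ridge along ``dx = v * dt`` whose
slope is the wave velocity; for a dispersive field the slope is a
band-averaged velocity.  A quadrant filter in the 2-D Fourier plane
optionally isolates one propagation direction (e.g. to reject reflected
waves) before the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft

from .geometry import CurvilinearSignal

__all__ = ["ToFMap", "tof_map", "tof_velocity", "directional_filter"]


@dataclass
class ToFMap:
    """Averaged pairwise correlation versus spatial lag ``dx`` and time lag ``dt``."""

    dx: np.ndarray
    dt: np.ndarray
    value: np.ndarray  # (n_dx, n_dt)

    def __post_init__(self) -> None:
        if self.value.shape != (self.dx.size, self.dt.size):
            raise ValueError("value must have shape (len(dx), len(dt))")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("correlation values must be finite")


def tof_map(sig: CurvilinearSignal, max_dx: float | None = None, max_dt: float | None = None) -> ToFMap:
    """Averaged, per-pair-normalized spatiotemporal correlation map.

    For each nonnegative spatial lag the time-domain cross-correlation
    between every valid trace pair is computed (zero-mean, unit-energy
    per trace, so bright segments do not dominate), averaged, and
    extended to negative spatial lags by the symmetry
    ``ToF(-dx, dt) = ToF(dx, -dt)``.  Positive ``dt`` at positive ``dx``
    means the farther trace lags the nearer one, i.e. a wave travelling
    toward increasing ``x``.
    """
    phi = sig.phi - sig.phi.mean(axis=1, keepdims=True)
    n_x, n_t = phi.shape
    dx_step, dt_step = sig.dx, sig.dt
    m_max = n_x - 1 if max_dx is None else min(n_x - 1, int(np.floor(max_dx / dx_step)))
    l_max = (n_t - 1) // 2 if max_dt is None else min(n_t - 1, int(np.floor(max_dt / dt_step)))
    if m_max < 1:
        raise ValueError("empty valid-pair set: aperture shorter than one spatial step")

    norms = np.linalg.norm(phi, axis=1)
    norms[norms == 0.0] = np.inf  # dead traces contribute zero correlation

    nfft = sfft.next_fast_len(2 * n_t - 1)
    spec = np.fft.rfft(phi, n=nfft, axis=1)

    # cross-correlation c_m(dt) = sum_t phi(x0, t) phi(x0+m, t+dt), via FFT;
    # lag k >= 0 sits at index k of the inverse transform, lag -k at nfft-k
    pos = np.empty((m_max + 1, 2 * l_max + 1))
    for m in range(m_max + 1):
        cross = np.conj(spec[: n_x - m]) * spec[m:]
        weight = 1.0 / (norms[: n_x - m] * norms[m:])
        corr = np.fft.irfft(cross * weight[:, None], n=nfft, axis=1).mean(axis=0)
        pos[m] = np.concatenate([corr[nfft - l_max :], corr[: l_max + 1]])

    dt_grid = np.arange(-l_max, l_max + 1) * dt_step
    dx_grid = np.arange(-m_max, m_max + 1) * dx_step
    value = np.vstack([pos[:0:-1, ::-1], pos])
    return ToFMap(dx=dx_grid, dt=dt_grid, value=value)


def tof_velocity(
    tof: ToFMap,
    corr_threshold: float = 0.25,
    min_points: int = 4,
    n_reweight: int = 5,
) -> tuple[float, float]:
    """Wave velocity from the slope of the correlation ridge.

    The ridge is tracked by continuity outward from the origin: for each
    time lag (increasing in magnitude) the local correlation maximum
    nearest the previously tracked spatial lag is selected and refined by
    three-point parabolic interpolation.  Tracking stops in each
    direction as soon as no local maximum exceeds ``corr_threshold`` or
    the tracked peak jumps back toward the origin (once the true ridge
    leaves the aperture, a periodic source leaves only correlation
    aliases, which must not enter the fit).  A weighted
    least-squares line through the origin (a wave passes ``dx = 0`` at
    ``dt = 0`` by construction), with bisquare reweighting against
    outliers at large lags, gives the velocity; the uncertainty comes
    from the weighted fit residuals.

    Raises
    ------
    RuntimeError
        If fewer than ``min_points`` usable ridge points exist.
    """
    dxs, dts, val = tof.dx, tof.dt, tof.value
    j0 = int(np.argmin(np.abs(dts)))
    dx_step = dxs[1] - dxs[0]
    pts_dt, pts_dx, pts_w = [], [], []
    for direction in (1, -1):
        prev_dx = 0.0
        for k in range(1, max(j0 + 1, dts.size - j0)):
            j = j0 + direction * k
            if not (0 <= j < dts.size):
                break
            col = val[:, j]
            interior = (
                (col[1:-1] >= col[:-2]) & (col[1:-1] >= col[2:]) & (col[1:-1] >= corr_threshold)
            )
            cand = np.nonzero(interior)[0] + 1
            if cand.size == 0:
                break
            i = int(cand[np.argmin(np.abs(dxs[cand] - prev_dx))])
            denom = col[i - 1] - 2.0 * col[i] + col[i + 1]
            delta = 0.5 * (col[i - 1] - col[i + 1]) / denom if denom != 0 else 0.0
            dx_peak = dxs[i] + delta * dx_step
            if abs(dx_peak) < abs(prev_dx) - 2.0 * dx_step:
                break  # ridge left the aperture and tracking snapped to an alias
            pts_dt.append(dts[j])
            pts_dx.append(dx_peak)
            pts_w.append(col[i])
            prev_dx = dx_peak
    if len(pts_dt) < min_points:
        raise RuntimeError(
            f"ridge absent: only {len(pts_dt)} usable ridge points above correlation {corr_threshold}"
        )
    dt_a = np.asarray(pts_dt)
    dx_a = np.asarray(pts_dx)
    w = np.asarray(pts_w)

    v = float(np.sum(w * dt_a * dx_a) / np.sum(w * dt_a**2))
    w_fit = w
    for _ in range(n_reweight):  # bisquare robust reweighting
        resid = dx_a - v * dt_a
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if scale <= 0:
            break
        u = resid / (4.685 * scale)
        w_rob = w * np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w_rob.sum() == 0:
            break
        v = float(np.sum(w_rob * dt_a * dx_a) / np.sum(w_rob * dt_a**2))
        w_fit = w_rob
    resid = dx_a - v * dt_a
    dof = max(len(dt_a) - 1, 1)
    sigma = float(np.sqrt(np.sum(w_fit * resid**2) / (dof * np.sum(w_fit * dt_a**2))))
    return v, sigma


def directional_filter(sig: CurvilinearSignal, direction: int) -> CurvilinearSignal:
    """Keep waves travelling in one direction by zeroing two Fourier quadrants.

    In the 2-D (space x time) Fourier plane a wave moving toward
    increasing ``x`` occupies the quadrants where the spatial and
    temporal frequencies have opposite signs.  The two quadrants of the
    rejected direction and the shared zero-frequency axes are zeroed and
    the field is transformed back (real part).  The two directional
    outputs therefore partition the input up to the axis bins.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    n_x, n_t = sig.phi.shape
    if n_x < 8 or n_t < 8:
        raise ValueError("directional filtering needs at least 8 positions and 8 time samples")
    F = np.fft.fft2(sig.phi)
    kx = np.fft.fftfreq(n_x)[:, None]
    ft = np.fft.fftfreq(n_t)[None, :]
    keep = np.sign(kx) * np.sign(ft) == -direction
    phi_f = np.fft.ifft2(F * keep).real
    return CurvilinearSignal(x=sig.x.copy(), t=sig.t.copy(), phi=phi_f)
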