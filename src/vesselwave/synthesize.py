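"""Seeded synthetic vessel movies and two-wall displacement traces.

The generator emulates the two kinds of recordings the analysis operates
on: optical power-Doppler movies of a retinal vessel (a bright curved
vessel on a noisy background whose intensity fluctuations carry the
waves) and per-wall displacement traces of a carotid artery imaged along
the ultrasound beam.  Waves are synthesized exactly in the frequency
domain as sums of travelling cosines — a cardiac-like source (fundamental
near 1.5 Hz plus harmonics) propagated along the vessel with either a
constant velocity (non-dispersive, symmetric-mode-like) or a dispersive
``v(f)`` law (flexural-mode-like).  All randomness (harmonic phases,
additive Gaussian measurement noise) is drawn from one seeded generator,
so a scenario is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import interpolate, spatial

from .theory import TubeGeometry, v_fpw_lowfreq

__all__ = [
    "SourceSpectrum",
    "ModeSpec",
    "AcquisitionSpec",
    "VesselMovie",
    "WallDisplacements",
    "make_source",
    "propagate",
    "render_movie",
    "render_walls",
    "arc_centerline",
    "retinal_scenario",
    "carotid_scenario",
    "RETINAL_GEOMETRY",
]

#: Tube geometry used for the retinal-scale dispersive synthesis law.
RETINAL_GEOMETRY = TubeGeometry(d=100e-6, h=15e-6, c_L=1500.0, c_T=0.35)


@dataclass(frozen=True)
class SourceSpectrum:
    """Cardiac-like source: harmonics ``k*f0`` with per-harmonic amplitude/phase.

    ``harmonic_amplitudes[k-1]`` is the relative amplitude of harmonic
    ``k`` (frequency ``k * fundamental_hz``); ``phases`` are the matching
    phase offsets in radians (zero if omitted).
    """

    fundamental_hz: float
    harmonic_amplitudes: tuple[float, ...]
    phases: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.fundamental_hz <= 0.0:
            raise ValueError("fundamental frequency must be positive")
        amps = tuple(float(a) for a in self.harmonic_amplitudes)
        if len(amps) == 0 or not any(a != 0.0 for a in amps):
            raise ValueError("at least one harmonic amplitude must be nonzero")
        object.__setattr__(self, "harmonic_amplitudes", amps)
        if self.phases is None:
            object.__setattr__(self, "phases", (0.0,) * len(amps))
        else:
            ph = tuple(float(p) for p in self.phases)
            if len(ph) != len(amps):
                raise ValueError("phases must match harmonic_amplitudes in length")
            object.__setattr__(self, "phases", ph)

    @property
    def frequencies(self) -> np.ndarray:
        """Harmonic frequencies ``k * f0`` in Hz, ``k = 1..K``."""
        return self.fundamental_hz * np.arange(1, len(self.harmonic_amplitudes) + 1)


@dataclass(frozen=True)
class ModeSpec:
    """One guided-wave mode to synthesize.

    ``velocity`` is either a constant phase velocity in m/s or a callable
    ``v(f)`` evaluated on the synthesis harmonics (dispersive law);
    ``direction`` is the propagation sign along the abscissa.
    """

    kind: str
    velocity: float | Callable[[np.ndarray], np.ndarray]
    amplitude: float = 1.0
    direction: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("symmetric", "antisymmetric"):
            raise ValueError("mode kind must be 'symmetric' or 'antisymmetric'")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def velocity_at(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if callable(self.velocity):
            v = np.asarray(self.velocity(f), dtype=float)
        else:
            v = np.full(f.shape, float(self.velocity))
        if np.any(~np.isfinite(v)) or np.any(v <= 0.0):
            raise ValueError(f"mode velocity law must be positive and finite on the synthesis band, got {v}")
        return v


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition parameters: frame rate, duration, sampling geometry, noise, seed."""

    frame_rate: float
    duration: float
    pixel_pitch: float | None = None
    field_of_view: float | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0.0:
            raise ValueError("frame_rate must be positive")
        if self.duration * self.frame_rate < 16:
            raise ValueError("record must contain at least 16 frames")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.frame_rate


@dataclass
class VesselMovie:
    """Image stack (time x rows x cols) with frame rate and pixel pitch metadata."""

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a 3-D stack with at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames must be finite")

    @property
    def mean_image(self) -> np.ndarray:
        return self.frames.mean(axis=0, dtype=np.float64)


@dataclass
class WallDisplacements:
    """Displacement matrices (position x time, metres) of the two opposite walls."""

    x: np.ndarray
    t: np.ndarray
    u_top: np.ndarray
    u_bottom: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.u_top = np.asarray(self.u_top, dtype=float)
        self.u_bottom = np.asarray(self.u_bottom, dtype=float)
        if self.u_top.shape != self.u_bottom.shape:
            raise ValueError("u_top and u_bottom must have the same shape")
        if self.u_top.shape != (self.x.size, self.t.size):
            raise ValueError("displacement matrices must be (n_positions, n_times)")
        for g, name in ((self.x, "x"), (self.t, "t")):
            if g.size > 1 and not np.allclose(np.diff(g), g[1] - g[0], rtol=1e-6, atol=0.0):
                raise ValueError(f"{name} grid must be uniformly sampled")


def make_source(spec: SourceSpectrum, acquisition: AcquisitionSpec) -> np.ndarray:
    """Source displacement time series ``s(t) = sum_k a_k cos(2 pi k f0 t + phi_k)``.

    Deterministic given the spectrum; rejects harmonics at or above the
    Nyquist frequency of the acquisition.
    """
    freqs = spec.frequencies
    nyquist = acquisition.frame_rate / 2.0
    if np.any(freqs >= nyquist):
        bad = freqs[freqs >= nyquist]
        raise ValueError(
            f"harmonics {bad} Hz are at or above the Nyquist frequency {nyquist} Hz; "
            "lower the harmonic count or raise the frame rate"
        )
    t = acquisition.times
    amps = np.asarray(spec.harmonic_amplitudes)
    phases = np.asarray(spec.phases)
    return (amps[:, None] * np.cos(2.0 * math.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)


def propagate(source: SourceSpectrum, mode: ModeSpec, x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Displacement field ``u(x, t)`` of one mode, synthesized harmonic by harmonic.

    Each harmonic ``f`` travels with wavenumber ``k(f) = 2 pi f / v(f)``
    in the mode's direction; a constant-velocity mode therefore yields a
    pure translation of the source waveform.  Returns a
    ``(len(x), len(t))`` matrix scaled by the mode amplitude.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    freqs = source.frequencies
    v = mode.velocity_at(freqs)
    k = 2.0 * math.pi * freqs / v
    amps = np.asarray(source.harmonic_amplitudes)
    phases = np.asarray(source.phases)
    u = np.zeros((x.size, t.size))
    for a, f, kk, ph in zip(amps, freqs, k, phases):
        if a == 0.0:
            continue
        u += a * np.cos(2.0 * math.pi * f * t[None, :] - mode.direction * kk * x[:, None] + ph)
    return mode.amplitude * u


def arc_centerline(n_pixels: int, margin_frac: float = 0.14, bulge_frac: float = 0.10, n_points: int | None = None) -> np.ndarray:
    """Gently curved default centerline: a circular-arc-like path across the frame.

    Returns ``(M, 2)`` float pixel coordinates (row, col) running
    diagonally with a transverse bulge of ``bulge_frac`` of the frame,
    inset by ``margin_frac`` from every border.
    """
    if n_points is None:
        n_points = 4 * n_pixels
    s = np.linspace(0.0, 1.0, n_points)
    lo, hi = margin_frac * n_pixels, (1.0 - margin_frac) * n_pixels
    rows = lo + (hi - lo) * s
    cols = lo + (hi - lo) * s + bulge_frac * n_pixels * np.sin(math.pi * s)
    return np.column_stack([rows, cols])


def _centerline_geometry(centerline: np.ndarray, pixel_pitch: float) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(centerline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("centerline must be an (M, 2) array of pixel coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) * pixel_pitch
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def render_movie(
    centerline: np.ndarray,
    fields: Sequence[tuple[np.ndarray, np.ndarray]],
    acquisition: AcquisitionSpec,
    *,
    vessel_sigma: float,
    baseline_amplitude: float = 1.0,
    background: float = 0.1,
) -> VesselMovie:
    """Paint a Gaussian-profile bright vessel and superpose travelling wave fields.

    ``fields`` is a list of ``(x_grid, u)`` pairs: curvilinear abscissa in
    metres and a ``(len(x_grid), n_frames)`` displacement/intensity
    matrix (e.g. from :func:`propagate`).  Pixel intensity is
    ``background + A * g(dist) * (1 + sum_j u_j(s_pixel, t) / A)`` with
    ``g`` a Gaussian transverse profile of scale ``vessel_sigma``
    (metres): the fluctuations ride multiplicatively on the vessel
    brightness profile, so they vanish off-vessel.  Seeded Gaussian noise
    of scale ``acquisition.noise_sigma`` is added to every pixel and the
    result is clipped at zero (intensities are nonnegative).
    """
    if vessel_sigma <= 0.0:
        raise ValueError("vessel width must be positive")
    if acquisition.pixel_pitch is None or acquisition.field_of_view is None:
        raise ValueError("acquisition must define pixel_pitch and field_of_view for movie rendering")
    pitch = acquisition.pixel_pitch
    n = int(round(acquisition.field_of_view / pitch))
    pts, s = _centerline_geometry(centerline, pitch)
    if pts.min() < 0 or pts.max() > n - 1:
        raise ValueError("centerline leaves the image frame")

    tree = spatial.cKDTree(pts)
    rr, cc = np.mgrid[0:n, 0:n]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist_px, idx = tree.query(pix, k=1)
    dist = dist_px.reshape(n, n) * pitch
    s_pix = s[idx].reshape(n, n)

    g = np.exp(-0.5 * (dist / vessel_sigma) ** 2)
    baseline = background + baseline_amplitude * g
    band = g > 1e-3
    s_band = s_pix[band]
    g_band = g[band]

    n_frames = acquisition.n_samples
    u_band = np.zeros((s_band.size, n_frames))
    for x_grid, u in fields:
        x_grid = np.asarray(x_grid, dtype=float)
        u = np.asarray(u, dtype=float)
        if u.shape != (x_grid.size, n_frames):
            raise ValueError("each field must be a (len(x_grid), n_frames) matrix")
        interp = interpolate.interp1d(x_grid, u, axis=0, bounds_error=False, fill_value=(u[0], u[-1]))
        u_band += interp(s_band)

    rng = np.random.default_rng(acquisition.seed)
    frames = np.empty((n_frames, n, n), dtype=np.float32)
    for j in range(n_frames):
        frame = baseline.copy()
        frame[band] += g_band * u_band[:, j]
        if acquisition.noise_sigma > 0.0:
            frame += rng.normal(0.0, acquisition.noise_sigma, size=frame.shape)
        np.maximum(frame, 0.0, out=frame)
        frames[j] = frame.astype(np.float32)
    return VesselMovie(frames=frames, frame_rate=acquisition.frame_rate, pixel_pitch=pitch)


def render_walls(
    sym_field: tuple[np.ndarray, np.ndarray],
    antisym_field: tuple[np.ndarray, np.ndarray],
    acquisition: AcquisitionSpec,
    *,
    misalignment: float = 1.0,
) -> WallDisplacements:
    """Two-wall displacements from per-mode fields, axial-beam convention.

    Radial expansion (symmetric mode ``u_s``) moves the two walls in
    opposite directions along the beam; flexion (antisymmetric ``u_a``)
    moves them together: ``u_top = u_a + u_s``, ``u_bottom = u_a - u_s``.
    ``misalignment`` scales the apparent antisymmetric amplitude (an
    imaging plane not aligned with the flexion plane sees a reduced
    projection; wavelengths are unaffected).  Independent seeded Gaussian
    noise of scale ``acquisition.noise_sigma`` (metres) is added per wall.
    """
    (x_s, u_s), (x_a, u_a) = sym_field, antisym_field
    x_s = np.asarray(x_s, dtype=float)
    x_a = np.asarray(x_a, dtype=float)
    u_s = np.asarray(u_s, dtype=float)
    u_a = np.asarray(u_a, dtype=float)
    if u_s.shape != u_a.shape or not np.array_equal(x_s, x_a):
        raise ValueError("symmetric and antisymmetric fields must share the same (x, t) grid")
    rng = np.random.default_rng(acquisition.seed)
    u_a_eff = misalignment * u_a
    noise_top = rng.normal(0.0, acquisition.noise_sigma, size=u_s.shape) if acquisition.noise_sigma else 0.0
    noise_bot = rng.normal(0.0, acquisition.noise_sigma, size=u_s.shape) if acquisition.noise_sigma else 0.0
    return WallDisplacements(
        x=x_s,
        t=acquisition.times,
        u_top=u_a_eff + u_s + noise_top,
        u_bottom=u_a_eff - u_s + noise_bot,
    )


# ---------------------------------------------------------------------------
# Default scenarios
# ---------------------------------------------------------------------------


def retinal_scenario(
    seed: int = 0,
    *,
    n_pixels: int = 512,
    duration: float = 8.0,
    snr: float = 10.0,
    n_harmonics: int = 5,
    dispersive: bool = True,
    constant_velocity: float = 0.025,
    geometry: TubeGeometry = RETINAL_GEOMETRY,
) -> tuple[VesselMovie, dict]:
    """Default retinal-scale scenario: 38 Hz, 5.3 mm field of view.

    A curved bright vessel carries an antisymmetric wave whose dispersion
    follows the low-frequency flexural law ``v(f) = sqrt(pi f d c_T /
    sqrt(3))`` (or a constant velocity when ``dispersive=False``), driven
    by a 1.5 Hz cardiac source with ``n_harmonics`` harmonics of
    decaying amplitude and seeded random phases.  The default duration
    puts an integer number of cycles of every harmonic in the record, so
    spectral peaks are bin-aligned.  ``snr`` is the ratio of the
    root-mean-square wave fluctuation at the vessel centre to the
    additive noise scale.

    Returns the movie and a ground-truth dictionary (source, mode,
    centerline, per-harmonic phase velocities).
    """
    frame_rate = 38.0
    fov = 5.3e-3
    pitch = fov / n_pixels
    rng = np.random.default_rng(seed)
    amps = tuple(0.3 + 0.7 * 0.72 ** np.arange(n_harmonics))
    phases = tuple(rng.uniform(0.0, 2.0 * math.pi, n_harmonics))
    source = SourceSpectrum(fundamental_hz=1.5, harmonic_amplitudes=amps, phases=phases)
    amplitude = 0.2
    if dispersive:
        law = lambda f: v_fpw_lowfreq(f, geometry)  # noqa: E731
    else:
        law = float(constant_velocity)
    mode = ModeSpec(kind="antisymmetric", velocity=law, amplitude=amplitude, direction=1)
    rms = amplitude * math.sqrt(0.5 * float(np.sum(np.square(amps))))
    acq = AcquisitionSpec(
        frame_rate=frame_rate,
        duration=duration,
        pixel_pitch=pitch,
        field_of_view=fov,
        noise_sigma=rms / snr if snr > 0 else 0.0,
        seed=seed,
    )
    centerline = arc_centerline(n_pixels)
    _, s = _centerline_geometry(centerline, pitch)
    x_grid = np.linspace(0.0, s[-1], 512)
    u = propagate(source, mode, x_grid, acq.times)
    movie = render_movie(centerline, [(x_grid, u)], acq, vessel_sigma=geometry.d / 2.0)
    truth = {
        "source": source,
        "mode": mode,
        "acquisition": acq,
        "geometry": geometry,
        "centerline": centerline,
        "arc_length": float(s[-1]),
        "harmonic_frequencies": source.frequencies,
        "phase_velocities": mode.velocity_at(source.frequencies),
    }
    return movie, truth


def carotid_scenario(
    seed: int = 0,
    *,
    n_positions: int = 64,
    duration: float = 2.0,
    v_symmetric: float = 3.4,
    v_antisymmetric: float = 0.5,
    amp_symmetric: float = 150e-6,
    amp_antisymmetric: float = 100e-6,
    noise_sigma: float = 5e-6,
) -> tuple[WallDisplacements, dict]:
    """Default carotid-scale scenario: 500 Hz frame rate, 4 cm aperture.

    Both guided modes propagate simultaneously: a fast non-dispersive
    symmetric pulse wave and a slower antisymmetric one, each driven by a
    1.5 Hz cardiac source whose harmonic amplitudes peak near 7.5 Hz (the
    band where carotid wave spectra concentrate).  Displacement
    amplitudes are of order 100 um, noise of order the micrometre
    precision of ultrasonic phase tracking.
    """
    frame_rate = 500.0
    aperture = 0.04
    x = np.linspace(0.0, aperture, n_positions)
    rng = np.random.default_rng(seed)
    k = np.arange(1, 10)
    amps = tuple(np.exp(-0.5 * ((k - 5) / 2.0) ** 2))
    src_sym = SourceSpectrum(1.5, amps, tuple(rng.uniform(0, 2 * math.pi, k.size)))
    src_anti = SourceSpectrum(1.5, amps, tuple(rng.uniform(0, 2 * math.pi, k.size)))
    mode_sym = ModeSpec("symmetric", v_symmetric, amplitude=amp_symmetric)
    mode_anti = ModeSpec("antisymmetric", v_antisymmetric, amplitude=amp_antisymmetric)
    acq = AcquisitionSpec(
        frame_rate=frame_rate,
        duration=duration,
        field_of_view=aperture,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    u_s = propagate(src_sym, mode_sym, x, acq.times)
    u_a = propagate(src_anti, mode_anti, x, acq.times)
    walls = render_walls((x, u_s), (x, u_a), acq)
    truth = {
        "sources": {"symmetric": src_sym, "antisymmetric": src_anti},
        "modes": {"symmetric": mode_sym, "antisymmetric": mode_anti},
        "acquisition": acq,
        "x": x,
        "u_symmetric": u_s,
        "u_antisymmetric": u_a,
        "velocities": {"symmetric": v_symmetric, "antisymmetric": v_antisymmetric},
    }
    return walls, truth
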