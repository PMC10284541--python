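"""Guided-wave dispersion theory for a traction-free elastic tube.

A blood vessel is modelled as a hollow circular cylinder of an isotropic,
nearly incompressible elastic solid (bulk compression speed ``c_L`` around
1500 m/s, bulk shear speed ``c_T`` well below 1 m/s for retinal-artery
walls).  Two guided modes matter for pulse-wave elastography:

* ``L(0,1)`` — the longitudinal, axisymmetric mode: a travelling diameter
  expansion.  At low frequency its phase velocity tends to the bar-wave
  limit ``sqrt(3) * c_T`` (incompressible limit of ``sqrt(E/rho)``).
* ``F(1,1)`` — the flexural, antisymmetric mode: whole-tube flexion with
  no cross-sectional change.  It is strongly dispersive, with a
  square-root dependence on frequency at low frequency.

Phase velocities are obtained by locating, at each frequency, the zero of
the characteristic determinant of the traction-free boundary-value
problem (Gazis' frequency equation), polished with Mueller's method.  The
classical Moens-Korteweg relation for the fluid-loaded symmetric pulse
wave and the shear-modulus identity ``mu = rho * c_T**2`` are provided as
companions.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "TubeGeometry",
    "ModeID",
    "TheoryCurve",
    "MullerResult",
    "characteristic_det",
    "muller_root",
    "dispersion_numeric",
    "v_fpw_lowfreq",
    "v_lpw_lowfreq",
    "v_fpw_beam",
    "moens_korteweg",
    "invert_moens_korteweg",
    "shear_modulus",
]


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry and bulk material parameters of the vessel wall.

    Parameters
    ----------
    d : float
        Outer diameter in metres.
    h : float
        Wall thickness in metres, ``0 < h < d/2``.
    rho : float
        Wall density in kg/m^3.
    c_L : float
        Bulk compression wave velocity in m/s.
    c_T : float
        Bulk shear wave velocity in m/s, ``0 < c_T < c_L``.
    """

    d: float
    h: float
    c_L: float
    c_T: float
    rho: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.h < self.d / 2.0):
            raise ValueError(f"wall thickness must satisfy 0 < h < d/2, got h={self.h}, d={self.d}")
        if not (0.0 < self.c_T < self.c_L):
            raise ValueError(f"wave speeds must satisfy 0 < c_T < c_L, got c_T={self.c_T}, c_L={self.c_L}")
        if self.rho <= 0.0:
            raise ValueError("density must be positive")

    @property
    def outer_radius(self) -> float:
        return self.d / 2.0

    @property
    def inner_radius(self) -> float:
        return self.d / 2.0 - self.h

    @property
    def mu(self) -> float:
        """Shear modulus, ``rho * c_T**2`` (Pa)."""
        return self.rho * self.c_T**2


@dataclass(frozen=True)
class ModeID:
    """Identifier of a guided tube mode: family 'L' (n=0) or 'F' (n=1), first branch."""

    family: str
    n: int
    m: int = 1

    def __post_init__(self) -> None:
        if (self.family, self.n, self.m) not in {("L", 0, 1), ("F", 1, 1)}:
            raise ValueError(f"only modes L(0,1) and F(1,1) are supported, got {self.family}({self.n},{self.m})")

    @classmethod
    def L01(cls) -> "ModeID":
        return cls("L", 0, 1)

    @classmethod
    def F11(cls) -> "ModeID":
        return cls("F", 1, 1)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.family}({self.n},{self.m})"


@dataclass
class TheoryCurve:
    """Numerically computed phase-velocity dispersion curve."""

    mode: ModeID
    f: np.ndarray
    v_phase: np.ndarray
    converged: np.ndarray
    residual: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f_hz": self.f,
                "v_m_per_s": self.v_phase,
                "converged": self.converged,
                "residual": self.residual,
            }
        )


# ---------------------------------------------------------------------------
# Characteristic determinant
# ---------------------------------------------------------------------------


def _radial_basis(p2: float, order: int, r: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Two independent solutions ``(Z, dZ/dr)`` of the radial Bessel equation.

    The equation is ``Z'' + Z'/r + (p2 - order^2/r^2) Z = 0`` with a real
    squared radial wavenumber ``p2`` of either sign: ordinary Bessel
    functions J/Y for ``p2 > 0``, modified Bessel functions I/K for
    ``p2 < 0`` (evanescent radial behaviour, the usual case when the phase
    velocity is far below the bulk speeds).
    """
    if p2 == 0.0:  # degenerate crossover; nudge off the measure-zero point
        p2 = 1e-30
    q = math.sqrt(abs(p2))
    x = q * r
    if p2 > 0.0:
        za = (special.jv(order, x), q * special.jvp(order, x))
        zb = (special.yv(order, x), q * special.yvp(order, x))
    else:
        za = (special.iv(order, x), q * special.ivp(order, x))
        zb = (special.kv(order, x), q * special.kvp(order, x))
    if not all(map(math.isfinite, (*za, *zb))):
        raise FloatingPointError(
            f"non-finite Bessel evaluation (order={order}, argument={x:.3g}); "
            "the requested frequency/velocity is outside the numerically safe range"
        )
    return za, zb


def _stress_rows(n: int, xi: float, a2: float, b2: float, r: float, basis_complex: bool = False):
    """Boundary stress rows (sigma_rr, sigma_rtheta, sigma_rz) at radius r.

    Returns a 3 x 6 block; columns are the two radial solutions of each of
    the three displacement potentials (compressional F, shear G1 of order
    n+1, shear G3 of order n).  Entries are per unit shear modulus; the
    common angular/axial harmonic factor is stripped.
    """
    if basis_complex:
        alpha = cmath.sqrt(complex(a2))
        beta = cmath.sqrt(complex(b2))
        Fb = [
            (special.jv(n, alpha * r), alpha * special.jvp(n, alpha * r)),
            (special.yv(n, alpha * r), alpha * special.yvp(n, alpha * r)),
        ]
        G1b = [
            (special.jv(n + 1, beta * r), beta * special.jvp(n + 1, beta * r)),
            (special.yv(n + 1, beta * r), beta * special.yvp(n + 1, beta * r)),
        ]
        G3b = [
            (special.jv(n, beta * r), beta * special.jvp(n, beta * r)),
            (special.yv(n, beta * r), beta * special.yvp(n, beta * r)),
        ]
        dtype = complex
    else:
        Fb = list(_radial_basis(a2, n, r))
        G1b = list(_radial_basis(b2, n + 1, r))
        G3b = list(_radial_basis(b2, n, r))
        dtype = float

    rows = np.zeros((3, 6), dtype=dtype)
    for j, (Z, dZ) in enumerate(Fb):
        rows[0, j] = (xi**2 - b2 + 2.0 * n**2 / r**2) * Z - (2.0 / r) * dZ
        rows[1, j] = (2.0 * n / r**2) * Z - (2.0 * n / r) * dZ
        rows[2, j] = -2.0 * xi * dZ
    for j, (Z, dZ) in enumerate(G1b):
        rows[0, 2 + j] = 2.0 * xi * dZ
        rows[1, 2 + j] = -(xi * (n + 1) / r) * Z + xi * dZ
        rows[2, 2 + j] = (b2 - xi**2 - n * (n + 1) / r**2) * Z - (n / r) * dZ
    for j, (Z, dZ) in enumerate(G3b):
        rows[0, 4 + j] = -(2.0 * n / r**2) * Z + (2.0 * n / r) * dZ
        rows[1, 4 + j] = (b2 - 2.0 * n**2 / r**2) * Z + (2.0 / r) * dZ
        rows[2, 4 + j] = -(n * xi / r) * Z
    return rows


def _boundary_matrix(mode: ModeID, f: float, v_trial: float, geom: TubeGeometry, basis_complex: bool = False):
    omega = 2.0 * math.pi * f
    xi = omega / v_trial
    a2 = (omega / geom.c_L) ** 2 - xi**2
    b2 = (omega / geom.c_T) ** 2 - xi**2
    n = mode.n
    blocks = [_stress_rows(n, xi, a2, b2, r, basis_complex) for r in (geom.inner_radius, geom.outer_radius)]
    mat = np.vstack(blocks)
    if n == 0:
        # sigma_rtheta vanishes identically and the order-n shear potential
        # decouples: keep the longitudinal 4x4 block.
        mat = mat[np.ix_([0, 2, 3, 5], [0, 1, 2, 3])]
    return mat


def characteristic_det(mode: ModeID, f: float, v_trial: float, geom: TubeGeometry, *, basis_complex: bool = False) -> float:
    """Normalized characteristic determinant of the traction-free tube.

    Assembles the boundary-condition matrix (zero radial, shear and axial
    traction on the inner and outer walls) for a trial phase velocity
    ``v_trial`` at frequency ``f`` and returns its determinant after
    scaling every column to unit maximum magnitude.  The scaling keeps the
    value in floating range without moving the roots; sign changes in
    ``v_trial`` bracket dispersion roots.

    With ``basis_complex=True`` the matrix is assembled from ordinary
    Bessel functions of complex argument instead of the sign-aware
    real J/Y-vs-I/K basis; the roots coincide, which is used as an
    independent consistency check.
    """
    if f <= 0.0:
        raise ValueError("frequency must be positive")
    if v_trial <= 0.0:
        raise ValueError("trial phase velocity must be positive")
    mat = _boundary_matrix(mode, f, v_trial, geom, basis_complex)
    scale = np.abs(mat).max(axis=0)
    scale[scale == 0.0] = 1.0
    det = np.linalg.det(mat / scale)
    return det if basis_complex else float(det)


# ---------------------------------------------------------------------------
# Mueller's method
# ---------------------------------------------------------------------------


class MullerResult(NamedTuple):
    root: float
    iterations: int
    fun: float


def muller_root(
    fn: Callable[[float], float],
    x0: float,
    x1: float,
    x2: float,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> MullerResult:
    """Find a root of ``fn`` by Mueller's three-point quadratic iteration.

    The parabola through the three most recent iterates is solved for its
    zero nearest the newest point; a degenerate (collinear) parabola falls
    back to a secant step.  Iteration stops when ``|fn|`` falls below
    ``tol`` times the scale of the starting function values (the
    characteristic determinant can be uniformly tiny, so an absolute
    criterion would be meaningless) or the step is below ``tol * |x|``.
    """
    xs = [float(x0), float(x1), float(x2)]
    if len(set(xs)) != 3:
        raise ValueError("Mueller's method needs three distinct starting points")
    fs = [fn(x) for x in xs]
    f_tol = tol * max(max(abs(f) for f in fs), 1e-300)
    real_mode = all(not isinstance(v, complex) or v.imag == 0.0 for v in (*xs, *fs))
    x_new = xs[2]
    for it in range(1, max_iter + 1):
        (xa, xb, xc), (fa, fb, fc) = xs, fs
        if abs(fc) < f_tol:
            return MullerResult(float(np.real(xc)), it - 1, float(abs(fc)))
        h1, h2 = xb - xa, xc - xb
        d1 = (fb - fa) / h1
        d2 = (fc - fb) / h2
        a = (d2 - d1) / (h2 + h1)
        b = a * h2 + d2
        c = fc
        if a == 0.0 and b == 0.0:
            raise RuntimeError("Mueller iteration degenerate: flat function values")
        if a == 0.0:  # collinear points: secant step
            step = -c / b
        else:
            disc = cmath.sqrt(b * b - 4.0 * a * c)
            den = b + disc if abs(b + disc) >= abs(b - disc) else b - disc
            step = -2.0 * c / den
        x_new = xc + step
        if real_mode or abs(np.imag(x_new)) < 1e-10 * max(1.0, abs(x_new)):
            x_new = float(np.real(x_new))
        f_new = fn(x_new)
        xs = [xb, xc, x_new]
        fs = [fb, fc, f_new]
        if abs(f_new) < f_tol or abs(step) < tol * max(abs(x_new), 1e-300):
            return MullerResult(float(np.real(x_new)), it, float(abs(f_new)))
    raise RuntimeError(f"Mueller's method did not converge in {max_iter} iterations (last x={x_new})")


# ---------------------------------------------------------------------------
# Dispersion curve computation
# ---------------------------------------------------------------------------


def _regime_bounds(guess: float, geom: TubeGeometry) -> tuple[float, float]:
    """Velocity interval of the same Bessel regime as ``guess`` (no c_T crossing)."""
    eps = 1e-3
    if guess < geom.c_T:
        return 1e-12, geom.c_T * (1.0 - eps)
    return geom.c_T * (1.0 + eps), geom.c_L * (1.0 - eps)


def _bracket_root(
    detfn: Callable[[float], float],
    guess: float,
    geom: TubeGeometry,
    span: float,
    n_scan: int,
) -> tuple[float, float] | None:
    lo_lim, hi_lim = _regime_bounds(guess, geom)
    lo = max(guess / span, lo_lim)
    hi = min(guess * span, hi_lim)
    vs = np.geomspace(lo, hi, n_scan)
    ds = np.array([detfn(v) for v in vs])
    sign_change = np.nonzero(np.diff(np.sign(ds)) != 0)[0]
    if sign_change.size == 0:
        return None
    mids = 0.5 * (vs[sign_change] + vs[sign_change + 1])
    k = int(sign_change[np.argmin(np.abs(np.log(mids / guess)))])
    return float(vs[k]), float(vs[k + 1])


def dispersion_numeric(
    mode: ModeID,
    geom: TubeGeometry,
    f_grid: Sequence[float],
    *,
    tol: float = 1e-9,
    n_scan: int = 81,
) -> TheoryCurve:
    """Phase-velocity dispersion curve ``v(f)`` of one guided mode.

    At the lowest frequency the root search is seeded from the
    low-frequency closed-form asymptote of the mode; at every subsequent
    frequency the previous root serves as a continuation guess.  The root
    is bracketed by a sign-change scan of the characteristic determinant
    around the guess (within a factor 1.5, never crossing the bulk shear
    speed, where the radial basis switches branch) and polished with
    Mueller's method.  Points whose determinant cannot be driven below
    ``tol`` are flagged as non-converged.

    Raises
    ------
    RuntimeError
        If the branch is lost, i.e. no sign change exists within +-50%
        of the continuation guess.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.ndim != 1 or f_grid.size == 0:
        raise ValueError("f_grid must be a non-empty 1-D array")
    if np.any(f_grid <= 0.0) or np.any(np.diff(f_grid) <= 0.0):
        raise ValueError("f_grid must be strictly ascending and positive")

    v_out = np.full(f_grid.shape, np.nan)
    ok = np.zeros(f_grid.shape, dtype=bool)
    res = np.full(f_grid.shape, np.nan)

    guess = v_fpw_lowfreq(f_grid[0], geom) if mode.family == "F" else v_lpw_lowfreq(geom)
    prev_root: float | None = None
    for i, f in enumerate(f_grid):
        detfn = lambda v: characteristic_det(mode, f, v, geom)  # noqa: E731
        span = 1.5 if prev_root is not None else 2.5
        n_pts = n_scan if prev_root is not None else max(n_scan, 161)
        bracket = _bracket_root(detfn, guess, geom, span, n_pts)
        if bracket is None:
            if prev_root is None:
                raise RuntimeError(f"no dispersion root found near seed {guess:.4g} m/s at {f:.4g} Hz")
            raise RuntimeError(
                f"lost the {mode} branch at {f:.4g} Hz: no sign change within +-50% of {guess:.4g} m/s"
            )
        lo, hi = bracket
        f_scale = max(abs(detfn(lo)), abs(detfn(hi)), 1e-300)
        try:
            sol = muller_root(detfn, lo, 0.5 * (lo + hi), hi, tol=tol)
            root, fval = sol.root, sol.fun
        except RuntimeError:
            root = float(np.nan)
            fval = float(np.inf)
        rel_res = fval / f_scale
        if math.isfinite(root) and lo * 0.9 <= root <= hi * 1.1 and rel_res < 1e-3:
            v_out[i] = root
            ok[i] = True
            res[i] = rel_res
            prev_root = root
            guess = root
        else:  # keep continuation alive from the bracket midpoint
            v_out[i] = 0.5 * (lo + hi)
            ok[i] = False
            res[i] = rel_res
            guess = v_out[i]
    return TheoryCurve(mode=mode, f=f_grid, v_phase=v_out, converged=ok, residual=res)


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------


def v_fpw_lowfreq(f, geom: TubeGeometry):
    """Low-frequency flexural-wave phase velocity, ``sqrt(pi f d c_T / sqrt(3))``.

    Square-root dispersion in the frequency-diameter product; vanishes at
    zero frequency.
    """
    f = np.asarray(f, dtype=float)
    out = np.sqrt(math.pi * f * geom.d * geom.c_T / math.sqrt(3.0))
    return float(out) if out.ndim == 0 else out


def v_lpw_lowfreq(geom: TubeGeometry) -> float:
    """Low-frequency longitudinal (bar) wave velocity, ``sqrt(3) * c_T``.

    Incompressible limit of the bar velocity ``sqrt(E/rho)``; independent
    of the tube geometry.
    """
    return math.sqrt(3.0) * geom.c_T


def v_fpw_beam(f, geom: TubeGeometry):
    """Euler-Bernoulli flexural asymptote ``sqrt(omega) * (E I / rho A)**0.25``.

    Independent thick-ring beam-theory limit of the flexural branch, used
    to cross-check the numerical Gazis solution: ``I/A = (a^2+b^2)/4`` for
    an annulus with outer radius ``a`` and inner radius ``b``, and
    ``E/rho = c_T^2 (3 c_L^2 - 4 c_T^2) / (c_L^2 - c_T^2)``.
    """
    f = np.asarray(f, dtype=float)
    e_over_rho = geom.c_T**2 * (3.0 * geom.c_L**2 - 4.0 * geom.c_T**2) / (geom.c_L**2 - geom.c_T**2)
    gyr2 = (geom.outer_radius**2 + geom.inner_radius**2) / 4.0
    out = np.sqrt(2.0 * math.pi * f) * (e_over_rho * gyr2) ** 0.25
    return float(out) if out.ndim == 0 else out


def moens_korteweg(geom: TubeGeometry) -> float:
    """Moens-Korteweg pulse wave velocity ``c_T * sqrt(3 h / d)`` (m/s).

    Classical symmetric pulse-wave speed of a thin-walled, fluid-filled
    tube, expressed through the bulk shear speed of an incompressible wall
    (``E = 3 mu``).
    """
    return geom.c_T * math.sqrt(3.0 * geom.h / geom.d)


def invert_moens_korteweg(pwv: float, h: float, d: float) -> float:
    """Bulk shear wave velocity from a measured Moens-Korteweg PWV."""
    if pwv <= 0.0 or h <= 0.0 or d <= 0.0:
        raise ValueError("pwv, h and d must be positive")
    return pwv * math.sqrt(d / (3.0 * h))


def shear_modulus(rho: float, c_T: float) -> float:
    """Shear modulus ``mu = rho * c_T**2`` (Pa)."""
    if rho <= 0.0:
        raise ValueError("density must be positive")
    return rho * c_T**2
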