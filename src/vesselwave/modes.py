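"""Separation of symmetric and antisymmetric wall motion.

With both wall displacements measured along the imaging beam, radial
expansion (the symmetric, longitudinal pulse wave) moves the two walls in
opposite directions while flexion (the antisymmetric, flexural pulse
wave) moves them together.  Summing and differencing the walls therefore
selects one mode or the other — an exact linear map, no filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthesize import WallDisplacements

__all__ = ["ModeFields", "separate_modes", "classify_snapshot"]


@dataclass
class ModeFields:
    """Per-mode displacement fields on the same (x, t) grid as the source walls.

    The factor 1/2 in both combinations makes each field the per-mode
    displacement amplitude rather than a bare sum/difference; only the
    wavelength matters downstream, the scale is a normalization choice.
    """

    x: np.ndarray
    t: np.ndarray
    symmetric: np.ndarray
    antisymmetric: np.ndarray
    convention: str = "axial-beam"


def separate_modes(walls: WallDisplacements) -> ModeFields:
    """Split two-wall displacements into symmetric and antisymmetric fields.

    ``antisymmetric = (u_top + u_bottom) / 2`` (common motion, flexion),
    ``symmetric = (u_top - u_bottom) / 2`` (opposing motion, expansion).
    Exact inverse of the wall-rendering convention: composing the two is
    the identity at machine precision for noiseless data.
    """
    if walls.u_top.shape != walls.u_bottom.shape:
        raise ValueError("wall displacement matrices must have the same shape")
    return ModeFields(
        x=walls.x,
        t=walls.t,
        symmetric=0.5 * (walls.u_top - walls.u_bottom),
        antisymmetric=0.5 * (walls.u_top + walls.u_bottom),
    )


def classify_snapshot(walls: WallDisplacements, t: float, dominance_ratio: float = 2.0) -> str:
    """Label the wall-motion pattern at time ``t``.

    Compares the spatial L2 norms of the symmetric and antisymmetric
    fields in the frame nearest ``t``; one mode is dominant when its norm
    exceeds the other by ``dominance_ratio``.  Returns
    ``'symmetric-dominant'``, ``'antisymmetric-dominant'`` or ``'mixed'``.
    """
    t_arr = np.asarray(walls.t)
    if not (t_arr[0] <= t <= t_arr[-1]):
        raise ValueError(f"time {t} s outside the record [{t_arr[0]}, {t_arr[-1]}] s")
    j = int(np.argmin(np.abs(t_arr - t)))
    fields = separate_modes(walls)
    norm_s = float(np.linalg.norm(fields.symmetric[:, j]))
    norm_a = float(np.linalg.norm(fields.antisymmetric[:, j]))
    if norm_s > dominance_ratio * norm_a:
        return "symmetric-dominant"
    if norm_a > dominance_ratio * norm_s:
        return "antisymmetric-dominant"
    return "mixed"
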