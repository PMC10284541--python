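"""Vessel segmentation and reduction of a movie to curvilinear traces.

The analysis is one-dimensional along the vessel: the time-averaged
image is segmented with a gradient (Sobel) edge detector, an ordered
centerline with curvilinear abscissa is extracted as the midline between
the two edges, and the movie is reduced to one time trace per cross
section by averaging the intensity over a short segment perpendicular to
the local tangent.  Cross-section averaging also suppresses any
axisymmetric intensity contribution (equal-and-opposite across the two
halves of the profile), which is why the slow antisymmetric wave
dominates the resulting traces.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .synthesize import VesselMovie

__all__ = ["VesselSegmentation", "CurvilinearSignal", "segment_vessel", "sample_cross_sections"]


@dataclass
class VesselSegmentation:
    """Edge mask, ordered centerline and arc-length parametrization of one vessel."""

    edge_mask: np.ndarray
    centerline: np.ndarray  # (M, 2) float (row, col), ordered, uniform arc step
    abscissa: np.ndarray  # (M,) cumulative arc length, metres
    width: np.ndarray  # (M,) local lumen width estimate, metres
    pixel_pitch: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")


@dataclass
class CurvilinearSignal:
    """One time trace per curvilinear abscissa: matrix ``phi`` of shape (n_x, n_t)."""

    x: np.ndarray
    t: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (self.x.size, self.t.size):
            raise ValueError("phi must have shape (len(x), len(t))")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi must be finite")
        for g, name in ((self.x, "x"), (self.t, "t")):
            if g.size > 1:
                steps = np.diff(g)
                if not np.allclose(steps, steps[0], rtol=1e-6, atol=0.0):
                    raise ValueError(f"{name} grid must have a uniform step")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def _order_skeleton(skel: np.ndarray) -> np.ndarray:
    """Ordered (row, col) path through a skeleton: longest geodesic, 8-connected."""
    pixels = np.column_stack(np.nonzero(skel))
    if pixels.shape[0] < 2:
        raise ValueError("skeleton too short to order")
    index = {tuple(p): i for i, p in enumerate(pixels)}
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    adj: list[list[int]] = [[] for _ in pixels]
    for i, (r, c) in enumerate(pixels):
        for dr, dc in offsets:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)

    def bfs(start: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(len(pixels), -1)
        parent = np.full(len(pixels), -1)
        dist[start] = 0
        q = deque([start])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    parent[v] = u
                    q.append(v)
        return dist, parent

    d0, _ = bfs(0)
    a = int(np.argmax(d0))
    d1, parent = bfs(a)
    b = int(np.argmax(d1))
    path = [b]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return pixels[path[::-1]]


def _smooth_path(path: np.ndarray, window: int = 5) -> np.ndarray:
    if path.shape[0] < window:
        return path.astype(float)
    kernel = np.ones(window) / window
    out = np.empty_like(path, dtype=float)
    for k in range(2):
        padded = np.concatenate([np.full(window // 2, path[0, k]), path[:, k], np.full(window // 2, path[-1, k])])
        out[:, k] = np.convolve(padded, kernel, mode="valid")
    return out


def segment_vessel(
    mean_image: np.ndarray,
    pixel_pitch: float = 1.0,
    gradient_threshold: float | None = None,
    seed_point: tuple[int, int] | None = None,
    min_sections: int = 16,
) -> VesselSegmentation:
    """Segment the vessel on a time-averaged image and extract its centerline.

    A Sobel gradient magnitude is thresholded (Otsu's threshold when none
    is given) and the connected edge component containing — or nearest —
    ``seed_point`` (the largest component if absent) is taken as the
    vessel's edges.  The centerline is the midline between the paired
    opposing edges, obtained as the morphological skeleton of the filled
    edge contour, ordered end to end, smoothed with a 5-point moving
    average and resampled to a uniform arc step of one pixel pitch.  The
    local lumen width is estimated from the distance transform of the
    filled contour.

    Raises
    ------
    ValueError
        If no edge component is found, or the vessel is shorter than
        ``min_sections`` cross sections.
    """
    img = np.asarray(mean_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("mean_image must be 2-D")
    grad = filters.sobel(img)
    if gradient_threshold is None:
        if grad.max() <= 0:
            raise ValueError("no vessel found: image has no gradient structure")
        gradient_threshold = filters.threshold_otsu(grad)
    edges = grad > gradient_threshold
    if not edges.any():
        raise ValueError("no vessel found: no pixel exceeds the gradient threshold")

    labels = measure.label(edges, connectivity=2)
    if seed_point is not None:
        lab = labels[int(seed_point[0]), int(seed_point[1])]
        if lab == 0:  # nearest component to the seed
            pts = np.column_stack(np.nonzero(labels > 0))
            nearest = pts[np.argmin(((pts - np.asarray(seed_point)) ** 2).sum(axis=1))]
            lab = labels[nearest[0], nearest[1]]
    else:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        lab = int(np.argmax(counts))
    edge_mask = labels == lab

    filled = ndimage.binary_fill_holes(edge_mask)
    skel = morphology.skeletonize(filled)
    if skel.sum() < 2:
        raise ValueError("no vessel found: degenerate edge component")
    path = _smooth_path(_order_skeleton(skel))

    seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s_raw = np.concatenate([[0.0], np.cumsum(seg_len)])  # pixels
    n_out = int(np.floor(s_raw[-1])) + 1
    if n_out < min_sections:
        raise ValueError(f"vessel too short: {n_out} cross sections, need at least {min_sections}")
    s_uniform = np.arange(n_out, dtype=float)
    center = np.column_stack([np.interp(s_uniform, s_raw, path[:, k]) for k in range(2)])

    dist = ndimage.distance_transform_edt(filled)
    rows = np.clip(np.round(center[:, 0]).astype(int), 0, img.shape[0] - 1)
    cols = np.clip(np.round(center[:, 1]).astype(int), 0, img.shape[1] - 1)
    width = 2.0 * dist[rows, cols] * pixel_pitch

    return VesselSegmentation(
        edge_mask=edge_mask,
        centerline=center,
        abscissa=s_uniform * pixel_pitch,
        width=width,
        pixel_pitch=pixel_pitch,
    )


def sample_cross_sections(
    movie: VesselMovie,
    seg: VesselSegmentation,
    half_width: float | None = None,
    detrend: bool = False,
) -> CurvilinearSignal:
    """Average the movie over a perpendicular segment at each centerline point.

    At each abscissa the intensity is averaged, per frame, along the
    normal to the local tangent (centered differences on the smoothed
    centerline) over a segment of total length ``2 * half_width`` metres
    (default: half the median measured lumen width on each side;
    ``half_width=0`` samples the centerline pixel itself).  Optionally
    removes a per-trace linear drift, which carries no wave information.

    Raises
    ------
    ValueError
        If any cross-section sample would leave the image frame.
    """
    pitch = seg.pixel_pitch
    center = seg.centerline
    if half_width is None:
        half_width = float(np.median(seg.width)) / 2.0
    if half_width < 0:
        raise ValueError("half_width must be nonnegative")

    tangent = np.gradient(center, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])

    hw_px = half_width / pitch
    n_off = max(int(np.ceil(hw_px / 0.5)), 0)
    offsets = np.linspace(-hw_px, hw_px, 2 * n_off + 1) if n_off else np.array([0.0])

    # coords: (2, n_points, n_offsets)
    coords = center[:, :, None] + normal[:, :, None] * offsets[None, None, :]
    n_rows, n_cols = movie.frames.shape[1:]
    if (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() > n_rows - 1
        or coords[:, 1].max() > n_cols - 1
    ):
        raise ValueError("cross section leaves the image frame; shorten the vessel or reduce half_width")

    flat = coords.transpose(0, 2, 1).reshape(center.shape[0] * offsets.size, 2).T
    n_frames = movie.frames.shape[0]
    phi = np.empty((center.shape[0], n_frames))
    for j in range(n_frames):
        samples = ndimage.map_coordinates(movie.frames[j].astype(float), flat, order=1)
        phi[:, j] = samples.reshape(center.shape[0], offsets.size).mean(axis=1)

    t = np.arange(n_frames) / movie.frame_rate
    if detrend:
        from scipy.signal import detrend as _detrend

        phi = _detrend(phi, axis=1, type="linear")
    return CurvilinearSignal(x=seg.abscissa.copy(), t=t, phi=phi)
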