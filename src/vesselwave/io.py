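"""File interfaces: TIFF movies with JSON sidecars, CSV matrices, JSON reports.

All on-disk quantities are SI (metres, seconds, Hz); CSV files are
comma-separated with a header row, UTF-8, dot decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import CurvilinearSignal
from .synthesize import VesselMovie, WallDisplacements

__all__ = [
    "write_movie",
    "read_movie",
    "write_walls",
    "read_walls",
    "write_curvilinear",
    "read_curvilinear",
    "write_focal_spot",
    "write_tof_map",
    "write_report",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: VesselMovie, path: str | Path, seed: int | None = None, scenario: str | None = None) -> Path:
    """Write a movie as a multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.frames, dtype=np.float32))
    meta = {
        "frame_rate_hz": movie.frame_rate,
        "pixel_pitch_m": movie.pixel_pitch,
        "seed": seed,
        "scenario": scenario,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_movie(path: str | Path) -> VesselMovie:
    """Read a multi-page TIFF movie; frame rate and pixel pitch come from the sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} not found next to {path}")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    return VesselMovie(frames=frames, frame_rate=float(meta["frame_rate_hz"]), pixel_pitch=float(meta["pixel_pitch_m"]))


def _matrix_frame(x: np.ndarray, t: np.ndarray, u: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(u, index=pd.Index(x, name="x_m"), columns=[f"{tv:.9g}" for tv in t])


def _read_matrix(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, index_col=0)
    x = frame.index.to_numpy(dtype=float)
    t = np.asarray([float(c) for c in frame.columns])
    return x, t, frame.to_numpy(dtype=float)


def write_walls(walls: WallDisplacements, path_top: str | Path, path_bottom: str | Path) -> tuple[Path, Path]:
    """Write the two wall-displacement matrices: one CSV per wall.

    First column is the curvilinear position in metres, the header row
    holds the sample times in seconds, the body is the displacement in
    metres.
    """
    path_top, path_bottom = Path(path_top), Path(path_bottom)
    _matrix_frame(walls.x, walls.t, walls.u_top).to_csv(path_top)
    _matrix_frame(walls.x, walls.t, walls.u_bottom).to_csv(path_bottom)
    return path_top, path_bottom


def read_walls(path_top: str | Path, path_bottom: str | Path) -> WallDisplacements:
    x1, t1, u_top = _read_matrix(Path(path_top))
    x2, t2, u_bottom = _read_matrix(Path(path_bottom))
    if not (np.allclose(x1, x2) and np.allclose(t1, t2)):
        raise ValueError("wall CSV files have mismatched position/time grids")
    return WallDisplacements(x=x1, t=t1, u_top=u_top, u_bottom=u_bottom)


def write_curvilinear(sig: CurvilinearSignal, path: str | Path) -> Path:
    path = Path(path)
    _matrix_frame(sig.x, sig.t, sig.phi).to_csv(path)
    return path


def read_curvilinear(path: str | Path) -> CurvilinearSignal:
    x, t, phi = _read_matrix(Path(path))
    return CurvilinearSignal(x=x, t=t, phi=phi)


def write_focal_spot(spot, path: str | Path) -> Path:
    """Dump a focal spot as a two-column CSV (r_m, C)."""
    path = Path(path)
    pd.DataFrame({"r_m": spot.r, "C": spot.C}).to_csv(path, index=False)
    return path


def write_tof_map(tof_map, path: str | Path) -> Path:
    """Dump a time-of-flight correlation map (rows: dx in m; columns: dt in s)."""
    path = Path(path)
    pd.DataFrame(
        tof_map.value, index=pd.Index(tof_map.dx, name="dx_m"), columns=[f"{v:.9g}" for v in tof_map.dt]
    ).to_csv(path)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(report), indent=2))
    return path
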