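"""File readers and writers.

Surfaces travel as STL/PLY (via trimesh) or legacy ASCII VTK polydata;
tetrahedral velocity fields as legacy ASCII VTK unstructured grids;
centerlines as x,y,z CSV; planes, neck annotations and configuration as
JSON.  A wall-shear-stress time series is a directory bundle:

    bundle/
      mesh.stl            the shared wall surface
      times.csv           one time value per row + "period" header comment
      tau_0000.csv ...    per-step files, one "tx,ty,tz" row per vertex

Everything round-trips losslessly to ~1e-7 (text float precision).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import trimesh

from .types import (
    Centerline,
    Config,
    Plane,
    SurfaceMesh,
    ValidationError,
    VolumeField,
    WssSeries,
)

log = logging.getLogger("tandemflow")

_FMT = "%.9g"


# ---------------------------------------------------------------- surfaces
def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower().lstrip(".")
    return path.suffix.lower().lstrip(".")


def read_surface_mesh(path, fmt: str | None = None) -> SurfaceMesh:
    """Read a triangulated surface (stl, ply or legacy VTK polydata).

    Unreferenced vertices are dropped and duplicates (within 1e-9 of the
    bounding-box diagonal) merged before validation.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = _detect_format(path, fmt)
    if fmt in ("stl", "ply"):
        tm = trimesh.load_mesh(path, file_type=fmt, process=False)
        vertices, triangles = np.asarray(tm.vertices, float), np.asarray(tm.faces)
    elif fmt == "vtk":
        vertices, triangles = _read_vtk_polydata(path)
    else:
        raise IOError(f"unsupported surface format: {fmt}")
    vertices, triangles = _clean_vertices(vertices, triangles)
    return SurfaceMesh(vertices, triangles)


def write_surface_mesh(mesh: SurfaceMesh, path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt in ("stl", "ply"):
        mesh.as_trimesh().export(path, file_type=fmt)
    elif fmt == "vtk":
        _write_vtk_polydata(path, mesh.vertices, mesh.triangles)
    else:
        raise IOError(f"unsupported surface format: {fmt}")
    return path


def _clean_vertices(vertices: np.ndarray, triangles: np.ndarray):
    """Merge near-duplicate vertices and drop unreferenced ones."""
    if len(vertices) == 0 or len(triangles) == 0:
        raise ValidationError("mesh has zero triangles")
    bbox = vertices.max(axis=0) - vertices.min(axis=0)
    tol = 1e-9 * max(float(np.linalg.norm(bbox)), 1e-30)
    # quantise to a grid of spacing tol for merging
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    vertices = vertices[first]
    triangles = inverse[triangles]
    used = np.zeros(len(vertices), dtype=bool)
    used[triangles] = True
    remap = np.cumsum(used) - 1
    return vertices[used], remap[triangles]


def _read_vtk_polydata(path: Path):
    tokens = _vtk_tokens(path)
    pts, polys = None, None
    i = 0
    while i < len(tokens):
        t = tokens[i].upper()
        if t == "POINTS":
            n = int(tokens[i + 1])
            data = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float)
            pts = data.reshape(n, 3)
            i += 3 + 3 * n
        elif t == "POLYGONS":
            n = int(tokens[i + 1])
            size = int(tokens[i + 2])
            data = np.array(tokens[i + 3 : i + 3 + size], dtype=np.int64)
            polys, j = [], 0
            for _ in range(n):
                k = data[j]
                cell = data[j + 1 : j + 1 + k]
                for a in range(1, k - 1):  # fan-triangulate any polygon
                    polys.append((cell[0], cell[a], cell[a + 1]))
                j += 1 + k
            polys = np.array(polys, dtype=np.int64)
            i += 3 + size
        else:
            i += 1
    if pts is None or polys is None:
        raise IOError(f"{path}: not a VTK polydata file")
    return pts, polys


def _write_vtk_polydata(path: Path, vertices, triangles, point_data: dict | None = None):
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntandemflow surface\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(vertices)} double\n")
        np.savetxt(f, vertices, fmt=_FMT)
        f.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        cells = np.column_stack([np.full(len(triangles), 3), triangles])
        np.savetxt(f, cells, fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {len(vertices)}\n")
            for name, values in point_data.items():
                values = np.asarray(values)
                if values.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, values, fmt=_FMT)
                else:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, values, fmt=_FMT)


def _vtk_tokens(path: Path) -> list[str]:
    lines = path.read_text().splitlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise IOError(f"{path}: not a legacy VTK file")
    if lines[2].strip().upper() != "ASCII":
        raise IOError(f"{path}: only ASCII legacy VTK supported")
    out: list[str] = []
    for ln in lines[3:]:
        out.extend(ln.split())
    return out


def validate_mesh(mesh: SurfaceMesh) -> dict:
    """Structural report: boundary edges, non-manifold edges, orientation.

    A surface is watertight iff it has no boundary edges.  An edge shared
    by two faces with the same traversal direction marks inconsistent
    winding (a flipped triangle).
    """
    t = mesh.triangles
    directed = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(undirected, axis=0, return_inverse=True, return_counts=True)
    boundary = int((counts == 1).sum())
    nonmanifold = int((counts > 2).sum())
    # orientation: for an interior edge the two incident faces should traverse
    # it in opposite directions
    flipped = 0
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    starts = np.searchsorted(sorted_inv, np.arange(len(uniq)))
    for e in np.flatnonzero(counts == 2):
        i, j = order[starts[e]], order[starts[e] + 1]
        if np.array_equal(directed[i], directed[j]):
            flipped += 1
    return {
        "n_vertices": len(mesh.vertices),
        "n_triangles": len(t),
        "boundary_edges": boundary,
        "non_manifold_edges": nonmanifold,
        "inconsistent_edges": flipped,
        "min_triangle_area": float(mesh.triangle_areas().min()),
        "watertight": boundary == 0,
    }


# --------------------------------------------------------------- WSS series
def write_wss_series(series: WssSeries, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_surface_mesh(series.mesh, directory / "mesh.stl")
    with open(directory / "times.csv", "w") as f:
        f.write(f"# period {series.period!r}\n")
        np.savetxt(f, series.times, fmt="%.12g")
    for k in range(series.n_times):
        np.savetxt(directory / f"tau_{k:04d}.csv", series.tau[k], fmt=_FMT, delimiter=",")
    return directory


def read_wss_series(directory) -> WssSeries:
    directory = Path(directory)
    mesh = read_surface_mesh(directory / "mesh.stl")
    lines = (directory / "times.csv").read_text().splitlines()
    period = float(lines[0].split()[-1])
    times = np.array([float(x) for x in lines[1:] if x.strip()])
    paths = sorted(directory.glob("tau_*.csv"))
    if len(paths) != len(times):
        raise ValidationError(f"{directory}: {len(paths)} step files for {len(times)} times")
    if len(paths) < 2:
        raise ValidationError("WSS series needs at least 2 time steps")
    tau = np.stack([np.loadtxt(p, delimiter=",").reshape(-1, 3) for p in paths])
    if tau.shape[1] != len(mesh.vertices):
        raise ValidationError("per-step vertex count does not match the shared mesh")
    return WssSeries(mesh, times, tau, period=period)


# ------------------------------------------------------------ volume fields
def write_volume_field(field: VolumeField, path) -> Path:
    """Legacy ASCII VTK unstructured grid with a point VECTORS 'velocity'."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ntandemflow volume\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(field.points)} double\n")
        np.savetxt(f, field.points, fmt=_FMT)
        f.write(f"CELLS {len(field.tets)} {5 * len(field.tets)}\n")
        np.savetxt(f, np.column_stack([np.full(len(field.tets), 4), field.tets]), fmt="%d")
        f.write(f"CELL_TYPES {len(field.tets)}\n")
        np.savetxt(f, np.full(len(field.tets), 10), fmt="%d")  # VTK_TETRA
        f.write(f"POINT_DATA {len(field.points)}\nVECTORS velocity double\n")
        np.savetxt(f, field.velocity, fmt=_FMT)
    return path


def read_volume_field(path) -> VolumeField:
    path = Path(path)
    tokens = _vtk_tokens(path)
    pts = tets = vel = None
    i = 0
    while i < len(tokens):
        t = tokens[i].upper()
        if t == "POINTS":
            n = int(tokens[i + 1])
            pts = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
            i += 3 + 3 * n
        elif t == "CELLS":
            n, size = int(tokens[i + 1]), int(tokens[i + 2])
            data = np.array(tokens[i + 3 : i + 3 + size], dtype=np.int64).reshape(n, 5)
            if (data[:, 0] != 4).any():
                raise IOError(f"{path}: non-tetrahedral cells present")
            tets = data[:, 1:]
            i += 3 + size
        elif t == "VECTORS":
            n = len(pts) if pts is not None else 0
            vel = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
            i += 3 + 3 * n
        else:
            i += 1
    if pts is None or tets is None or vel is None:
        raise IOError(f"{path}: missing POINTS/CELLS/VECTORS data")
    return VolumeField(pts, tets, vel)


# ------------------------------------------------------- centerlines, JSON
def read_centerline(path) -> Centerline:
    """CSV with one x,y,z row per centerline point, ordered."""
    pts = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
    return Centerline(pts[:, :3])


def write_centerline(cl: Centerline, path) -> Path:
    path = Path(path)
    np.savetxt(path, cl.points, fmt=_FMT, delimiter=",", header="x,y,z")
    return path


def write_json(obj: dict, path) -> Path:
    """Deterministic JSON: sorted keys, fixed float precision."""
    path = Path(path)
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _round_floats(obj, ndigits: int = 9):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def plane_to_dict(plane: Plane) -> dict:
    return {"origin": plane.origin.tolist(), "normal": plane.normal.tolist()}


def plane_from_dict(d: dict) -> Plane:
    return Plane(np.asarray(d["origin"]), np.asarray(d["normal"]))


def write_config(config: Config, path) -> Path:
    return write_json(config.to_dict(), path)


def read_config(path) -> Config:
    return Config.from_dict(read_json(path))


def setup_logging(path=None, level=logging.INFO) -> logging.Logger:
    """JSON-lines structured log (one {"level","msg"} object per line)."""

    class _JsonLines(logging.Formatter):
        def format(self, record):
            return json.dumps({"level": record.levelname, "msg": record.getMessage()})

    log.setLevel(level)
    handler = logging.FileHandler(path) if path else logging.StreamHandler()
    handler.setFormatter(_JsonLines())
    log.handlers = [handler]
    return log
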