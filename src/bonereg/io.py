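"""Readers and writers for the formats the toolkit touches.

Meshes go through :mod:`trimesh` (binary PLY is the canonical lossless
interchange; STL/OBJ are supported for interoperability despite ASCII
precision loss).  Point sets are CSV with a ``label,x,y,z`` header (mm) or
an equivalent JSON document.  Rigid transforms are JSON with the 9
row-major rotation entries, the translation and the scale.  Binary masks
are NIfTI-1 with an affine built from the grid's origin/spacing under the
voxel-CENTER origin convention, so mask export and Dice voxelization can
never drift by half a voxel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GeometryError, ImageGrid, Point3Set, RigidTransform, TriangleMesh
from .contours import BSplineContour, ContourStack

__all__ = [
    "read_mesh", "write_mesh",
    "read_points", "write_points",
    "read_transform", "write_transform",
    "read_contour_stack", "write_contour_stack",
    "read_mask", "write_mask",
    "write_provenance",
]

_MESH_FORMATS = {".ply": "ply", ".stl": "stl", ".obj": "obj"}


class FormatError(ValueError):
    """Unreadable or inconsistent file content."""


def _mesh_format(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if f".{fmt}" not in _MESH_FORMATS:
        raise FormatError(f"unsupported mesh format '{fmt}' (use ply/stl/obj)")
    return fmt


def read_mesh(path, fmt: str | None = None, frame_id: str = "world") -> TriangleMesh:
    """Load a triangulated surface; coordinates are assumed to be in mm."""
    import trimesh

    path = Path(path)
    fmt = _mesh_format(path, fmt)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:
        raise FormatError(f"failed to parse {fmt.upper()} mesh {path}: {exc}") from exc
    if tm.is_empty or len(tm.faces) == 0:
        raise FormatError(f"{fmt.upper()} file {path} contains no triangles")
    # STL stores per-facet vertices; merge duplicates so meshes round-trip closed
    if fmt == "stl":
        tm.merge_vertices()
    return TriangleMesh.from_trimesh(tm, frame_id)


def _write_ply_double(mesh: TriangleMesh, path: Path) -> None:
    """Binary little-endian PLY with float64 vertices (lossless round-trip)."""
    header = "\n".join([
        "ply",
        "format binary_little_endian 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]) + "\n"
    faces = np.empty((len(mesh.faces), 13), dtype=np.uint8)
    faces[:, 0] = 3
    faces[:, 1:] = mesh.faces.astype("<i4").view(np.uint8).reshape(-1, 12)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
        fh.write(faces.tobytes())


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> Path:
    path = Path(path)
    fmt = _mesh_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        _write_ply_double(mesh, path)
    else:
        mesh.to_trimesh().export(str(path), file_type=fmt)
    return path


def read_points(path, dialect: str | None = None) -> Point3Set:
    """Read a labelled point set from ``label,x,y,z`` CSV or JSON."""
    path = Path(path)
    dialect = (dialect or path.suffix.lstrip(".")).lower()
    if not path.exists():
        raise FormatError(f"point file not found: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"point file {path} is empty")
    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise FormatError(f"failed to parse CSV {path}: {exc}") from exc
        missing = {"label", "x", "y", "z"} - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
        if len(df) == 0:
            raise FormatError(f"{path}: no point rows")
        for col in ("x", "y", "z"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = np.nonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0]
            if len(bad):
                raise FormatError(
                    f"{path}: non-numeric {col} coordinate at data row {bad[0] + 1}"
                )
            df[col] = vals
        return Point3Set(df[["x", "y", "z"]].to_numpy(dtype=float),
                         frame_id="world",
                         labels=tuple(str(v) for v in df["label"]))
    if dialect == "json":
        try:
            doc = json.loads(path.read_text())
        except Exception as exc:
            raise FormatError(f"failed to parse JSON {path}: {exc}") from exc
        try:
            pts = np.asarray(doc["points"], dtype=float)
            labels = tuple(doc["labels"]) if doc.get("labels") else None
            return Point3Set(pts, doc.get("frame_id", "world"), labels)
        except (KeyError, TypeError, ValueError, GeometryError) as exc:
            raise FormatError(f"{path}: invalid point JSON: {exc}") from exc
    raise FormatError(f"unsupported point dialect '{dialect}' (csv or json)")


def write_points(points: Point3Set, path, dialect: str | None = None) -> Path:
    path = Path(path)
    dialect = (dialect or path.suffix.lstrip(".")).lower()
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = points.labels or tuple(f"p{i}" for i in range(len(points)))
    if dialect == "csv":
        df = pd.DataFrame({
            "label": labels,
            "x": points.points[:, 0],
            "y": points.points[:, 1],
            "z": points.points[:, 2],
        })
        df.to_csv(path, index=False)
        return path
    if dialect == "json":
        doc = {
            "frame_id": points.frame_id,
            "labels": list(labels),
            "points": points.points.tolist(),
        }
        path.write_text(json.dumps(doc, indent=1))
        return path
    raise FormatError(f"unsupported point dialect '{dialect}' (csv or json)")


def write_transform(transform: RigidTransform, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "rotation": transform.rotation.reshape(-1).tolist(),  # row-major
        "translation": transform.translation.tolist(),
        "scale": transform.scale,
        "source_frame": transform.source_frame,
        "target_frame": transform.target_frame,
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_transform(path) -> RigidTransform:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"transform file not found: {path}")
    try:
        doc = json.loads(path.read_text())
        return RigidTransform(
            np.asarray(doc["rotation"], dtype=float).reshape(3, 3),
            np.asarray(doc["translation"], dtype=float),
            float(doc.get("scale", 1.0)),
            source_frame=doc.get("source_frame"),
            target_frame=doc.get("target_frame"),
        )
    except (KeyError, ValueError, GeometryError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: invalid transform JSON: {exc}") from exc


def write_contour_stack(stack: ContourStack, path) -> Path:
    """Serialise a contour stack as JSON (control polygons plus metadata)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "plane": stack.plane,
        "slices": [
            {
                "slice_index": i,
                "position_mm": float(z),
                "degree": c.degree,
                "closed": c.closed,
                "control_points_mm": c.control_points.tolist(),
            }
            for i, (c, z) in enumerate(zip(stack.contours, stack.slice_positions))
        ],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_contour_stack(path) -> ContourStack:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"contour file not found: {path}")
    try:
        doc = json.loads(path.read_text())
        slices = sorted(doc["slices"], key=lambda s: s["slice_index"])
        contours = tuple(
            BSplineContour(np.asarray(s["control_points_mm"], dtype=float),
                           degree=int(s.get("degree", 3)),
                           closed=bool(s.get("closed", True)))
            for s in slices
        )
        positions = np.asarray([s["position_mm"] for s in slices], dtype=float)
        return ContourStack(contours, positions, doc.get("plane", "z"))
    except (KeyError, ValueError, TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: invalid contour JSON: {exc}") from exc


def write_mask(volume: np.ndarray, grid: ImageGrid, path) -> Path:
    """Write a binary occupancy volume as NIfTI-1 under the grid's affine."""
    import nibabel as nib

    volume = np.asarray(volume)
    if volume.shape != tuple(grid.dims):
        raise FormatError(
            f"volume shape {volume.shape} does not match grid dims {grid.dims}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume.astype(np.uint8), grid.affine())
    img.header.set_zooms(tuple(grid.spacing))
    nib.save(img, str(path))
    return path


def read_mask(path, frame_id: str = "world") -> tuple[np.ndarray, ImageGrid]:
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FormatError(f"mask file not found: {path}")
    img = nib.load(str(path))
    affine = img.affine
    data = np.asarray(img.get_fdata() > 0.5)
    spacing = np.abs(np.diag(affine)[:3])
    origin = affine[:3, 3]
    grid = ImageGrid(origin, spacing, data.shape, frame_id)
    return data, grid


def write_provenance(path, payload: dict) -> Path:
    """Sidecar recording config, seeds and software version for re-runs."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"software": "bonereg", "version": __version__, **payload}
    path.write_text(json.dumps(doc, indent=1, default=str))
    return path
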