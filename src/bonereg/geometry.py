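"""Geometric primitives shared by the registration toolkit.

All coordinates live in physical millimetres in a right-handed world frame;
registration never happens in voxel indices, so image sets with different
resolutions (e.g. a 0.3 mm CT and a 0.5 mm MRI) share one metric space.
Coordinate frames are opaque text labels: the toolkit never converts between
anatomical conventions (LPS/RAS), it only checks that operations combine data
from compatible frames.

Rigid transforms act as ``p -> s * R @ p + t`` (rotate, then translate), the
parameterisation of the rigid coherent point drift model.  ``scale`` is 1 for
genuinely rigid motion and is only freed when explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Point3Set",
    "TriangleMesh",
    "RigidTransform",
    "ImageGrid",
    "apply_transform",
    "compose",
    "invert",
    "transform_discrepancy",
    "rotation_about_axis",
]

_ORTHO_TOL = 1e-9


class GeometryError(ValueError):
    """Invalid geometric input (non-finite coordinates, bad mesh, ...)."""


def _as_points(points, name: str = "points") -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise GeometryError(f"{name} must be an (n, 3) array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise GeometryError(f"{name} contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class Point3Set:
    """Ordered labelled 3-D point set in millimetres.

    Houses attraction points, fiducial coordinates and surface samples alike.
    """

    points: np.ndarray
    frame_id: str = "world"
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "points", _as_points(self.points))
        if not self.frame_id:
            raise GeometryError("frame_id must be a non-empty label")
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != len(self.points):
                raise GeometryError(
                    f"{len(labels)} labels for {len(self.points)} points"
                )
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray, frame_id: str | None = None) -> "Point3Set":
        points = np.asarray(points, dtype=float)
        labels = self.labels if (self.labels is not None
                                 and len(self.labels) == len(points)) else None
        return Point3Set(points, frame_id or self.frame_id, labels)


@dataclass
class TriangleMesh:
    """Closed triangulated surface in millimetres.

    Wraps plain vertex/face arrays; conversion to :mod:`trimesh` is used for
    watertightness checks, areas, volumes and file I/O.  Volumetric
    operations (Dice, fiducial embedding) require a closed, manifold,
    outward-wound surface; :meth:`require_closed` enforces that.
    """

    vertices: np.ndarray
    faces: np.ndarray
    frame_id: str = "world"

    def __post_init__(self):
        self.vertices = _as_points(self.vertices, "vertices")
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (m, 3) index array")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise GeometryError("face indices out of range")
        if not self.frame_id:
            raise GeometryError("frame_id must be a non-empty label")
        self._tm = None
        self._surface_cache = None  # KD-tree acceleration, built lazily

    # -- trimesh bridge -------------------------------------------------
    def to_trimesh(self):
        import trimesh

        if self._tm is None:
            self._tm = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm

    @classmethod
    def from_trimesh(cls, tm, frame_id: str = "world") -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, dtype=float),
                   np.asarray(tm.faces, dtype=np.int64), frame_id)

    # -- derived quantities ---------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.face_areas().sum())

    def signed_volume(self) -> float:
        t = self.triangles
        return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)

    def boundary_edge_count(self) -> int:
        edges = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0 and len(self.faces) > 0

    def require_closed(self, context: str = "volumetric operation") -> None:
        n_bad = self.boundary_edge_count()
        if n_bad or not len(self.faces):
            raise GeometryError(
                f"{context} requires a closed mesh; "
                f"{n_bad} edge(s) are not shared by exactly 2 faces"
            )
        if self.signed_volume() <= 0:
            raise GeometryError(
                f"{context} requires outward-wound faces (signed volume > 0)"
            )

    def has_degenerate_faces(self, tol: float = 0.0) -> bool:
        return bool(np.any(self.face_areas() <= tol))

    def transformed(self, transform: "RigidTransform",
                    frame_id: str | None = None) -> "TriangleMesh":
        return TriangleMesh(
            transform.apply(self.vertices),
            self.faces.copy(),
            frame_id or transform.target_frame or self.frame_id,
        )


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise GeometryError("rotation must be a 3x3 matrix")
    if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-6:
        raise GeometryError("rotation matrix is not orthonormal")
    if np.linalg.det(r) < 0:
        raise GeometryError("rotation matrix is a reflection (det < 0)")
    # re-orthonormalise so long compose/invert chains do not drift
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class RigidTransform:
    """Similarity transform ``p -> scale * rotation @ p + translation``.

    ``scale`` defaults to 1 (rigid); it is only non-unit when scaling was
    explicitly enabled in a registration.  ``source_frame``/``target_frame``
    are optional frame labels used to tag transformed point sets.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0
    source_frame: str | None = None
    target_frame: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise GeometryError("translation contains non-finite values")
        object.__setattr__(self, "translation", t)
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise GeometryError("scale must be a positive finite scalar")

    @classmethod
    def identity(cls, frame: str | None = None) -> "RigidTransform":
        return cls(source_frame=frame, target_frame=frame)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = _as_points(points)
        return self.scale * (p @ self.rotation.T) + self.translation

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m

    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def apply_transform(transform: RigidTransform, points: Point3Set) -> Point3Set:
    """Map a point set through a rigid transform, retagging its frame."""
    out = transform.apply(points.points)
    frame = transform.target_frame or points.frame_id
    return Point3Set(out, frame, points.labels)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Transform equal to applying ``b`` first, then ``a``."""
    rotation = a.rotation @ b.rotation
    scale = a.scale * b.scale
    translation = a.scale * (a.rotation @ b.translation) + a.translation
    return RigidTransform(rotation, translation, scale,
                          source_frame=b.source_frame, target_frame=a.target_frame)


def invert(t: RigidTransform) -> RigidTransform:
    rotation = t.rotation.T
    scale = 1.0 / t.scale
    translation = -scale * (rotation @ t.translation)
    return RigidTransform(rotation, translation, scale,
                          source_frame=t.target_frame, target_frame=t.source_frame)


def transform_discrepancy(a: RigidTransform, b: RigidTransform) -> tuple[float, float]:
    """Rotation (degrees, in [0, 180]) and translation (mm) between two rigid
    transforms, measured on the residual ``a * b^-1``."""
    if not (np.isclose(a.scale, 1.0) and np.isclose(b.scale, 1.0)):
        raise GeometryError("transform_discrepancy requires scale-1 transforms")
    residual = compose(a, invert(b))
    return residual.rotation_angle_deg(), float(np.linalg.norm(residual.translation))


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise GeometryError("rotation axis must be non-zero")
    k = axis / n
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    th = np.radians(angle_deg)
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


@dataclass(frozen=True)
class ImageGrid:
    """Regular voxel grid; ``origin`` is the CENTER of voxel (0, 0, 0).

    Voxel indices are 0-based.  The affine mapping index -> mm is
    ``x = origin + index * spacing`` (axis-aligned; no obliquity).
    """

    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]
    frame_id: str = "world"

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        s = np.asarray(self.spacing, dtype=float).reshape(3)
        if not np.all(np.isfinite(o)):
            raise GeometryError("grid origin must be finite")
        if not np.all(s > 0):
            raise GeometryError("grid spacing must be strictly positive")
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise GeometryError("grid dims must be three integers >= 1")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "spacing", s)
        object.__setattr__(self, "dims", dims)

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    def affine(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = np.diag(self.spacing)
        m[:3, 3] = self.origin
        return m

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))
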