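"""Per-slice B-spline contours and lofting them into closed surface meshes.

Segmentations are represented the way a sub-pixel contouring workflow
produces them: each image slice carries a closed B-spline curve (control
polygon in in-plane mm coordinates), and the ordered stack of slices is
lofted into a closed, manifold, outward-wound triangle mesh.

Conventions (the upstream contouring literature does not fix them, so they
are package choices): uniform knot vectors, periodic for closed contours and
clamped for open ones; cubic degree by default; slice-to-slice stitching
after resampling both contours to a common count and removing the cyclic
offset that minimises the summed squared inter-slice distances; end caps as
triangle fans to the contour centroid.  Branching anatomy (two contours on
one slice) is rejected - one closed contour per slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .geometry import GeometryError, TriangleMesh

__all__ = ["BSplineContour", "ContourStack", "loft_contour_stack"]

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class ContourError(ValueError):
    """Invalid contour or stack input."""


@dataclass(frozen=True)
class BSplineContour:
    """A single planar B-spline curve defined by its control polygon (mm).

    Closed contours are periodic: ``evaluate(0) == evaluate(1)`` and the
    parameter wraps modulo 1.  Open contours use a clamped uniform knot
    vector so the curve interpolates the first and last control points.
    """

    control_points: np.ndarray
    degree: int = 3
    closed: bool = True

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 2:
            raise ContourError("control_points must be an (m, 2) array")
        if not np.all(np.isfinite(cp)):
            raise ContourError("control points must be finite")
        if self.degree < 1:
            raise ContourError("degree must be >= 1")
        if len(cp) < self.degree + 1:
            raise ContourError(
                f"need at least degree+1={self.degree + 1} control points, got {len(cp)}"
            )
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "_spline", self._build_spline(cp))

    def _build_spline(self, cp: np.ndarray) -> BSpline:
        k = self.degree
        if self.closed:
            n = len(cp)
            coefs = cp[np.arange(n + k) % n]
            knots = (np.arange(n + 2 * k + 1) - k) / n
            return BSpline(knots, coefs, k, extrapolate=False)
        n = len(cp)
        interior = np.linspace(0.0, 1.0, n - k + 1)
        knots = np.concatenate([np.zeros(k), interior, np.ones(k)])
        return BSpline(knots, cp, k, extrapolate=False)

    def evaluate(self, t) -> np.ndarray:
        """Point(s) on the curve at parameter(s) ``t`` in [0, 1)."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if self.closed:
            t = np.mod(t, 1.0)
        elif np.any(t < 0) or np.any(t > 1):
            raise ContourError("parameter outside [0, 1] for an open contour")
        out = self._spline(np.clip(t, 0.0, 1.0))
        return out[0] if scalar else out

    def resample(self, n: int, dense: int = 4096) -> np.ndarray:
        """``n`` approximately arc-length-uniform points along the curve.

        Orientation (winding direction) of the control polygon is preserved.
        """
        if n < 3:
            raise ContourError("resampling needs n >= 3 points")
        dense = max(dense, 8 * n)
        t_grid = np.linspace(0.0, 1.0, dense + 1)
        pts = self.evaluate(t_grid)
        arc = np.concatenate(
            [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
        )
        total = arc[-1]
        if total <= 1e-12:
            raise ContourError("degenerate contour: near-zero arc length")
        targets = np.linspace(0.0, total, n, endpoint=not self.closed)
        t_new = np.interp(targets, arc, t_grid)
        return self.evaluate(t_new)

    def perimeter(self, dense: int = 8192) -> float:
        tt = np.linspace(0.0, 1.0, dense, endpoint=True)
        pts = self.evaluate(tt)
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def evaluate_contour(contour: BSplineContour, t) -> np.ndarray:
    return contour.evaluate(t)


def resample_contour(contour: BSplineContour, n: int) -> np.ndarray:
    return contour.resample(n)


@dataclass(frozen=True)
class ContourStack:
    """Ordered per-slice contours plus their out-of-plane positions (mm)."""

    contours: tuple[BSplineContour, ...]
    slice_positions: np.ndarray
    plane: str = "z"

    def __post_init__(self):
        contours = tuple(self.contours)
        pos = np.asarray(self.slice_positions, dtype=float).reshape(-1)
        if len(contours) != len(pos):
            raise ContourError("one slice position per contour required")
        d = np.diff(pos)
        if len(pos) and not (np.all(d > 0) or np.all(d < 0)):
            raise ContourError("slice positions must be strictly monotone")
        if self.plane not in _AXIS_INDEX:
            raise ContourError("plane must be one of 'x', 'y', 'z'")
        object.__setattr__(self, "contours", contours)
        object.__setattr__(self, "slice_positions", pos)

    def __len__(self) -> int:
        return len(self.contours)


def _polygon_signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _best_cyclic_offset(a: np.ndarray, b: np.ndarray) -> int:
    """Offset k minimising sum ||a[j] - b[(j+k) % n]||^2."""
    n = len(a)
    # maximise correlation sum_j a[j] . b[j+k]
    best_k, best_val = 0, -np.inf
    for k in range(n):
        val = float(np.einsum("ij,ij->", a, np.roll(b, -k, axis=0)))
        if val > best_val:
            best_val, best_k = val, k
    return best_k


def _lift(poly2d: np.ndarray, position: float, plane: str) -> np.ndarray:
    axis = _AXIS_INDEX[plane]
    in_plane = [i for i in range(3) if i != axis]
    out = np.empty((len(poly2d), 3))
    out[:, in_plane[0]] = poly2d[:, 0]
    out[:, in_plane[1]] = poly2d[:, 1]
    out[:, axis] = position
    return out


def loft_contour_stack(stack: ContourStack, samples_per_contour: int = 128,
                       frame_id: str = "world") -> TriangleMesh:
    """Stitch a contour stack into a closed, manifold, outward-wound mesh.

    Raises on stacks whose stitching self-intersects badly enough to produce
    a non-positive enclosed volume.
    """
    if len(stack) < 2:
        raise ContourError("lofting needs at least 2 contours")
    if samples_per_contour < 3:
        raise ContourError("samples_per_contour must be >= 3")

    positions = stack.slice_positions
    order = np.argsort(positions)
    positions = positions[order]
    contours = [stack.contours[i] for i in order]

    n = samples_per_contour
    rings2d = []
    for c in contours:
        poly = c.resample(n)
        if _polygon_signed_area(poly) < 0:  # enforce CCW viewed from +axis
            poly = poly[::-1]
        rings2d.append(poly)

    # remove cyclic twist between consecutive rings
    for i in range(1, len(rings2d)):
        k = _best_cyclic_offset(rings2d[i - 1], rings2d[i])
        rings2d[i] = np.roll(rings2d[i], -k, axis=0)

    rings = [_lift(p, z, stack.plane) for p, z in zip(rings2d, positions)]
    n_rings = len(rings)
    vertices = np.concatenate(rings, axis=0)
    bottom_c = len(vertices)
    top_c = bottom_c + 1
    vertices = np.concatenate(
        [vertices, rings[0].mean(axis=0, keepdims=True), rings[-1].mean(axis=0, keepdims=True)]
    )

    faces = []
    for i in range(n_rings - 1):
        lo, hi = i * n, (i + 1) * n
        for j in range(n):
            a, b = lo + j, lo + (j + 1) % n
            c, d = hi + (j + 1) % n, hi + j
            if j % 2 == 0:
                faces.append((a, b, c))
                faces.append((a, c, d))
            else:
                faces.append((a, b, d))
                faces.append((b, c, d))
    for j in range(n):  # bottom cap, outward -axis
        faces.append((bottom_c, (j + 1) % n, j))
    base = (n_rings - 1) * n
    for j in range(n):  # top cap, outward +axis
        faces.append((top_c, base + j, base + (j + 1) % n))

    mesh = TriangleMesh(vertices, np.asarray(faces, dtype=np.int64), frame_id)
    vol = mesh.signed_volume()
    if vol < 0:
        mesh = TriangleMesh(vertices, mesh.faces[:, [0, 2, 1]], frame_id)
        vol = -vol
    if vol <= 0:
        raise GeometryError(
            "lofted surface encloses non-positive volume; the stitch between "
            "at least one adjacent slice pair self-intersects"
        )
    return mesh
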