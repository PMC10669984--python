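"""Planar cross-sections of triangle meshes and their polygon metrics.

This module is the area oracle of the package: connector detection uses it to
measure initial cross-sectional areas and the area-matching solver re-measures
the deformed mesh here at every iteration.

The plane/mesh intersection kernel computes one intersection point per
crossing mesh *edge* (not per triangle), so shared edges of adjacent triangles
map to the identical point and loop chaining is exact by construction.  Loops
are returned as :class:`PlanarPolygon` objects in a 2-D chart spanned by
caller-supplied in-plane axes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InputError, ParameterError
from .geometry import Plane, unit

__all__ = [
    "PlanarPolygon",
    "SectionMetrics",
    "intersect_plane",
    "polygon_area",
    "select_connector_loop",
    "section_metrics",
]

#: plane-offset used to nudge vertices that lie exactly on the slicing plane
_ON_PLANE_EPS = 1e-12
#: collinear-point cleanup tolerance (mm)
_COLLINEAR_TOL = 1e-9


@dataclass
class PlanarPolygon:
    """A closed planar loop in a 2-D chart embedded in 3-D.

    Parameters
    ----------
    plane:
        The 3-D plane the loop lies in.
    vertices:
        (n, 2) loop coordinates ``(u, v)`` in the chart, ordered
        counter-clockwise.  For connector sections the chart is
        ``u = ŷ`` (buccal) and ``v = x̂`` (occlusal) of the owning site, so the
        reported "length" is the bucco-lingual extent and "height" the
        occluso-gingival extent.
    axis_u, axis_v:
        Unit 3-vectors spanning the chart; the chart origin is ``plane.point``.
    """

    plane: Plane
    vertices: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    closed: bool = True

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.axis_u = unit(self.axis_u)
        self.axis_v = unit(self.axis_v)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise InputError("polygon vertices must be an (n, 2) array")

    def to_3d(self) -> np.ndarray:
        """Loop vertices embedded back into 3-D world coordinates."""
        u, v = self.vertices[:, 0:1], self.vertices[:, 1:2]
        return self.plane.point + u * self.axis_u + v * self.axis_v

    def centroid_3d(self) -> np.ndarray:
        cu, cv = _shoelace_centroid(self.vertices)
        return self.plane.point + cu * self.axis_u + cv * self.axis_v


@dataclass(frozen=True)
class SectionMetrics:
    """Polygon descriptors of a connector section."""

    area: float
    centroid: tuple
    height: float  # extent along axis_v (occluso-gingival)
    length: float  # extent along axis_u (bucco-lingual)
    principal_moments: tuple  # principal second moments of area, mm^4

    def __post_init__(self):
        if self.area <= 0 or self.height <= 0 or self.length <= 0:
            raise InputError("section metrics require positive area/extents")


# ---------------------------------------------------------------------------
# intersection kernel
# ---------------------------------------------------------------------------

def _chart_axes(normal: np.ndarray):
    """Deterministic in-plane orthonormal pair for an arbitrary normal."""
    n = unit(normal)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([1.0, 0.0, 0.0])
    u = unit(np.cross(helper, n))
    v = np.cross(n, u)
    return u, v


def _section_segments(vertices, faces, signed):
    """Per-edge intersection points and per-face crossing-edge pairs.

    Returns ``(points, pairs)`` where ``points`` is (p, 3) and ``pairs`` is
    (q, 2) indices into ``points``; each pair is the intersection segment of
    one triangle.  ``signed`` must be non-zero for every vertex.
    """
    s = np.sign(signed)
    fs = s[faces]  # (m, 3)
    crossing = ~np.all(fs == fs[:, [0]], axis=1)
    if not crossing.any():
        return np.empty((0, 3)), np.empty((0, 2), dtype=np.int64)
    f = faces[crossing]

    # gather crossing edges (canonical vertex order) per face
    edges = np.stack(
        [f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]], axis=1
    )  # (m, 3, 2)
    edge_cross = s[edges[:, :, 0]] != s[edges[:, :, 1]]  # (m, 3)
    # each crossing triangle has exactly two crossing edges
    canon = np.sort(edges, axis=2)
    flat_edges = canon[edge_cross]  # (2m, 2) in face order
    per_face = edge_cross.sum(axis=1)
    if not np.all(per_face == 2):  # pragma: no cover - guarded by sign nudge
        raise InputError("inconsistent plane crossing; degenerate triangles?")

    uniq, inverse = np.unique(flat_edges, axis=0, return_inverse=True)
    da = signed[uniq[:, 0]]
    db = signed[uniq[:, 1]]
    t = da / (da - db)
    points = vertices[uniq[:, 0]] + t[:, None] * (
        vertices[uniq[:, 1]] - vertices[uniq[:, 0]]
    )
    pairs = inverse.reshape(-1, 2)
    return points, pairs


def _chain_loops(n_points: int, pairs: np.ndarray):
    """Chain intersection segments into closed loops of point indices.

    Each point (mesh edge) joins exactly two segments on a watertight mesh;
    open chains are dropped with a warning.
    """
    adjacency = {}
    for a, b in pairs:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))
    visited = set()
    loops, open_chains = [], 0
    for start in adjacency:
        if start in visited:
            continue
        if len(adjacency[start]) != 2:
            open_chains += 1
            visited.add(start)
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        closed = False
        while True:
            nbrs = adjacency[cur]
            nxt = None
            for cand in nbrs:
                if cand != prev:
                    nxt = cand
                    break
            if nxt is None or len(adjacency.get(nxt, [])) != 2:
                open_chains += 1
                break
            if nxt == start:
                closed = True
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        if closed and len(loop) >= 3:
            loops.append(loop)
    if open_chains:
        warnings.warn(
            f"dropped {open_chains} open intersection chain(s); "
            "mesh is not watertight near the slicing plane",
            stacklevel=3,
        )
    return loops


def _cleanup_collinear(pts: np.ndarray, tol: float = _COLLINEAR_TOL):
    """Remove duplicate and collinear points from a closed 2-D loop."""
    if len(pts) < 3:
        return pts
    prev = np.roll(pts, 1, axis=0)
    keep = np.linalg.norm(pts - prev, axis=1) > tol
    pts = pts[keep]
    if len(pts) < 3:
        return pts
    a = pts - np.roll(pts, 1, axis=0)
    b = np.roll(pts, -1, axis=0) - pts
    cross = np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    pts = pts[cross > tol]
    return pts


def intersect_plane(
    mesh,
    plane: Plane,
    axis_u: np.ndarray | None = None,
    axis_v: np.ndarray | None = None,
    _signed: np.ndarray | None = None,
) -> list[PlanarPolygon]:
    """All closed loops of the mesh/plane intersection, as 2-D chart polygons.

    Parameters
    ----------
    mesh:
        A :class:`~fpdremodel.mesh_io.TriangleMesh`.
    plane:
        Slicing plane with unit normal.
    axis_u, axis_v:
        Optional in-plane chart axes (must be orthonormal and perpendicular to
        the normal); a deterministic pair is derived from the normal if absent.
    """
    if axis_u is None or axis_v is None:
        axis_u, axis_v = _chart_axes(plane.normal)
    else:
        axis_u, axis_v = unit(axis_u), unit(axis_v)
    signed = _signed
    if signed is None:
        signed = (mesh.vertices - plane.point) @ plane.normal
    signed = signed.copy()
    on_plane = np.abs(signed) < _ON_PLANE_EPS
    if on_plane.any():
        signed[on_plane] = _ON_PLANE_EPS  # nudge to the positive side
    points, pairs = _section_segments(mesh.vertices, mesh.faces, signed)
    if len(pairs) == 0:
        return []
    loops = _chain_loops(len(points), pairs)
    polys = []
    rel = points - plane.point
    uv = np.column_stack([rel @ axis_u, rel @ axis_v])
    for loop in loops:
        pts = _cleanup_collinear(uv[loop])
        if len(pts) < 3:
            continue
        if _shoelace(pts) < 0:  # normalize CCW
            pts = pts[::-1]
        polys.append(
            PlanarPolygon(plane=plane, vertices=pts, axis_u=axis_u, axis_v=axis_v)
        )
    return polys


# ---------------------------------------------------------------------------
# polygon metrics
# ---------------------------------------------------------------------------

def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1)) - np.sum(y * np.roll(x, -1))
    )


def _shoelace_centroid(pts: np.ndarray):
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-15:
        return float(x.mean()), float(y.mean())
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return float(cx), float(cy)


def _require_simple(pts: np.ndarray):
    if len(pts) < 3:
        raise InputError("polygon needs at least 3 vertices")
    if not _ShapelyPolygon(pts).is_valid:
        raise InputError("polygon is self-intersecting")


def polygon_area(poly: PlanarPolygon, validate: bool = True) -> float:
    """Shoelace area (mm²) of a simple closed polygon; always positive."""
    pts = _cleanup_collinear(poly.vertices)
    if validate:
        _require_simple(pts)
    elif len(pts) < 3:
        raise InputError("polygon needs at least 3 vertices")
    return abs(_shoelace(pts))


def select_connector_loop(loops: list[PlanarPolygon], site) -> PlanarPolygon:
    """The loop whose centroid is nearest the site's frame origin.

    Raises if no loop exists (the connector has been pinched away, e.g. by a
    deformation-parameter overshoot).
    """
    if not loops:
        raise InputError("no section loop at the connector plane")
    origin = np.asarray(site.frame.origin, dtype=float)
    d = np.array([np.linalg.norm(lp.centroid_3d() - origin) for lp in loops])
    order = np.argsort(d)
    if len(loops) > 1 and d[order[1]] - d[order[0]] < 1.0:
        warnings.warn(
            "multiple section loops within 1 mm of the connector origin; "
            "taking the nearest",
            stacklevel=2,
        )
    return loops[int(order[0])]


def section_metrics(poly: PlanarPolygon) -> SectionMetrics:
    """Area, centroid, chart-axis extents and principal second moments.

    "height" is the extent along ``axis_v`` (occluso-gingival for connector
    charts) and "length" the extent along ``axis_u`` (bucco-lingual).  Second
    moments are computed about the centroid with the standard polygon moment
    formulas and diagonalized.
    """
    pts = _cleanup_collinear(poly.vertices)
    _require_simple(pts)
    if _shoelace(pts) < 0:
        pts = pts[::-1]
    area = _shoelace(pts)
    cx, cy = _shoelace_centroid(pts)
    x = pts[:, 0] - cx
    y = pts[:, 1] - cy
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    ixx = np.sum((y * y + y * yn + yn * yn) * cross) / 12.0
    iyy = np.sum((x * x + x * xn + xn * xn) * cross) / 12.0
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross) / 24.0
    eig = np.linalg.eigvalsh(np.array([[ixx, -ixy], [-ixy, iyy]]))
    length = float(pts[:, 0].max() - pts[:, 0].min())
    height = float(pts[:, 1].max() - pts[:, 1].min())
    return SectionMetrics(
        area=float(area),
        centroid=(cx, cy),
        height=height,
        length=length,
        principal_moments=(float(eig[0]), float(eig[1])),
    )
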