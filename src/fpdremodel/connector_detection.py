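"""Automatic connector detection for n-unit FPD meshes.

The connectors (the narrow necks joining adjacent crown/pontic units) are
located by framing the bridge in its smallest oriented bounding box, slicing
it with equally spaced planes perpendicular to the mesio-distal mid-axis,
bounding each intersection curve with a rectangle split at mid-height into an
occlusal and a gingival part, and finding the local minima of the two
resulting area series.  Occlusal and gingival minima are detected separately
and paired, so oblique connectors (whose occlusal and gingival waists sit at
different stations) are handled.

Anatomical face labels cannot be derived from the box alone; they come from
orientation hints (approximate occlusal, buccal and mesial→distal directions)
that default to the world axes +Z, +Y and +X.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from . import cross_section
from .errors import DetectionError, InputError, ParameterError
from .geometry import Plane, plane_intersection_3, unit
from .mesh_io import TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "OrientationHints",
    "OrientedBox",
    "MidAxis",
    "Rect2D",
    "SliceProfile",
    "LocalFrame",
    "ConnectorSite",
    "DetectionParams",
    "fit_oriented_box",
    "mid_axis",
    "slice_profiles",
    "split_rectangles",
    "find_connector_minima",
    "build_connector_site",
    "detect_connectors",
]


@dataclass(frozen=True)
class OrientationHints:
    """Approximate anatomical directions used to label the bounding box."""

    occlusal: tuple = (0.0, 0.0, 1.0)
    buccal: tuple = (0.0, 1.0, 0.0)
    mesial_to_distal: tuple = (1.0, 0.0, 0.0)

    def rotated(self, rotation: np.ndarray) -> "OrientationHints":
        r = np.asarray(rotation, dtype=float)
        return OrientationHints(
            occlusal=tuple(r @ np.asarray(self.occlusal, float)),
            buccal=tuple(r @ np.asarray(self.buccal, float)),
            mesial_to_distal=tuple(r @ np.asarray(self.mesial_to_distal, float)),
        )


@dataclass
class OrientedBox:
    """Smallest oriented bounding box with anatomical axis labels.

    ``axis_md`` points mesial→distal, ``axis_og`` gingival→occlusal and
    ``axis_lb`` lingual→buccal; ``half_extents`` are the corresponding half
    side lengths.  ``e_mid`` is the mid-plane between the occlusal and
    gingival faces, ``e_mid2`` between the lingual and buccal faces.
    """

    center: np.ndarray
    axis_md: np.ndarray
    axis_og: np.ndarray
    axis_lb: np.ndarray
    half_extents: np.ndarray  # (md, og, lb) order

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.axis_md = unit(self.axis_md)
        self.axis_og = unit(self.axis_og)
        self.axis_lb = unit(self.axis_lb)
        self.half_extents = np.asarray(self.half_extents, dtype=float)

    @property
    def e_mid(self) -> Plane:
        return Plane(self.center, self.axis_og)

    @property
    def e_mid2(self) -> Plane:
        return Plane(self.center, self.axis_lb)

    def face_center(self, label: str) -> np.ndarray:
        axis, sign, k = {
            "distal": (self.axis_md, +1.0, 0),
            "mesial": (self.axis_md, -1.0, 0),
            "occlusal": (self.axis_og, +1.0, 1),
            "gingival": (self.axis_og, -1.0, 1),
            "buccal": (self.axis_lb, +1.0, 2),
            "lingual": (self.axis_lb, -1.0, 2),
        }[label]
        return self.center + sign * self.half_extents[k] * axis


@dataclass(frozen=True)
class MidAxis:
    """Segment joining the centers of the distal and mesial box faces."""

    start: np.ndarray  # distal face center
    end: np.ndarray  # mesial face center

    @property
    def direction(self) -> np.ndarray:
        return unit(np.asarray(self.end) - np.asarray(self.start))

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.end) - np.asarray(self.start)))

    def point_at(self, station: float) -> np.ndarray:
        return np.asarray(self.start) + station * self.direction


@dataclass(frozen=True)
class Rect2D:
    """An axis-aligned rectangle in a slice chart (u = lingual→buccal,
    v = gingival→occlusal, v = 0 on the box mid-plane)."""

    umin: float
    umax: float
    vmin: float
    vmax: float

    @property
    def area(self) -> float:
        return max(0.0, self.umax - self.umin) * max(0.0, self.vmax - self.vmin)

    def is_empty(self) -> bool:
        return self.umax <= self.umin or self.vmax <= self.vmin


@dataclass
class SliceProfile:
    """Per-plane slicing record: curves, split rectangles and their areas."""

    index: int
    station: float  # mm along the mid-axis from the distal face
    plane: Plane
    curves: list  # list of PlanarPolygon
    rect_occ: Rect2D | None
    rect_gin: Rect2D | None
    a_occ: float
    a_gin: float


@dataclass
class LocalFrame:
    """Right-handed connector frame: x̂ occlusal, ŷ buccal, ẑ = x̂ × ŷ.

    The origin is the intersection of the box mid-planes with the connector
    plane; the connector plane is the local x–y plane.
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def to_local(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack(
            [rel @ self.x_axis, rel @ self.y_axis, rel @ self.z_axis]
        )

    def to_world(self, local: np.ndarray) -> np.ndarray:
        local = np.atleast_2d(local)
        return (
            self.origin
            + local[:, 0:1] * self.x_axis
            + local[:, 1:2] * self.y_axis
            + local[:, 2:3] * self.z_axis
        )


@dataclass
class ConnectorSite:
    """A detected connector and everything needed to adjust it."""

    ordinal: int  # 0-based, distal→mesial
    alpha: int  # slice index of the occlusal area minimum
    beta: int  # slice index of the gingival area minimum
    l_o: np.ndarray  # (2, 3) occlusal edge segment
    l_g: np.ndarray  # (2, 3) gingival edge segment
    e_midcon: Plane
    frame: LocalFrame
    a0: float
    section_loop: cross_section.PlanarPolygon
    station: float = 0.0  # mm along the mid-axis from the distal face

    @property
    def obliquity_deg(self) -> float:
        """Angle between the connector plane normal and the mid-axis."""
        c = abs(float(self.e_midcon.normal @ self.frame.z_axis))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the minima search on the discrete area series."""

    n_planes: int = 300
    smoothing_window: int = 5
    prominence_frac: float = 0.05
    pairing_window: int = 15


# ---------------------------------------------------------------------------
# oriented box and mid-axis
# ---------------------------------------------------------------------------

def fit_oriented_box(
    mesh: TriangleMesh, hints: OrientationHints | None = None
) -> OrientedBox:
    """Smallest oriented bounding box with anatomically labeled axes.

    The box is found by a convex-hull based orientation search (1° scan
    granularity, deterministic).  Labels: the axis of largest extent is
    mesio-distal (signed by the mesial→distal hint); of the remaining two the
    one most parallel to the occlusal hint is occluso-gingival; the last is
    linguo-buccal, signed by the buccal hint.
    """
    hints = hints or OrientationHints()
    tm = mesh.as_trimesh()
    try:
        to_origin, extents = trimesh.bounds.oriented_bounds(tm, angle_digits=1)
    except Exception as exc:
        raise InputError(f"oriented box fit failed: {exc}") from exc
    if np.min(extents) < 1e-9:
        raise InputError("degenerate (flat or linear) geometry")
    rot = np.asarray(to_origin)[:3, :3]
    center = -rot.T @ np.asarray(to_origin)[:3, 3]
    axes = [rot[i, :] for i in range(3)]
    half = np.asarray(extents, dtype=float) / 2.0

    i_md = int(np.argmax(half))
    rest = [i for i in range(3) if i != i_md]
    occ_hint = unit(np.asarray(hints.occlusal, float))
    i_og = max(rest, key=lambda i: abs(axes[i] @ occ_hint))
    i_lb = [i for i in rest if i != i_og][0]

    axis_md = axes[i_md]
    if axis_md @ unit(np.asarray(hints.mesial_to_distal, float)) < 0:
        axis_md = -axis_md
    axis_og = axes[i_og]
    if axis_og @ occ_hint < 0:
        axis_og = -axis_og
    axis_lb = axes[i_lb]
    if axis_lb @ unit(np.asarray(hints.buccal, float)) < 0:
        axis_lb = -axis_lb

    return OrientedBox(
        center=center,
        axis_md=axis_md,
        axis_og=axis_og,
        axis_lb=axis_lb,
        half_extents=half[[i_md, i_og, i_lb]],
    )


def mid_axis(box: OrientedBox) -> MidAxis:
    """The line joining the centers of the (smallest) distal and mesial faces."""
    return MidAxis(start=box.face_center("distal"), end=box.face_center("mesial"))


# ---------------------------------------------------------------------------
# slicing
# ---------------------------------------------------------------------------

def split_rectangles(curves: list, box: OrientedBox):
    """Bounding rectangle of the slice curves, clipped at the box mid-plane.

    The full rectangle (sides parallel to the box axes) is divided by
    ``e_mid`` into an occlusal and a gingival sub-rectangle; the two share
    their lingual–buccal extent and their boundary on the mid-plane.  Returns
    ``(rect_occ, rect_gin, a_occ, a_gin)``; a side not reached by the curves
    has zero area.
    """
    if not curves:
        return None, None, 0.0, 0.0
    pts = np.vstack([c.vertices for c in curves])
    umin, vmin = pts.min(axis=0)
    umax, vmax = pts.max(axis=0)
    width = umax - umin
    rect_occ = Rect2D(umin, umax, max(vmin, 0.0), vmax)
    rect_gin = Rect2D(umin, umax, vmin, min(vmax, 0.0))
    a_occ = width * max(0.0, vmax - max(vmin, 0.0))
    a_gin = width * max(0.0, min(vmax, 0.0) - vmin)
    return rect_occ, rect_gin, a_occ, a_gin


def slice_profiles(
    mesh: TriangleMesh,
    box: OrientedBox,
    n_planes: int = 300,
) -> list[SliceProfile]:
    """Slice the mesh with equally spaced planes perpendicular to the mid-axis.

    Stations run over the full mid-axis length with a half-spacing margin at
    both ends (plane i sits at ``(i + 1/2) * L / n`` from the distal face).
    Chart convention per slice: ``u`` along ``axis_lb`` and ``v`` along
    ``axis_og`` with ``v = 0`` on ``e_mid``.
    """
    if n_planes < 10:
        raise ParameterError("n_planes must be >= 10")
    axis = mid_axis(box)
    d = axis.direction
    proj = mesh.vertices @ d  # reused for every plane
    profiles = []
    spacing = axis.length / n_planes
    for i in range(n_planes):
        station = (i + 0.5) * spacing
        point = axis.point_at(station)
        plane = Plane(point, d)
        signed = proj - (point @ d)
        curves = cross_section.intersect_plane(
            mesh, plane, axis_u=box.axis_lb, axis_v=box.axis_og, _signed=signed
        )
        if not curves:
            logger.warning("slice %d at station %.3f mm has no section", i, station)
        rect_occ, rect_gin, a_occ, a_gin = split_rectangles(curves, box)
        profiles.append(
            SliceProfile(
                index=i,
                station=station,
                plane=plane,
                curves=curves,
                rect_occ=rect_occ,
                rect_gin=rect_gin,
                a_occ=a_occ,
                a_gin=a_gin,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# minima search and pairing
# ---------------------------------------------------------------------------

def _local_minima(series: np.ndarray, window: int, prominence_frac: float):
    if window > 1:
        smooth = uniform_filter1d(series.astype(float), size=window, mode="nearest")
    else:
        smooth = series.astype(float)
    rng = float(smooth.max() - smooth.min())
    if rng <= 0:
        return np.array([], dtype=int)
    # absolute floor: 1% of the series maximum, so a near-flat series with
    # discretization ripple does not spawn spurious "connectors"
    prominence = max(prominence_frac * rng, 0.01 * float(smooth.max()))
    idx, _ = find_peaks(-smooth, prominence=prominence)
    return idx


def find_connector_minima(
    profiles: list[SliceProfile], params: DetectionParams | None = None
):
    """Paired local minima (α_j, β_j) of the occlusal and gingival area series.

    The two series are searched separately (connectors may be oblique) after
    optional moving-average smoothing; minima must have prominence at least
    ``prominence_frac`` of the series range.  α and β minima are paired by
    nearest index within ``pairing_window``; unpaired minima are dropped with
    a warning.  Pairs are returned ordered distal→mesial.
    """
    if len(profiles) < 10:
        raise ParameterError("need at least 10 slice profiles")
    params = params or DetectionParams()
    a_occ = np.array([p.a_occ for p in profiles])
    a_gin = np.array([p.a_gin for p in profiles])
    alphas = _local_minima(a_occ, params.smoothing_window, params.prominence_frac)
    betas = _local_minima(a_gin, params.smoothing_window, params.prominence_frac)

    pairs = []
    available = list(betas)
    for a in alphas:
        if not available:
            warnings.warn(f"unpaired occlusal minimum at slice {a}; dropped")
            continue
        j = int(np.argmin(np.abs(np.asarray(available) - a)))
        b = available[j]
        if abs(b - a) <= params.pairing_window:
            pairs.append((int(a), int(b)))
            available.pop(j)
        else:
            warnings.warn(f"unpaired occlusal minimum at slice {a}; dropped")
    for b in available:
        warnings.warn(f"unpaired gingival minimum at slice {b}; dropped")
    pairs.sort(key=lambda ab: ab[0])
    return pairs


# ---------------------------------------------------------------------------
# site construction
# ---------------------------------------------------------------------------

def _rect_edge_3d(profile: SliceProfile, rect: Rect2D, edge: str, box: OrientedBox):
    """A horizontal rectangle edge embedded in the slice plane, as (2, 3)."""
    v = rect.vmax if edge == "top" else rect.vmin
    p = profile.plane.point
    a = p + rect.umin * box.axis_lb + v * box.axis_og
    b = p + rect.umax * box.axis_lb + v * box.axis_og
    return np.vstack([a, b])


def build_connector_site(
    mesh: TriangleMesh,
    profiles: list[SliceProfile],
    pair,
    box: OrientedBox,
    ordinal: int = 0,
) -> ConnectorSite:
    """Assemble a :class:`ConnectorSite` from a paired (α, β) minimum.

    ``L_o`` is the occlusal (top) edge of the occlusal rectangle at α, ``L_g``
    the gingival (bottom) edge of the gingival rectangle at β.  The connector
    plane contains both edges (they are parallel, both along the
    lingual–buccal axis); if they are collinear the plane falls back to the
    slice plane at α.  The local frame and the initial section follow.
    """
    alpha, beta = pair
    p_a, p_b = profiles[alpha], profiles[beta]
    if p_a.rect_occ is None or p_b.rect_gin is None:
        raise DetectionError("empty slice at a connector minimum")
    l_o = _rect_edge_3d(p_a, p_a.rect_occ, "top", box)
    l_g = _rect_edge_3d(p_b, p_b.rect_gin, "bottom", box)

    c_o = l_o.mean(axis=0)
    c_g = l_g.mean(axis=0)
    dvec = c_g - c_o
    n = np.cross(box.axis_lb, dvec)
    if np.linalg.norm(n) < 1e-9:
        warnings.warn(
            "L_o and L_g are collinear; falling back to the slice plane at α"
        )
        normal = p_a.plane.normal
    else:
        normal = unit(n)
    axis = mid_axis(box)
    if normal @ axis.direction < 0:
        normal = -normal
    e_midcon = Plane(c_o, normal)

    origin = plane_intersection_3(box.e_mid, box.e_mid2, e_midcon)
    # intersection of L_o with e_mid2 (L_o runs along axis_lb)
    t = (box.center - c_o) @ box.axis_lb
    q = c_o + t * box.axis_lb
    x_axis = unit(q - origin)
    y_axis = box.axis_lb
    z_axis = np.cross(x_axis, y_axis)
    frame = LocalFrame(origin=origin, x_axis=x_axis, y_axis=y_axis, z_axis=z_axis)

    site = ConnectorSite(
        ordinal=ordinal,
        alpha=int(alpha),
        beta=int(beta),
        l_o=l_o,
        l_g=l_g,
        e_midcon=e_midcon,
        frame=frame,
        a0=0.0,
        section_loop=None,
        station=float((origin - axis.start) @ axis.direction),
    )
    loops = cross_section.intersect_plane(
        mesh, Plane(origin, e_midcon.normal), axis_u=y_axis, axis_v=x_axis
    )
    loop = cross_section.select_connector_loop(loops, site)
    site.section_loop = loop
    site.a0 = cross_section.polygon_area(loop)
    if site.a0 <= 0:
        raise DetectionError("connector section has zero area")
    return site


def detect_connectors(
    mesh: TriangleMesh,
    hints: OrientationHints | None = None,
    params: DetectionParams | None = None,
):
    """Full detection pipeline: box → slices → minima → sites.

    Returns ``(box, profiles, sites)`` with sites ordered distal→mesial.
    """
    params = params or DetectionParams()
    box = fit_oriented_box(mesh, hints)
    profiles = slice_profiles(mesh, box, n_planes=params.n_planes)
    pairs = find_connector_minima(profiles, params)
    sites = [
        build_connector_site(mesh, profiles, pair, box, ordinal=j)
        for j, pair in enumerate(pairs)
    ]
    return box, profiles, sites
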