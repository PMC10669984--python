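"""Area-constrained connector remodelling.

A detected connector is shrunk toward a target cross-sectional area by moving
the mesh vertices near the connector plane.  In the connector's local frame
(x̂ occlusal, ŷ buccal, ẑ completing the right-handed frame; the connector
plane is the x–y plane) the occlusal-direction law displaces every selected
vertex with x > 0 to

    x_new = x − k · d_yz · B(d_xy) · x

where ``d_yz = |x|`` is the distance to the y–z plane, ``d_xy = |z|`` the
distance to the connector plane, ``k`` the shrink parameter, and ``B`` a
cubic Bézier-type falloff

    B(t) = (w−t)³·w + 3t(w−t)²·0.9w + 3t²(w−t)·0.1w,

i.e. w⁴ times the cubic Bernstein combination with control values
(1, 0.9, 0.1, 0) at s = t/w: full effect on the connector plane, smoothly
fading to zero at distance w (only vertices with d_xy < w are selected, so
the deformation is C⁰-continuous at the selection boundary).  The gingival,
lingual and buccal laws are the sign/axis mirrors; "iso" applies all four
with one shared k.

Because the displaced coordinate is scaled by the strictly-decreasing factor
(1 − k·d_yz·B), the section area at the connector plane is monotone
non-increasing in k, and k is solved by deterministic bisection until the
measured area matches the requested one within ±0.001 mm² (default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import cross_section
from .errors import InputError, ParameterError, SolverError
from .geometry import Plane
from .mesh_io import TriangleMesh

logger = logging.getLogger(__name__)

DIRECTIONS = ("occlusal", "gingival", "lingual", "buccal", "iso")

__all__ = [
    "DIRECTIONS",
    "AdjustmentSpec",
    "ConnectorPointSet",
    "AdjustmentResult",
    "bezier_weight",
    "select_points",
    "max_safe_k",
    "apply_displacement",
    "solve_k",
    "adjust_connector",
]


@dataclass(frozen=True)
class AdjustmentSpec:
    """What to do to one connector.

    Exactly one of ``target_area`` (absolute, mm²) or ``reduction`` (fraction
    of the initial area, e.g. 0.1 for a 10% reduction) must be given; a
    fraction is resolved to an absolute area once, against the site's A0.
    """

    site_ordinal: int
    direction: str
    target_area: float | None = None
    reduction: float | None = None
    w: float = 1.0
    tolerance: float = 1e-3
    k_bounds: tuple | None = None

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ParameterError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )
        if (self.target_area is None) == (self.reduction is None):
            raise ParameterError("give exactly one of target_area or reduction")
        if self.reduction is not None and not (0.0 < self.reduction < 1.0):
            raise ParameterError("reduction must be in (0, 1)")
        if self.w <= 0:
            raise ParameterError("falloff width w must be positive")
        if self.tolerance <= 0:
            raise ParameterError("area tolerance must be positive")

    def resolve_target(self, a0: float) -> float:
        target = (
            self.target_area
            if self.target_area is not None
            else (1.0 - self.reduction) * a0
        )
        if not (0.0 < target <= a0):
            raise ParameterError(
                f"target area {target:.4f} mm² must lie in (0, A0={a0:.4f}]"
            )
        return float(target)


@dataclass
class ConnectorPointSet:
    """Vertices within the falloff band of a connector, in local coordinates.

    ``indices`` are mesh vertex indices with unsigned distance to the
    connector plane d_i < w (strict); ``local`` holds their (x, y, z) frame
    coordinates.  Directional subsets partition by coordinate sign; ``d_xy``
    and ``d_yz`` are the distances to the x–y and y–z planes.
    """

    indices: np.ndarray
    local: np.ndarray  # (n, 3)
    w: float

    @property
    def x(self):
        return self.local[:, 0]

    @property
    def y(self):
        return self.local[:, 1]

    @property
    def z(self):
        return self.local[:, 2]

    @property
    def d_xy(self):
        return np.abs(self.local[:, 2])

    @property
    def d_yz(self):
        return np.abs(self.local[:, 0])

    @property
    def d_xz(self):
        return np.abs(self.local[:, 1])

    def subset(self, name: str) -> np.ndarray:
        """Boolean mask of the directional subset P_i-<name>."""
        return {
            "occlusal": self.x > 0,
            "gingival": self.x < 0,
            "buccal": self.y > 0,
            "lingual": self.y < 0,
        }[name]


@dataclass(frozen=True)
class AdjustmentResult:
    """Outcome of the area-matching search for one connector."""

    k: float
    a_initial: float
    a_final: float
    iterations: int
    achieved: float  # |a_final - target|
    displaced_count: int


def bezier_weight(t, w: float):
    """Cubic Bézier-type falloff B(t) on [0, w]; scale w⁴ at t = 0, zero at w.

    Values outside [0, w] are clamped to the endpoint values (the selection
    step guarantees t < w in normal operation).
    """
    if w <= 0:
        raise ParameterError("w must be positive")
    t = np.asarray(t, dtype=float)
    clipped = np.clip(t, 0.0, w)
    if np.any(t != clipped):
        logger.debug("bezier_weight: argument outside [0, w] clamped")
    t = clipped
    r = w - t
    out = r**3 * w + 3.0 * t * r**2 * 0.9 * w + 3.0 * t**2 * r * 0.1 * w
    return out if out.ndim else float(out)


def select_points(mesh: TriangleMesh, site, w: float) -> ConnectorPointSet:
    """All mesh vertices strictly closer than ``w`` to the connector plane."""
    if w <= 0:
        raise ParameterError("w must be positive")
    local = site.frame.to_local(mesh.vertices)
    mask = np.abs(local[:, 2]) < w
    if not mask.any():
        raise InputError(
            "no vertices within the falloff band; w too small for this mesh"
        )
    return ConnectorPointSet(
        indices=np.flatnonzero(mask), local=local[mask], w=w
    )


def _active_factors(points: ConnectorPointSet, direction: str):
    """(mask, coord, d·B) products for every sub-law of ``direction``."""
    b = bezier_weight(points.d_xy, points.w)
    laws = []
    if direction in ("occlusal", "iso"):
        laws.append(("x", points.subset("occlusal"), points.d_yz * b))
    if direction in ("gingival", "iso"):
        laws.append(("x", points.subset("gingival"), points.d_yz * b))
    if direction in ("buccal", "iso"):
        laws.append(("y", points.subset("buccal"), points.d_xz * b))
    if direction in ("lingual", "iso"):
        laws.append(("y", points.subset("lingual"), points.d_xz * b))
    return laws


def max_safe_k(points: ConnectorPointSet, direction: str) -> float:
    """Largest k for which the displacement map stays fold-over free.

    Along a line of constant (y, z) the occlusal law is x ↦ x − k·x²·B, whose
    derivative 1 − 2k·x·B must stay positive for the map to remain injective
    (merely keeping the shrink factor 1 − k·x·B positive is not enough: two
    vertices can still swap order and invert the surface).  We return 0.99 ×
    the injectivity limit, minimized over all selected vertices of every
    active sub-law.
    """
    if direction not in DIRECTIONS:
        raise ParameterError(f"unknown direction {direction!r}")
    denom = []
    for _, mask, factor in _active_factors(points, direction):
        f = factor[mask]
        denom.append(f[f > 0])
    denom = np.concatenate(denom) if denom else np.array([])
    if len(denom) == 0:
        raise InputError("no displaceable vertices for this direction")
    return float(0.99 / (2.0 * denom.max()))


def apply_displacement(
    points: ConnectorPointSet, k: float, w: float, direction: str
) -> np.ndarray:
    """Displaced local coordinates for the given direction and parameter k.

    Returns a new (n, 3) array; coordinates not governed by the direction's
    law are bit-identical to the input.  ``w`` must match the selection width
    (kept as an explicit argument because B's domain is [0, w]).
    """
    if direction not in DIRECTIONS:
        raise ParameterError(f"unknown direction {direction!r}")
    if k < 0:
        raise ParameterError("k must be non-negative")
    if w != points.w:
        raise ParameterError("w must match the selection width")
    if k > 0 and k > max_safe_k(points, direction):
        raise ParameterError(
            "k exceeds the fold-over limit for this point set"
        )
    out = points.local.copy()
    if k == 0:
        return out
    col = {"x": 0, "y": 1}
    for coord, mask, factor in _active_factors(points, direction):
        c = col[coord]
        out[mask, c] = points.local[mask, c] * (1.0 - k * factor[mask])
    return out


def _measure_area(mesh, site, vertices):
    """Section area of a displaced vertex set at the original connector plane."""
    moved = mesh.with_vertices(vertices, provenance=mesh.provenance)
    plane = Plane(site.frame.origin, site.e_midcon.normal)
    loops = cross_section.intersect_plane(
        moved, plane, axis_u=site.frame.y_axis, axis_v=site.frame.x_axis
    )
    loop = cross_section.select_connector_loop(loops, site)
    return cross_section.polygon_area(loop, validate=False)


def solve_k(mesh: TriangleMesh, site, spec: AdjustmentSpec):
    """Find k so the connector section area matches the target within tolerance.

    Bracketed bisection on the monotone map k ↦ area(k), measured by
    re-slicing the displaced mesh at the site's *original* connector plane
    (the post-deformation minimum section may migrate; it is not re-detected).
    Terminates when |A₂ − A_input| ≤ tolerance; deterministic.

    Returns ``(result, vertices)`` where ``vertices`` is the full displaced
    vertex array realizing ``result.k``.
    """
    points = select_points(mesh, site, spec.w)
    a0 = _measure_area(mesh, site, mesh.vertices)
    target = spec.resolve_target(a0)

    def vertices_at(k):
        v = mesh.vertices.copy()
        v[points.indices] = site.frame.to_world(
            apply_displacement(points, k, spec.w, spec.direction)
        )
        return v

    if abs(a0 - target) <= spec.tolerance:
        return (
            AdjustmentResult(0.0, a0, a0, 0, abs(a0 - target), 0),
            mesh.vertices.copy(),
        )

    lo, hi = 0.0, max_safe_k(points, spec.direction)
    if spec.k_bounds is not None:
        lo = max(lo, float(spec.k_bounds[0]))
        hi = min(hi, float(spec.k_bounds[1]))
    v_hi = vertices_at(hi)
    try:
        a_hi = _measure_area(mesh, site, v_hi)
    except InputError as exc:
        raise SolverError(
            "connector section vanished at the fold-over limit"
        ) from exc
    if a_hi > a0 + spec.tolerance:
        raise SolverError("section area is not monotone in k on this mesh")
    if a_hi > target + spec.tolerance:
        raise SolverError(
            f"target {target:.4f} mm² unreachable: minimum achievable area "
            f"is {a_hi:.4f} mm² at k = {hi:.6g}"
        )

    a_lo = a0
    for iteration in range(1, 201):
        mid = 0.5 * (lo + hi)
        v_mid = vertices_at(mid)
        a_mid = _measure_area(mesh, site, v_mid)
        if abs(a_mid - target) <= spec.tolerance:
            n_moved = int(np.count_nonzero(
                np.any(v_mid[points.indices] != mesh.vertices[points.indices], axis=1)
            ))
            result = AdjustmentResult(
                k=float(mid),
                a_initial=float(a0),
                a_final=float(a_mid),
                iterations=iteration,
                achieved=float(abs(a_mid - target)),
                displaced_count=n_moved,
            )
            return result, v_mid
        if a_mid > target:
            lo, a_lo = mid, a_mid
        else:
            hi, a_hi = mid, a_mid
        if hi - lo < 1e-15 * max(hi, 1.0):
            break
    raise SolverError(
        "bisection failed to meet the area tolerance "
        f"(last bracket areas {a_lo:.6f}..{a_hi:.6f} mm²)"
    )


def adjust_connector(mesh: TriangleMesh, site, spec: AdjustmentSpec):
    """Solve k and return ``(adjusted_mesh, result)``.

    The adjusted mesh shares the face list with the input (only vertices
    move); the input mesh is left unmodified.
    """
    result, vertices = solve_k(mesh, site, spec)
    return mesh.with_vertices(vertices, provenance="adjusted"), result
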