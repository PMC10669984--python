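"""Parametric synthetic FPD-like meshes with known connector ground truth.

Scanned prosthesis geometries are rarely redistributable, so every stage of
the pipeline is exercised on generated stand-ins: an n-unit bridge built as a
smooth-minimum union of superellipsoid "crowns" bridged by superelliptic
"necks", extracted as a watertight triangle surface by marching cubes.  The
neck cross-sections are irregular ovals (superellipses) whose exponent is
solved so the construction area matches a requested target; after meshing the
neck dimensions are re-calibrated once or twice by direct slicing so the
blended surface's minimum section stays close to the construction target.

Default dimensions emulate a 4-unit posterior bridge: overall extents
32.5 × 11.7 × 9.0 mm with three connector necks of 33.1 / 28.5 / 33.2 mm²
(heights 5.7 / 5.7 / 5.8 mm, lengths 6.8 / 6.0 / 6.8 mm), listed
distal→mesial.  Axis convention of the generated geometry: +x distal,
+y buccal, +z occlusal (matching the default orientation hints).
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.special import gamma as _gamma, logsumexp
from skimage import measure as _skmeasure

from . import cross_section
from .errors import InputError, ParameterError
from .geometry import Plane
from .mesh_io import TriangleMesh

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "NeckTruth",
    "generate_fpd",
    "generate_dumbbell",
    "generate_cylinder",
]

# default 4-unit connector dimensions, distal→mesial
_DEFAULT_NECK_HEIGHTS = (5.7, 5.7, 5.8)
_DEFAULT_NECK_LENGTHS = (6.8, 6.0, 6.8)
_DEFAULT_NECK_AREAS = (33.1, 28.5, 33.2)


def _superellipse_fill(p: float) -> float:
    """Area of the superellipse |u|^p + |v|^p <= 1 inscribed in the unit
    square [-1, 1]², as a fraction of the square's area (π/4 at p = 2 → 1)."""
    return float(_gamma(1 + 1 / p) ** 2 / _gamma(1 + 2 / p))


def _superellipse_exponent(height: float, length: float, area: float) -> float:
    """Exponent p so the superellipse with the given extents has the area."""
    frac = area / (height * length)
    if not (np.pi / 4 - 1e-9 < frac < 0.999):
        raise ParameterError(
            f"neck area {area} incompatible with extents {height}x{length}: "
            f"fill fraction {frac:.3f} outside (π/4, 1)"
        )
    return float(brentq(lambda p: _superellipse_fill(p) - frac, 1.999, 60.0,
                        xtol=1e-10))


@dataclass(frozen=True)
class NeckTruth:
    """Construction parameters of one connector neck (approximate on the
    blended surface)."""

    ordinal: int  # 0-based distal→mesial
    station_x: float  # x coordinate of the neck plane, mm
    height: float
    length: float
    area: float


@dataclass(frozen=True)
class GroundTruth:
    """Sidecar truth emitted with every generated mesh."""

    necks: tuple
    symmetry_planes: tuple = ("y=0", "z=0")

    def to_json(self) -> str:
        return json.dumps(
            {
                "necks": [vars(n) for n in self.necks],
                "symmetry_planes": list(self.symmetry_planes),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            necks=tuple(NeckTruth(**n) for n in obj["necks"]),
            symmetry_planes=tuple(obj["symmetry_planes"]),
        )


@dataclass
class SyntheticSpec:
    """Generator parameters for an n-unit synthetic bridge.

    ``None`` per-connector fields are derived: neck stations at the gap
    centers between adjacent crowns; for n = 4 the neck dimensions default to
    the values above, otherwise they scale with the overall width and height.
    """

    n_units: int = 4
    length: float = 32.5
    width: float = 11.7
    height: float = 9.0
    crown_exponent: float = 4.0
    crown_length_frac: float = 0.8  # crown x-half-length / (unit half-span)
    neck_stations: tuple | None = None  # x coordinates, distal→mesial
    neck_heights: tuple | None = None
    neck_lengths: tuple | None = None
    neck_areas: tuple | None = None
    neck_half_span: float | None = None  # x half-extent of each neck piece
    blend_sharpness: float = 4.0  # mm^-1, smooth-min sharpness
    pitch: float = 0.15  # marching-cubes voxel size, mm
    jitter: float = 0.0  # white vertex jitter amplitude along normals, mm
    seed: int = 42
    calibrate: bool = True

    def __post_init__(self):
        if self.n_units < 2:
            raise ParameterError("need at least 2 units")
        m = self.n_units - 1
        if self.neck_stations is None:
            # +x is distal: gap centers between adjacent crowns, distal→mesial
            centers = self.crown_centers()
            self.neck_stations = tuple(
                (centers[i] + centers[i + 1]) / 2.0
                for i in reversed(range(m))
            )
        if self.neck_heights is None:
            self.neck_heights = (
                _DEFAULT_NECK_HEIGHTS
                if self.n_units == 4
                else tuple([0.63 * self.height] * m)
            )
        if self.neck_lengths is None:
            self.neck_lengths = (
                _DEFAULT_NECK_LENGTHS
                if self.n_units == 4
                else tuple([0.52 * self.width] * m)
            )
        if self.neck_areas is None:
            if self.n_units == 4 and self.neck_heights == _DEFAULT_NECK_HEIGHTS:
                self.neck_areas = _DEFAULT_NECK_AREAS
            else:
                self.neck_areas = tuple(
                    0.85 * h * l
                    for h, l in zip(self.neck_heights, self.neck_lengths)
                )
        if self.neck_half_span is None:
            self.neck_half_span = 0.45 * self.length / self.n_units
        for name in ("neck_stations", "neck_heights", "neck_lengths", "neck_areas"):
            if len(getattr(self, name)) != m:
                raise ParameterError(f"{name} must have {m} entries")
        stations_mesial_up = self.neck_stations[::-1]
        if not np.all(np.diff(stations_mesial_up) > 0):
            raise ParameterError("neck stations must be strictly ordered")
        min_dim = min(min(self.neck_heights), min(self.neck_lengths))
        if self.pitch >= min_dim / 6:
            raise ParameterError(
                f"pitch {self.pitch} too coarse for neck dimension {min_dim}"
            )

    def crown_half_length(self) -> float:
        return self.crown_length_frac * self.length / (2 * self.n_units)

    def crown_centers(self) -> list:
        """Crown center x-coordinates, mesial→distal (increasing x); the two
        end crowns are pushed outward so their tips reach the full length."""
        a = self.crown_half_length()
        centers = [
            -self.length / 2 + (i + 0.5) * self.length / self.n_units
            for i in range(self.n_units)
        ]
        centers[0] = -self.length / 2 + a
        centers[-1] = self.length / 2 - a
        return centers


# ---------------------------------------------------------------------------
# implicit fields
# ---------------------------------------------------------------------------

def _superellipsoid_pseudodist(x, y, z, cx, a, b, c, p):
    rho = (
        np.abs((x - cx) / a) ** p + np.abs(y / b) ** p + np.abs(z / c) ** p
    ) ** (1.0 / p)
    return (rho - 1.0) * min(a, b, c)


def _neck_pseudodist(x, y, z, sx, half_h, half_l, p, half_span):
    rho = (np.abs(y / half_l) ** p + np.abs(z / half_h) ** p) ** (1.0 / p)
    d2d = (rho - 1.0) * min(half_h, half_l)
    dx = np.abs(x - sx) - half_span
    return np.maximum(d2d, dx)


def _march(field_fn, bounds_lo, bounds_hi, pitch: float) -> TriangleMesh:
    lo = np.asarray(bounds_lo, float) - 4 * pitch
    hi = np.asarray(bounds_hi, float) + 4 * pitch
    axes = [np.arange(lo[i], hi[i] + pitch, pitch) for i in range(3)]
    if min(len(a) for a in axes) < 8:
        raise ParameterError("pitch too coarse for the requested geometry")
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    vol = field_fn(gx, gy, gz)
    if vol.min() > 0 or vol.max() < 0:
        raise InputError("implicit field has no zero crossing on the grid")
    verts, faces, _, _ = _skmeasure.marching_cubes(
        vol, level=0.0, spacing=(pitch, pitch, pitch)
    )
    verts = verts + lo
    return TriangleMesh.from_arrays(verts, faces, provenance="original")


def _apply_jitter(mesh: TriangleMesh, amplitude: float, seed: int) -> TriangleMesh:
    if amplitude == 0:
        return mesh
    rng = np.random.default_rng(seed)
    tm = mesh.as_trimesh()
    normals = np.asarray(tm.vertex_normals)
    offsets = amplitude * rng.standard_normal(mesh.n_vertices)
    return mesh.with_vertices(
        mesh.vertices + offsets[:, None] * normals, provenance="original"
    )


def _measure_neck_area(mesh: TriangleMesh, station_x: float) -> float:
    plane = Plane(np.array([station_x, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    loops = cross_section.intersect_plane(mesh, plane)
    if not loops:
        raise InputError(f"no section at neck station x={station_x}")
    d = [np.linalg.norm(lp.centroid_3d() - plane.point) for lp in loops]
    return cross_section.polygon_area(loops[int(np.argmin(d))], validate=False)


def generate_fpd(spec: SyntheticSpec | None = None):
    """Generate a synthetic n-unit bridge mesh and its ground truth.

    Deterministic for a fixed spec and seed; jitter 0 (default) is
    bit-reproducible.  Returns ``(mesh, ground_truth)``.
    """
    spec = spec or SyntheticSpec()
    n = spec.n_units
    # crowns are shorter than their unit span (the necks bridge the gaps, so
    # they govern the waist); see SyntheticSpec.crown_centers
    crown_a = spec.crown_half_length()
    crown_centers = spec.crown_centers()
    heights = list(spec.neck_heights)
    lengths = list(spec.neck_lengths)
    exps = [
        _superellipse_exponent(h, l, a)
        for h, l, a in zip(heights, lengths, spec.neck_areas)
    ]

    def build(hs, ls):
        def field(x, y, z):
            parts = [
                _superellipsoid_pseudodist(
                    x, y, z, cx, crown_a, spec.width / 2, spec.height / 2,
                    spec.crown_exponent,
                )
                for cx in crown_centers
            ]
            parts += [
                _neck_pseudodist(
                    x, y, z, sx, h / 2, l / 2, p, spec.neck_half_span
                )
                for sx, h, l, p in zip(spec.neck_stations, hs, ls, exps)
            ]
            stack = np.stack(parts, axis=0)
            return -logsumexp(
                -spec.blend_sharpness * stack, axis=0
            ) / spec.blend_sharpness

        lo = (-spec.length / 2, -spec.width / 2, -spec.height / 2)
        hi = (spec.length / 2, spec.width / 2, spec.height / 2)
        return _march(field, lo, hi, spec.pitch)

    mesh = build(heights, lengths)
    if spec.calibrate:
        for _ in range(3):
            scale_needed = False
            for j, (sx, target) in enumerate(
                zip(spec.neck_stations, spec.neck_areas)
            ):
                measured = _measure_neck_area(mesh, sx)
                if abs(measured - target) / target > 0.02:
                    s = float(np.sqrt(target / measured))
                    heights[j] *= s
                    lengths[j] *= s
                    scale_needed = True
            if not scale_needed:
                break
            mesh = build(heights, lengths)

    mesh = _apply_jitter(mesh, spec.jitter, spec.seed)
    truth = GroundTruth(
        necks=tuple(
            NeckTruth(
                ordinal=j,
                station_x=float(spec.neck_stations[j]),
                height=float(spec.neck_heights[j]),
                length=float(spec.neck_lengths[j]),
                area=float(spec.neck_areas[j]),
            )
            for j in range(n - 1)
        )
    )
    return mesh, truth


def generate_dumbbell(
    radius: float = 5.0,
    neck_radius: float = 2.0,
    length: float = 24.0,
    pitch: float = 0.2,
):
    """Two spheres joined by a circular neck: the minimal detection fixture.

    A sharp (non-blended) union keeps the neck section exactly circular, so
    the single connector at mid-station has area π·neck_radius².
    """
    if neck_radius > radius:
        raise ParameterError("neck_radius must not exceed radius")
    if length < 4 * radius:
        raise ParameterError("length must be at least 4x radius")
    half = length / 2 - radius  # sphere centers at ±half

    def field(x, y, z):
        s1 = np.sqrt((x - half) ** 2 + y**2 + z**2) - radius
        s2 = np.sqrt((x + half) ** 2 + y**2 + z**2) - radius
        neck = np.maximum(
            np.sqrt(y**2 + z**2) - neck_radius, np.abs(x) - half
        )
        return np.minimum(np.minimum(s1, s2), neck)

    mesh = _march(
        field,
        (-length / 2, -radius, -radius),
        (length / 2, radius, radius),
        pitch,
    )
    truth = GroundTruth(
        necks=(
            NeckTruth(
                ordinal=0,
                station_x=0.0,
                height=2 * neck_radius,
                length=2 * neck_radius,
                area=float(np.pi * neck_radius**2),
            ),
        )
    )
    return mesh, truth


def generate_cylinder(
    radius: float = 2.0, length: float = 20.0, pitch: float = 0.2
) -> TriangleMesh:
    """Capped cylinder along x: the null fixture with no connectors."""
    if radius <= 0 or length <= 0 or pitch <= 0:
        raise ParameterError("radius, length and pitch must be positive")
    sections = max(32, int(np.ceil(2 * np.pi * radius / pitch)))
    tm = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
    rot = trimesh.transformations.rotation_matrix(np.pi / 2, [0, 1, 0])
    tm.apply_transform(rot)
    return TriangleMesh.from_arrays(tm.vertices, tm.faces, provenance="original")
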