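"""Small geometric primitives shared across the package.

Planes are stored as (point, unit normal); signed distance is positive on the
normal side.  All frames in the package are right-handed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["Plane", "unit", "plane_intersection_3", "rotation_about_axis"]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalized to unit length; raise on (near-)zero vectors."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ParameterError("cannot normalize a zero-length vector")
    return v / n


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", unit(self.normal))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of ``points`` (N,3 or 3,) to the plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        return d if np.ndim(points) > 1 else d[0]

    def contains(self, points: np.ndarray, tol: float = 1e-6) -> bool:
        return bool(np.all(np.abs(self.signed_distance(np.atleast_2d(points))) <= tol))


def plane_intersection_3(p1: Plane, p2: Plane, p3: Plane) -> np.ndarray:
    """Intersection point of three pairwise non-parallel planes."""
    a = np.vstack([p1.normal, p2.normal, p3.normal])
    b = np.array(
        [p1.normal @ p1.point, p2.normal @ p2.point, p3.normal @ p3.point]
    )
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate config
        raise ParameterError("planes do not intersect in a single point") from exc


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix for a rotation of ``angle_rad`` about ``axis``."""
    k = unit(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * kx + (1 - np.cos(angle_rad)) * kx @ kx
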