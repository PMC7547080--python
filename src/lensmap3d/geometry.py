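"""Lens geometry: equatorial frame fitting and spherical mapping.

Three user-picked landmark points at the GZ/MR boundary define a
near-equatorial circle; the ray from its centre along the plane normal,
extended toward the data-populated hemisphere, meets the epithelium at
the anterior pole (AP).  The point cloud is then rigidly realigned so
the lens axis is +z with the AP on top, and every nucleus receives
spherical angle coordinates (theta from the AP axis, so the equator is
at 90 deg; phi measured from the first landmark).

Because the landmark ring generally sits somewhat below the true
equator, the frame is by default *refined* by fitting an axis-aligned
spheroid to the whole aligned cloud: the landmark normal fixes the axis
direction, while the fit recovers the true centre and the equatorial
radius R_max.  Without refinement the construction is the bare
three-point one (circle radius = R_max, circle centre = lens centre).

Before angle assignment each point is affinely normalized
``(x/R_max, y/R_max, z/R_min)`` onto the unit sphere, which makes theta
well defined on lentoid (non-spherical) lenses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateLandmarksError",
    "AmbiguousOrientationError",
    "NoPoleFoundError",
    "LensFrame",
    "fit_circle_3pt",
    "orient_normal",
    "find_anterior_pole",
    "fit_spheroid",
    "rotation_to_z",
    "build_frame",
    "align_to_canonical",
    "spherical_coordinates",
    "lens_metrics",
    "angle_between_deg",
]


class DegenerateLandmarksError(ValueError):
    """Landmark points are collinear or coincident."""


class AmbiguousOrientationError(ValueError):
    """The point cloud is exactly balanced across the landmark plane."""


class NoPoleFoundError(ValueError):
    """No nucleus lies close enough to the polar ray."""


def fit_circle_3pt(p1, p2, p3):
    """Circumscribed circle of three non-collinear 3D points.

    Returns ``(center, radius, normal)``; the normal's sign is
    arbitrary until :func:`orient_normal` resolves it.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p2 - p1
    v2 = p3 - p1
    cr = np.cross(v1, v2)
    area2 = np.linalg.norm(cr)
    scale = max(np.linalg.norm(v1), np.linalg.norm(v2), 1e-300)
    if area2 < 1e-12 * scale**2:
        raise DegenerateLandmarksError(
            "landmark points are collinear or duplicated; cannot fit a circle"
        )
    n = cr / area2
    center = p1 + np.cross(
        np.dot(v1, v1) * v2 - np.dot(v2, v2) * v1, cr
    ) / (2.0 * area2**2)
    radius = float(np.linalg.norm(p1 - center))
    return center, radius, n


def orient_normal(points, center, normal) -> np.ndarray:
    """Point the plane normal toward the data-populated hemisphere.

    Flips the normal if fewer than half the points lie on its positive
    side; an exact balance is ambiguous and raises (better landmarks
    are needed).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    side = (pts - np.asarray(center, dtype=float)) @ n
    n_pos = int(np.sum(side > 0))
    n_neg = len(side) - n_pos
    if n_pos == n_neg:
        raise AmbiguousOrientationError(
            "point cloud is exactly balanced across the landmark plane"
        )
    return n if n_pos > n_neg else -n


def find_anterior_pole(points, center, normal, r_max, perp_tol_frac=0.05):
    """Anterior pole: the nucleus the polar ray meets.

    Among nuclei within a perpendicular distance
    ``perp_tol_frac * r_max`` of the ray ``{center + t * normal, t > 0}``,
    the one with minimal perpendicular distance is chosen (ties broken
    by larger t, i.e. the farther nucleus).

    Returns ``(ap, index)``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise NoPoleFoundError("empty point set")
    c = np.asarray(center, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    rel = pts - c
    t = rel @ n
    perp = np.linalg.norm(rel - np.outer(t, n), axis=1)
    ok = (t > 0) & (perp <= perp_tol_frac * r_max)
    if not ok.any():
        raise NoPoleFoundError(
            f"no nucleus within {perp_tol_frac:.3g} * R_max of the polar ray; "
            "check the landmark plane"
        )
    idx = np.flatnonzero(ok)
    pmin = perp[idx].min()
    near = idx[perp[idx] <= pmin + 1e-9]
    best = near[np.argmax(t[near])]
    return pts[best], int(best)


def fit_spheroid(points):
    """Algebraic least-squares fit of an axis-aligned spheroid.

    Fits ``(x-cx)^2/a^2 + (y-cy)^2/a^2 + (z-cz)^2/b^2 = 1`` to an
    ``(n, 3)`` cloud by the homogeneous linear system
    ``u (x^2+y^2) + p x + q y + v z^2 + w z + t = 0`` solved with SVD
    (exact for noise-free surface points, stable under rotation of the
    input into this frame).

    Returns ``(center, a, b)``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 6:
        raise ValueError("spheroid fit needs at least 6 points")
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    # column scaling for conditioning
    s = max(float(np.abs(pts).max()), 1e-300)
    xs, ys, zs = x / s, y / s, z / s
    M = np.column_stack(
        [xs**2 + ys**2, xs, ys, zs**2, zs, np.ones_like(xs)]
    )
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    u, p, q, v, w, t = vt[-1]
    if u * v <= 0:
        raise ValueError("degenerate spheroid fit (not an ellipsoid)")
    if u < 0:
        u, p, q, v, w, t = -u, -p, -q, -v, -w, -t
    cx = -p / (2 * u)
    cy = -q / (2 * u)
    cz = -w / (2 * v)
    k = u * (cx**2 + cy**2) + v * cz**2 - t
    if k <= 0:
        raise ValueError("degenerate spheroid fit (non-positive radius)")
    a = math.sqrt(k / u) * s
    b = math.sqrt(k / v) * s
    center = np.array([cx, cy, cz]) * s
    return center, a, b


def rotation_to_z(normal) -> np.ndarray:
    """Rotation matrix R with ``R @ n = +z`` (identity if already there),
    rotating about ``n x z`` by ``arccos(n . z)``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    c = float(n @ z)
    if s < 1e-15:
        if c > 0:
            return np.eye(3)
        return np.diag([1.0, -1.0, -1.0])  # pi about x
    axis = axis / s
    angle = math.atan2(s, c)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def angle_between_deg(u, v) -> float:
    """Numerically stable angle between two vectors, degrees."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return math.degrees(
        math.atan2(np.linalg.norm(np.cross(u, v)), float(u @ v))
    )


@dataclass
class LensFrame:
    """Fitted equatorial frame of a lens.

    ``rotation`` and ``center`` define the canonical transform
    ``p_canonical = rotation @ (p - center)`` taking the lens centre to
    the origin, the axis to +z (AP side positive) and the first landmark
    to phi = 0.  ``D`` holds the distances D1-D3 of the landmarks to the
    landmark-circle centre (equal to the circle radius by construction)
    and D4 = |AP - center| = R_min.
    """

    landmarks: np.ndarray
    circle_center: np.ndarray
    circle_radius: float
    normal: np.ndarray
    center: np.ndarray
    r_max: float
    r_min: float
    ap: np.ndarray
    rotation: np.ndarray
    refined: bool
    D: np.ndarray = field(default=None)

    @property
    def aspect_ratio(self) -> float:
        return self.r_min / self.r_max

    @property
    def hemisphere_volume(self) -> float:
        """(2/3) pi R_max^2 R_min, um^3."""
        return (2.0 / 3.0) * math.pi * self.r_max**2 * self.r_min

    @property
    def spheroid_volume(self) -> float:
        """Oblate-spheroid volume = twice the hemisphere volume."""
        return 2.0 * self.hemisphere_volume

    def to_dict(self) -> dict:
        return {
            "landmarks": self.landmarks.tolist(),
            "circle_center": self.circle_center.tolist(),
            "circle_radius": self.circle_radius,
            "normal": self.normal.tolist(),
            "center": self.center.tolist(),
            "r_max": self.r_max,
            "r_min": self.r_min,
            "aspect_ratio": self.aspect_ratio,
            "hemisphere_volume_um3": self.hemisphere_volume,
            "spheroid_volume_um3": self.spheroid_volume,
            "ap": self.ap.tolist(),
            "rotation": self.rotation.tolist(),
            "refined": self.refined,
            "D": self.D.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LensFrame":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            landmarks=np.asarray(d["landmarks"]),
            circle_center=np.asarray(d["circle_center"]),
            circle_radius=float(d["circle_radius"]),
            normal=np.asarray(d["normal"]),
            center=np.asarray(d["center"]),
            r_max=float(d["r_max"]),
            r_min=float(d["r_min"]),
            ap=np.asarray(d["ap"]),
            rotation=np.asarray(d["rotation"]),
            refined=bool(d["refined"]),
            D=np.asarray(d["D"]),
        )


def radial_distances(frame: LensFrame) -> tuple[float, float, float, float]:
    """(D1, D2, D3, D4): landmark and AP distances to the frame centres."""
    return tuple(frame.D)


def build_frame(
    points,
    landmarks,
    refine: bool = True,
    ap_tol_frac: float = 0.1,
) -> LensFrame:
    """Construct the full lens frame from nuclei and three landmarks.

    Steps: three-point circle fit, normal orientation toward the data,
    rotation of the cloud so the normal is +z, optional spheroid
    refinement of centre and radii, AP detection along the +z ray
    (R_min = |AP - centre|), and an in-plane rotation putting the first
    landmark at phi = 0.

    ``ap_tol_frac`` is the perpendicular gate of the AP search as a
    fraction of R_max; the default 0.1 suits this package's sparse
    synthetic clouds (a dense full-scale lens supports the tighter
    0.05 of :func:`find_anterior_pole`).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    lm = np.asarray(landmarks, dtype=float).reshape(3, 3)
    c0, r0, n_raw = fit_circle_3pt(*lm)
    n = orient_normal(pts, c0, n_raw)
    r0mat = rotation_to_z(n)
    local = (pts - c0) @ r0mat.T
    if refine and len(pts) >= 10:
        center_l, a, b = fit_spheroid(local)
        refined = True
    else:
        center_l = np.zeros(3)
        a = r0
        refined = False
    local2 = local - center_l
    ap_local, _ = find_anterior_pole(
        local2, np.zeros(3), np.array([0.0, 0.0, 1.0]), a, ap_tol_frac
    )
    r_min = float(np.linalg.norm(ap_local))
    lm_local = (lm[0] - c0) @ r0mat.T - center_l
    ang = math.atan2(lm_local[1], lm_local[0])
    ca, sa = math.cos(-ang), math.sin(-ang)
    rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rotation = rz @ r0mat
    center = c0 + r0mat.T @ center_l
    ap_global = center + rotation.T @ ap_local
    D = np.array(
        [
            np.linalg.norm(lm[0] - c0),
            np.linalg.norm(lm[1] - c0),
            np.linalg.norm(lm[2] - c0),
            r_min,
        ]
    )
    return LensFrame(
        landmarks=lm,
        circle_center=c0,
        circle_radius=r0,
        normal=n,
        center=center,
        r_max=float(a),
        r_min=r_min,
        ap=ap_global,
        rotation=rotation,
        refined=refined,
        D=D,
    )


def align_to_canonical(points, frame: LensFrame) -> np.ndarray:
    """Apply the frame's rigid transform: centre at origin, axis +z,
    first landmark at phi = 0.  Pairwise distances are preserved."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return (pts - frame.center) @ frame.rotation.T


def spherical_coordinates(points_canonical, r_max: float, r_min: float):
    """Spherical angles after affine normalization to the unit sphere.

    theta (deg, in [0, 180]) is the polar angle from +z (the AP axis:
    AP at 0, equator at 90); phi (deg, in [0, 360)) is atan2(y, x).
    A point at the origin has undefined angles and raises.
    """
    pts = np.asarray(points_canonical, dtype=float).reshape(-1, 3)
    nx = pts[:, 0] / r_max
    ny = pts[:, 1] / r_max
    nz = pts[:, 2] / r_min
    rho = np.hypot(nx, ny)
    if np.any((rho == 0) & (nz == 0)):
        raise ValueError("point at the lens centre has undefined angles")
    theta = np.degrees(np.arctan2(rho, nz))
    phi = np.degrees(np.arctan2(ny, nx)) % 360.0
    return theta, phi


def lens_metrics(frame: LensFrame) -> dict:
    """Shape metrics of a fitted frame (aspect ratio and volumes)."""
    if frame.r_max <= 0 or frame.r_min <= 0:
        raise ValueError("radii must be positive")
    return {
        "aspect_ratio": frame.aspect_ratio,
        "hemisphere_volume_um3": frame.hemisphere_volume,
        "spheroid_volume_um3": frame.spheroid_volume,
    }
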