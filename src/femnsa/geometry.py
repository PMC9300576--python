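"""Geometric primitives for neck-shaft-angle measurement.

Least-squares sphere fitting, RANSAC circle fitting with the standard
trial-count formula, plane construction and point-to-plane projection,
centroids, vector angles, and inverse-distance-weighted interpolation.
All lengths are in millimetres, angles in degrees unless stated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "FitFailureError",
    "Sphere",
    "Circle2D",
    "Plane",
    "Axis",
    "RansacConfig",
    "fit_sphere_lsq",
    "centroid",
    "plane_from_points",
    "project_point",
    "plane_basis",
    "to_plane_coords",
    "from_plane_coords",
    "ransac_trials",
    "circumcircle_2d",
    "fit_circle_lsq",
    "fit_circle_ransac",
    "angle_between",
    "line_closest_approach",
    "idw_interpolate",
]


class DegenerateGeometryError(ValueError):
    """Raised when the input geometry does not determine the model."""


class FitFailureError(RuntimeError):
    """Raised when a robust fit cannot reach consensus."""


@dataclass(frozen=True)
class Sphere:
    """A sphere: ``center`` (3,) in mm and ``radius`` in mm."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("sphere center must be a finite 3-vector")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError("sphere radius must be positive and finite")
        object.__setattr__(self, "center", c)


@dataclass(frozen=True)
class Circle2D:
    """A circle in plane coordinates: ``center`` (2,) and ``radius``, mm."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (2,) or not np.all(np.isfinite(c)):
            raise ValueError("circle center must be a finite 2-vector")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValueError("circle radius must be positive and finite")
        object.__setattr__(self, "center", c)


@dataclass(frozen=True)
class Plane:
    """Implicit plane A·x + B·y + C·z + D = 0 with unit normal (A, B, C)."""

    A: float
    B: float
    C: float
    D: float

    def __post_init__(self):
        n = np.array([self.A, self.B, self.C], dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-300 or not np.isfinite(self.D):
            raise ValueError("plane coefficients must be finite with nonzero normal")
        object.__setattr__(self, "A", float(n[0] / norm))
        object.__setattr__(self, "B", float(n[1] / norm))
        object.__setattr__(self, "C", float(n[2] / norm))
        object.__setattr__(self, "D", float(self.D / norm))

    @property
    def normal(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C])

    def signed_distance(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return p @ self.normal + self.D


@dataclass(frozen=True)
class Axis:
    """An oriented line: ``anchor`` point (mm) and unit ``direction``."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.anchor, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if a.shape != (3,) or not np.all(np.isfinite(a)):
            raise ValueError("axis anchor must be a finite 3-vector")
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n < 1e-12:
            raise ValueError("axis direction must be a nonzero vector")
        object.__setattr__(self, "anchor", a)
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class RansacConfig:
    """RANSAC settings for the head-circle fit.

    confidence
        Desired probability of drawing at least one all-inlier minimal
        sample (the P of the trial-count formula).
    inlier_ratio_floor
        Lower bound on the inlier fraction used when computing the
        adaptive trial count.
    sample_size
        Minimal-sample size; 3 points determine a circle.
    inlier_threshold
        Absolute point-to-circle distance (mm) below which a point counts
        as an inlier.  Default 1.0 mm, ~1.6x the 0.625 mm voxel pitch of
        typical hip CT.
    """

    confidence: float = 0.99
    inlier_ratio_floor: float = 0.2
    sample_size: int = 3
    inlier_threshold: float = 1.0
    max_trials: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if not 0 < self.inlier_ratio_floor < 1:
            raise ValueError("inlier_ratio_floor must be in (0, 1)")
        if self.sample_size < 3:
            raise ValueError("sample_size must be >= 3")
        if self.inlier_threshold <= 0:
            raise ValueError("inlier_threshold must be positive")
        if self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


def _as_points(points, dim=3, min_count=1, name="points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != dim:
        raise ValueError(f"{name} must be an (N, {dim}) array")
    if pts.shape[0] < min_count:
        raise ValueError(f"{name} needs at least {min_count} rows, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


def fit_sphere_lsq(points) -> Sphere:
    """Least-squares sphere fit via the 3x3 normal equations on
    mean-centered coordinates.

    With u_i = x_i - mean(x) (and likewise v, w), the center (u0, v0, w0)
    solves::

        [Suu Suv Suw] [u0]   [S(u^3 + u v^2 + u w^2) / 2]
        [Suv Svv Svw] [v0] = [S(u^2 v + v^3 + v w^2) / 2]
        [Suw Svw Sww] [w0]   [S(u^2 w + v^2 w + w^3) / 2]

    and the radius is the RMS distance of the points to the center.
    Requires >= 4 non-coplanar points.
    """
    pts = _as_points(points, min_count=4, name="sphere points")
    mean = pts.mean(axis=0)
    q = pts - mean
    M = q.T @ q
    # rhs: 0.5 * sum_i q_i * |q_i|^2
    rhs = 0.5 * (q * (q * q).sum(axis=1, keepdims=True)).sum(axis=0)
    if np.linalg.cond(M) > 1e12:
        raise DegenerateGeometryError(
            "sphere fit is ill-conditioned (points coplanar or degenerate)"
        )
    center_local = np.linalg.solve(M, rhs)
    center = center_local + mean
    radius = float(np.sqrt(np.mean(((pts - center) ** 2).sum(axis=1))))
    return Sphere(center=center, radius=radius)


def centroid(points) -> np.ndarray:
    """Component-wise arithmetic mean of a nonempty point set."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("centroid requires a nonempty (N, d) point array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("centroid input contains non-finite coordinates")
    return pts.mean(axis=0)


def plane_from_points(p1, p2, p3) -> Plane:
    """Plane through three non-collinear points, unit-normal form."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    e1 = p2 - p1
    e2 = p3 - p1
    n = np.cross(e1, e2)
    scale = np.linalg.norm(e1) * np.linalg.norm(e2)
    if scale == 0 or np.linalg.norm(n) <= 1e-9 * scale:
        raise DegenerateGeometryError("the three points are (nearly) collinear")
    n = n / np.linalg.norm(n)
    return Plane(A=n[0], B=n[1], C=n[2], D=-float(n @ p1))


def project_point(plane: Plane, p) -> np.ndarray:
    """Foot of the perpendicular from ``p`` (or an (N,3) stack) to the plane.

    Parametrically, p' = p - t n with t the signed distance
    (A x + B y + C z + D) / (A^2 + B^2 + C^2); the normal is unit so the
    denominator is 1.
    """
    p = np.asarray(p, dtype=float)
    t = plane.signed_distance(p)
    return p - np.multiply.outer(t, plane.normal) if p.ndim > 1 else p - t * plane.normal


def plane_basis(plane: Plane, origin) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (e1, e2).

    ``origin`` must lie on the plane (within 1e-6 mm).  e1 is built by
    crossing the normal with the coordinate axis of the normal's
    smallest-magnitude component, so the basis depends only on the plane.
    """
    origin = np.asarray(origin, dtype=float)
    if abs(float(plane.signed_distance(origin))) > 1e-6:
        raise ValueError("plane_basis origin must lie on the plane")
    n = plane.normal
    k = int(np.argmin(np.abs(n)))
    axis = np.zeros(3)
    axis[k] = 1.0
    e1 = np.cross(n, axis)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


def to_plane_coords(points3d, origin, e1, e2) -> np.ndarray:
    """Express points (already on the plane) in (e1, e2) coordinates."""
    q = np.asarray(points3d, dtype=float) - np.asarray(origin, dtype=float)
    return np.stack([q @ e1, q @ e2], axis=-1)


def from_plane_coords(points2d, origin, e1, e2) -> np.ndarray:
    """Map (e1, e2) plane coordinates back to 3D."""
    p = np.asarray(points2d, dtype=float)
    return np.asarray(origin, dtype=float) + np.multiply.outer(p[..., 0], e1) + np.multiply.outer(p[..., 1], e2)


def ransac_trials(confidence: float, inlier_ratio: float, sample_size: int) -> int:
    """Minimum number of RANSAC trials S = ceil(log(1-P) / log(1-rho^K)).

    P is the required confidence of drawing one uncontaminated minimal
    sample, rho the inlier fraction, K the minimal-sample size.  If every
    point is an inlier (rho^K == 1) a single trial suffices.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if not 0 < inlier_ratio <= 1:
        raise ValueError("inlier_ratio must be in (0, 1]")
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    good = inlier_ratio**sample_size
    if good >= 1.0:
        return 1
    return int(math.ceil(math.log(1.0 - confidence) / math.log(1.0 - good)))


def circumcircle_2d(p1, p2, p3) -> Circle2D:
    """Unique circle through three non-collinear 2D points."""
    (x1, y1), (x2, y2), (x3, y3) = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    scale = max(abs(x1) + abs(y1), abs(x2) + abs(y2), abs(x3) + abs(y3), 1.0)
    if abs(d) <= 1e-12 * scale**2:
        raise DegenerateGeometryError("circumcircle points are collinear")
    s1 = x1 * x1 + y1 * y1
    s2 = x2 * x2 + y2 * y2
    s3 = x3 * x3 + y3 * y3
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = math.hypot(x1 - ux, y1 - uy)
    return Circle2D(center=np.array([ux, uy]), radius=r)


def fit_circle_lsq(points2d) -> Circle2D:
    """Algebraic (Kasa) least-squares circle fit to 2D points."""
    pts = _as_points(points2d, dim=2, min_count=3, name="circle points")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateGeometryError("circle fit degenerate (collinear points)")
    return Circle2D(center=np.array([cx, cy]), radius=float(np.sqrt(r2)))


def fit_circle_ransac(points2d, config: RansacConfig | None = None) -> tuple[Circle2D, np.ndarray]:
    """Robust circle fit: minimal 3-point hypotheses scored by inlier count.

    Repeats (sample 3 points, circumscribe, count points with
    |distance to circle| <= inlier_threshold) for an adaptive number of
    trials: the trial budget starts from the formula evaluated at
    ``inlier_ratio_floor`` and shrinks as better consensus sets raise the
    observed inlier ratio, capped at ``max_trials``.  Ties on inlier count
    are broken by smaller mean inlier residual, then by earlier trial.
    The returned model is an algebraic least-squares refit on the best
    inlier set; the boolean mask marks the inliers of that final model.
    Fully reproducible from ``config.seed``.
    """
    if config is None:
        config = RansacConfig()
    pts = _as_points(points2d, dim=2, min_count=3, name="circle points")
    n = len(pts)
    rng = np.random.default_rng(config.seed)
    thr = config.inlier_threshold

    best_count = 0
    best_resid = np.inf
    best_mask = None
    trials_needed = min(
        config.max_trials,
        ransac_trials(config.confidence, config.inlier_ratio_floor, config.sample_size),
    )
    trial = 0
    while trial < trials_needed:
        trial += 1
        idx = rng.choice(n, size=3, replace=False)
        try:
            cand = circumcircle_2d(*pts[idx])
        except DegenerateGeometryError:
            continue
        resid = np.abs(np.linalg.norm(pts - cand.center, axis=1) - cand.radius)
        mask = resid <= thr
        count = int(mask.sum())
        if count < 3:
            continue
        mean_resid = float(resid[mask].mean())
        if count > best_count or (count == best_count and mean_resid < best_resid):
            best_count = count
            best_resid = mean_resid
            best_mask = mask
            ratio = max(count / n, config.inlier_ratio_floor)
            trials_needed = min(
                config.max_trials,
                max(trial, ransac_trials(config.confidence, ratio, config.sample_size)),
            )

    if best_mask is None or best_count < config.sample_size:
        raise FitFailureError("RANSAC found no circle with sufficient consensus")

    # local optimization: alternate least-squares refit and inlier
    # reselection, keeping the best consensus seen (count, then mean
    # residual), so the final model neither inherits an off-center
    # minimal-sample hypothesis nor slides into a worse local optimum
    mask = best_mask
    best_model = None
    best_score = (-1, np.inf)
    for _ in range(20):
        model = fit_circle_lsq(pts[mask])
        resid = np.abs(np.linalg.norm(pts - model.center, axis=1) - model.radius)
        new_mask = resid <= thr
        count = int(new_mask.sum())
        if count < config.sample_size:
            break
        score = (count, float(resid[new_mask].mean()))
        if score[0] > best_score[0] or (score[0] == best_score[0] and score[1] < best_score[1]):
            best_model, best_mask, best_score = model, new_mask, score
        else:
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    if best_model is None:
        best_model = fit_circle_lsq(pts[best_mask])
    return best_model, best_mask


def angle_between(u, v) -> float:
    """Angle in degrees between two direction vectors, in [0, 180].

    cos(theta) = u . v / (|u| |v|), clamped to [-1, 1] against rounding.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise ValueError("angle_between requires nonzero vectors")
    c = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def line_closest_approach(a: Axis, b: Axis) -> float:
    """Minimal distance (mm) between two lines; generally skew in 3D."""
    w = b.anchor - a.anchor
    n = np.cross(a.direction, b.direction)
    norm = np.linalg.norm(n)
    if norm < 1e-12:  # parallel lines
        return float(np.linalg.norm(w - (w @ a.direction) * a.direction))
    return float(abs(w @ n) / norm)


def idw_interpolate(query, neighbor_points, neighbor_values, power: float = 2.0, k: int = 3):
    """Inverse-distance-weighted interpolation over the k nearest neighbors.

    Weights are w_i = 1 / d(x, x_i)^power, normalized to sum to one.  If
    the query coincides with a neighbor (distance <= 1e-12 mm) that
    neighbor's value is returned exactly.  Used to propagate per-point
    labels or features from a sparse to a dense cloud.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = _as_points(neighbor_points, min_count=1, name="neighbors")
    vals = np.asarray(neighbor_values, dtype=float)
    if len(vals) != len(pts):
        raise ValueError("neighbor_points and neighbor_values length mismatch")
    q = np.asarray(query, dtype=float)
    d = np.linalg.norm(pts - q, axis=1)
    hit = np.nonzero(d <= 1e-12)[0]
    if hit.size:
        return vals[hit[0]]
    take = np.argsort(d, kind="stable")[: min(k, len(pts))]
    w = 1.0 / d[take] ** power
    w = w / w.sum()
    if vals.ndim == 1:
        return float(w @ vals[take])
    return w @ vals[take]
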