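"""Parametric proximal-femur point-cloud generator with analytic ground truth.

The generator emulates the surface clouds exported from CT
reconstruction: a spherical head, an obliquely oriented tapered neck,
and a long near-cylindrical shaft, ~2048 points in total, with surface
noise at the scale of the CT voxel pitch.  The true neck-shaft angle,
femoral anteversion and the closest-approach offset between the neck
and shaft axes are construction parameters, so every downstream
measurement can be scored against an exact reference.

Sampling is quasi-uniform by surface area: the shaft and neck are built
from rings of equally spaced azimuths (reconstructed meshes are
structured surfaces, not random samples), the head from a Fibonacci
sphere lattice.  Noise and outliers are the seeded stochastic component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Axis, angle_between
from .io import LABEL_HEAD, LABEL_NECK, LABEL_SHAFT, LabeledPointCloud

__all__ = ["FemurSpec", "GroundTruth", "FemurSpecError", "generate_femur", "sweep"]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


class FemurSpecError(ValueError):
    """The requested femur geometry is invalid or impossible."""


@dataclass(frozen=True)
class FemurSpec:
    """Construction parameters of one synthetic proximal femur.

    Angles in degrees, lengths in mm.  ``nsa_true`` is the angle between
    the neck axis (neck toward head) and the shaft axis (proximal toward
    distal); ``anteversion`` rotates the neck about the shaft axis (which
    preserves the NSA); ``axis_offset`` translates the neck axis along
    the common perpendicular so the two axes are skew with exactly this
    closest-approach distance.  Defaults describe a normal adult femur
    digitized at ~0.6 mm voxel pitch: noise_sigma is half the 0.625 mm
    voxel, n_points matches the 2048-point clouds the segmentation
    network consumes.
    """

    nsa_true: float = 127.0
    anteversion: float = 15.0
    axis_offset: float = 0.0
    head_radius: float = 22.0
    neck_length: float = 55.0
    neck_radius: float = 14.0
    shaft_length: float = 120.0
    shaft_radius: float = 14.0
    shaft_bow: float = 0.0
    noise_sigma: float = 0.3125
    outlier_fraction: float = 0.0
    n_points: int = 2048
    seed: int = 0

    def __post_init__(self):
        if not 90.0 < self.nsa_true < 180.0:
            raise FemurSpecError("nsa_true must lie in (90, 180) degrees")
        for name in ("head_radius", "neck_length", "neck_radius", "shaft_length", "shaft_radius"):
            if getattr(self, name) <= 0:
                raise FemurSpecError(f"{name} must be positive")
        if not 0.0 <= self.outlier_fraction < 0.5:
            raise FemurSpecError("outlier_fraction must be in [0, 0.5)")
        if self.n_points < 512:
            raise FemurSpecError("n_points must be >= 512")
        if self.noise_sigma < 0 or self.shaft_bow < 0 or self.axis_offset < 0:
            raise FemurSpecError("noise_sigma, shaft_bow and axis_offset must be >= 0")
        if self.neck_radius >= self.head_radius:
            raise FemurSpecError("neck_radius must be smaller than head_radius")
        if self._neck_span()[1] - self._neck_span()[0] < 5.0:
            raise FemurSpecError(
                "neck too short: less than 5 mm of free neck between shaft exit and head"
            )

    def _neck_span(self) -> tuple[float, float]:
        """Axial extent [t_start, t_end] of the exposed neck surface."""
        theta = math.radians(self.nsa_true)
        t_start = self.shaft_radius / math.sin(theta) + 1.0
        t_end = self.neck_length - math.sqrt(self.head_radius**2 - self.neck_radius**2)
        return t_start, t_end


@dataclass(frozen=True)
class GroundTruth:
    """Analytic reference geometry of a generated femur (pre-noise)."""

    neck_axis: Axis
    shaft_axis: Axis
    head_center: np.ndarray
    nsa_true: float
    offset_true: float


def _ring_partition(n: int, ring_size: int = 16) -> list[int]:
    """Split n points into rings of equally spaced azimuths.

    Every ring has >= 2 points, so each ring's azimuthal sum cancels
    exactly and ring centroids fall on the generating axis.
    """
    if n < 2:
        raise FemurSpecError("a surface needs at least 2 points")
    sizes = [ring_size] * (n // ring_size)
    rem = n % ring_size
    if rem:
        if sizes and rem == 1:
            sizes[-1] += 1
        else:
            sizes.append(max(rem, 2) if rem >= 2 else rem)
            if rem == 1:  # unreachable when sizes nonempty; guard tiny n
                sizes[-1] = 2
    return sizes


def _lattice_tube(n: int, t_lo: float, t_hi: float, radius_of, origin, axis, u, v) -> np.ndarray:
    """Quasi-uniform points on a (possibly tapered/bowed) tube surface."""
    sizes = _ring_partition(n)
    pts = np.empty((n, 3))
    k = 0
    n_rings = len(sizes)
    for j, m in enumerate(sizes):
        t = t_lo + (j + 0.5) / n_rings * (t_hi - t_lo)
        r = radius_of(t)
        phase = 2.0 * math.pi * ((j * _GOLDEN) % 1.0)
        ang = phase + 2.0 * math.pi * np.arange(m) / m
        center = origin(t) if callable(origin) else origin + t * axis
        pts[k : k + m] = center + r * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)
        k += m
    return pts


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = 2.0 * math.pi * ((i * _GOLDEN) % 1.0)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _orthobasis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = int(np.argmin(np.abs(axis)))
    e = np.zeros(3)
    e[k] = 1.0
    u = np.cross(axis, e)
    u /= np.linalg.norm(u)
    return u, np.cross(axis, u)


def generate_femur(spec: FemurSpec) -> tuple[LabeledPointCloud, GroundTruth]:
    """Generate one labeled femur cloud plus its analytic ground truth.

    Construction frame: the shaft axis runs from the origin (proximal)
    along -z (distal), the neck rises from the origin at ``nsa_true`` to
    the shaft direction within the x-z (coronal) plane, then is rotated
    by ``anteversion`` about the shaft axis and shifted by
    ``axis_offset`` along the common perpendicular of the two axes.
    Deterministic for a given spec (including its seed).
    """
    theta = math.radians(spec.nsa_true)
    av = math.radians(spec.anteversion)
    B = np.array([0.0, 0.0, -1.0])  # shaft, proximal -> distal
    N = np.array(
        [math.sin(theta) * math.cos(av), math.sin(theta) * math.sin(av), -math.cos(theta)]
    )  # neck, toward the head
    w = np.cross(N, B)
    w /= np.linalg.norm(w)
    origin = np.zeros(3)
    neck_anchor = origin + spec.axis_offset * w
    head_center = neck_anchor + spec.neck_length * N
    t_start, t_end = spec._neck_span()

    # surface-area-proportional point allocation
    area_head = 4.0 * math.pi * spec.head_radius**2
    area_neck = 2.0 * math.pi * spec.neck_radius * (t_end - t_start)
    area_shaft = 2.0 * math.pi * spec.shaft_radius * spec.shaft_length
    total = area_head + area_neck + area_shaft
    n_head = max(64, int(round(spec.n_points * area_head / total)))
    n_neck = max(48, int(round(spec.n_points * area_neck / total)))
    n_shaft = spec.n_points - n_head - n_neck
    if n_shaft < 48:
        raise FemurSpecError("n_points too small for the requested proportions")

    # shaft: rings about the (optionally bowed, toward +y anterior) centerline
    nu, nv = _orthobasis(B)

    def shaft_center(t):
        s = t / spec.shaft_length
        return np.array([0.0, spec.shaft_bow * math.sin(math.pi * s), -t])

    shaft_pts = _lattice_tube(
        n_shaft, 0.0, spec.shaft_length, lambda t: spec.shaft_radius, shaft_center, B, nu, nv
    )

    # neck: mildly tapered frustum widening toward the shaft
    un, vn = _orthobasis(N)
    span = t_end - t_start

    def neck_radius_of(t):
        return spec.neck_radius * (1.15 - 0.15 * (t - t_start) / span)

    neck_pts = _lattice_tube(
        n_neck, t_start, t_end, neck_radius_of, lambda t: neck_anchor + t * N, N, un, vn
    )

    # head: Fibonacci sphere, minus the cap buried in the neck
    cap_depth = math.sqrt(spec.head_radius**2 - spec.neck_radius**2) / spec.head_radius
    m = int(math.ceil(n_head / (1.0 - (1.0 - cap_depth) / 2.0))) + 8
    while True:
        unit = _fibonacci_sphere(m)
        keep = unit @ (-N) <= cap_depth
        if keep.sum() >= n_head:
            break
        m = int(m * 1.2) + 8
    head_pts = head_center + spec.head_radius * unit[keep][:n_head]

    points = np.vstack([head_pts, neck_pts, shaft_pts])
    labels = np.concatenate(
        [
            np.full(n_head, LABEL_HEAD, dtype=np.int32),
            np.full(n_neck, LABEL_NECK, dtype=np.int32),
            np.full(n_shaft, LABEL_SHAFT, dtype=np.int32),
        ]
    )

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        points = points + rng.normal(0.0, spec.noise_sigma, points.shape)
    if spec.outlier_fraction > 0:
        k = int(round(spec.outlier_fraction * len(points)))
        if k:
            idx = rng.choice(len(points), size=k, replace=False)
            lo = points.min(axis=0)
            hi = points.max(axis=0)
            points[idx] = rng.uniform(lo, hi, size=(k, 3))

    cloud = LabeledPointCloud(points=points, labels=labels, id=f"synthetic_seed{spec.seed}")
    truth = GroundTruth(
        neck_axis=Axis(anchor=neck_anchor, direction=N),
        shaft_axis=Axis(anchor=origin, direction=B),
        head_center=head_center,
        nsa_true=spec.nsa_true,
        offset_true=spec.axis_offset,
    )
    return cloud, truth


def sweep(specs, ransac_config=None) -> pd.DataFrame:
    """Measure a batch of synthetic femurs with both pipelines.

    Returns one row per spec with the true and measured angles, the
    per-method recovery errors, the 2D-3D difference and the measured
    axis closest-approach distance.  Per-row failures are recorded in
    the ``error`` column and the sweep continues.
    """
    from .measure import measure_nsa_2d, measure_nsa_3d  # local: avoid import cycle

    specs = list(specs)
    if not specs:
        raise ValueError("sweep requires at least one spec")
    rows = []
    for i, spec in enumerate(specs):
        row = {
            "index": i,
            "nsa_true": spec.nsa_true,
            "anteversion": spec.anteversion,
            "axis_offset": spec.axis_offset,
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
            "nsa_2d": np.nan,
            "nsa_3d": np.nan,
            "err_2d": np.nan,
            "err_3d": np.nan,
            "diff_2d_3d": np.nan,
            "closest_approach_mm": np.nan,
            "error": None,
        }
        try:
            cloud, truth = generate_femur(spec)
            r3 = measure_nsa_3d(cloud)
            r2 = measure_nsa_2d(cloud, ransac_config)
            row.update(
                nsa_2d=r2.nsa_deg,
                nsa_3d=r3.nsa_deg,
                err_2d=abs(r2.nsa_deg - truth.nsa_true),
                err_3d=abs(r3.nsa_deg - truth.nsa_true),
                diff_2d_3d=abs(r2.nsa_deg - r3.nsa_deg),
                closest_approach_mm=r3.diagnostics["closest_approach_mm"],
            )
        except Exception as exc:  # noqa: BLE001 - per-row failures are data
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
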