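"""The two neck-shaft-angle measurement pipelines.

3D method: fit a sphere to the head, take the neck centroid, and join
them for the neck axis; join the 60-70% and 70-80% shaft-slab centroids
for the shaft axis; the NSA is the angle between the two directions.
The two 3D axes are generally skew, so their closest-approach distance
is reported as a diagnostic.

2D method: build a projection plane through the head-sphere center, the
neck centroid and the distal-10% shaft centroid (simulating the
anteroposterior radiograph, whose positioning counterbalances femoral
anteversion), project every region onto it, recover the projected head
center with a robust RANSAC circle fit in plane coordinates, and
measure the angle between the in-plane neck and shaft axes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry as geo
from .geometry import Axis, Plane, RansacConfig
from .io import LABEL_HEAD, LABEL_NECK, LABEL_SHAFT, LABEL_NAMES, LabeledPointCloud
from . import regions

__all__ = [
    "NSAResult",
    "MissingRegionError",
    "neck_axis_3d",
    "shaft_axis_3d",
    "measure_nsa_3d",
    "build_projection_plane",
    "measure_nsa_2d",
]

SLAB_PROXIMAL = (0.6, 0.7)
SLAB_DISTAL = (0.7, 0.8)
DISTAL_FRACTION = 0.10


class MissingRegionError(ValueError):
    """The input cloud lacks one of the head/neck/shaft regions."""


@dataclass
class NSAResult:
    """One NSA measurement with its full provenance.

    nsa_deg is the angle between ``neck_axis.direction`` (pointing neck
    to head center) and ``shaft_axis.direction`` (pointing proximal to
    distal); with these orientations the angle lands in the anatomical
    range (~110-150 deg) rather than its supplement.  ``plane`` is the
    projection plane for the 2D method and ``None`` for the 3D method.
    """

    method: str  # "2d" | "3d"
    nsa_deg: float
    neck_axis: Axis
    shaft_axis: Axis
    plane: Plane | None
    centroids: dict[str, np.ndarray]
    diagnostics: dict = field(default_factory=dict)
    id: str = ""

    def __post_init__(self):
        if self.method not in ("2d", "3d"):
            raise ValueError("method must be '2d' or '3d'")
        if not 0.0 < self.nsa_deg < 180.0:
            raise ValueError("nsa_deg must lie strictly between 0 and 180 degrees")
        if self.method == "3d" and self.plane is not None:
            raise ValueError("3d results carry no projection plane")
        if self.method == "2d" and self.plane is None:
            raise ValueError("2d results must carry their projection plane")
        if self.nsa_deg < 90.0:
            self.diagnostics.setdefault("orientation_suspect", True)
            warnings.warn(
                f"measured NSA {self.nsa_deg:.2f} deg is below 90 deg; "
                "this usually indicates an axis-orientation fault, the anatomical "
                "angle may be the supplement",
                RuntimeWarning,
                stacklevel=2,
            )


def _require_regions(cloud: LabeledPointCloud) -> dict[int, np.ndarray]:
    parts = {lab: cloud.region(lab) for lab in LABEL_NAMES}
    for lab, pts in parts.items():
        if pts.shape[0] == 0:
            raise MissingRegionError(f"cloud {cloud.id!r} has no {LABEL_NAMES[lab]} points")
    return parts


def neck_axis_3d(head_center, neck_centroid) -> Axis:
    """Neck axis: anchored at the neck centroid, pointing at the head center."""
    head_center = np.asarray(head_center, dtype=float)
    neck_centroid = np.asarray(neck_centroid, dtype=float)
    d = head_center - neck_centroid
    if np.linalg.norm(d) <= 1e-6:
        raise geo.DegenerateGeometryError("head center and neck centroid coincide")
    return Axis(anchor=neck_centroid, direction=d)


def shaft_axis_3d(slab_60_70_centroid, slab_70_80_centroid) -> Axis:
    """Shaft axis through the two slab centroids, oriented proximal->distal."""
    a = np.asarray(slab_60_70_centroid, dtype=float)
    b = np.asarray(slab_70_80_centroid, dtype=float)
    if np.linalg.norm(b - a) <= 1e-6:
        raise geo.DegenerateGeometryError("shaft slab centroids coincide")
    return Axis(anchor=a, direction=b - a)


def _anatomy(cloud: LabeledPointCloud):
    """Shared first stage: head sphere, neck centroid, shaft slabs."""
    parts = _require_regions(cloud)
    head_sphere = geo.fit_sphere_lsq(parts[LABEL_HEAD])
    neck_c = geo.centroid(parts[LABEL_NECK])
    shaft_pts = parts[LABEL_SHAFT]
    param = regions.shaft_param(shaft_pts, proximal_hint=head_sphere.center)
    slab_a = regions.extract_slab(shaft_pts, param, *SLAB_PROXIMAL)
    slab_b = regions.extract_slab(shaft_pts, param, *SLAB_DISTAL)
    distal = regions.distal_fraction(shaft_pts, param, DISTAL_FRACTION)
    centroids = {
        "head_center": head_sphere.center,
        "neck": neck_c,
        "shaft_slab_60_70": geo.centroid(slab_a),
        "shaft_slab_70_80": geo.centroid(slab_b),
        "shaft_distal10": geo.centroid(distal),
    }
    return parts, head_sphere, centroids


def measure_nsa_3d(cloud: LabeledPointCloud) -> NSAResult:
    """Direct 3D NSA measurement by spatial axis fitting."""
    _, head_sphere, centroids = _anatomy(cloud)
    neck_axis = neck_axis_3d(centroids["head_center"], centroids["neck"])
    shaft_axis = shaft_axis_3d(centroids["shaft_slab_60_70"], centroids["shaft_slab_70_80"])
    nsa = geo.angle_between(neck_axis.direction, shaft_axis.direction)
    return NSAResult(
        method="3d",
        nsa_deg=nsa,
        neck_axis=neck_axis,
        shaft_axis=shaft_axis,
        plane=None,
        centroids=centroids,
        diagnostics={
            "closest_approach_mm": geo.line_closest_approach(neck_axis, shaft_axis),
            "head_radius_mm": head_sphere.radius,
        },
        id=cloud.id,
    )


def build_projection_plane(cloud: LabeledPointCloud) -> tuple[Plane, dict[str, np.ndarray]]:
    """Plane through head-sphere center, neck centroid and distal-10% centroid.

    This simulates the anteroposterior radiograph plane; a perfectly
    straight specimen (collinear centroids) cannot define it.
    """
    _, _, centroids = _anatomy(cloud)
    plane = geo.plane_from_points(
        centroids["head_center"], centroids["neck"], centroids["shaft_distal10"]
    )
    return plane, centroids


def silhouette_points(points2d: np.ndarray, n_sectors: int = 72, ref_point=None) -> np.ndarray:
    """Outermost point per azimuthal sector about the 2D centroid.

    Approximates the silhouette rim of a projected solid shape; sectors
    with no points (e.g. where the neck attaches to the head) are
    skipped.  When ``ref_point`` is given, sector zero starts at the
    direction from the centroid to it, which makes the sector
    partition — and hence the extracted silhouette — independent of the
    in-plane coordinate frame.
    """
    pts = np.asarray(points2d, dtype=float)
    c0 = pts.mean(axis=0)
    d = pts - c0
    ang = np.arctan2(d[:, 1], d[:, 0])
    if ref_point is not None:
        r = np.asarray(ref_point, dtype=float) - c0
        ang = ang - math.atan2(r[1], r[0])
    ang = np.mod(ang, 2.0 * math.pi)
    rad = np.linalg.norm(d, axis=1)
    sec = np.floor(ang / (2.0 * math.pi) * n_sectors).astype(int) % n_sectors
    out = []
    for s in range(n_sectors):
        m = np.nonzero(sec == s)[0]
        if m.size:
            out.append(pts[m[np.argmax(rad[m])]])
    return np.asarray(out)


def _refine_circle(points2d: np.ndarray, circle, scale: float = 1.0):
    """Polish a consensus circle by geometric fits at shrinking inlier bands.

    The silhouette's per-sector outermost points sit slightly inside the
    true rim by a sector-dependent amount (largest next to the rim gap at
    the neck); tightening the band trims those deficit points so the
    final center is not pulled toward the gap.
    """
    from scipy.optimize import least_squares

    p = np.r_[circle.center, circle.radius]
    for thr in (1.0 * scale, 0.6 * scale, 0.35 * scale, 0.2 * scale):
        resid = np.abs(np.linalg.norm(points2d - p[:2], axis=1) - p[2])
        m = resid <= thr
        if int(m.sum()) < 10:
            break
        sel = points2d[m]
        p = least_squares(
            lambda q: np.linalg.norm(sel - q[:2], axis=1) - q[2], p, method="lm"
        ).x
    return geo.Circle2D(center=p[:2], radius=float(abs(p[2])))


def measure_nsa_2d(
    cloud: LabeledPointCloud,
    config: RansacConfig | None = None,
    head_fit: str = "boundary",
) -> NSAResult:
    """NSA measured on the simulated anteroposterior projection plane.

    Head, neck and shaft are orthogonally projected onto the plane; the
    projected head center comes from a RANSAC circle fit in plane
    coordinates; slab membership is computed on the 3D shaft —
    projection is affine, so the projected members' centroids equal the
    projections of the 3D slab centroids.

    ``head_fit`` selects the circle-fit input: ``"boundary"`` (default)
    first extracts the projected head's silhouette rim (one outermost
    point per azimuthal sector) and fits the circle to it, ``"all"``
    fits directly on every projected head point.  The projected head is
    a solid disc whose rim has a gap where the neck attaches; with
    interior points included the consensus circle is poorly constrained
    along the gap direction, so the silhouette path is the default.
    """
    if config is None:
        config = RansacConfig()
    if head_fit not in ("boundary", "all"):
        raise ValueError("head_fit must be 'boundary' or 'all'")
    parts, head_sphere, centroids = _anatomy(cloud)
    plane = geo.plane_from_points(
        centroids["head_center"], centroids["neck"], centroids["shaft_distal10"]
    )
    origin = geo.project_point(plane, centroids["neck"])
    e1, e2 = geo.plane_basis(plane, origin)

    head_proj = geo.project_point(plane, parts[LABEL_HEAD])
    head_2d = geo.to_plane_coords(head_proj, origin, e1, e2)
    neck_2d = geo.to_plane_coords(origin, origin, e1, e2)  # neck centroid = origin
    fit_input = (
        silhouette_points(head_2d, ref_point=neck_2d) if head_fit == "boundary" else head_2d
    )
    circle, inliers = geo.fit_circle_ransac(fit_input, config)
    circle = _refine_circle(fit_input, circle, scale=config.inlier_threshold)
    head_center_2d3 = geo.from_plane_coords(circle.center, origin, e1, e2)

    neck_c_proj = geo.project_point(plane, geo.centroid(parts[LABEL_NECK]))
    slab_a_proj = geo.project_point(plane, centroids["shaft_slab_60_70"])
    slab_b_proj = geo.project_point(plane, centroids["shaft_slab_70_80"])

    neck_axis = neck_axis_3d(head_center_2d3, neck_c_proj)
    shaft_axis = shaft_axis_3d(slab_a_proj, slab_b_proj)
    nsa = geo.angle_between(neck_axis.direction, shaft_axis.direction)

    proj_centroids = dict(centroids)
    proj_centroids["head_center_projected"] = head_center_2d3
    proj_centroids["neck_projected"] = neck_c_proj
    return NSAResult(
        method="2d",
        nsa_deg=nsa,
        neck_axis=neck_axis,
        shaft_axis=shaft_axis,
        plane=plane,
        centroids=proj_centroids,
        diagnostics={
            "head_circle_radius_mm": circle.radius,
            "head_circle_inliers": int(inliers.sum()),
            "head_sphere_radius_mm": head_sphere.radius,
        },
        id=cloud.id,
    )
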