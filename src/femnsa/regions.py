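"""Shaft-axis parameterization and percentage-slab extraction.

The shaft axis construction needs the centroids of the 60-70% and
70-80% slabs of the shaft length, and the projection plane needs the
centroid of the distal 10%.  Axial position is the scalar projection of
each shaft point onto the shaft's dominant principal direction, oriented
proximal (0%) to distal (100%); the percentage base is by default the
labeled shaft region alone, since the distal femur may be absent from a
hip CT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, _as_points

__all__ = ["ShaftParam", "EmptySlabError", "shaft_param", "extract_slab", "distal_fraction"]


class EmptySlabError(ValueError):
    """Raised when a requested axial slab contains no points."""

    def __init__(self, lo: float, hi: float):
        super().__init__(f"no points in axial slab [{lo:g}, {hi:g})")
        self.lo = lo
        self.hi = hi


@dataclass(frozen=True)
class ShaftParam:
    """Straight-line axial parameterization of the shaft region.

    axis_point, axis_dir
        A point on the axis and the unit direction, oriented
        proximal -> distal.
    t_min, t_max
        Extreme scalar projections (mm) of the shaft points onto the
        axis; ``length = t_max - t_min`` is the shaft length used as the
        percentage base.
    """

    axis_point: np.ndarray
    axis_dir: np.ndarray
    t_min: float
    t_max: float

    @property
    def length(self) -> float:
        return self.t_max - self.t_min

    def axial_fraction(self, points) -> np.ndarray:
        """Normalized axial coordinate s in [0, 1] of each point."""
        pts = np.asarray(points, dtype=float)
        t = (pts - self.axis_point) @ self.axis_dir
        return (t - self.t_min) / self.length


def shaft_param(shaft_points, proximal_hint) -> ShaftParam:
    """Fit the shaft's principal axis, oriented away from the proximal hint.

    The direction is the dominant eigenvector of the mean-centered shaft
    covariance, sign-flipped so that it points away from
    ``proximal_hint`` (the head-sphere center or neck centroid), i.e.
    proximal to distal.  Fails when the point set has no dominant
    elongation (top two principal spreads within 5% of each other).
    """
    pts = _as_points(shaft_points, min_count=10, name="shaft points")
    hint = np.asarray(proximal_hint, dtype=float)
    mean = pts.mean(axis=0)
    q = pts - mean
    cov = q.T @ q / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    spread = np.sqrt(np.maximum(evals, 0.0))
    if spread[2] <= 0 or (spread[2] - spread[1]) <= 0.05 * spread[2]:
        raise DegenerateGeometryError("shaft points have no dominant principal direction")
    direction = evecs[:, 2]
    if direction @ (mean - hint) < 0:
        direction = -direction
    t = pts @ direction
    t_min = float(t.min())
    t_max = float(t.max())
    if t_max - t_min <= 10.0:
        raise DegenerateGeometryError("shaft region spans less than 10 mm along its axis")
    return ShaftParam(axis_point=np.zeros(3), axis_dir=direction, t_min=t_min, t_max=t_max)


def extract_slab(points, param: ShaftParam, lo: float, hi: float) -> np.ndarray:
    """Points whose normalized axial coordinate lies in [lo, hi).

    The interval is half-open so adjacent slabs partition the shaft
    without double counting; ``hi == 1`` additionally includes s == 1 so
    the distal endpoint is never dropped.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("slab bounds must satisfy 0 <= lo < hi <= 1")
    pts = np.asarray(points, dtype=float)
    s = param.axial_fraction(pts)
    mask = (s >= lo) & ((s <= hi) if hi >= 1.0 else (s < hi))
    out = pts[mask]
    if out.shape[0] == 0:
        raise EmptySlabError(lo, hi)
    return out


def distal_fraction(shaft_points, param: ShaftParam, fraction: float = 0.10) -> np.ndarray:
    """The distal ``fraction`` of the shaft: slab [1 - fraction, 1]."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return extract_slab(shaft_points, param, 1.0 - fraction, 1.0)
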