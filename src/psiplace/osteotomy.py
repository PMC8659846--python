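"""Osteotomy cross-sections and the maximum osteotomy deviation (MOD).

An osteotomy is modeled as a cutting plane through the bone surface. The
planned cut is the plane's intersection curve with the mesh; the achieved
cut is the intersection of the same plane moved by the guide's
planned-to-actual transform (the bone stays fixed, the plane moves). Both
curves are sampled as dense point clouds at uniform arc-length spacing,
and the deviation is the directed closest-point distance from every
planned point to the achieved point cloud; its maximum over the planned
curve is the MOD, in mm.

The metric is deliberately asymmetric (planned -> achieved) and uses
unsigned 3-D Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry_io import CuttingPlane, RigidTransform, TriangleMesh

__all__ = [
    "CrossSection",
    "DeviationReport",
    "NoIntersectionError",
    "intersect_plane_mesh",
    "max_osteotomy_deviation",
    "assess_placement",
]

DEFAULT_SPACING = 0.1  # mm between resampled section points


class NoIntersectionError(ValueError):
    """The cutting plane does not intersect the bone mesh (off-bone placement)."""


@dataclass(frozen=True)
class CrossSection:
    """Point cloud sampling the plane ∩ mesh intersection curve(s)."""

    points: np.ndarray
    source_plane: CuttingPlane

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("a cross-section needs at least 2 points of shape (n, 3)")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="x,y,z", comments="")

    def to_ply(self, path) -> None:
        trimesh.PointCloud(self.points).export(str(path))


@dataclass(frozen=True)
class DeviationReport:
    """Deviation of an achieved cut from the planned one. ``mod`` is the max."""

    mod: float
    mean_deviation: float
    per_point_distances: np.ndarray
    region: str | None = None

    def to_dict(self) -> dict:
        return {
            "mod_mm": self.mod,
            "mean_deviation_mm": self.mean_deviation,
            "n_points": int(len(self.per_point_distances)),
            "region": self.region,
        }


def _resample_polyline(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc length; closed loops drop the repeat."""
    closed = np.allclose(poly[0], poly[-1])
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    length = seg.sum()
    if length <= 0:
        return poly[:1]
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(np.ceil(length / spacing)) + 1)
    target = np.linspace(0.0, length, n)
    out = np.column_stack([np.interp(target, s, poly[:, k]) for k in range(3)])
    return out[:-1] if closed else out


def intersect_plane_mesh(
    mesh: TriangleMesh,
    plane: CuttingPlane,
    spacing: float = DEFAULT_SPACING,
    near: np.ndarray | None = None,
) -> CrossSection:
    """Intersect a cutting plane with the bone mesh, resampled uniformly.

    Triangle/plane crossing segments are chained into polylines and
    resampled at ``spacing`` mm of arc length so the point-cloud density is
    independent of mesh resolution. By default every connected component of
    the intersection is kept; passing ``near`` (a 3-D point, e.g. the guide
    footprint centroid) keeps only the component closest to it. Raises
    :class:`NoIntersectionError` when the plane misses the bone.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.origin
    )
    if len(segments) == 0:
        raise NoIntersectionError("cutting plane does not intersect the mesh")
    path = trimesh.load_path(segments)
    # entities are the chained polylines; Path3D.discrete would drop open curves
    polylines = [np.asarray(e.discrete(path.vertices), dtype=float) for e in path.entities]
    if near is not None and len(polylines) > 1:
        near = np.asarray(near, dtype=float).reshape(3)
        polylines = [min(polylines,
                         key=lambda p: np.linalg.norm(p - near, axis=1).min())]
    pts = np.vstack([_resample_polyline(p, spacing) for p in polylines])
    if len(pts) < 2:
        raise NoIntersectionError("plane-mesh intersection is degenerate (single point)")
    return CrossSection(pts, plane)


def max_osteotomy_deviation(
    planned: CrossSection, actual: CrossSection, region: str | None = None
) -> DeviationReport:
    """Directed deviation from the planned cut to the achieved cut.

    For every point of the planned section, the Euclidean distance to its
    closest point in the achieved section; the maximum over the planned
    section is the MOD. The direction matters: swapping the arguments can
    change the result.
    """
    d, _ = cKDTree(actual.points).query(planned.points)
    return DeviationReport(
        mod=float(d.max()),
        mean_deviation=float(d.mean()),
        per_point_distances=d,
        region=region,
    )


def assess_placement(
    mesh: TriangleMesh,
    plane: CuttingPlane,
    plan_to_real: RigidTransform,
    spacing: float = DEFAULT_SPACING,
    region: str | None = None,
) -> DeviationReport:
    """MOD of one guide placement: move the plane by planToReal, re-intersect.

    The planned section comes from ``plane``; the achieved section from the
    transformed plane (origin R·o + t, normal R·n) intersected with the same
    fixed bone. A transformed plane that misses the bone raises
    :class:`NoIntersectionError` — callers record such trials as off-bone
    placements rather than clamping them.
    """
    planned = intersect_plane_mesh(mesh, plane, spacing)
    actual = intersect_plane_mesh(mesh, plane.transformed(plan_to_real), spacing)
    return max_osteotomy_deviation(planned, actual, region=region)
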