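"""Core geometric types, rigid-motion algebra, and mesh / point-set I/O.

All coordinates are in millimetres in a right-handed frame, matching the
clinical CT convention. Rigid transforms act on column points as
``p' = R @ p + t``; :func:`compose` applies its *second* argument first,
so ``compose(T2, T1)`` is the motion "T1, then T2".

Triangle meshes are represented by :class:`trimesh.Trimesh`, the standard
container for surface meshes in scientific Python; :func:`load_mesh` adds
the load-time cleaning (duplicate-vertex merging, degenerate-face removal)
that downstream closest-point queries rely on.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh

__all__ = [
    "RigidTransform",
    "CuttingPlane",
    "FiducialSet",
    "TriangleMesh",
    "MeshFormatError",
    "load_mesh",
    "save_mesh",
    "apply_transform",
    "compose",
    "invert",
    "closest_points_on_mesh",
]

#: Alias for the mesh container used throughout the package (vertices in mm).
TriangleMesh = trimesh.Trimesh

_ORTHO_TOL = 1e-9
_DEGENERATE_AREA = 1e-9  # mm^2; faces below this are dropped at load time


class MeshFormatError(ValueError):
    """Raised when a mesh file is unreadable, empty, or truncated."""


def _as_points(pts) -> np.ndarray:
    a = np.asarray(pts, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected (n, 3) points, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion: rotation ``R`` (det +1) plus translation ``t`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(f"rotation is not orthonormal (|R'R - I|_inf = {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection, not a rigid motion)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from an axis-angle rotation vector (radians) and a translation."""
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    @classmethod
    def about_point(cls, rotation, center, extra_translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation about an arbitrary ``center`` followed by a translation."""
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        c = np.asarray(center, dtype=float).reshape(3)
        t = c - R @ c + np.asarray(extra_translation, dtype=float).reshape(3)
        return cls(R, t)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, pts) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        out = _as_points(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return self ∘ first (apply ``first``, then ``self``)."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


def apply_transform(T: RigidTransform, pts) -> np.ndarray:
    """Apply ``p' = R p + t`` to one point or an (n, 3) array of points."""
    return T.apply(pts)


def compose(T2: RigidTransform, T1: RigidTransform) -> RigidTransform:
    """Composition that applies ``T1`` first, then ``T2``."""
    return T2.compose(T1)


def invert(T: RigidTransform) -> RigidTransform:
    return T.inverse()


@dataclass(frozen=True)
class CuttingPlane:
    """A planned osteotomy plane: a point on the plane and its unit normal (mm)."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError("plane normal has zero length")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n / norm)

    def transformed(self, T: RigidTransform) -> "CuttingPlane":
        """The plane after a rigid motion: origin R·o + t, normal R·n."""
        return CuttingPlane(T.apply(self.origin), T.rotation @ self.normal)

    def signed_distance(self, pts) -> np.ndarray:
        return (_as_points(pts) - self.origin) @ self.normal

    def to_dict(self) -> dict:
        return {"origin": self.origin.tolist(), "normal": self.normal.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CuttingPlane":
        return cls(np.asarray(d["origin"]), np.asarray(d["normal"]))


@dataclass(frozen=True)
class FiducialSet:
    """Ordered, labeled 3-D points (PSI pinholes, landmarks, surface samples).

    ``frame`` records which coordinate frame the points live in: ``"bone"``
    (the planning CT / mesh frame) or ``"tracker"`` (optical tracker frame).
    """

    labels: tuple
    points: np.ndarray
    frame: str = "bone"

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        pts = _as_points(self.points)
        if len(labels) != len(pts):
            raise ValueError(f"{len(labels)} labels but {len(pts)} points")
        if len(set(labels)) != len(labels):
            raise ValueError("fiducial labels must be unique")
        if self.frame not in ("bone", "tracker"):
            raise ValueError(f"frame must be 'bone' or 'tracker', got {self.frame!r}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.labels)

    def reordered_like(self, other: "FiducialSet") -> "FiducialSet":
        """Return a copy with points reordered to match ``other``'s labels."""
        if set(self.labels) != set(other.labels):
            raise ValueError(f"label sets differ: {sorted(self.labels)} vs {sorted(other.labels)}")
        idx = [self.labels.index(lab) for lab in other.labels]
        return FiducialSet(other.labels, self.points[idx], self.frame)

    def transformed(self, T: RigidTransform, frame: str | None = None) -> "FiducialSet":
        return FiducialSet(self.labels, T.apply(self.points), frame or self.frame)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "x", "y", "z"])
            for lab, p in zip(self.labels, self.points):
                w.writerow([lab, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])

    @classmethod
    def from_csv(cls, path, frame: str = "bone") -> "FiducialSet":
        labels, pts = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                labels.append(row["label"])
                pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
        if not labels:
            raise ValueError(f"no fiducials found in {path}")
        return cls(tuple(labels), np.asarray(pts), frame)

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "points": self.points.tolist(), "frame": self.frame}

    @classmethod
    def from_dict(cls, d: dict) -> "FiducialSet":
        return cls(tuple(d["labels"]), np.asarray(d["points"]), d.get("frame", "bone"))


# ---------------------------------------------------------------------------
# Mesh I/O


def load_mesh(path) -> TriangleMesh:
    """Load an STL (binary or ASCII) or PLY surface mesh, with cleaning.

    Duplicate vertices are merged and degenerate (zero-area) faces dropped so
    that downstream closest-point and plane-section queries see sane topology.
    Coordinates are taken verbatim as millimetres.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load(str(path), force="mesh")
    except Exception as exc:  # trimesh raises a zoo of types on bad files
        raise MeshFormatError(f"could not read mesh from {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"no triangle faces found in {path}")
    return clean_mesh(mesh)


def clean_mesh(mesh: TriangleMesh) -> TriangleMesh:
    """Merge duplicate vertices and drop faces below the degenerate-area tolerance."""
    mesh = mesh.copy()
    mesh.merge_vertices()
    keep = mesh.area_faces > _DEGENERATE_AREA
    if not keep.all():
        mesh.update_faces(keep)
        mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise MeshFormatError("mesh has no non-degenerate faces after cleaning")
    return mesh


def save_mesh(mesh: TriangleMesh, path) -> None:
    mesh.export(str(path))


# ---------------------------------------------------------------------------
# Exact closest point on a triangle mesh (used by ICP)


def _closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i, vectorized over i.

    Standard barycentric-region classification (cf. Ericson, *Real-Time
    Collision Detection*), operating on matched arrays of shape (n, 3) and
    (n, 3, 3).
    """
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab, ac, ap = b - a, c - a, points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(d1 - d3 != 0, d1 - d3, 1.0)
    v = (d1 / denom)[:, None]
    out[m] = (a + v * ab)[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(d2 - d6 != 0, d2 - d6, 1.0)
    w = (d2 / denom)[:, None]
    out[m] = (a + w * ac)[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom_bc = (d4 - d3) + (d5 - d6)
    denom_bc = np.where(denom_bc != 0, denom_bc, 1.0)
    w = ((d4 - d3) / denom_bc)[:, None]
    out[m] = (b + w * (c - b))[m]
    done |= m

    # interior
    m = ~done
    denom_in = va + vb + vc
    denom_in = np.where(denom_in != 0, denom_in, 1.0)
    v = (vb / denom_in)[:, None]
    w = (vc / denom_in)[:, None]
    out[m] = (a + v * ab + w * ac)[m]
    return out


def closest_points_on_mesh(mesh: TriangleMesh, points) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest surface points and distances for a batch of query points.

    Uses a KD-tree over face centroids to prune candidate triangles, with a
    nearest-vertex distance bound guaranteeing that the true closest face is
    always among the candidates; for small problems it simply checks every
    face. Returns ``(surface_points, distances)``.
    """
    from scipy.spatial import cKDTree

    points = _as_points(points)
    tri = mesh.triangles  # (F, 3, 3)
    n_f, n_p = len(tri), len(points)

    if n_f * n_p <= 2_000_000:
        # brute force: all point-triangle pairs
        pts_rep = np.repeat(points, n_f, axis=0)
        tri_rep = np.tile(tri, (n_p, 1, 1))
        cand = _closest_point_on_triangles(pts_rep, tri_rep).reshape(n_p, n_f, 3)
        d2 = ((cand - points[:, None, :]) ** 2).sum(axis=2)
        best = d2.argmin(axis=1)
        closest = cand[np.arange(n_p), best]
        return closest, np.sqrt(d2[np.arange(n_p), best])

    centroids = tri.mean(axis=1)
    # max distance from any face centroid to its own vertices: pruning radius pad
    pad = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    vtree = cKDTree(mesh.vertices)
    ctree = cKDTree(centroids)
    d_vert, _ = vtree.query(points)

    closest = np.empty_like(points)
    dist = np.empty(n_p)
    for i, (p, bound) in enumerate(zip(points, d_vert)):
        cand_idx = ctree.query_ball_point(p, bound + pad + 1e-9)
        cand_tri = tri[cand_idx]
        cp = _closest_point_on_triangles(np.broadcast_to(p, (len(cand_tri), 3)).copy(), cand_tri)
        d2 = ((cp - p) ** 2).sum(axis=1)
        j = d2.argmin()
        closest[i] = cp[j]
        dist[i] = np.sqrt(d2[j])
    return closest, dist
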