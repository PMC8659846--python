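"""Rigid registration: paired-point (Horn/Kabsch), ICP surface refinement,
and the planned-to-actual guide transform (planToReal).

The paired-point solver is the SVD closed form minimizing
``sum_i || R m_i + t - f_i ||^2`` with reflections excluded (det R = +1);
its RMS residual is the fiducial registration error (FRE). ICP alternates
exact closest-point-on-surface correspondence with the paired-point update,
which makes the point-to-surface RMS non-increasing across iterations.

planToReal estimates the rigid motion of a patient-specific guide (PSI)
from its planned pose to the pose actually achieved by the user, from the
four pinhole fiducials every guide carries. Both pinhole sets must already
be expressed in the bone frame; measured points recorded in the tracker
frame are mapped through the bone registration first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry_io import (
    FiducialSet,
    RigidTransform,
    TriangleMesh,
    closest_points_on_mesh,
)

__all__ = [
    "RegistrationResult",
    "InsufficientPointsError",
    "DegenerateConfigurationError",
    "PinholeCountError",
    "paired_point_registration",
    "icp_refine",
    "plan_to_real",
]


class InsufficientPointsError(ValueError):
    """Fewer corresponding point pairs than a rigid fit needs."""


class DegenerateConfigurationError(ValueError):
    """Point configuration (e.g. collinear) does not determine a rotation."""


class PinholeCountError(ValueError):
    """planToReal requires exactly the four pinholes of the guide protocol."""


@dataclass(frozen=True)
class RegistrationResult:
    transform: RigidTransform
    rms_residual: float
    max_residual: float
    iterations: int = 0
    converged: bool = True
    rms_history: tuple = ()  # per-iteration point-to-surface RMS (ICP only)

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.to_dict(),
            "rms_residual": self.rms_residual,
            "max_residual": self.max_residual,
            "iterations": self.iterations,
            "converged": self.converged,
        }


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid motion mapping ``moving`` onto ``fixed`` (arrays)."""
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    H = (moving - mc).T @ (fixed - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    # re-orthonormalize to keep the orthonormality invariant tight
    Ur, _, Vtr = np.linalg.svd(R)
    R = Ur @ Vtr
    return RigidTransform(R, fc - R @ mc)


def _residuals(T: RigidTransform, moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    return np.linalg.norm(T.apply(moving) - fixed, axis=1)


def paired_point_registration(moving: FiducialSet, fixed: FiducialSet) -> RegistrationResult:
    """Closed-form rigid registration of labeled corresponding point sets.

    Points are matched by label (``fixed`` is reordered to ``moving``'s label
    order). Requires at least three non-collinear pairs. The returned
    ``rms_residual`` is the fiducial registration error in mm.
    """
    fixed = fixed.reordered_like(moving)
    m, f = moving.points, fixed.points
    if len(m) < 3:
        raise InsufficientPointsError(f"need >= 3 point pairs, got {len(m)}")
    s = np.linalg.svd(m - m.mean(axis=0), compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateConfigurationError("moving points are collinear; rotation is not determined")
    T = _kabsch(m, f)
    r = _residuals(T, m, f)
    return RegistrationResult(T, float(np.sqrt((r**2).mean())), float(r.max()))


def icp_refine(
    points: FiducialSet,
    mesh: TriangleMesh,
    init: RigidTransform,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> RegistrationResult:
    """Iterative closest point refinement of ``init`` against a surface mesh.

    Alternates (a) exact closest-point-on-triangle correspondence for the
    currently transformed points and (b) the paired-point update, until the
    change in point-to-surface RMS drops below ``tol`` (mm) or ``max_iter``
    is reached. ``rms_residual`` / ``max_residual`` report the final
    point-to-surface distances.
    """
    pts = points.points if isinstance(points, FiducialSet) else np.asarray(points, float)
    if len(pts) < 3:
        raise InsufficientPointsError(f"ICP needs >= 3 points, got {len(pts)}")
    if len(mesh.faces) == 0:
        raise ValueError("ICP target mesh has no faces")

    T = init
    targets, dists = closest_points_on_mesh(mesh, T.apply(pts))
    rms = float(np.sqrt((dists**2).mean()))
    history = [rms]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T = _kabsch(pts, targets)
        targets, dists = closest_points_on_mesh(mesh, T.apply(pts))
        new_rms = float(np.sqrt((dists**2).mean()))
        history.append(new_rms)
        if abs(rms - new_rms) < tol:
            rms = new_rms
            converged = True
            break
        rms = new_rms
    return RegistrationResult(T, rms, float(dists.max()), iterations=it,
                              converged=converged, rms_history=tuple(history))


def plan_to_real(planned_pinholes: FiducialSet, measured_pinholes: FiducialSet) -> RegistrationResult:
    """Estimate the guide's planned-to-actual transform from its 4 pinholes.

    Both sets must contain exactly the four labeled pinholes of the guide
    protocol and be expressed in the bone frame (tracker-frame measurements
    are mapped through the bone registration beforehand). Delegates to the
    paired-point solver; the result's transform is planToReal.
    """
    if len(planned_pinholes) != 4 or len(measured_pinholes) != 4:
        raise PinholeCountError(
            f"expected 4 pinholes each, got {len(planned_pinholes)} planned "
            f"and {len(measured_pinholes)} measured"
        )
    if set(planned_pinholes.labels) != set(measured_pinholes.labels):
        raise ValueError("planned and measured pinhole labels do not match")
    if "tracker" in (planned_pinholes.frame, measured_pinholes.frame):
        raise ValueError("pinholes must be in the bone frame; apply the bone registration first")
    return paired_point_registration(planned_pinholes, measured_pinholes)
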