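"""Synthetic stand-ins for the physical placement experiment.

Physical placement experiments of this kind seat pairs of patient-specific
guides (PSIs) on a 3D printed hemipelvis: one guide in the narrow,
characteristically shaped supra-acetabular region (S) and one on the
broad, homogeneous iliac crest (C). Phantom meshes and plans for such
experiments are not generally available, and the assessed geometry
pipeline is shape-agnostic, so this module generates a parametric bone
stand-in that reproduces the two features the analysis hinges on:

* a broad low-curvature crest band (the C region) whose surface texture
  amplitude scales with ``1 - crest_homogeneity`` and grows along the
  band, giving both "small guide on a smooth area" and "large guide on a
  featured area" configurations;
* a narrow high-curvature notch (the S region).

Placement error is simulated per method: a small random rotation about the
guide's footprint plus a random translation for all methods, inflated when
a soft-tissue (silicone) layer is present, and — for freehand placement on
the homogeneous crest only — an occasional large tangential slide along
the crest that produces the heavy tail seen in freehand deviations.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry_io import (
    CuttingPlane,
    FiducialSet,
    RigidTransform,
    TriangleMesh,
    clean_mesh,
    closest_points_on_mesh,
)

__all__ = [
    "PhantomSpec",
    "CaseSpec",
    "PlacementModel",
    "make_phantom_mesh",
    "make_cases",
    "simulate_placement",
    "simulate_pinhole_measurement",
    "sample_surface_fiducials",
    "random_rigid_transform",
    "default_models",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic bone shell.

    ``size_mm`` is the overall scale (bounding extent of the shell);
    ``crest_homogeneity`` in [0, 1] controls how feature-less the crest
    band is (1 = perfectly smooth); ``tissue_thickness_mm`` > 0 marks the
    "realistic" silicone-coated variant (it inflates placement noise, not
    the geometry). Resolution gives a shell of ~10k triangles by default.
    """

    seed: int = 0
    size_mm: float = 180.0
    crest_homogeneity: float = 0.5
    tissue_thickness_mm: float = 0.0
    n_u: int = 84
    n_v: int = 60

    def __post_init__(self):
        if not (0.0 <= self.crest_homogeneity <= 1.0):
            raise ValueError("crest_homogeneity must be in [0, 1]")
        if self.tissue_thickness_mm < 0:
            raise ValueError("tissue_thickness_mm must be >= 0")


@dataclass(frozen=True)
class CaseSpec:
    """One resection scenario in one region: cutting plane + planned pinholes."""

    case_id: int
    region: str
    footprint_size_mm: float
    plane: CuttingPlane
    pinholes_planned: FiducialSet
    slip_direction: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.region not in ("S", "C"):
            raise ValueError("region must be 'S' or 'C'")
        if len(self.pinholes_planned) != 4:
            raise ValueError("a guide carries exactly 4 pinholes")
        d = np.linalg.norm(self.pinholes_planned.points - self.plane.origin, axis=1)
        if d.max() > self.footprint_size_mm:
            raise ValueError("pinholes lie outside the guide footprint")
        object.__setattr__(self, "slip_direction", np.asarray(self.slip_direction, float).reshape(3))

    @property
    def footprint_centroid(self) -> np.ndarray:
        return self.pinholes_planned.points.mean(axis=0)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "region": self.region,
            "footprint_size_mm": self.footprint_size_mm,
            "plane": self.plane.to_dict(),
            "pinholes_planned": self.pinholes_planned.to_dict(),
            "slip_direction": self.slip_direction.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseSpec":
        return cls(
            case_id=int(d["case_id"]),
            region=d["region"],
            footprint_size_mm=float(d["footprint_size_mm"]),
            plane=CuttingPlane.from_dict(d["plane"]),
            pinholes_planned=FiducialSet.from_dict(d["pinholes_planned"]),
            slip_direction=np.asarray(d.get("slip_direction", [0, 0, 0]), float),
        )


@dataclass(frozen=True)
class PlacementModel:
    """Stochastic model of how a user installs a guide with one method.

    Sigmas are the scales of the small pose perturbation every placement
    incurs; ``slip_prob``/``slip_scale_mm`` generate the rare large
    tangential slide of freehand placement on homogeneous bone;
    ``tissue_extra_sigma_mm`` is added to the translation scale when the
    phantom carries a soft-tissue layer.
    """

    method: str
    rot_sigma_deg: float
    trans_sigma_mm: float
    slip_prob: float = 0.0
    slip_scale_mm: float = 0.0
    tissue_extra_sigma_mm: float = 0.8

    def __post_init__(self):
        if min(self.rot_sigma_deg, self.trans_sigma_mm,
               self.slip_scale_mm, self.tissue_extra_sigma_mm) < 0:
            raise ValueError("sigmas must be >= 0")
        if not (0.0 <= self.slip_prob <= 1.0):
            raise ValueError("slip_prob must be in [0, 1]")

    @classmethod
    def freehand(cls) -> "PlacementModel":
        return cls("freehand", rot_sigma_deg=2.0, trans_sigma_mm=1.5,
                   slip_prob=0.15, slip_scale_mm=8.0)

    @classmethod
    def smartphone(cls) -> "PlacementModel":
        return cls("smartphone", rot_sigma_deg=1.0, trans_sigma_mm=0.5)

    @classmethod
    def hololens(cls) -> "PlacementModel":
        return cls("hololens", rot_sigma_deg=1.1, trans_sigma_mm=0.55)


def default_models() -> dict:
    return {
        "freehand": PlacementModel.freehand(),
        "smartphone": PlacementModel.smartphone(),
        "hololens": PlacementModel.hololens(),
    }


# ---------------------------------------------------------------------------
# Parametric shell surface

_THETA_SPAN = np.radians(100.0)   # azimuthal extent of the shell
_PHI_RANGE = (np.radians(20.0), np.radians(105.0))
_S_CENTER_UV = (0.75, 0.55)       # supra-acetabular notch in (u, v)
_S_DEPTH_FRAC = 0.035             # notch depth relative to size_mm
_S_SIGMA_UV = (0.030, 0.045)
_C_BAND_V = 0.10                  # Gaussian half-width of the crest band in v
_TEXTURE_AMP_FRAC = 0.010         # max texture amplitude relative to size_mm
_N_TEXTURE_BUMPS = 14


def _texture_bumps(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    """Seed-determined random bumps living on the featured half of the crest."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(0.40, 0.98, _N_TEXTURE_BUMPS)
    v = rng.uniform(0.0, 0.25, _N_TEXTURE_BUMPS)
    h = rng.uniform(-1.0, 1.0, _N_TEXTURE_BUMPS)
    su = rng.uniform(0.02, 0.05, _N_TEXTURE_BUMPS)
    sv = rng.uniform(0.03, 0.07, _N_TEXTURE_BUMPS)
    return u, v, h, su, sv


def _surface(spec: PhantomSpec, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Evaluate the shell surface at parameter coordinates (u, v) in [0,1]^2."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    s = spec.size_mm
    a, b, c = 0.55 * s, 0.30 * s, 0.50 * s
    theta = (u - 0.5) * _THETA_SPAN
    phi = _PHI_RANGE[0] + v * (_PHI_RANGE[1] - _PHI_RANGE[0])
    base = np.stack(
        [a * np.sin(phi) * np.cos(theta),
         b * np.sin(phi) * np.sin(theta),
         c * np.cos(phi)],
        axis=-1,
    )
    radial = base / np.linalg.norm(base, axis=-1, keepdims=True)

    # crest texture: only within the band, ramping up along u so the low-u
    # crest is homogeneous and the high-u crest is "featured"
    amp = _TEXTURE_AMP_FRAC * s * (1.0 - spec.crest_homogeneity)
    disp = np.zeros(np.broadcast_shapes(u.shape, v.shape))
    if amp > 0:
        band = np.exp(-0.5 * (v / _C_BAND_V) ** 2)
        ramp = np.clip((u - 0.35) / 0.30, 0.0, 1.0)
        bu, bv, bh, bsu, bsv = _texture_bumps(spec)
        for k in range(len(bu)):
            disp = disp + bh[k] * np.exp(
                -0.5 * (((u - bu[k]) / bsu[k]) ** 2 + ((v - bv[k]) / bsv[k]) ** 2)
            )
        disp = amp * band * ramp * disp

    # supra-acetabular notch: narrow, deep, always present
    u0, v0 = _S_CENTER_UV
    su, sv = _S_SIGMA_UV
    notch = -_S_DEPTH_FRAC * s * np.exp(
        -0.5 * (((u - u0) / su) ** 2 + ((v - v0) / sv) ** 2)
    )
    return base + (disp + notch)[..., None] * radial


def _surface_tangents(spec: PhantomSpec, u: float, v: float, eps: float = 1e-4):
    """Unit tangents along u and v at one parameter point."""
    du = (_surface(spec, np.array(u + eps), np.array(v)) -
          _surface(spec, np.array(u - eps), np.array(v)))
    dv = (_surface(spec, np.array(u), np.array(v + eps)) -
          _surface(spec, np.array(u), np.array(v - eps)))
    du = du / np.linalg.norm(du)
    dv = dv / np.linalg.norm(dv)
    return du, dv


def make_phantom_mesh(spec: PhantomSpec) -> TriangleMesh:
    """Generate the synthetic bone shell for ``spec`` (deterministic in seed).

    The result is an open curved shell (watertightness is not needed by any
    downstream step) of roughly ``2 (n_u-1)(n_v-1)`` triangles, with the
    generating spec stored in ``mesh.metadata`` so that :func:`make_cases`
    can place guides on the parametric surface.
    """
    uu, vv = np.meshgrid(np.linspace(0, 1, spec.n_u), np.linspace(0, 1, spec.n_v),
                         indexing="ij")
    verts = _surface(spec, uu, vv).reshape(-1, 3)

    idx = np.arange(spec.n_u * spec.n_v).reshape(spec.n_u, spec.n_v)
    f1 = np.stack([idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:]], axis=-1).reshape(-1, 3)
    f2 = np.stack([idx[:-1, :-1], idx[1:, 1:], idx[:-1, 1:]], axis=-1).reshape(-1, 3)
    faces = np.vstack([f1, f2])

    mesh = TriangleMesh(vertices=verts, faces=faces, process=False)
    mesh = clean_mesh(mesh)
    mesh.metadata["phantom_spec"] = {
        "seed": spec.seed,
        "size_mm": spec.size_mm,
        "crest_homogeneity": spec.crest_homogeneity,
        "tissue_thickness_mm": spec.tissue_thickness_mm,
        "n_u": spec.n_u,
        "n_v": spec.n_v,
    }
    return mesh


def _spec_from_mesh(phantom: TriangleMesh) -> PhantomSpec:
    meta = phantom.metadata.get("phantom_spec")
    if meta is None:
        raise ValueError(
            "mesh carries no phantom parameters; generate it with make_phantom_mesh "
            "or build CaseSpecs explicitly"
        )
    return PhantomSpec(**meta)


# (u position along crest, footprint mm) per case for the C region; cases 1
# and 4 are small guides on the homogeneous low-u crest, 3 and 5 large
# guides on the featured high-u crest, matching the size/location contrast
# the regional analysis examines.
_C_CASE_LAYOUT = {
    1: (0.18, 22.0),
    2: (0.32, 30.0),
    3: (0.72, 40.0),
    4: (0.26, 24.0),
    5: (0.62, 38.0),
    6: (0.47, 30.0),
}
_C_PLANE_V = 0.14
_S_FOOTPRINTS = {1: 16.0, 2: 15.0, 3: 18.0, 4: 14.0, 5: 17.0, 6: 16.0}
_PINHOLE_STANDOFF = 2.5  # mm; pinholes sit on the guide body above the bone


def _build_case(
    spec: PhantomSpec,
    phantom: TriangleMesh,
    case_id: int,
    region: str,
    u0: float,
    v0: float,
    footprint: float,
    normal_along: str,
) -> CaseSpec:
    origin = np.asarray(_surface(spec, np.array(u0), np.array(v0)), float).reshape(3)
    tu, tv = _surface_tangents(spec, u0, v0)
    normal = tu if normal_along == "u" else tv

    # pinhole rectangle in the local tangent frame, projected to the surface
    e1 = tu if normal_along == "v" else tv
    e2 = np.cross(e1, origin / np.linalg.norm(origin))
    e2 /= np.linalg.norm(e2)
    w, h = 0.40 * footprint, 0.25 * footprint
    corners = origin + np.array(
        [[-w, -h], [w, -h], [w, h], [-w, h]], float
    ) @ np.stack([e1, e2])
    on_surf, _ = closest_points_on_mesh(phantom, corners)
    outward = on_surf / np.linalg.norm(on_surf, axis=1, keepdims=True)
    pin_pts = on_surf + _PINHOLE_STANDOFF * outward
    pinholes = FiducialSet(
        tuple(f"case{case_id}{region}_pin{k}" for k in range(1, 5)), pin_pts, "bone"
    )
    return CaseSpec(
        case_id=case_id,
        region=region,
        footprint_size_mm=footprint,
        plane=CuttingPlane(origin, normal),
        pinholes_planned=pinholes,
        slip_direction=tu,
    )


def make_cases(phantom: TriangleMesh, seed: int = 0) -> list[tuple[CaseSpec, CaseSpec]]:
    """Six paired scenarios (S guide, C guide) on the synthetic phantom.

    C-region guides vary in footprint size and position along the crest
    band; S-region guides cluster around the narrow notch with smaller
    footprints. Positions get a small seeded jitter so different seeds give
    different but statistically equivalent experiments. Every plane is
    guaranteed to intersect the phantom (its origin lies on the surface and
    its normal is tangent to it).
    """
    spec = _spec_from_mesh(phantom)
    rng = np.random.default_rng(seed)
    cases = []
    for case_id in range(1, 7):
        u_c, size_c = _C_CASE_LAYOUT[case_id]
        u_c = float(np.clip(u_c + rng.normal(0, 0.015), 0.05, 0.95))
        c_spec = _build_case(spec, phantom, case_id, "C", u_c, _C_PLANE_V,
                             size_c, normal_along="u")
        u_s = float(np.clip(_S_CENTER_UV[0] + rng.normal(0, 0.012), 0.05, 0.95))
        v_s = float(np.clip(_S_CENTER_UV[1] + 0.08 + rng.normal(0, 0.010), 0.05, 0.95))
        s_spec = _build_case(spec, phantom, case_id, "S", u_s, v_s,
                             _S_FOOTPRINTS[case_id], normal_along="v")
        cases.append((s_spec, c_spec))
    return cases


# ---------------------------------------------------------------------------
# Stochastic placement and measurement


def simulate_placement(
    case: CaseSpec,
    model: PlacementModel,
    tissue_thickness_mm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> RigidTransform:
    """Draw one ground-truth placement perturbation (planned -> achieved).

    A rotation of magnitude ``|N(0, rot_sigma)|`` about a random axis through
    the footprint centroid, plus an isotropic Gaussian translation whose
    scale is inflated by ``tissue_extra_sigma_mm`` when a soft-tissue layer
    is present. On the homogeneous crest (region C) a freehand-style model
    with ``slip_prob > 0`` occasionally adds a large slide of magnitude
    ``slip_scale * (1 + Exp(1))`` along the crest direction — the
    heavy-tailed failure mode of unguided placement.
    """
    rng = rng if rng is not None else np.random.default_rng()
    trans_sigma = model.trans_sigma_mm
    if tissue_thickness_mm > 0:
        trans_sigma = trans_sigma + model.tissue_extra_sigma_mm

    angle = abs(rng.normal(0.0, np.radians(model.rot_sigma_deg)))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    delta = rng.normal(0.0, trans_sigma, size=3) if trans_sigma > 0 else np.zeros(3)

    if case.region == "C" and model.slip_prob > 0 and rng.random() < model.slip_prob:
        magnitude = model.slip_scale_mm * (1.0 + rng.exponential(1.0))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta = delta + sign * magnitude * case.slip_direction

    return RigidTransform.about_point(R, case.footprint_centroid, delta)


def simulate_pinhole_measurement(
    case: CaseSpec,
    placement: RigidTransform,
    pointer_sigma_mm: float = 0.2,
    rng: np.random.Generator | None = None,
) -> FiducialSet:
    """Tracked-pointer measurement of the placed guide's 4 pinholes (bone frame).

    The planned pinholes are moved by the achieved placement and perturbed
    by isotropic Gaussian pointer noise.
    """
    if pointer_sigma_mm < 0:
        raise ValueError("pointer_sigma_mm must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    pts = placement.apply(case.pinholes_planned.points)
    if pointer_sigma_mm > 0:
        pts = pts + rng.normal(0.0, pointer_sigma_mm, size=pts.shape)
    return FiducialSet(case.pinholes_planned.labels, pts, "bone")


def sample_surface_fiducials(
    mesh: TriangleMesh,
    n: int,
    rng: np.random.Generator,
    prefix: str = "pt",
    spread: bool = False,
) -> FiducialSet:
    """Random points on the mesh surface (area-weighted), as a FiducialSet.

    With ``spread=True`` a farthest-point subsample of a larger candidate
    pool is returned — appropriate for registration landmarks, which should
    cover the bone rather than cluster.
    """
    n_cand = max(n * 30, 60) if spread else n
    face_p = mesh.area_faces / mesh.area_faces.sum()
    fi = rng.choice(len(mesh.faces), size=n_cand, p=face_p)
    r1, r2 = rng.random(n_cand), rng.random(n_cand)
    swap = r1 + r2 > 1
    r1[swap], r2[swap] = 1 - r1[swap], 1 - r2[swap]
    tri = mesh.triangles[fi]
    pts = tri[:, 0] + r1[:, None] * (tri[:, 1] - tri[:, 0]) + r2[:, None] * (tri[:, 2] - tri[:, 0])
    if spread:
        chosen = [int(rng.integers(n_cand))]
        d = np.linalg.norm(pts - pts[chosen[0]], axis=1)
        for _ in range(n - 1):
            nxt = int(d.argmax())
            chosen.append(nxt)
            d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
        pts = pts[chosen]
    return FiducialSet(tuple(f"{prefix}{k}" for k in range(n)), pts, "bone")


def random_rigid_transform(
    rng: np.random.Generator, angle_deg: float = 10.0, translation_mm: float = 20.0
) -> RigidTransform:
    """A rigid motion with the given rotation magnitude and translation norm."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    t_dir = rng.normal(size=3)
    t_dir /= np.linalg.norm(t_dir)
    return RigidTransform(R, translation_mm * t_dir)
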