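import numpy as np
import pytest
import trimesh

from psiplace import PhantomSpec, make_cases, make_phantom_mesh


@pytest.fixture(scope="session")
def phantom():
    return make_phantom_mesh(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def cases(phantom):
    return make_cases(phantom, seed=0)


@pytest.fixture(scope="session")
def cylinder():
    """Fine right cylinder, radius 20 mm, axis z, for closed-form sections."""
    return trimesh.creation.cylinder(radius=20.0, height=60.0, sections=256)


@pytest.fixture(scope="session")
def coarse_cylinder():
    """Coarse mesh (< 500 faces) for exhaustive brute-force oracles."""
    mesh = trimesh.creation.cylinder(radius=20.0, height=60.0, sections=48)
    assert len(mesh.faces) <= 500
    return mesh


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def brute_force_rigid_rms(moving, fixed):
    """Independent numerical least-squares oracle for rigid registration.

    Multi-start BFGS over the 6-parameter angle-axis + translation space;
    returns the best RMS residual found. Deliberately shares no code with
    the closed-form solver it is used to check.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    def cost(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        res = moving @ R.T + x[3:] - fixed
        return (res**2).sum()

    best = np.inf
    for seed in range(6):
        gen = np.random.default_rng(seed)
        x0 = np.concatenate([
            gen.normal(scale=0.5, size=3),
            fixed.mean(0) - moving.mean(0) + gen.normal(scale=1.0, size=3),
        ])
        r = minimize(cost, x0, method="BFGS", options={"gtol": 1e-12, "maxiter": 2000})
        best = min(best, r.fun)
    return np.sqrt(best / len(moving))


@pytest.fixture(scope="session")
def rigid_rms_oracle():
    return brute_force_rigid_rms
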