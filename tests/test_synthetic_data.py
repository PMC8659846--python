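import numpy as np
import pytest
import trimesh

from psiplace import (
    PhantomSpec,
    PlacementModel,
    assess_placement,
    make_cases,
    make_phantom_mesh,
    plan_to_real,
    simulate_placement,
    simulate_pinhole_measurement,
)
from psiplace.synthetic_data import _S_CENTER_UV, default_models


class TestPhantom:
    def test_same_seed_same_mesh(self):
        a = make_phantom_mesh(PhantomSpec(seed=11))
        b = make_phantom_mesh(PhantomSpec(seed=11))
        np.testing.assert_array_equal(a.vertices, b.vertices)
        np.testing.assert_array_equal(a.faces, b.faces)

    def test_different_seed_different_texture(self):
        a = make_phantom_mesh(PhantomSpec(seed=1, crest_homogeneity=0.0))
        b = make_phantom_mesh(PhantomSpec(seed=2, crest_homogeneity=0.0))
        assert not np.allclose(a.vertices, b.vertices)

    def test_face_count_at_default_resolution(self, phantom):
        assert len(phantom.faces) >= 5000

    def test_scaling_doubles_bounding_diagonal(self):
        small = make_phantom_mesh(PhantomSpec(seed=3, size_mm=150.0))
        large = make_phantom_mesh(PhantomSpec(seed=3, size_mm=300.0))
        ratio = np.linalg.norm(large.extents) / np.linalg.norm(small.extents)
        assert abs(ratio - 2.0) < 1e-6

    def test_homogeneous_crest_has_lower_curvature_than_notch(self):
        """With crest_homogeneity=1 the C band is smooth while the S notch
        stays sharply curved — the regional contrast the study relies on."""
        spec = PhantomSpec(seed=0, crest_homogeneity=1.0)
        mesh = make_phantom_mesh(spec)
        assert len(mesh.vertices) == spec.n_u * spec.n_v  # grid order preserved
        defects = np.abs(trimesh.curvature.vertex_defects(mesh))
        uu, vv = np.meshgrid(np.linspace(0, 1, spec.n_u), np.linspace(0, 1, spec.n_v),
                             indexing="ij")
        u, v = uu.ravel(), vv.ravel()
        c_band = (v > 0.02) & (v < 0.25) & (u > 0.08) & (u < 0.92)
        u0, v0 = _S_CENTER_UV
        s_area = (np.abs(u - u0) < 0.08) & (np.abs(v - v0) < 0.10)
        assert defects[c_band].max() < defects[s_area].max()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(crest_homogeneity=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(tissue_thickness_mm=-1.0)


class TestCases:
    def test_six_paired_cases(self, cases):
        assert len(cases) == 6
        for s_spec, c_spec in cases:
            assert s_spec.region == "S"
            assert c_spec.region == "C"
            assert s_spec.case_id == c_spec.case_id

    def test_every_plane_intersects_phantom(self, phantom, cases):
        from psiplace import intersect_plane_mesh

        for pair in cases:
            for case in pair:
                cs = intersect_plane_mesh(phantom, case.plane, spacing=0.5)
                assert len(cs) >= 2

    def test_s_footprints_smaller_than_c(self, cases):
        for s_spec, c_spec in cases:
            assert s_spec.footprint_size_mm < c_spec.footprint_size_mm

    def test_c_footprints_vary_in_size_and_position(self, cases):
        sizes = [c.footprint_size_mm for _, c in cases]
        origins = np.array([c.plane.origin for _, c in cases])
        assert max(sizes) - min(sizes) >= 10.0
        assert np.linalg.norm(origins - origins.mean(0), axis=1).max() > 10.0

    def test_pinholes_close_to_surface(self, phantom, cases):
        from psiplace import closest_points_on_mesh

        for pair in cases:
            for case in pair:
                _, d = closest_points_on_mesh(phantom, case.pinholes_planned.points)
                # pinholes sit on the guide body, a few mm off the bone
                assert d.max() < 6.0

    def test_same_seed_same_cases(self, phantom):
        a = make_cases(phantom, seed=5)
        b = make_cases(phantom, seed=5)
        for (sa, ca), (sb, cb) in zip(a, b):
            np.testing.assert_array_equal(sa.pinholes_planned.points, sb.pinholes_planned.points)
            np.testing.assert_array_equal(ca.plane.origin, cb.plane.origin)


class TestPlacementModel:
    def test_zero_noise_gives_identity(self, cases, rng):
        model = PlacementModel("freehand", rot_sigma_deg=0.0, trans_sigma_mm=0.0)
        T = simulate_placement(cases[0][1], model, 0.0, rng)
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-12)

    def test_certain_slip_gives_large_translation(self, cases, rng):
        model = PlacementModel("freehand", rot_sigma_deg=0.0, trans_sigma_mm=0.0,
                               slip_prob=1.0, slip_scale_mm=8.0)
        T = simulate_placement(cases[0][1], model, 0.0, rng)
        assert np.linalg.norm(T.translation) >= 8.0

    def test_slip_confined_to_crest_region(self, cases, rng):
        model = PlacementModel("freehand", rot_sigma_deg=0.0, trans_sigma_mm=0.0,
                               slip_prob=1.0, slip_scale_mm=8.0)
        T = simulate_placement(cases[0][0], model, 0.0, rng)  # S region
        np.testing.assert_allclose(T.matrix, np.eye(4), atol=1e-12)

    def test_tissue_layer_inflates_translation_scale(self, cases):
        model = PlacementModel.smartphone()
        norms = {}
        for tissue in (0.0, 2.0):
            rng = np.random.default_rng(99)
            draws = [simulate_placement(cases[0][1], model, tissue, rng)
                     for _ in range(400)]
            norms[tissue] = np.median([np.linalg.norm(T.translation) for T in draws])
        assert norms[2.0] > norms[0.0]

    def test_freehand_mod_exceeds_ar_mod(self, phantom, cases):
        """Monte-Carlo on one crest case: the freehand error model must give
        larger median deviations than the AR-guided models."""
        from psiplace import NoIntersectionError

        case = cases[0][1]
        rng = np.random.default_rng(4)
        mods = {}
        for name, model in default_models().items():
            draws = []
            for _ in range(60):
                T = simulate_placement(case, model, 0.0, rng)
                try:
                    draws.append(assess_placement(phantom, case.plane, T, spacing=0.25).mod)
                except NoIntersectionError:
                    draws.append(np.inf)  # slid clean off the bone: gross failure
            mods[name] = np.median(draws)
        assert mods["freehand"] > mods["smartphone"]
        assert mods["freehand"] > mods["hololens"]

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            PlacementModel("freehand", rot_sigma_deg=-1.0, trans_sigma_mm=0.0)
        with pytest.raises(ValueError):
            PlacementModel("freehand", rot_sigma_deg=0.0, trans_sigma_mm=0.0, slip_prob=1.5)


class TestPinholeMeasurement:
    def test_noiseless_identity_reproduces_planned(self, cases, rng):
        case = cases[0][1]
        from psiplace import RigidTransform

        fs = simulate_pinhole_measurement(case, RigidTransform.identity(), 0.0, rng)
        np.testing.assert_allclose(fs.points, case.pinholes_planned.points)

    def test_noiseless_measurement_closes_the_loop(self, cases, rng):
        case = cases[0][1]
        model = PlacementModel.freehand()
        placement = simulate_placement(case, model, 0.0, rng)
        measured = simulate_pinhole_measurement(case, placement, 0.0, rng)
        est = plan_to_real(case.pinholes_planned, measured).transform
        assert np.abs(est.matrix - placement.matrix).max() < 1e-9

    def test_pointer_noise_translation_error_bounded(self, cases, rng):
        """Mean recovered-translation error under 0.2 mm pointer noise."""
        case = cases[0][1]
        from psiplace import RigidTransform

        centroid = case.footprint_centroid
        errors = []
        for _ in range(500):
            measured = simulate_pinhole_measurement(case, RigidTransform.identity(), 0.2, rng)
            est = plan_to_real(case.pinholes_planned, measured).transform
            errors.append(np.linalg.norm(est.apply(centroid) - centroid))
        assert np.mean(errors) < 0.4
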