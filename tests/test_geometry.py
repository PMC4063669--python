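"""Referential extraction, rigid transforms, shape maps and registration."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from atlasforge import (
    EmbryoSpec, NucleusSet, RigidTransform, VolumeImage, apply_transform,
    build_frame, cohort_radius_report, fit_margin_plane, fit_sphere,
    frame_alignment_transform, register_rigid, select_outer_nuclei,
    shape_weight_map,
)
from atlasforge.synthetic import true_nucleus_layout


def _sphere_points(rng, center, radius, n, noise=0.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return center + radius * v + rng.normal(scale=noise, size=(n, 3))


class TestRigidTransform:
    def test_round_trip_and_composition(self, rng):
        t = RigidTransform.random(rng, 1.0, 20.0)
        pts = rng.uniform(-50, 50, (100, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)
        u = RigidTransform.random(rng, 1.0, 20.0)
        np.testing.assert_allclose(t.compose(u).apply(pts), t.apply(u.apply(pts)),
                                   atol=1e-9)

    def test_improper_rotation_rejected(self):
        refl = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            RigidTransform(refl, np.zeros(3))

    def test_serialization_round_trip(self, rng):
        t = RigidTransform.random(rng, 0.5, 5.0)
        back = RigidTransform.from_dict(t.to_dict())
        np.testing.assert_allclose(back.rotation, t.rotation)
        np.testing.assert_allclose(back.translation, t.translation)


class TestFitSphere:
    def test_exact_recovery_from_axis_points(self):
        c = np.array([1.0, 2.0, 3.0])
        pts = c + 10.0 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                                   [0, -1, 0], [0, 0, 1], [0, 0, -1]], float)
        center, radius, rms = fit_sphere(pts)
        np.testing.assert_allclose(center, c, atol=1e-9)
        assert radius == pytest.approx(10.0)
        assert rms < 1e-9

    def test_noisy_fit_matches_iterative_geometric_oracle(self, rng):
        c, r = np.array([5.0, -3.0, 12.0]), 40.0
        pts = _sphere_points(rng, c, r, 500, noise=0.1)
        center, radius, _ = fit_sphere(pts)

        def residuals(p):
            return np.linalg.norm(pts - p[:3], axis=1) - p[3]

        sol = least_squares(residuals, x0=[0, 0, 0, 30.0]).x
        assert np.linalg.norm(center - sol[:3]) < 0.05
        assert abs(radius - sol[3]) < 0.05

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.raises(ValueError, match="degenerate|coplanar"):
            fit_sphere(pts)


class TestSelectOuterNuclei:
    def test_two_layer_cap_selects_outer_layer(self, rng):
        inner = _sphere_points(rng, np.zeros(3), 80.0, 200)
        outer = _sphere_points(rng, np.zeros(3), 100.0, 200)
        ns = NucleusSet(np.vstack([inner, outer]))
        sel = select_outer_nuclei(ns, fraction=0.5)
        radii = np.linalg.norm(sel.centers, axis=1)
        assert np.all(radii > 90.0)

    def test_single_exact_layer_keeps_all(self, rng):
        # antipodal pairs: the centroid is the exact sphere centre, so every
        # nucleus sits at the same radius and the whole layer is the shell
        half = _sphere_points(rng, np.zeros(3), 50.0, 50)
        ns = NucleusSet(np.vstack([half, -half]))
        assert len(select_outer_nuclei(ns, fraction=0.5)) == len(ns)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            select_outer_nuclei(NucleusSet(np.empty((0, 3))))


class TestFitMarginPlane:
    def test_synthetic_cap_margin_recovered(self, default_embryo, true_nuclei):
        spec, _, _, truth = default_embryo
        normal, offset = fit_margin_plane(true_nuclei, fraction=0.05,
                                          provisional_av=(0, 0, 1))
        z_margin = truth.sphere_center[2] + spec.sphere_radius * spec.cap_cos_theta
        angle = np.degrees(np.arccos(np.clip(normal @ [0, 0, 1], -1, 1)))
        assert angle <= 2.0
        assert abs(offset - z_margin) <= 0.5 * true_nuclei.ind

    def test_exactly_planar_nuclei_give_that_plane(self, rng):
        xy = rng.uniform(0, 100, (50, 2))
        pts = np.column_stack([xy, np.full(50, 17.0)])
        normal, offset = fit_margin_plane(NucleusSet(pts), fraction=0.5)
        np.testing.assert_allclose(np.abs(normal), [0, 0, 1], atol=1e-9)
        assert offset == pytest.approx(17.0 * np.sign(normal[2]))

    def test_hemisphere_margin_lies_below_equator(self, rng):
        pts = _sphere_points(rng, np.zeros(3), 50.0, 600)
        pts = pts[pts[:, 2] >= 0]  # upper hemisphere
        _, offset = fit_margin_plane(NucleusSet(pts), fraction=0.5)
        assert offset < 25.0  # median latitude of a hemisphere is above z=0

    def test_too_few_selected_rejected(self):
        ns = NucleusSet(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [4, 4, 4.0]]))
        with pytest.raises(ValueError, match="at least 3"):
            fit_margin_plane(ns, fraction=0.05)


class TestBuildFrame:
    def test_matches_analytic_frame_of_synthetic_embryo(self, default_embryo,
                                                        true_nuclei):
        spec, _, _, truth = default_embryo
        frame = build_frame(true_nuclei, truth.true_positive_flags["gsc"])
        true = truth.true_frame
        for mine, ref in [(frame.u, true.u), (frame.v, true.v), (frame.w, true.w)]:
            angle = np.degrees(np.arccos(np.clip(mine @ ref, -1, 1)))
            assert angle <= 2.0
        on_sphere = abs(np.linalg.norm(frame.origin - frame.sphere_center)
                        - frame.sphere_radius)
        assert on_sphere <= 1e-3 * frame.sphere_radius

    def test_equivariance_under_rigid_motion(self, true_nuclei, default_embryo,
                                             rng):
        _, _, _, truth = default_embryo
        flags = truth.true_positive_flags["gsc"]
        frame = build_frame(true_nuclei, flags)
        t = RigidTransform.from_axis_angle([0.2, 0.3, 1.0], 0.4, [30.0, -10.0, 20.0])
        moved = NucleusSet(t.apply(true_nuclei.centers))
        frame2 = build_frame(moved, flags, provisional_av=t.rotation @ [0, 0, 1])
        np.testing.assert_allclose(frame2.u, t.rotation @ frame.u, atol=1e-6)
        np.testing.assert_allclose(frame2.v, t.rotation @ frame.v, atol=1e-6)
        np.testing.assert_allclose(frame2.origin, t.apply(frame.origin), atol=1e-3)

    def test_gsc_centroid_on_av_axis_is_degenerate(self):
        # structured cap of rings: the southernmost ring is exactly planar so
        # the margin normal is exactly the AV axis, and the positives form an
        # axis-symmetric polar ring whose centroid lies on that axis
        rings = []
        for k, z in enumerate([10.0, 20.0, 30.0, 40.0]):
            radius = np.sqrt(50.0 ** 2 - z ** 2)
            ang = np.linspace(0, 2 * np.pi, 16, endpoint=False) + 0.1 * k
            rings.append(np.column_stack([radius * np.cos(ang),
                                          radius * np.sin(ang),
                                          np.full(16, z)]))
        pts = np.vstack(rings)
        flags = np.zeros(len(pts), bool)
        flags[-16:] = True  # the top ring
        with pytest.raises(ValueError, match="degenerate dorsal"):
            build_frame(NucleusSet(pts), flags)


class TestFrameAlignment:
    def test_identity_and_known_motion(self, default_embryo, true_nuclei):
        _, _, _, truth = default_embryo
        flags = truth.true_positive_flags["gsc"]
        frame = build_frame(true_nuclei, flags)
        ident = frame_alignment_transform(frame, frame)
        assert ident.rotation_angle_deg < 1e-9
        np.testing.assert_allclose(ident.translation, 0, atol=1e-9)
        t = RigidTransform.from_axis_angle([1, 2, 0.5], 0.3, [12.0, -5.0, 8.0])
        moved = build_frame(NucleusSet(t.apply(true_nuclei.centers)), flags,
                            provisional_av=t.rotation @ [0, 0, 1])
        align = frame_alignment_transform(moved, frame)
        np.testing.assert_allclose(align.rotation, t.inverse().rotation, atol=1e-6)
        np.testing.assert_allclose(align.translation, t.inverse().translation,
                                   atol=1e-3)

    def test_alignment_composition_is_consistent(self, default_embryo,
                                                 true_nuclei):
        _, _, _, truth = default_embryo
        flags = truth.true_positive_flags["gsc"]
        f0 = build_frame(true_nuclei, flags)
        t1 = RigidTransform.from_axis_angle([0, 0, 1], 0.2, [5.0, 0, 0])
        t2 = RigidTransform.from_axis_angle([1, 0, 0], 0.1, [0, -4.0, 2.0])
        f1 = build_frame(NucleusSet(t1.apply(true_nuclei.centers)), flags,
                         provisional_av=t1.rotation @ [0, 0, 1])
        f2 = build_frame(NucleusSet(t2.apply(t1.apply(true_nuclei.centers))), flags,
                         provisional_av=(t2.rotation @ t1.rotation) @ [0, 0, 1])
        direct = frame_alignment_transform(f2, f0)
        composed = frame_alignment_transform(f1, f0).compose(
            frame_alignment_transform(f2, f1))
        np.testing.assert_allclose(direct.rotation, composed.rotation, atol=1e-9)
        np.testing.assert_allclose(direct.translation, composed.translation,
                                   atol=1e-6)


class TestShapeWeightMap:
    def test_weight_profile_along_a_ray(self):
        ns = NucleusSet(np.array([[40.0, 40.0, 40.0]]))
        vol = shape_weight_map(ns, ind=10.0, spacing=(2.0, 2.0, 2.0),
                               shape=(40, 40, 40))
        profile = vol.values[20:, 20, 20]
        peak = int(np.argmax(profile))
        assert profile.max() <= 1.0
        assert profile.max() >= 1.0 / (1.0 + 2.0 / 10.0)  # within half a voxel
        assert np.all(np.diff(profile[:peak + 1]) >= -1e-9)  # rises to contour
        assert np.all(profile[peak + 1:][profile[peak + 1:] > 0]
                      <= profile[peak])  # never exceeds the contour weight
        assert profile[-1] == 0.0  # zero far outside

    def test_map_rotates_with_the_point_set(self, rng):
        spec = EmbryoSpec(seed=6, n_nuclei=120, sphere_radius=60.0)
        centers, sphere_center = true_nucleus_layout(spec)
        ns = NucleusSet(centers)
        t = RigidTransform.from_axis_angle([0, 0, 1], np.pi / 2,
                                           center=sphere_center)
        vol = shape_weight_map(ns, ns.ind, spacing=(3, 3, 3))
        rotated_pts = shape_weight_map(NucleusSet(t.apply(centers)), ns.ind,
                                       spacing=(3, 3, 3), shape=vol.shape)
        rotated_map = apply_transform(vol, t, reference=rotated_pts)
        sel = rotated_pts.values > 0.2
        diff = np.abs(rotated_pts.values[sel] - rotated_map.values[sel])
        assert np.median(diff) < 0.05


class TestRegisterRigid:
    def test_self_registration_is_identity(self, true_nuclei):
        vol = shape_weight_map(true_nuclei, true_nuclei.ind, spacing=(4, 4, 4))
        est, cc = register_rigid(vol, vol)
        assert cc == pytest.approx(1.0, abs=1e-6)
        assert est.rotation_angle_deg < 0.05
        assert np.linalg.norm(est.translation) < 0.05

    def test_recovers_small_misalignment(self):
        spec = EmbryoSpec(seed=8, n_nuclei=300, sphere_radius=100.0)
        centers, sphere_center = true_nucleus_layout(spec)
        ns = NucleusSet(centers)
        t = RigidTransform.from_axis_angle([0.3, 1.0, 0.2], np.radians(3.0),
                                           [8.0, -6.0, 5.0], center=sphere_center)
        fixed = shape_weight_map(ns, ns.ind, spacing=(3, 3, 3))
        moving = shape_weight_map(NucleusSet(t.apply(centers)), ns.ind,
                                  spacing=(3, 3, 3), shape=fixed.shape)
        est, cc = register_rigid(moving, fixed)
        assert est.compose(t).rotation_angle_deg <= 1.0
        disp = np.linalg.norm(est.apply(t.apply(centers)) - centers, axis=1).mean()
        assert disp <= 0.5 * ns.ind

    def test_far_initialization_never_degrades_the_metric(self, true_nuclei):
        # monotone acceptance: the returned cc is at least the cc at init
        vol = shape_weight_map(true_nuclei, true_nuclei.ind, spacing=(4, 4, 4))
        far = RigidTransform.from_axis_angle([0, 0, 1], np.radians(40.0),
                                             center=vol.extent / 2)
        est, cc = register_rigid(vol, vol, init=far)

        def ncc(t):
            resampled = apply_transform(vol, t, reference=vol)
            a, b = resampled.values.ravel(), vol.values.ravel()
            return np.corrcoef(a, b)[0, 1]

        assert cc >= ncc(far) - 1e-3


class TestApplyTransform:
    def test_identity_returns_input(self, rng):
        vol = VolumeImage(rng.uniform(size=(12, 10, 8)).astype(np.float32), (2, 2, 2))
        out = apply_transform(vol, RigidTransform.identity())
        np.testing.assert_allclose(out.values, vol.values, atol=1e-5)

    def test_whole_voxel_translation_equals_index_shift(self, rng):
        vol = VolumeImage(rng.uniform(size=(16, 14, 10)).astype(np.float32),
                          (2.0, 2.0, 4.0))
        t = RigidTransform(np.eye(3), [4.0, 2.0, 8.0])  # (2, 1, 2) voxels
        out = apply_transform(vol, t)
        expected = np.zeros_like(vol.values)
        expected[2:, 1:, 2:] = vol.values[:-2, :-1, :-2]
        np.testing.assert_allclose(out.values, expected, atol=1e-5)


class TestCohortRadiusReport:
    @pytest.mark.parametrize("radii,expected", [
        ([10.0, 10.0, 10.0], 1.0),
        ([9.0, 10.0, 11.0], 1.0),
        ([10.0, 10.0, 13.0], 2 / 3),
    ])
    def test_fraction_within_ten_percent(self, radii, expected):
        assert cohort_radius_report(radii) == pytest.approx(expected)
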