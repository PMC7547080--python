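"""Lens frame fitting, alignment and spherical mapping."""

import math

import numpy as np
import pytest

from lensmap3d.geometry import (
    AmbiguousOrientationError,
    DegenerateLandmarksError,
    NoPoleFoundError,
    align_to_canonical,
    angle_between_deg,
    build_frame,
    find_anterior_pole,
    fit_circle_3pt,
    fit_spheroid,
    lens_metrics,
    orient_normal,
    radial_distances,
    rotation_to_z,
    spherical_coordinates,
)
from lensmap3d.pipeline import map_points
from lensmap3d.synthetic import (
    apply_tilt,
    boundary_landmarks,
    mature_config,
    sample_epithelium,
    young_config,
)


def circle_points(center, radius, normal, angles_deg):
    """Analytic construction of points on a 3D circle."""
    n = np.asarray(normal, dtype=float)
    n /= np.linalg.norm(n)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(n @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    out = []
    for a in np.radians(angles_deg):
        out.append(np.asarray(center) + radius * (math.cos(a) * u + math.sin(a) * v))
    return np.array(out)


class TestCircleFit:
    def test_unit_circle(self):
        c, r, n = fit_circle_3pt((1, 0, 0), (0, 1, 0), (-1, 0, 0))
        np.testing.assert_allclose(c, 0.0, atol=1e-12)
        assert r == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(n), (0, 0, 1), atol=1e-12)

    def test_analytic_circle_recovered(self):
        center = np.array([2.0, 3.0, 5.0])
        normal = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        pts = circle_points(center, 4.0, normal, [10, 130, 250])
        c, r, n = fit_circle_3pt(*pts)
        np.testing.assert_allclose(c, center, atol=1e-9)
        assert r == pytest.approx(4.0, abs=1e-9)
        assert min(np.linalg.norm(n - normal), np.linalg.norm(n + normal)) < 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateLandmarksError):
            fit_circle_3pt((0, 0, 0), (1, 1, 1), (2, 2, 2))


class TestOrientNormal:
    def test_flips_toward_data(self, rng):
        pts = rng.normal(size=(40, 3))
        pts[:, 2] = np.abs(pts[:, 2]) + 0.1
        n = orient_normal(pts, np.zeros(3), np.array([0, 0, -1.0]))
        np.testing.assert_allclose(n, (0, 0, 1))
        n2 = orient_normal(pts, np.zeros(3), np.array([0, 0, 1.0]))
        np.testing.assert_allclose(n2, (0, 0, 1))

    def test_balanced_cloud_is_ambiguous(self):
        pts = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        with pytest.raises(AmbiguousOrientationError):
            orient_normal(pts, np.zeros(3), np.array([0, 0, 1.0]))

    def test_mature_cloud_oriented_anterior(self, mature_truth):
        cfg = mature_truth.config
        pts = mature_truth.true_xyz()
        lm = boundary_landmarks(cfg)
        c, _, n_raw = fit_circle_3pt(*lm)
        n = orient_normal(pts, c, n_raw)
        anterior = apply_tilt(np.array([[0.0, 0.0, 1.0]]), cfg.tilt_deg)[0]
        assert n @ anterior > 0.9


class TestAnteriorPole:
    def test_point_on_ray_selected(self):
        pts = np.array([[0, 0, 0.7], [0.3, 0, 0.5], [0, 0.4, 0.2]])
        ap, idx = find_anterior_pole(pts, np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        assert idx == 0
        np.testing.assert_allclose(ap, (0, 0, 0.7))

    def test_tie_broken_by_larger_t(self):
        pts = np.array([[0, 0, 0.4], [0, 0, 0.9]])
        ap, idx = find_anterior_pole(pts, np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        assert idx == 1

    def test_empty_and_far_clouds_raise(self):
        with pytest.raises(NoPoleFoundError):
            find_anterior_pole(np.empty((0, 3)), np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        with pytest.raises(NoPoleFoundError):
            find_anterior_pole(
                np.array([[0.5, 0.5, 0.5]]), np.zeros(3), np.array([0, 0, 1.0]), 1.0
            )


class TestSpheroidFit:
    def test_exact_recovery_from_surface_points(self, rng):
        a, b = 1000.0, 700.0
        center = np.array([5.0, -3.0, 12.0])
        theta = np.arccos(rng.uniform(-0.4, 1.0, 500))
        phi = rng.uniform(0, 2 * np.pi, 500)
        pts = center + np.column_stack(
            [a * np.sin(theta) * np.cos(phi), a * np.sin(theta) * np.sin(phi),
             b * np.cos(theta)]
        )
        c, ra, rb = fit_spheroid(pts)
        np.testing.assert_allclose(c, center, atol=1e-6)
        assert ra == pytest.approx(a, abs=1e-6)
        assert rb == pytest.approx(b, abs=1e-6)


class TestAlignment:
    def test_canonical_cloud_keeps_identity(self):
        cfg = mature_config(seed=3, tilt_deg=0.0)
        truth = sample_epithelium(cfg)
        frame = build_frame(truth.true_xyz(), boundary_landmarks(cfg))
        np.testing.assert_allclose(frame.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(frame.center, 0.0, atol=1e-6)

    def test_mounting_tilt_realigned(self):
        """A 35-degree mounted cloud realigns with the pole on +z."""
        cfg = mature_config(seed=3, tilt_deg=35.0)
        truth = sample_epithelium(cfg)
        pts = np.vstack([truth.true_xyz(),
                         apply_tilt(np.array([[0.0, 0.0, cfg.r_min]]), 35.0)])
        frame = build_frame(pts, boundary_landmarks(cfg))
        aligned = align_to_canonical(pts, frame)
        ap_aligned = aligned[-1]
        assert np.hypot(ap_aligned[0], ap_aligned[1]) < 1e-6
        assert angle_between_deg(frame.normal, [0, 0, 1]) == pytest.approx(
            35.0, abs=1e-6
        )

    def test_rigid_motion_preserves_pairwise_distances(self, rng):
        pts = rng.normal(size=(30, 3)) * 50
        rot = rotation_to_z(rng.normal(size=3))
        moved = pts @ rot.T + rng.normal(size=3) * 100

        def pdist(p):
            return np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)

        np.testing.assert_allclose(pdist(moved), pdist(pts), rtol=1e-9, atol=1e-9)

    def test_rotation_to_z_sends_normal_to_z(self, rng):
        for _ in range(5):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            np.testing.assert_allclose(rotation_to_z(n) @ n, (0, 0, 1), atol=1e-12)


class TestSphericalCoordinates:
    def test_pole_and_equator_angles(self):
        theta, phi = spherical_coordinates(
            np.array([[0, 0, 700.0], [1000.0, 0, 0], [0, -1000.0, 0]]), 1000.0, 700.0
        )
        np.testing.assert_allclose(theta, (0.0, 90.0, 90.0), atol=1e-12)
        assert phi[1] == pytest.approx(0.0)
        assert phi[2] == pytest.approx(270.0)

    def test_origin_point_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            spherical_coordinates(np.zeros((1, 3)), 1.0, 1.0)

    def test_equatorial_landmark_maps_to_90_on_sphere(self, rng):
        """With landmarks on a sphere's true equator, the bare 3-point
        frame puts the first landmark at theta = 90."""
        r = 500.0
        theta = np.arccos(rng.uniform(-0.3, 1.0, 400))
        phi = rng.uniform(0, 2 * np.pi, 400)
        pts = r * np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        pts[0] = (0, 0, r)  # exact pole nucleus
        lm = circle_points((0, 0, 0), r, (0, 0, 1), [0, 120, 240])
        frame = build_frame(pts, lm, refine=False)
        t_lm, _ = spherical_coordinates(
            align_to_canonical(lm, frame), frame.r_max, frame.r_min
        )
        np.testing.assert_allclose(t_lm, 90.0, atol=1e-6)

    def test_assigned_theta_matches_generator_truth(self, mature_truth):
        mapped, _ = map_points(
            mature_truth.points, boundary_landmarks(mature_truth.config)
        )
        err = mapped["theta_deg"] - mature_truth.points["true_theta_deg"]
        assert float(np.sqrt(np.mean(err**2))) < 1.0


class TestFrameMetrics:
    def test_unit_sphere_metrics(self, rng):
        r = 1.0
        theta = np.arccos(rng.uniform(-0.2, 1.0, 300))
        phi = rng.uniform(0, 2 * np.pi, 300)
        pts = r * np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        pts[0] = (0, 0, 1.0)
        lm = circle_points((0, 0, 0), r, (0, 0, 1), [10, 130, 250])
        frame = build_frame(pts, lm, refine=False)
        m = lens_metrics(frame)
        assert m["aspect_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert m["hemisphere_volume_um3"] == pytest.approx(2 * np.pi / 3, rel=1e-6)
        np.testing.assert_allclose(
            radial_distances(frame), (1.0, 1.0, 1.0, 1.0), atol=1e-9
        )

    def test_aspect_ratio_recovered_per_preset(self):
        for factory, aspect in ((mature_config, 0.7), (young_config, 0.9)):
            cfg = factory(seed=1)
            truth = sample_epithelium(cfg)
            frame = build_frame(truth.true_xyz(), boundary_landmarks(cfg))
            assert frame.aspect_ratio == pytest.approx(aspect, abs=0.02)

    def test_scaling_homogeneity_of_distances(self):
        cfg = mature_config(seed=4, tilt_deg=0.0)
        truth = sample_epithelium(cfg)
        lm = boundary_landmarks(cfg)
        f1 = build_frame(truth.true_xyz(), lm)
        f2 = build_frame(2.0 * truth.true_xyz(), 2.0 * lm)
        np.testing.assert_allclose(f2.D, 2.0 * np.asarray(f1.D), rtol=1e-6)
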