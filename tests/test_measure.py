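"""Axis estimation, section fans, loop intersection, AMD computation."""

import numpy as np
import pytest

from fdpfit.margins import MarginLoop
from fdpfit.measure import (
    AxisFrame,
    build_section_fan,
    classify_acceptability,
    compute_amd,
    estimate_axis,
    intersect_loop_with_fan,
    measure_retainer_amd,
    summarize_prosthesis,
)
from fdpfit.registration import RigidTransform


def circle_loop(radius=4.0, z=0.0, n=720, center=(0.0, 0.0)):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return MarginLoop(
        np.column_stack([
            radius * np.cos(theta) + center[0],
            radius * np.sin(theta) + center[1],
            np.full(n, z),
        ]),
        closed=True,
    )


class TestAxis:
    def test_planar_circle_gives_plus_z(self):
        lp = circle_loop()
        surface = np.array([[0.0, 0.0, 5.0]])  # preparation bulk above
        ax = estimate_axis(lp, surface)
        np.testing.assert_allclose(ax.direction, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(ax.origin, [0, 0, 0], atol=1e-9)
        np.testing.assert_allclose(ax.azimuth_ref, [1, 0, 0], atol=1e-9)

    def test_orientation_flips_toward_surface(self):
        lp = circle_loop()
        ax = estimate_axis(lp, np.array([[0.0, 0.0, -5.0]]))
        np.testing.assert_allclose(ax.direction, [0, 0, -1], atol=1e-9)

    def test_equivariance_under_rotation(self):
        lp = circle_loop()
        t = RigidTransform.random(np.random.default_rng(8), 40, 5)
        surface = np.array([[0.0, 0.0, 5.0]])
        ax0 = estimate_axis(lp, surface)
        ax1 = estimate_axis(lp.transformed(t), t.apply(surface))
        np.testing.assert_allclose(ax1.origin, t.apply(ax0.origin), atol=1e-9)
        np.testing.assert_allclose(
            np.abs(ax1.direction @ (t.rotation @ ax0.direction)), 1.0, atol=1e-9
        )

    def test_tilted_phantom_axis_recovered_within_1deg(self):
        """Rotating the margin circle 5 deg must rotate the axis with it."""
        tilt = RigidTransform(
            np.array([
                [1, 0, 0],
                [0, np.cos(np.radians(5)), -np.sin(np.radians(5))],
                [0, np.sin(np.radians(5)), np.cos(np.radians(5))],
            ]),
            np.zeros(3),
        )
        lp = circle_loop().transformed(tilt)
        ax = estimate_axis(lp, tilt.apply(np.array([[0.0, 0.0, 5.0]])))
        true_dir = tilt.rotation @ np.array([0, 0, 1.0])
        angle = np.degrees(np.arccos(np.clip(ax.direction @ true_dir, -1, 1)))
        assert angle < 1.0

    def test_degenerate_loop_rejected(self):
        line = MarginLoop(
            np.column_stack([np.linspace(0, 1, 20), np.zeros(20), np.zeros(20)]),
            closed=True,
        )
        with pytest.raises(ValueError, match="degenerate"):
            estimate_axis(line)


class TestFan:
    def make_axis(self):
        return AxisFrame(np.zeros(3), np.array([0, 0, 1.0]), np.array([1.0, 0, 0]))

    def test_default_25_sections_give_50_half_planes(self):
        fan = build_section_fan(self.make_axis(), 25)
        assert fan.n_half_planes == 50
        az = fan.azimuths_deg
        np.testing.assert_allclose(np.diff(az), 7.2)
        assert az[0] == 0.0

    def test_8_sections_give_16_at_22_5(self):
        fan = build_section_fan(self.make_axis(), 8)
        assert fan.n_half_planes == 16
        np.testing.assert_allclose(np.diff(fan.azimuths_deg), 22.5)

    def test_too_few_sections_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            build_section_fan(self.make_axis(), 4)


class TestIntersection:
    def make_axis(self):
        return AxisFrame(np.zeros(3), np.array([0, 0, 1.0]), np.array([1.0, 0, 0]))

    def test_circle_intersections_at_radius(self):
        fan = build_section_fan(self.make_axis(), 25)
        hits = intersect_loop_with_fan(circle_loop(radius=4.0), fan)
        assert hits.n_valid == 50
        assert hits.n_ambiguous == 0
        r = np.linalg.norm(hits.points[:, :2], axis=1)
        # polygonal chord sagitta bounds the radial error of a 720-gon
        assert np.abs(r - 4.0).max() < 4 * (1 - np.cos(np.pi / 720)) + 1e-12
        # azimuths are honored: point 0 on +x, point at 90 deg on +y
        np.testing.assert_allclose(hits.points[0, :2], [4, 0], atol=1e-6)

    def test_displaced_loop_marks_missing(self):
        lp = circle_loop(radius=1.0, center=(10.0, 0.0))  # entirely at x > 0
        fan = build_section_fan(self.make_axis(), 25)
        hits = intersect_loop_with_fan(lp, fan)
        assert hits.missing[len(hits.missing) // 2]  # the 180 deg azimuth
        assert hits.n_valid < 50

    def test_off_axis_loop_keeps_outermost_crossing(self):
        lp = circle_loop(radius=1.0, center=(2.0, 0.0))  # axis outside... encloses?
        fan = build_section_fan(self.make_axis(), 25)
        hits = intersect_loop_with_fan(lp, fan)
        # loop does not enclose the axis: each intersecting azimuth crosses twice
        assert hits.n_ambiguous > 0
        r_kept = np.linalg.norm(hits.points[0, :2])
        np.testing.assert_allclose(r_kept, 3.0, atol=1e-6)  # outer, not inner (1.0)


class TestAMD:
    def test_coincident_points_zero(self):
        pts = circle_loop(n=50).points
        prof = compute_amd(pts, pts, np.arange(50) * 7.2)
        assert prof.mean_um == 0.0
        assert prof.n_missing == 0

    def test_analytic_oracle_no_meshes(self):
        """AMD(delta, v) == sqrt(delta^2 + v^2) * 1000 on analytic loops."""
        axis = AxisFrame(np.zeros(3), np.array([0, 0, 1.0]), np.array([1.0, 0, 0]))
        for delta, v in [(0.1, 0.0), (0.06, 0.08), (0.0, 0.05)]:
            prof = measure_retainer_amd(
                circle_loop(4.0), circle_loop(4.0 + delta, z=v), axis
            )
            expected = np.hypot(delta, v) * 1000.0
            np.testing.assert_allclose(prof.distances_um, expected, atol=0.05)

    def test_rigid_motion_leaves_distances_unchanged(self):
        t = RigidTransform.random(np.random.default_rng(12), 30, 20)
        ab, cr = circle_loop(4.0), circle_loop(4.1, z=0.02)
        axis0 = AxisFrame(np.zeros(3), np.array([0, 0, 1.0]), np.array([1.0, 0, 0]))
        p0 = measure_retainer_amd(ab, cr, axis0)
        d = t.rotation @ np.array([0, 0, 1.0])
        u = t.rotation @ np.array([1.0, 0, 0])
        axis1 = AxisFrame(t.apply(np.zeros(3)), d, u)
        p1 = measure_retainer_amd(ab.transformed(t), cr.transformed(t), axis1)
        np.testing.assert_allclose(
            p1.distances_um, p0.distances_um, atol=1e-6
        )

    def test_all_missing_raises(self):
        nanpts = np.full((50, 3), np.nan)
        with pytest.raises(ValueError, match="missing"):
            compute_amd(nanpts, nanpts, np.arange(50.0))


class TestClassification:
    def make_profile(self, mean_um):
        # uniform translation: every pair distance is exactly mean_um
        pts = circle_loop(n=50).points
        return compute_amd(pts, pts + [0, 0, mean_um / 1000.0], np.arange(50) * 7.2)

    @pytest.mark.parametrize(
        "mean_um,acceptable",
        [(106.69, True), (119.99, True), (120.0, False), (130.0, False)],
    )
    def test_threshold_is_strict(self, mean_um, acceptable):
        prof = self.make_profile(mean_um)
        res = classify_acceptability(prof, threshold_um=120.0)
        assert res.acceptable is acceptable

    def test_fraction_exceeding_reported(self):
        prof = self.make_profile(119.0)
        res = classify_acceptability(prof, threshold_um=120.0)
        assert 0.0 <= res.fraction_exceeding <= 1.0


class TestSummaries:
    def two_profiles(self, means=(100.0, 110.0), missing=(0, 10)):
        profs = []
        for mean, miss in zip(means, missing):
            pts = circle_loop(n=50).points
            shifted = pts + [mean / 1000.0, 0, 0]
            prof = compute_amd(pts, shifted, np.arange(50) * 7.2)
            scale = mean / prof.mean_um
            a, b = pts.copy(), (pts + (shifted - pts) * scale)
            if miss:
                a[:miss] = np.nan
            profs.append(compute_amd(a, b, np.arange(50) * 7.2))
        return profs

    def test_mean_of_retainers(self):
        profs = self.two_profiles(missing=(0, 0))
        np.testing.assert_allclose(
            summarize_prosthesis(profs, "mean_of_retainers"), 105.0, atol=1e-9
        )

    def test_single_retainer_is_its_own_mean(self):
        profs = self.two_profiles(missing=(0, 0))[:1]
        np.testing.assert_allclose(summarize_prosthesis(profs), 100.0, atol=1e-9)

    def test_pooled_rule_matches_brute_force(self):
        profs = self.two_profiles(missing=(0, 10))
        pooled = summarize_prosthesis(profs, "pooled")
        brute = np.concatenate(
            [p.distances_um[~np.isnan(p.distances_um)] for p in profs]
        ).mean()
        np.testing.assert_allclose(pooled, brute, rtol=1e-12)
        assert profs[1].n_missing == 10

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_prosthesis([])
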