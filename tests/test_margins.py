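"""Feature-edge detection, loop chaining, margin selection."""

import numpy as np
import pytest
import trimesh

from fdpfit.margins import (
    MarginAmbiguityError,
    MarginLoop,
    MarginNotFoundError,
    branch_vertices,
    chain_edges_to_loops,
    detect_feature_edges,
    loops_near,
    orient_loop_ccw,
    resample_loop,
    select_margin_loop,
    smooth_loop,
)
from fdpfit.registration import RigidTransform


def flat_grid(n=6):
    """Planar triangulated grid: no interior feature edges."""
    xs, ys = np.meshgrid(np.arange(n), np.arange(n))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)]).astype(float)
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + 1, a + n])
            faces.append([a + 1, a + n + 1, a + n])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def circle_edges(n=64, radius=4.0, center=(0.0, 0.0, 0.0)):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
    ) + np.asarray(center)
    edges = np.column_stack([np.arange(n), (np.arange(n) + 1) % n])
    return pts, edges


class TestDetect:
    def test_flat_grid_has_only_boundary_edges(self):
        grid = flat_grid()
        edges = detect_feature_edges(grid, 30.0)
        boundary = 4 * (6 - 1)  # perimeter segments
        assert len(edges) == boundary
        v = grid.vertices.view(np.ndarray)
        on_border = (
            np.isin(v[:, 0], [0, 5]) | np.isin(v[:, 1], [0, 5])
        )
        assert on_border[np.unique(edges)].all()

    def test_cube_creases_are_the_12_edges(self, cube):
        edges = detect_feature_edges(cube, 30.0)
        assert len(edges) == 12  # welded cube: one mesh edge per cube edge
        assert len(branch_vertices(edges)) == 8  # every corner joins 3 creases

    def test_crease_count_stable_under_refinement(self, cube):
        """Refining faces must not create new creases away from the 12 edges."""
        fine = cube.subdivide().subdivide()
        fine = trimesh.Trimesh(fine.vertices, fine.faces, process=False)
        edges = detect_feature_edges(fine, 30.0)
        v = fine.vertices.view(np.ndarray)
        mids = 0.5 * (v[edges[:, 0]] + v[edges[:, 1]])
        # every feature edge midpoint lies on a cube edge: two coordinates at a face bound
        on_bound = np.isclose(np.abs(mids), 0.5).sum(axis=1)
        assert (on_bound >= 2).all()
        loops = chain_edges_to_loops(edges, v)
        total_pts = sum(len(l) for l in loops)
        assert total_pts >= len(edges)  # all crease segments chained

    def test_phantom_abutment_contains_margin_circles(self, noiseless_triad):
        mesh = noiseless_triad.abutment.mesh
        edges = detect_feature_edges(mesh, 30.0)
        loops = chain_edges_to_loops(edges, mesh.vertices.view(np.ndarray))
        center = np.array([-8.0, 0.0, 0.0])
        radii = sorted(
            float(np.linalg.norm(l.points[:, :2] - center[:2], axis=1).mean())
            for l in loops_near(loops, center, 6.0)
            if l.closed and abs(l.centroid[2]) < 0.3 and len(l) >= 16
        )
        # shoulder inner (3.0) and outer margin (4.0) circles both detected
        assert any(abs(r - 3.0) < 0.02 for r in radii)
        assert any(abs(r - 4.0) < 0.02 for r in radii)


class TestChaining:
    def test_single_circle_one_closed_loop(self):
        pts, edges = circle_edges()
        loops = chain_edges_to_loops(edges, pts)
        assert len(loops) == 1
        assert loops[0].closed
        assert len(loops[0]) == 64

    def test_two_disjoint_circles_two_loops(self):
        p1, e1 = circle_edges()
        p2, e2 = circle_edges(center=(20, 0, 0))
        pts = np.vstack([p1, p2])
        edges = np.vstack([e1, e2 + len(p1)])
        loops = chain_edges_to_loops(edges, pts)
        assert len(loops) == 2
        assert all(l.closed for l in loops)

    def test_cube_chains_cover_all_edges(self, cube):
        edges = detect_feature_edges(cube, 30.0)
        loops = chain_edges_to_loops(edges, cube.vertices.view(np.ndarray))
        covered = sum(len(l) - (0 if l.closed else 1) for l in loops)
        assert covered == 12  # every cube edge in exactly one chain

    def test_gap_closure_repairs_broken_circle(self):
        pts, edges = circle_edges(n=64)
        # remove two edges -> two arcs with ~0.39 mm gaps
        keep = np.ones(len(edges), dtype=bool)
        keep[[0, 32]] = False
        loops = chain_edges_to_loops(edges[keep], pts, gap_close=0.5)
        closed = [l for l in loops if l.closed]
        assert len(closed) == 1
        assert len(closed[0]) >= 62

    def test_no_gap_closure_leaves_open_chains(self):
        pts, edges = circle_edges(n=64)
        keep = np.ones(len(edges), dtype=bool)
        keep[[0, 32]] = False
        loops = chain_edges_to_loops(edges[keep], pts, gap_close=0.0)
        assert all(not l.closed for l in loops)


class TestSelection:
    def make_loop(self, radius, z=0.0, n=64, center=(0.0, 0.0)):
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return MarginLoop(
            np.column_stack([
                radius * np.cos(theta) + center[0],
                radius * np.sin(theta) + center[1],
                np.full(n, z),
            ]),
            closed=True,
        )

    def test_outer_loop_wins(self):
        loops = [self.make_loop(3.0), self.make_loop(4.0)]
        sel = select_margin_loop(loops, np.zeros(3), np.array([0, 0, 1.0]), (-0.5, 0.5))
        r = np.linalg.norm(sel.points[:, :2], axis=1)
        np.testing.assert_allclose(r, 4.0, atol=1e-9)

    def test_single_candidate_returned(self):
        lp = self.make_loop(4.0)
        sel = select_margin_loop([lp], np.zeros(3), np.array([0, 0, 1.0]), (-0.5, 0.5))
        assert len(sel) == len(lp)

    def test_band_excludes_out_of_band_loops(self):
        loops = [self.make_loop(5.0, z=3.0), self.make_loop(4.0, z=0.0)]
        sel = select_margin_loop(loops, np.zeros(3), np.array([0, 0, 1.0]), (-0.5, 0.5))
        r = np.linalg.norm(sel.points[:, :2], axis=1)
        np.testing.assert_allclose(r, 4.0, atol=1e-9)

    def test_empty_and_ambiguous(self):
        axis = np.array([0, 0, 1.0])
        with pytest.raises(MarginNotFoundError, match="margin not found"):
            select_margin_loop([], np.zeros(3), axis, (-0.5, 0.5))
        twins = [self.make_loop(4.0), self.make_loop(4.0 + 5e-4)]
        with pytest.raises(MarginAmbiguityError):
            select_margin_loop(twins, np.zeros(3), axis, (-0.5, 0.5))

    def test_selection_orients_ccw(self):
        cw = MarginLoop(self.make_loop(4.0).points[::-1].copy(), closed=True)
        sel = select_margin_loop([cw], np.zeros(3), np.array([0, 0, 1.0]), (-0.5, 0.5))
        rel = sel.points
        winding = np.cross(rel, np.roll(rel, -1, axis=0))[:, 2].sum()
        assert winding > 0


class TestLoopOps:
    def test_rigid_invariance_of_extraction(self, noiseless_triad):
        """Transforming the mesh transforms the extracted loop identically."""
        mesh = noiseless_triad.abutment.mesh
        t = RigidTransform.random(np.random.default_rng(5), 25, 10)
        moved = mesh.copy()
        moved.vertices = t.apply(moved.vertices.view(np.ndarray))

        def margin_of(m, origin, direction):
            edges = detect_feature_edges(m, 30.0)
            loops = chain_edges_to_loops(edges, m.vertices.view(np.ndarray))
            return select_margin_loop(
                loops_near(loops, origin, 6.0), origin, direction, (-0.5, 0.5)
            )

        c = np.array([-8.0, 0.0, 0.0])
        z = np.array([0.0, 0.0, 1.0])
        lp = margin_of(mesh, c, z)
        lp_moved = margin_of(moved, t.apply(c), t.rotation @ z)
        # same point set, transformed (allow cyclic shift)
        a = np.sort(np.round(t.apply(lp.points), 9), axis=0)
        b = np.sort(np.round(lp_moved.points, 9), axis=0)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_resample_preserves_geometry(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        lp = MarginLoop(
            np.column_stack([4 * np.cos(theta), 4 * np.sin(theta), np.zeros(100)]),
            closed=True,
        )
        rs = resample_loop(lp, 720)
        assert len(rs) == 720
        r = np.linalg.norm(rs.points[:, :2], axis=1)
        assert np.abs(r - 4.0).max() < 4 * (1 - np.cos(np.pi / 100)) + 1e-9

    def test_smooth_reduces_jitter(self):
        rng = np.random.default_rng(2)
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        noisy = MarginLoop(
            np.column_stack([
                (4 + rng.normal(0, 0.02, 720)) * np.cos(theta),
                (4 + rng.normal(0, 0.02, 720)) * np.sin(theta),
                rng.normal(0, 0.02, 720),
            ]),
            closed=True,
        )
        sm = smooth_loop(noisy, 9)
        r_noisy = np.linalg.norm(noisy.points[:, :2], axis=1)
        r_sm = np.linalg.norm(sm.points[:, :2], axis=1)
        assert r_sm.std() < 0.5 * r_noisy.std()
        assert abs(r_sm.mean() - 4.0) < 0.005
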