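import numpy as np
import pytest

from astromorph import morphometry as mm
from astromorph.morphology_io import CellMorphology

import _oracles as orc
from conftest import make_cell, straight_cable


class TestDecompose:
    def test_single_cable(self):
        d = mm.decompose(straight_cable())
        assert d.n_segments == 1
        assert d.segments[0].order == 1 and d.segments[0].is_terminal
        assert d.primary_count == 1 and d.terminal_orders == [1]

    def test_single_bifurcation(self):
        cell = make_cell([(1, -1, 0, 0, 0, 5), (2, 1, 10, 0, 0, 1),
                          (3, 2, 15, 5, 0, 1), (4, 2, 15, -5, 0, 1)])
        d = mm.decompose(cell)
        assert d.n_segments == 3
        assert sorted(s.order for s in d.segments) == [1, 2, 2]
        assert d.n_branch_points == 1
        assert sorted(d.terminal_orders) == [2, 2]

    def test_matches_traversal_oracle(self, small_cells):
        for cell in small_cells:
            d = mm.decompose(cell)
            got = {(tuple(int(cell.ids[k]) for k in s.nodes), s.order,
                    s.is_terminal) for s in d.segments}
            assert got == orc.segment_oracle(cell)


class TestComplexity:
    def test_single_cable_closed_form(self):
        d = mm.decompose(straight_cable(length=100.0))
        assert mm.complexity(d, 100.0) == pytest.approx(200.0)

    def test_bifurcation_closed_form(self):
        # 10 μm primary splitting into two 5 μm terminals of order 2
        cell = make_cell([(1, -1, 0, 0, 0, 5), (2, 1, 10, 0, 0, 1),
                          (3, 2, 15, 0, 0, 1), (4, 2, 10, 5, 0, 1)])
        d = mm.decompose(cell)
        assert mm.complexity(d, 20.0) == pytest.approx(120.0)

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_m_cables_closed_form(self, m):
        L = 37.5
        nodes = [(1, -1, 0, 0, 0, 5)]
        for i in range(m):
            nodes.append((i + 2, 1, L * np.cos(i), L * np.sin(i), 0, 1))
        d = mm.decompose(make_cell(nodes))
        assert mm.complexity(d, m * L) == pytest.approx(2 * m * L)

    def test_monotone_in_length(self, small_cells):
        cell = small_cells[0]
        d = mm.decompose(cell)
        assert (mm.complexity(d, 200.0) > mm.complexity(d, 100.0))


class TestPathMetrics:
    def test_straight_cable(self):
        total, tort, spm, base = mm.path_metrics(straight_cable(11, 100.0))
        assert total == pytest.approx(100.0)
        assert tort == pytest.approx(1.0)
        assert spm == pytest.approx(10.0)
        assert base == pytest.approx(2.0)

    def test_semicircle_tortuosity(self):
        t = np.linspace(0, np.pi, 200)
        nodes = [(1, -1, 50.0, 0, 0, 1.0)]
        for i, ti in enumerate(t[1:], start=2):
            nodes.append((i, i - 1, 50 * np.cos(ti), 50 * np.sin(ti), 0, 1.0))
        _, tort, _, _ = mm.path_metrics(make_cell(nodes))
        assert tort == pytest.approx(np.pi / 2, rel=1e-3)

    def test_total_length_matches_oracle(self, small_cells):
        for cell in small_cells:
            total, _, _, _ = mm.path_metrics(cell)
            assert total == pytest.approx(orc.total_length_oracle(cell),
                                          rel=1e-9)


class TestFrustum:
    def test_cylinder(self):
        cell = make_cell([(1, -1, 0, 0, 0, 1.0), (2, 1, 0, 0, 10.0, 1.0)])
        area, _, vol = mm.frustum_metrics(cell)
        assert area == pytest.approx(2 * np.pi * 1 * 10)
        assert vol == pytest.approx(np.pi * 10)

    def test_cone_volume(self):
        cell = make_cell([(1, -1, 0, 0, 0, 1.0), (2, 1, 0, 0, 10.0, 1e-12)])
        _, _, vol = mm.frustum_metrics(cell)
        assert vol == pytest.approx(np.pi * 10 / 3, rel=1e-6)

    def test_matches_oracle(self, small_cells):
        for cell in small_cells:
            area, _, vol = mm.frustum_metrics(cell)
            oa, ov = orc.frustum_oracle(cell)
            assert area == pytest.approx(oa, rel=1e-9)
            assert vol == pytest.approx(ov, rel=1e-9)


class TestPlanarAngle:
    def test_right_angle(self):
        cell = make_cell([(1, -1, 0, 0, 0, 5), (2, 1, 10, 0, 0, 1),
                          (3, 2, 20, 0, 0, 1), (4, 2, 10, 10, 0, 1)])
        assert mm.planar_angle(cell) == pytest.approx(90.0)

    def test_straight_through(self):
        cell = make_cell([(1, -1, 0, 0, 0, 5), (2, 1, 10, 0, 0, 1),
                          (3, 2, 20, 0, 0, 1), (4, 2, 0.0, 1e-8, 0, 1)])
        assert mm.planar_angle(cell) == pytest.approx(180.0, rel=1e-5)

    def test_no_bifurcation_is_nan(self):
        assert np.isnan(mm.planar_angle(straight_cable()))

    def test_matches_oracle(self, small_cells):
        for cell in small_cells:
            got = mm.planar_angle(cell)
            want = orc.planar_angle_oracle(cell)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-9)


class TestConvexHull:
    def test_unit_cube(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], float)
        h = mm.convex_hull_metrics(corners)
        assert h.volume_3d == pytest.approx(1.0)
        assert h.surface_area_3d == pytest.approx(6.0)
        assert h.area_2d == pytest.approx(1.0)
        assert h.perimeter_2d == pytest.approx(4.0)

    def test_coplanar_degenerate(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        with pytest.warns(UserWarning):
            h = mm.convex_hull_metrics(pts)
        assert h.volume_3d == 0.0 and h.degenerate_3d

    def test_random_points_vs_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pts = rng.uniform(-50, 50, size=(50, 3))
            h = mm.convex_hull_metrics(pts)
            per, area, _ = orc.brute_hull_2d(pts[:, :2])
            s3, v3, _ = orc.brute_hull_3d(pts)
            assert h.perimeter_2d == pytest.approx(per, rel=1e-9)
            assert h.area_2d == pytest.approx(area, rel=1e-9)
            assert h.surface_area_3d == pytest.approx(s3, rel=1e-9)
            assert h.volume_3d == pytest.approx(v3, rel=1e-9)


class TestVertex:
    def test_single_bifurcation(self):
        cell = make_cell([(1, -1, 0, 0, 0, 5), (2, 1, 10, 0, 0, 1),
                          (3, 2, 15, 5, 0, 1), (4, 2, 15, -5, 0, 1)])
        assert mm.vertex_analysis(mm.decompose(cell)) == (1, 0, 0)

    def test_symmetric_depth_two(self):
        # 1 primary, bifurcating twice: 4 terminals -> Va=2, Vb=0, Vc=1
        cell = make_cell([
            (1, -1, 0, 0, 0, 5), (2, 1, 10, 0, 0, 1),
            (3, 2, 20, 5, 0, 1), (4, 2, 20, -5, 0, 1),
            (5, 3, 30, 10, 0, 1), (6, 3, 30, 0, 0, 1),
            (7, 4, 30, -10, 0, 1), (8, 4, 30, 0.5, 0, 1)])
        assert mm.vertex_analysis(mm.decompose(cell)) == (2, 0, 1)

    def test_matches_oracle(self, small_cells):
        for cell in small_cells:
            assert (mm.vertex_analysis(mm.decompose(cell))
                    == orc.vertex_oracle(cell))


class TestFractalDimension:
    def test_single_point_zero(self):
        assert mm.fractal_dimension(make_cell([(1, -1, 0, 0, 0, 1)])) == 0.0

    def test_straight_line_dimension_one(self):
        cell = straight_cable(n_nodes=201, length=500.0)
        k = mm.fractal_dimension(cell, scales=np.array([2., 4., 8., 16., 32., 64.]))
        assert k == pytest.approx(1.0, abs=0.1)

    def test_planar_grid_dimension_two(self):
        xs, ys = np.meshgrid(np.linspace(0, 100, 500), np.linspace(0, 100, 500))
        pts = np.c_[xs.ravel(), ys.ravel(), np.zeros(xs.size)]
        k = mm.box_counting_dimension(pts, np.array([1., 2., 4., 8.]))
        assert k == pytest.approx(2.0, abs=0.15)

    def test_too_few_scales(self):
        with pytest.raises(ValueError):
            mm.fractal_dimension(straight_cable(), scales=np.array([2., 4.]))

    def test_matches_oracle(self, small_cells):
        for cell in small_cells[:20]:
            assert mm.fractal_dimension(cell) == pytest.approx(
                orc.kdim_oracle(cell), rel=1e-9)


def _transform(cell, R=None, t=None, s=1.0):
    xyz = cell.xyz * s
    if R is not None:
        xyz = xyz @ R.T
    if t is not None:
        xyz = xyz + t
    return CellMorphology(cell.cell_id, cell.ids, cell.parents, xyz,
                          cell.radius * s, cell.type_tag)


class TestInvariance:
    LENGTH_FEATURES = {"total_branch_length", "base_diameter", "complexity",
                       "hull_perimeter_2d"}
    AREA_FEATURES = {"branch_surface_area", "tree_surface_area",
                     "hull_area_2d", "hull_surface_area_3d"}
    VOLUME_FEATURES = {"total_branch_volume", "hull_volume_3d"}
    INVARIANT = {"tortuosity", "n_segments", "n_branch_points",
                 "planar_angle", "vertex_va", "vertex_vb", "vertex_vc",
                 "k_dim"}

    def test_rigid_motion_invariance(self, small_cells):
        # rotation about z keeps the section plane, so even the XY-projection
        # hull metrics must be preserved along with all Euclidean invariants
        rng = np.random.default_rng(0)
        for cell in small_cells[:6]:
            a = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(a), -np.sin(a), 0],
                          [np.sin(a), np.cos(a), 0],
                          [0, 0, 1.0]])
            t = rng.uniform(-100, 100, 3)
            f0 = mm.compute_features(cell)
            f1 = mm.compute_features(_transform(cell, R=R, t=t))
            np.testing.assert_allclose(f1.to_numpy(float), f0.to_numpy(float),
                                       rtol=1e-6)

    def test_full_3d_rotation_invariance(self, small_cells):
        # arbitrary rigid motion: everything except the section-plane
        # projection hulls is a Euclidean invariant
        rng = np.random.default_rng(1)
        from scipy.spatial.transform import Rotation
        for cell in small_cells[:6]:
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-100, 100, 3)
            drop = ["hull_perimeter_2d", "hull_area_2d"]
            f0 = mm.compute_features(cell).drop(drop)
            f1 = mm.compute_features(_transform(cell, R=R, t=t)).drop(drop)
            np.testing.assert_allclose(f1.to_numpy(float), f0.to_numpy(float),
                                       rtol=1e-6)

    def test_uniform_scaling(self, small_cells):
        s = 2.5
        for cell in small_cells[:6]:
            f0 = mm.compute_features(cell)
            f1 = mm.compute_features(_transform(cell, s=s))
            for name in f0.index:
                if name in self.LENGTH_FEATURES:
                    expect = f0[name] * s
                elif name in self.AREA_FEATURES:
                    expect = f0[name] * s ** 2
                elif name in self.VOLUME_FEATURES:
                    expect = f0[name] * s ** 3
                elif name == "segments_per_mm":
                    expect = f0[name] / s
                else:
                    expect = f0[name]
                if np.isnan(expect):
                    assert np.isnan(f1[name]), name
                else:
                    assert f1[name] == pytest.approx(expect, rel=1e-6), name


class TestComputeFeatures:
    def test_trivial_cable_composition(self):
        with pytest.warns(UserWarning, match="degenerate"):
            f = mm.compute_features(straight_cable(11, 100.0))
        assert f["total_branch_length"] == pytest.approx(100.0)
        assert f["complexity"] == pytest.approx(200.0)
        assert f["n_segments"] == 1
        assert (f[["vertex_va", "vertex_vb", "vertex_vc"]] == 0).all()

    def test_no_invalid_values(self, small_cells):
        nonneg = [n for n in mm.FEATURE_NAMES
                  if n not in ("planar_angle", "tortuosity")]
        for cell in small_cells[:20]:
            f = mm.compute_features(cell)
            assert not f[nonneg].isna().any()
            assert (f[nonneg] >= 0).all()

    def test_self_consistent_with_operations(self, small_cells):
        for cell in small_cells[:10]:
            f = mm.compute_features(cell)
            d = mm.decompose(cell)
            total, tort, spm, base = mm.path_metrics(cell, d)
            assert f["total_branch_length"] == total
            assert f["complexity"] == mm.complexity(d, total)
            va, vb, vc = mm.vertex_analysis(d)
            assert (f["vertex_va"], f["vertex_vb"], f["vertex_vc"]) == (va, vb, vc)
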