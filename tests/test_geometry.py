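"""Colony surface construction, normals, accretion and remeshing."""

import numpy as np
import pytest

from coralform import geometry as geo


class TestInitialColony:
    def test_rejects_oversized_edge(self):
        with pytest.raises(ValueError):
            geo.make_initial_colony(0.06, 0.02)

    def test_closed_and_clipped(self):
        col = geo.make_initial_colony(0.06, 0.002)
        assert col.is_closed()
        assert col.vertices[:, 2].min() >= -1e-12
        # volume below the full sphere (a cap was removed)
        _, vol = geo.surface_area_volume(col)
        assert vol < np.pi / 6 * 0.06 ** 3
        # rim/cap vertices flagged fixed and on the plane
        assert col.fixed.any()
        assert np.abs(col.vertices[col.fixed, 2]).max() < 1e-9

    def test_hemisphere_volume(self):
        col = geo.make_initial_colony(0.06, 0.002, center_height=0.0)
        _, vol = geo.surface_area_volume(col)
        expected = 2.0 / 3.0 * np.pi * 0.03 ** 3
        assert vol == pytest.approx(expected, rel=0.02)

    def test_edge_lengths_near_target(self):
        v, f = geo.geodesic_sphere(0.03, 18)
        surf = geo.TriSurface(v, f, np.zeros(len(v), dtype=bool))
        e = surf.edge_lengths()
        assert (e > 0.0016).all() and (e < 0.0024).all()
        assert e.mean() == pytest.approx(0.002, rel=0.2)


class TestVertexNormals:
    def test_sphere_normals_radial(self, unit_sphere):
        n = geo.vertex_normals(unit_sphere)
        radial = unit_sphere.vertices / np.linalg.norm(
            unit_sphere.vertices, axis=1, keepdims=True)
        angles = np.degrees(np.arccos(
            np.clip(np.einsum("ij,ij->i", n, radial), -1, 1)))
        assert angles.max() < 2.0

    def test_flat_fan_normal_is_z(self):
        th = np.linspace(0, 2 * np.pi, 7)[:-1]
        v = np.vstack([[0, 0, 0], np.column_stack(
            [np.cos(th), np.sin(th), np.zeros(6)])])
        f = np.array([[0, 1 + i, 1 + (i + 1) % 6] for i in range(6)])
        surf = geo.TriSurface(v, f, np.zeros(7, dtype=bool))
        n = geo.vertex_normals(surf)
        assert np.allclose(np.abs(n[:, 2]), 1.0)
        assert np.allclose(n[:, :2], 0.0)

    def test_saddle_matches_accumulation_oracle(self):
        rng = np.random.default_rng(11)
        g = np.linspace(-1, 1, 5)
        X, Y = np.meshgrid(g, g, indexing="ij")
        Z = X ** 2 - Y ** 2
        v = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        faces = []
        for i in range(4):
            for j in range(4):
                a = i * 5 + j
                faces.append([a, a + 5, a + 1])
                faces.append([a + 1, a + 5, a + 6])
        surf = geo.TriSurface(v, np.array(faces), np.zeros(25, dtype=bool))
        n = geo.vertex_normals(surf)
        # oracle: direct per-triangle angle-weighted accumulation
        acc = np.zeros_like(v)
        for tri in surf.faces:
            p = v[tri]
            fn = np.cross(p[1] - p[0], p[2] - p[0])
            fn = fn / np.linalg.norm(fn)
            for c in range(3):
                e1 = p[(c + 1) % 3] - p[c]
                e2 = p[(c + 2) % 3] - p[c]
                ang = np.arccos(np.dot(e1, e2)
                                / (np.linalg.norm(e1) * np.linalg.norm(e2)))
                acc[tri[c]] += ang * fn
        oracle = acc / np.linalg.norm(acc, axis=1, keepdims=True)
        assert np.abs(n - oracle).max() < 1e-9

    def test_isolated_vertex_raises(self, unit_sphere):
        surf = unit_sphere.copy()
        surf.vertices = np.vstack([surf.vertices, [[5.0, 5.0, 5.0]]])
        surf.fixed = np.append(surf.fixed, False)
        with pytest.raises(ValueError, match=str(len(surf.vertices) - 1)):
            geo.vertex_normals(surf)


class TestAccrete:
    def test_zero_layer_is_identity(self, unit_sphere):
        out = geo.accrete(unit_sphere,
                          geo.GrowthLayer(np.zeros(unit_sphere.n_vertices)))
        assert np.array_equal(out.vertices, unit_sphere.vertices)

    def test_uniform_layer_inflates_sphere(self, unit_sphere):
        out = geo.accrete(unit_sphere,
                          geo.GrowthLayer(np.full(unit_sphere.n_vertices,
                                                  0.01)))
        r = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(r - 1.01).max() < 1e-6

    def test_mixed_layer_displaces_along_normals(self, unit_sphere):
        rng = np.random.default_rng(3)
        l = rng.uniform(0, 0.02, unit_sphere.n_vertices)
        n = geo.vertex_normals(unit_sphere)
        out = geo.accrete(unit_sphere, geo.GrowthLayer(l))
        disp = out.vertices - unit_sphere.vertices
        assert np.abs(np.linalg.norm(disp, axis=1) - l).max() < 1e-12
        dots = np.einsum("ij,ij->i", disp, n)
        assert np.abs(dots - l).max() < 1e-12

    def test_negative_layer_rejected(self, unit_sphere):
        l = np.zeros(unit_sphere.n_vertices)
        l[0] = -1e-3
        with pytest.raises(ValueError):
            geo.accrete(unit_sphere, geo.GrowthLayer(l))

    def test_fixed_vertices_do_not_move(self, colony_6cm):
        out = geo.accrete(colony_6cm, geo.GrowthLayer(
            np.full(colony_6cm.n_vertices, 1e-3)))
        moved = np.linalg.norm(out.vertices - colony_6cm.vertices, axis=1)
        assert moved[colony_6cm.fixed].max() == 0.0
        assert moved[~colony_6cm.fixed].min() > 0.0

    def test_self_intersection_detected(self):
        # two overlapping tetrahedra in one mesh
        def tet(offset):
            v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
            f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
            return v + offset, f
        v1, f1 = tet(np.zeros(3))
        v2, f2 = tet(np.array([0.2, 0.2, 0.2]))
        surf = geo.TriSurface(np.vstack([v1, v2]),
                              np.vstack([f1, f2 + 4]),
                              np.zeros(8, dtype=bool))
        assert geo.self_intersects(surf)
        far = geo.TriSurface(np.vstack([v1, v2 + 10.0]),
                             np.vstack([f1, f2 + 4]),
                             np.zeros(8, dtype=bool))
        assert not geo.self_intersects(far)


class TestRemesh:
    def test_conforming_mesh_unchanged(self, unit_sphere):
        target = float(unit_sphere.edge_lengths().mean())
        out = geo.remesh(unit_sphere, target)
        assert out.n_vertices == unit_sphere.n_vertices
        assert len(out.faces) == len(unit_sphere.faces)

    def test_single_long_edge_split_once(self):
        # planar double triangle sharing one long edge, plus closing faces
        v, f = geo.geodesic_sphere(1.0, 4)
        surf = geo.TriSurface(v, f, np.zeros(len(v), dtype=bool))
        target = float(surf.edge_lengths().mean())
        # stretch one vertex to lengthen its edges beyond 1.5x target
        surf2 = surf.copy()
        surf2.vertices[0] *= 1.9
        long_before = (surf2.edge_lengths() > 1.5 * target).sum()
        out = geo.remesh(surf2, target)
        assert (out.edge_lengths() > 1.5 * target).sum() == 0
        assert out.n_vertices > surf2.n_vertices
        assert out.is_closed()

    def test_grow_and_remesh_keeps_edges_bounded(self, unit_sphere):
        surf = unit_sphere.copy()
        target = float(surf.edge_lengths().mean())
        for _ in range(10):
            surf = geo.accrete(surf, geo.GrowthLayer(
                np.full(surf.n_vertices, 0.05)))
            surf = geo.remesh(surf, target)
        e = surf.edge_lengths()
        assert e.mean() > 0.5 * target and e.mean() < 1.5 * target
        assert surf.is_closed()

    def test_remesh_area_change_small(self, unit_sphere):
        surf = geo.accrete(unit_sphere, geo.GrowthLayer(
            np.full(unit_sphere.n_vertices, 0.3)))
        target = float(unit_sphere.edge_lengths().mean())
        a0 = geo.surface_area(surf)
        out = geo.remesh(surf, target)
        assert abs(geo.surface_area(out) - a0) / a0 < 0.005

    def test_interpolates_vertex_data(self, unit_sphere):
        surf = unit_sphere.copy()
        surf.vertex_data["c"] = surf.vertices[:, 2].copy()
        surf.vertices[0] *= 1.9
        surf.vertex_data["c"][0] = surf.vertices[0, 2]
        target = float(unit_sphere.edge_lengths().mean())
        out = geo.remesh(surf, target)
        assert len(out.vertex_data["c"]) == out.n_vertices
        # interpolated channel stays within the original bounds
        assert out.vertex_data["c"].max() <= surf.vertex_data["c"].max() + 1e-12
        assert out.vertex_data["c"].min() >= surf.vertex_data["c"].min() - 1e-12


class TestMeasures:
    def test_icosphere_area_volume(self):
        v, f = geo.geodesic_sphere(1.0, 16)
        surf = geo.TriSurface(v, f, np.zeros(len(v), dtype=bool))
        area, vol = geo.surface_area_volume(surf)
        assert area == pytest.approx(4 * np.pi, rel=0.01)
        assert vol == pytest.approx(4 * np.pi / 3, rel=0.01)

    def test_open_surface_rejected(self, unit_sphere):
        surf = unit_sphere.copy()
        surf.faces = surf.faces[:-1]
        with pytest.raises(ValueError):
            geo.surface_area_volume(surf)

    def test_volume_monotone_under_growth(self, colony_6cm):
        rng = np.random.default_rng(5)
        surf = colony_6cm
        prev = geo.surface_area_volume(surf)[1]
        for _ in range(3):
            l = rng.uniform(0, 1e-3, surf.n_vertices)
            surf = geo.accrete(surf, geo.GrowthLayer(l))
            surf = geo.remesh(surf, 0.004)
            vol = geo.surface_area_volume(surf)[1]
            assert vol >= prev - 1e-12
            prev = vol
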