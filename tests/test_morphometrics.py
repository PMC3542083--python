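"""Skeletonization, branch thickness, symmetry measures, statistics."""

import numpy as np
import pytest

from coralform import morphometrics as M
from coralform.fixtures import FixtureSpec, make_branching_volume
from tests.conftest import capsule_mask


def make_cylinder(d_vox, length=62, pitch=0.001):
    n = d_vox + 13
    n += (n + 1) % 2  # odd-sized grid: axis on a voxel centre
    vol = np.zeros((n, n, length + 8), dtype=bool)
    X, Y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    c = (n - 1) / 2
    vol[(X - c) ** 2 + (Y - c) ** 2 <= (d_vox / 2) ** 2, 4:4 + length] = True
    return M.VoxelVolume(vol, (pitch,) * 3)


class TestSkeletonize:
    def test_straight_cylinder_single_path(self):
        sk = M.skeletonize_volume(make_cylinder(12))
        assert sk.graph.number_of_nodes() == 2
        assert len(sk.endpoints()) == 2
        assert sk.cycle_rank() == 0

    def test_y_shape_one_junction_three_tips(self, voxel_grid_61):
        pts = voxel_grid_61
        c = 30.5
        vol = (capsule_mask(pts, (c, c, 5), (c, c, 30), 4)
               | capsule_mask(pts, (c, c, 30), (15.5, c, 50), 4)
               | capsule_mask(pts, (c, c, 30), (45.5, c, 50), 4))
        sk = M.skeletonize_volume(M.VoxelVolume(vol, (0.001,) * 3))
        assert len(sk.endpoints()) == 3
        junctions = [n for n, d in sk.graph.nodes(data=True)
                     if not d["endpoint"]]
        assert len(junctions) == 1
        assert sk.cycle_rank() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fixture_endpoint_count_matches_branches(self, seed):
        vol, truth = make_branching_volume(FixtureSpec(n_branches=8,
                                                       seed=seed))
        sk = M.skeletonize_volume(vol)
        usable = [n for n in sk.endpoints()
                  if not sk.graph.nodes[n]["border"] and n != sk.root]
        assert len(usable) == 8

    def test_multicomponent_rejected(self):
        vol = np.zeros((30, 30, 30), dtype=bool)
        vol[2:8, 2:8, 2:8] = True
        vol[20:26, 20:26, 20:26] = True
        with pytest.raises(ValueError, match="largest-component"):
            M.skeletonize_volume(M.VoxelVolume(vol, (0.001,) * 3))

    def test_rotation_invariance_about_z(self, voxel_grid_61):
        pts = voxel_grid_61
        c = 30.5
        vol = (capsule_mask(pts, (c, c, 5), (c, c, 30), 4)
               | capsule_mask(pts, (c, c, 30), (15.5, c, 50), 4)
               | capsule_mask(pts, (c, c, 30), (45.5, c, 50), 4))
        sk0 = M.skeletonize_volume(M.VoxelVolume(vol, (0.001,) * 3))
        sk90 = M.skeletonize_volume(
            M.VoxelVolume(np.rot90(vol, 1, axes=(0, 1)).copy(),
                          (0.001,) * 3))
        assert sk90.graph.number_of_nodes() == sk0.graph.number_of_nodes()
        assert len(sk90.endpoints()) == len(sk0.endpoints())


class TestTerminalThickness:
    @pytest.mark.parametrize("d_vox", [6, 12, 16, 20])
    def test_cylinder_dc_within_one_voxel(self, d_vox):
        sk = M.skeletonize_volume(make_cylinder(d_vox))
        dc, mean = M.terminal_thickness(sk)
        assert abs(mean / 0.001 - d_vox) <= 1.0

    def test_fixture_radii_recovered(self):
        spec = FixtureSpec(n_branches=3, branch_radius=[0.002, 0.003, 0.004],
                           branch_length=0.045, elevation_deg=50.0,
                           azimuth_jitter=0.0, seed=2)
        vol, truth = make_branching_volume(spec)
        dc, mean = M.terminal_thickness(M.skeletonize_volume(vol))
        assert mean == pytest.approx(0.006, abs=spec.pitch)

    def test_sphere_has_no_terminal_branches(self):
        n = 31
        vol = np.zeros((n, n, n), dtype=bool)
        X, Y, Z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        vol[(X - 15) ** 2 + (Y - 15) ** 2 + (Z - 15) ** 2 <= 100] = True
        sk = M.skeletonize_volume(M.VoxelVolume(vol, (0.001,) * 3))
        with pytest.raises(ValueError, match="endpoint"):
            M.terminal_thickness(sk)


class TestSymmetryMeasures:
    def _graph_from_offsets(self, offsets):
        import networkx as nx
        g = nx.Graph()
        g.add_node(0, pos=np.zeros(3), radius=0.001, endpoint=False,
                   border=False, voxel=(0, 0, 0))
        for i, off in enumerate(offsets, start=1):
            g.add_node(i, pos=np.asarray(off, dtype=float), radius=0.001,
                       endpoint=True, border=False, voxel=(0, 0, 0))
            g.add_edge(0, i, length=float(np.linalg.norm(off)))
        return M.SkeletonGraph(graph=g, root=0)

    def test_diagonal_vector_gives_45_45(self):
        sk = self._graph_from_offsets([(1 / np.sqrt(2), 0, 1 / np.sqrt(2))])
        h, v = M.symmetry_angles(sk, flow_axis=(1, 0, 0))
        assert h[0] == pytest.approx(45.0, abs=1e-9)
        assert v[0] == pytest.approx(45.0, abs=1e-9)

    def test_axis_aligned_vectors(self):
        sk = self._graph_from_offsets([(1, 0, 0), (0, 1, 0)])
        h, v = M.symmetry_angles(sk, flow_axis=(1, 0, 0))
        assert h[0] == pytest.approx(0.0, abs=1e-9)   # along flow
        assert v[0] == pytest.approx(90.0, abs=1e-9)
        assert h[1] == pytest.approx(0.0, abs=1e-9)   # cross-stream
        assert v[1] == pytest.approx(0.0, abs=1e-9)

    def test_vertical_flow_axis_rejected(self):
        sk = self._graph_from_offsets([(1, 0, 0)])
        with pytest.raises(ValueError):
            M.symmetry_angles(sk, flow_axis=(0, 0, 1))

    def test_mirror_pair_sm_cancels(self):
        sk = self._graph_from_offsets([(0.02, 0.01, 0.0),
                                       (-0.02, -0.01, 0.0)])
        sm, signed, mag = M.symmetry_magnitude(sk, upstream_ref=(-1, 0, 0))
        assert signed == pytest.approx(0.0, abs=1e-12)
        assert mag > 0

    def test_clustered_upstream_positive_mean(self):
        offs = [(-0.02, 0.002, 0.005), (-0.03, -0.003, 0.01),
                (-0.025, 0.001, 0.0)]
        sk = self._graph_from_offsets(offs)
        sm, signed, mag = M.symmetry_magnitude(sk, upstream_ref=(-1, 0, 0))
        assert signed > 0
        norms = [np.linalg.norm(o) for o in offs]
        assert mag == pytest.approx(np.mean(norms), rel=0.05)

    def test_degenerate_reference_rejected(self):
        sk = self._graph_from_offsets([(1, 0, 0)])
        with pytest.raises(ValueError):
            M.symmetry_magnitude(sk, upstream_ref=(0, 0, 5.0))

    def test_mirror_symmetric_volume_sm_below_pitch(self):
        spec = FixtureSpec(n_branches=8, branch_length=0.045,
                           branch_radius=0.003, azimuth_jitter=0.0, seed=7)
        vol, _ = make_branching_volume(spec)
        sk = M.skeletonize_volume(vol)
        v0 = sk.graph.nodes[sk.root]["pos"]
        _, signed, _ = M.symmetry_magnitude(sk, v0 + np.array([-1, 0, 0]))
        assert abs(signed) < spec.pitch

    def test_orientation_bias_raises_signed_sm(self):
        signed = []
        for b in (0.0, 0.45, 0.9):
            vol, _ = make_branching_volume(
                FixtureSpec(n_branches=8, seed=5, orientation_bias=b))
            sk = M.skeletonize_volume(vol)
            v0 = sk.graph.nodes[sk.root]["pos"]
            _, s, _ = M.symmetry_magnitude(sk, v0 + np.array([-1, 0, 0]))
            signed.append(s)
        assert signed[0] < signed[1] < signed[2]


class TestAngleStats:
    def test_matches_textbook_formulas(self):
        a = np.array([41, 43, 44, 45, 45, 46, 47, 49, 50, 44,
                      43, 45, 46, 44, 45, 47, 42, 44, 48, 45.0])
        st = M.angle_distribution_stats(a)
        n = len(a)
        mean = a.sum() / n
        s = np.sqrt(((a - mean) ** 2).sum() / (n - 1))
        m3 = ((a - mean) ** 3).sum() / n
        m2 = ((a - mean) ** 2).sum() / n
        g1 = m3 / m2 ** 1.5
        skew_adj = np.sqrt(n * (n - 1)) / (n - 2) * g1
        assert st["mean"] == pytest.approx(mean)
        assert st["skewness"] == pytest.approx(skew_adj, rel=1e-10)
        m4 = ((a - mean) ** 4).sum() / n
        g2 = m4 / m2 ** 2 - 3
        kurt_adj = ((n - 1) / ((n - 2) * (n - 3))
                    * ((n + 1) * g2 + 6))
        assert st["kurtosis"] == pytest.approx(kurt_adj, rel=1e-10)
        lo, hi = st["ci95"]
        assert lo < mean < hi

    def test_symmetric_data_zero_skewness(self):
        a = np.array([40.0, 42, 44, 46, 48, 50])
        assert M.angle_distribution_stats(a)["skewness"] == \
            pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            M.angle_distribution_stats([45.0, 45.0])
        with pytest.raises(ValueError):
            M.angle_distribution_stats([45.0] * 10)


class TestMorphReport:
    def test_table_style_numbers_from_config(self):
        vol, _ = make_branching_volume(FixtureSpec(n_branches=6, seed=4))
        rep = M.morph_report(vol, flow_speed=0.05, diffusivity=1e-1,
                             viscosity=5e-2, density=1000.0)
        # Pe/Re recomputed from the same convention: u*dc/D, rho*u*dc/mu
        assert rep.pe_branch == pytest.approx(
            0.05 * rep.dc_mean / 1e-1, rel=1e-12)
        assert rep.re_branch == pytest.approx(
            1000.0 * 0.05 * rep.dc_mean / 5e-2, rel=1e-12)
        row = rep.to_row()
        assert row["Surface Volume Ratio (m^-1)"] == pytest.approx(
            rep.surface_area / rep.volume)

    def test_mesh_input_uses_exact_geometry(self, colony_6cm):
        from coralform.geometry import surface_area_volume
        rep = M.morph_report(colony_6cm, mesh_pitch=0.003)
        area, vol = surface_area_volume(colony_6cm)
        assert rep.surface_area == pytest.approx(area, rel=1e-12)
        assert rep.volume == pytest.approx(vol, rel=1e-12)

    def test_voxel_and_mesh_volume_agree(self, colony_6cm):
        from coralform.geometry import surface_area_volume
        vol = M.mesh_to_volume(colony_6cm, 0.002)
        _, exact = surface_area_volume(colony_6cm)
        assert vol.volume_m3() == pytest.approx(exact, rel=0.1)
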