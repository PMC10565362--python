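import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gravident import (
    DisplacementField,
    TetMesh,
    element_kinematics,
    read_displacement_field,
    read_mesh,
)
from gravident.mesh import (
    InvertedElementError,
    write_displacement_csv,
    write_vtk,
)
from gravident.synthetic import cube_mesh

UNIT_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])

GMSH2_UNIT_TET = """$MeshFormat
2.2 0 8
$EndMeshFormat
$Nodes
4
1 0 0 0
2 1 0 0
3 0 1 0
4 0 0 1
$EndNodes
$Elements
1
1 4 2 0 1 1 2 3 4
$EndElements
"""

GMSH4_UNIT_TET = """$MeshFormat
4.1 0 8
$EndMeshFormat
$Nodes
1 4 1 4
3 1 0 4
1
2
3
4
0 0 0
1 0 0
0 1 0
0 0 1
$EndNodes
$Elements
1 1 1 1
3 1 4 1
1 1 2 3 4
$EndElements
"""

FEB_UNIT_TET = """<?xml version="1.0"?>
<febio_spec version="3.0">
  <Mesh>
    <Nodes name="all">
      <node id="1">0,0,0</node>
      <node id="2">1,0,0</node>
      <node id="3">0,1,0</node>
      <node id="4">0,0,1</node>
    </Nodes>
    <Elements type="tet4" name="brain">
      <elem id="1">1,2,3,4</elem>
    </Elements>
  </Mesh>
</febio_spec>
"""


class TestReadMesh:
    def test_gmsh2_unit_tet(self, tmp_path):
        f = tmp_path / "tet.msh"
        f.write_text(GMSH2_UNIT_TET)
        mesh = read_mesh(f)
        assert mesh.n_elements == 1
        assert mesh.volumes[0] == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_gmsh2_swapped_vertices_reoriented(self, tmp_path):
        f = tmp_path / "tet.msh"
        f.write_text(GMSH2_UNIT_TET.replace("1 1 2 3 4", "1 1 3 2 4"))
        mesh = read_mesh(f)
        assert mesh.volumes[0] == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_gmsh4_unit_tet(self, tmp_path):
        f = tmp_path / "tet4.msh"
        f.write_text(GMSH4_UNIT_TET)
        mesh = read_mesh(f)
        assert mesh.n_nodes == 4
        assert mesh.volumes[0] == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_feb_unit_tet(self, tmp_path):
        f = tmp_path / "model.feb"
        mesh = read_mesh(_write(f, FEB_UNIT_TET))
        assert mesh.n_elements == 1
        assert mesh.volumes[0] == pytest.approx(1.0 / 6.0, rel=1e-14)

    def test_feb_mm_units_flag(self, tmp_path):
        f = tmp_path / "model.feb"
        mesh = read_mesh(_write(f, FEB_UNIT_TET), units="mm")
        assert mesh.volumes[0] == pytest.approx(1e-9 / 6.0, rel=1e-12)

    def test_feb_non_tet4_rejected(self, tmp_path):
        f = tmp_path / "model.feb"
        bad = FEB_UNIT_TET.replace('type="tet4"', 'type="hex8"')
        with pytest.raises(ValueError, match="tet4"):
            read_mesh(_write(f, bad))

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh(tmp_path / "nope.msh")

    def test_degenerate_element_rejected(self):
        nodes = np.vstack([UNIT_TET[:3], UNIT_TET[0]])  # coplanar
        with pytest.raises(InvertedElementError):
            TetMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3]]))

    def test_vtk_mesh_roundtrip(self, tmp_path):
        mesh = cube_mesh(2)
        f = tmp_path / "cube.vtk"
        write_vtk(f, mesh)
        back = read_mesh(f)
        np.testing.assert_array_equal(back.elements, mesh.elements)
        np.testing.assert_allclose(back.nodes, mesh.nodes, atol=0)


class TestBoundary:
    def test_single_tet_all_nodes_on_boundary(self):
        mesh = TetMesh(nodes=UNIT_TET, elements=np.array([[0, 1, 2, 3]]))
        assert set(mesh.boundary_nodes) == {0, 1, 2, 3}

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_cube_boundary_count(self, n):
        mesh = cube_mesh(n)
        expected = (n + 1) ** 3 - max(n - 1, 0) ** 3
        assert len(mesh.boundary_nodes) == expected

    def test_cube_volume_sums_to_one(self):
        mesh = cube_mesh(3, edge=1.0)
        assert mesh.volumes.sum() == pytest.approx(1.0, rel=1e-12)


class TestKinematics:
    def test_zero_displacement_identity(self):
        mesh = cube_mesh(2)
        disp = DisplacementField(np.zeros((mesh.n_nodes, 3)))
        k = element_kinematics(mesh, disp, 5)
        np.testing.assert_allclose(k.F, np.eye(3), atol=1e-15)
        assert k.J == pytest.approx(1.0)

    def test_affine_diag_field(self):
        mesh = cube_mesh(2)
        A = np.diag([0.1, 0.0, 0.0])
        disp = DisplacementField(mesh.nodes @ A.T)
        for e in range(mesh.n_elements):
            k = element_kinematics(mesh, disp, e)
            np.testing.assert_allclose(k.F, np.diag([1.1, 1.0, 1.0]), atol=1e-13)
            assert k.J == pytest.approx(1.1, rel=1e-12)

    def test_rigid_translation(self):
        mesh = cube_mesh(2)
        disp = DisplacementField(np.tile([0.3, -0.2, 0.5], (mesh.n_nodes, 1)))
        F = mesh.deformation_gradients(disp.values)
        np.testing.assert_allclose(F, np.broadcast_to(np.eye(3), F.shape), atol=1e-12)

    def test_rigid_rotation(self):
        from scipy.spatial.transform import Rotation

        mesh = cube_mesh(2)
        R = Rotation.from_rotvec([0.3, -0.1, 0.7]).as_matrix()
        disp = DisplacementField(mesh.nodes @ R.T - mesh.nodes)
        F = mesh.deformation_gradients(disp.values)
        np.testing.assert_allclose(F, np.broadcast_to(R, F.shape), atol=1e-12)
        np.testing.assert_allclose(np.linalg.det(F), 1.0, rtol=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-0.2, 0.2), min_size=9, max_size=9))
    def test_affine_exactness(self, entries):
        A = np.array(entries).reshape(3, 3)
        mesh = cube_mesh(1)
        disp = DisplacementField(mesh.nodes @ A.T)
        F = mesh.deformation_gradients(disp.values)
        np.testing.assert_allclose(F, np.broadcast_to(np.eye(3) + A, F.shape),
                                   atol=1e-13)

    def test_finite_difference_oracle(self, rng):
        """F from shape gradients vs central differences of the interpolated map."""
        nodes = UNIT_TET + 0.1 * rng.standard_normal((4, 3))
        mesh = TetMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3]]))
        A = 0.05 * rng.standard_normal((3, 3))
        disp = DisplacementField(mesh.nodes @ A.T)
        k = element_kinematics(mesh, disp, 0)

        # independent route: finite differences of x(X) = X + A X at the centroid
        def phi(X):
            return X + A @ X

        X0 = mesh.nodes[mesh.elements[0]].mean(axis=0)
        h = 1e-6
        F_fd = np.empty((3, 3))
        for j in range(3):
            dX = np.zeros(3)
            dX[j] = h
            F_fd[:, j] = (phi(X0 + dX) - phi(X0 - dX)) / (2 * h)
        np.testing.assert_allclose(k.F, F_fd, rtol=1e-8)

    def test_inverted_state_flagged(self):
        mesh = cube_mesh(1)
        u = mesh.nodes @ (np.diag([-2.0, 1.0, 1.0]) - np.eye(3)).T
        with pytest.raises(ValueError, match="element 0"):
            element_kinematics(mesh, DisplacementField(u), 0)


class TestDisplacementIO:
    def test_csv_zeros(self, tmp_path):
        mesh = TetMesh(nodes=UNIT_TET, elements=np.array([[0, 1, 2, 3]]))
        f = tmp_path / "u.csv"
        f.write_text("node,ux,uy,uz\n1,0,0,0\n2,0,0,0\n3,0,0,0\n4,0,0,0\n")
        d = read_displacement_field(f, mesh)
        np.testing.assert_array_equal(d.values, 0.0)

    def test_csv_mm_default_units(self, tmp_path):
        mesh = TetMesh(nodes=UNIT_TET, elements=np.array([[0, 1, 2, 3]]))
        f = tmp_path / "u.csv"
        f.write_text("node,ux,uy,uz\n1,1,0,0\n2,0,2,0\n3,0,0,3\n4,0,0,0\n")
        d = read_displacement_field(f, mesh)
        assert d.values[0, 0] == pytest.approx(1e-3)
        assert d.values[2, 2] == pytest.approx(3e-3)

    def test_csv_count_mismatch(self, tmp_path):
        mesh = TetMesh(nodes=UNIT_TET, elements=np.array([[0, 1, 2, 3]]))
        f = tmp_path / "u.csv"
        f.write_text("node,ux,uy,uz\n1,0,0,0\n")
        with pytest.raises(ValueError):
            read_displacement_field(f, mesh)

    def test_csv_nan_rejected(self, tmp_path):
        mesh = TetMesh(nodes=UNIT_TET, elements=np.array([[0, 1, 2, 3]]))
        f = tmp_path / "u.csv"
        f.write_text("node,ux,uy,uz\n1,nan,0,0\n2,0,0,0\n3,0,0,0\n4,0,0,0\n")
        with pytest.raises(ValueError, match="NaN"):
            read_displacement_field(f, mesh)

    def test_csv_roundtrip(self, tmp_path, rng):
        mesh = cube_mesh(2)
        d = DisplacementField(1e-3 * rng.standard_normal((mesh.n_nodes, 3)))
        f = tmp_path / "u.csv"
        write_displacement_csv(f, d, units="mm")
        back = read_displacement_field(f, mesh, units="mm")
        np.testing.assert_allclose(back.values, d.values, rtol=1e-14)

    def test_vtk_point_data_roundtrip(self, tmp_path, rng):
        mesh = cube_mesh(2)
        d = DisplacementField(1e-3 * rng.standard_normal((mesh.n_nodes, 3)))
        f = tmp_path / "u.vtk"
        write_vtk(f, mesh, {"displacement": d.values})
        back = read_displacement_field(f, mesh)
        np.testing.assert_array_equal(back.values, d.values)

    def test_mat_reader(self, tmp_path, rng):
        from scipy.io import savemat

        mesh = cube_mesh(1)
        u_mm = rng.standard_normal((mesh.n_nodes, 3))
        f = tmp_path / "disp.mat"
        savemat(f, {"u": u_mm})
        d = read_displacement_field(f, mesh)  # defaults to mm
        np.testing.assert_allclose(d.values, 1e-3 * u_mm, rtol=1e-14)

    def test_mat_unsupported_layout(self, tmp_path):
        from scipy.io import savemat

        mesh = cube_mesh(1)
        f = tmp_path / "disp.mat"
        savemat(f, {"u": np.zeros((5, 5))})
        with pytest.raises(ValueError, match="unsupported MAT layout"):
            read_displacement_field(f, mesh)


def _write(path, text):
    path.write_text(text)
    return path
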