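"""P1 linear elasticity: constitutive law, assembly, solve, stress."""
import numpy as np
import pytest

from stomamech import (DisplacementField, LoadCase, Material, MaterialTable,
                       MeshError, SolverError, TetMesh,
                       assemble_pressure_load, assemble_stiffness,
                       build_hollow_sphere, build_unit_cube,
                       compute_strain_stress, hooke_isotropic, solve_case,
                       solve_displacements, von_mises, von_mises_voigt)
from stomamech.cli_pipeline import patch_test_error, lame_sphere_error
from stomamech.mesh_core import facet_area_vectors

TABLE_MATERIALS = list(MaterialTable.abdominal_wall().items())


def single_tet():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]), np.array(["m"]))
    mesh.facet_groups["base"] = np.array([[0, 2, 1]])   # z=0 face, outward -z
    return mesh


class TestHooke:
    def test_zero_poisson(self):
        C = hooke_isotropic(1.0, 0.0)
        assert np.allclose(np.diag(C), [1, 1, 1, 0.5, 0.5, 0.5])
        assert C[0, 1] == 0.0

    def test_lame_parameters_rectus_value(self):
        # E = 0.52, nu = 0.3  ->  lambda = 0.3 MPa, mu = 0.2 MPa exactly
        C = hooke_isotropic(0.52, 0.3)
        lam, mu = 0.3, 0.2
        assert C[0, 0] == pytest.approx(lam + 2 * mu, abs=1e-15)
        assert C[0, 1] == pytest.approx(lam, abs=1e-15)
        assert C[3, 3] == pytest.approx(mu, abs=1e-15)

    @pytest.mark.parametrize("tag,mat", TABLE_MATERIALS)
    def test_positive_definite(self, tag, mat):
        C = hooke_isotropic(mat.E, mat.nu)
        assert np.linalg.eigvalsh(C).min() > 0
        assert np.allclose(C, C.T)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError, match="incompressible"):
            hooke_isotropic(1.0, 0.5 - 1e-8)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            Material(-1.0, 0.3)
        with pytest.raises(ValueError):
            Material(1.0, 0.6)


class TestStiffness:
    def test_single_tet_translations_in_kernel(self):
        K = assemble_stiffness(single_tet(), MaterialTable({"m": (1.0, 0.3)}))
        assert K.shape == (12, 12)
        Kd = K.toarray()
        assert np.allclose(Kd, Kd.T, atol=1e-12)
        for c in range(3):
            t = np.zeros(12)
            t[c::3] = 1.0
            assert np.abs(Kd @ t).max() < 1e-12

    def test_rigid_rotation_in_kernel_on_cube(self):
        mesh = build_unit_cube(0.5)
        K = assemble_stiffness(mesh, MaterialTable({"cube": (1.0, 0.3)}))
        c = mesh.nodes - 0.5
        rot = np.column_stack([-c[:, 1], c[:, 0], np.zeros(len(c))]).ravel()
        assert np.abs(K @ rot).max() < 1e-8

    def test_uniform_strain_energy(self):
        mesh = build_unit_cube(0.5)
        mat = Material(1.3, 0.25)
        K = assemble_stiffness(mesh, MaterialTable({"cube": mat}))
        eps = np.array([1e-3, -2e-3, 5e-4, 1e-3, 0.0, -5e-4])
        grad = np.array([[eps[0], eps[3] / 2, eps[5] / 2],
                         [eps[3] / 2, eps[1], eps[4] / 2],
                         [eps[5] / 2, eps[4] / 2, eps[2]]])
        u = (mesh.nodes @ grad.T).ravel()
        C = hooke_isotropic(mat.E, mat.nu)
        exact = 0.5 * eps @ C @ eps * 1.0          # energy density x volume
        assert u @ K @ u * 0.5 == pytest.approx(exact, rel=1e-8)

    def test_missing_material_named(self, coarse_phantom):
        with pytest.raises(MeshError, match="LA"):
            assemble_stiffness(coarse_phantom,
                               MaterialTable({t: (1.0, 0.3)
                                              for t in ("EO", "IO", "RA", "TR")}))


class TestPressureLoad:
    def test_single_facet_force(self):
        mesh = single_tet()
        p = 0.375
        f = assemble_pressure_load(mesh, "base", p).reshape(-1, 3)
        area = 0.5
        # outward normal of 'base' is -z, so pressure pushes along +z
        assert np.linalg.norm(f.sum(axis=0)) == pytest.approx(p * area)
        assert f.sum(axis=0)[2] == pytest.approx(p * area)
        for i in (0, 1, 2):
            assert np.linalg.norm(f[i]) == pytest.approx(p * area / 3)

    def test_linearity_in_pressure(self):
        mesh = single_tet()
        f1 = assemble_pressure_load(mesh, "base", 0.01)
        f2 = assemble_pressure_load(mesh, "base", 0.02)
        np.testing.assert_array_equal(f2, 2.0 * f1)

    def test_closed_surface_zero_resultant(self):
        mesh = build_hollow_sphere(10.0, 20.0, 5.0)
        f = assemble_pressure_load(mesh, "inner_surface", 0.02).reshape(-1, 3)
        area = 4 * np.pi * 100
        assert np.linalg.norm(f.sum(axis=0)) < 1e-8 * 0.02 * area

    def test_inconsistent_orientation_detected(self):
        mesh = build_hollow_sphere(10.0, 20.0, 8.0)
        faces = mesh.facet_groups["inner_surface"].copy()
        faces[0] = faces[0, ::-1]
        mesh.facet_groups["inner_surface"] = faces
        with pytest.raises(MeshError, match="orientation"):
            assemble_pressure_load(mesh, "inner_surface", 0.02)


class TestSolve:
    def test_zero_pressure_zero_displacement(self, coarse_phantom,
                                             abdominal_materials):
        u = solve_displacements(coarse_phantom, abdominal_materials,
                                LoadCase(pressure=0.0))
        assert np.abs(u.u).max() == 0.0

    def test_fixed_nodes_exactly_zero(self, coarse_hole_solution,
                                      coarse_phantom_with_hole):
        u = coarse_hole_solution.displacement.u
        fixed = coarse_phantom_with_hole.node_groups["fixed_edges"]
        assert np.abs(u[fixed]).max() == 0.0

    @pytest.mark.parametrize("tag,mat", TABLE_MATERIALS)
    def test_patch_test(self, tag, mat):
        """Uniform-strain state reproduced to 1e-8 for every wall tissue."""
        assert patch_test_error(mat) < 1e-8

    def test_pressure_scaling_exact(self, coarse_phantom_with_hole,
                                    abdominal_materials, coarse_hole_solution):
        low = solve_case(coarse_phantom_with_hole, abdominal_materials,
                         LoadCase(pressure=0.005),
                         stiffness=coarse_hole_solution.stiffness)
        ref = coarse_hole_solution.displacement.u
        assert np.abs(low.displacement.u * 4.0 - ref).max() \
            <= 1e-8 * np.abs(ref).max()

    def test_determinism(self, coarse_phantom, abdominal_materials):
        u1 = solve_displacements(coarse_phantom, abdominal_materials,
                                 LoadCase(pressure=0.01))
        u2 = solve_displacements(coarse_phantom, abdominal_materials,
                                 LoadCase(pressure=0.01))
        assert np.array_equal(u1.u, u2.u)

    def test_cg_matches_direct(self, abdominal_materials):
        mesh = build_unit_cube(0.34)
        mats = MaterialTable({"cube": (1.0, 0.3)})
        load = LoadCase(pressure=0.01, pressure_group="face_z1",
                        fixed_group="nodes_z0")
        ud = solve_displacements(mesh, mats, load, method="direct").u
        uc = solve_displacements(mesh, mats, load, method="cg").u
        assert np.abs(ud - uc).max() < 1e-8 * np.abs(ud).max()

    def test_empty_constraints_rejected(self):
        mesh = single_tet()
        mesh.node_groups["none"] = np.array([], dtype=int)
        with pytest.raises(SolverError, match="insufficient constraints"):
            solve_case(mesh, MaterialTable({"m": (1.0, 0.3)}),
                       LoadCase(pressure=0.01, pressure_group="base",
                                fixed_group="none"))

    def test_unknown_group_listed(self, coarse_phantom, abdominal_materials):
        with pytest.raises(MeshError, match="fixed_edges"):
            solve_displacements(coarse_phantom, abdominal_materials,
                                LoadCase(pressure=0.01, fixed_group="nope"))

    def test_reactions_balance_load(self, coarse_hole_solution):
        applied = coarse_hole_solution.load_vector.reshape(-1, 3).sum(axis=0)
        reacted = coarse_hole_solution.reactions().sum(axis=0)
        assert np.linalg.norm(applied + reacted) \
            < 1e-6 * np.linalg.norm(applied)


class TestLameSphere:
    def test_error_within_two_percent_and_decreasing(self):
        errors = [lame_sphere_error(res) for res in (8.0, 4.0)]
        assert errors[1] < errors[0]
        assert errors[1] < 0.05            # default-resolution check lives
        # in the acceptance suite; here only the coarse trend


class TestStress:
    def test_rigid_translation_zero_stress(self, coarse_phantom,
                                           abdominal_materials):
        u = DisplacementField(np.ones((coarse_phantom.n_nodes, 3)))
        st = compute_strain_stress(coarse_phantom, abdominal_materials, u)
        assert np.abs(st.strain).max() < 1e-12
        assert np.abs(st.von_mises).max() < 1e-12

    def test_uniform_strain_recovered(self):
        mesh = build_unit_cube(0.5)
        mats = MaterialTable({"cube": (2.0, 0.2)})
        grad = np.array([[1e-3, 2e-4, 0], [2e-4, -5e-4, 1e-4],
                         [0, 1e-4, 3e-4]])
        u = DisplacementField(mesh.nodes @ grad.T)
        st = compute_strain_stress(mesh, mats, u)
        expected = np.array([grad[0, 0], grad[1, 1], grad[2, 2],
                             2 * grad[0, 1], 2 * grad[1, 2], 2 * grad[2, 0]])
        np.testing.assert_allclose(
            st.strain, np.tile(expected, (len(st.strain), 1)), atol=1e-12)
        C = hooke_isotropic(2.0, 0.2)
        np.testing.assert_allclose(
            st.stress, np.tile(C @ expected, (len(st.stress), 1)), atol=1e-12)


class TestVonMises:
    def test_uniaxial(self):
        assert von_mises(np.diag([1.0, 0, 0])) == pytest.approx(1.0)

    def test_hydrostatic_zero(self):
        assert von_mises(np.diag([2.0, 2.0, 2.0])) == pytest.approx(0.0, abs=1e-14)

    def test_pure_shear(self):
        tau = 0.37
        t = np.array([[0, tau, 0], [tau, 0, 0], [0, 0, 0.0]])
        assert von_mises(t) == pytest.approx(np.sqrt(3) * tau)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(42)
        A = rng.standard_normal((3, 3))
        sig = A + A.T
        ref = von_mises(sig)
        for _ in range(100):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            assert abs(von_mises(q @ sig @ q.T) - ref) < 1e-10

    def test_voigt_matches_tensor(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((3, 3))
        sig = A + A.T
        voigt = np.array([[sig[0, 0], sig[1, 1], sig[2, 2],
                           sig[0, 1], sig[1, 2], sig[2, 0]]])
        assert von_mises_voigt(voigt)[0] == pytest.approx(von_mises(sig))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            von_mises(np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0.0]]))
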