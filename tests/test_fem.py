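"""Solver verification: element oracle, patch test, bars, invariances."""

import numpy as np
import pytest

from orthofem import fem
from orthofem.anatomy import LandmarkSet, Region
from orthofem.mesh import VolumeMesh, boundary_faces, box_mesh, tetrahedralize, to_quadratic
from orthofem.fem import (
    LoadBoundarySpec,
    MaterialTable,
    SamplingError,
    SingularSystemError,
    assemble,
    face_traction_loads,
    solve,
    solve_dirichlet,
    von_mises_at,
    von_mises_of,
)


def oracle_tet4_stiffness(coords, E, nu):
    """Independent dense stiffness of one linear tetrahedron.

    Shape functions via the 4x4 Vandermonde inverse (a different route from
    the implementation's barycentric-gradient formulation).
    """
    M = np.hstack([np.ones((4, 1)), coords])  # rows [1, x, y, z]
    C = np.linalg.inv(M)  # N_i(x) = C[0,i] + C[1,i] x + C[2,i] y + C[3,i] z
    V = abs(np.linalg.det(M)) / 6.0
    B = np.zeros((6, 12))
    for i in range(4):
        bx, by, bz = C[1, i], C[2, i], C[3, i]
        B[0, 3 * i] = bx
        B[1, 3 * i + 1] = by
        B[2, 3 * i + 2] = bz
        B[3, 3 * i] = by
        B[3, 3 * i + 1] = bx
        B[4, 3 * i + 1] = bz
        B[4, 3 * i + 2] = by
        B[5, 3 * i] = bz
        B[5, 3 * i + 2] = bx
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return V * B.T @ D @ B


def single_tet_mesh():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    return VolumeMesh(
        nodes=nodes,
        elements=np.array([[0, 1, 2, 3]]),
        region=np.array([Region.TOOTH], dtype=np.int32),
    )


def unit_materials(nu=0.0, E=1.0):
    return MaterialTable({"tooth": (E, nu)})


class TestAssembly:
    def test_single_tet_matches_dense_oracle(self):
        mesh = single_tet_mesh()
        op = assemble(mesh, unit_materials(nu=0.0, E=1.0))
        K = op.K.toarray()
        Ko = oracle_tet4_stiffness(mesh.nodes, E=1.0, nu=0.0)
        assert np.abs(K - Ko).max() < 1e-12

    def test_single_tet_oracle_with_poisson(self):
        mesh = single_tet_mesh()
        op = assemble(mesh, unit_materials(nu=0.3, E=200.0))
        assert np.abs(op.K.toarray() - oracle_tet4_stiffness(mesh.nodes, 200.0, 0.3)).max() < 1e-10

    def test_symmetry(self, solved_coarse):
        op, _, _ = solved_coarse
        d = abs(op.K - op.K.T)
        assert d.max() < 1e-12 * abs(op.K).max()

    def test_rigid_body_null_space(self):
        mesh = box_mesh((2.0, 1.0, 1.0), (2, 1, 1))
        op = assemble(mesh, unit_materials(nu=0.25, E=100.0))
        knorm = abs(op.K).max()
        for vec in (np.tile([1, 0, 0], mesh.n_nodes), np.tile([0, 0, 1], mesh.n_nodes)):
            assert np.linalg.norm(op.K @ vec) / knorm < 1e-10
        # rotation about z
        rot = np.cross(np.broadcast_to([0, 0, 1.0], mesh.nodes.shape), mesh.nodes).ravel()
        assert np.linalg.norm(op.K @ rot) / (knorm * np.linalg.norm(rot)) < 1e-10

    def test_missing_material_raises(self):
        mesh = single_tet_mesh()
        with pytest.raises(KeyError):
            assemble(mesh, MaterialTable({"pdl": (1.0, 0.3)}))


def _apply_linear_field(mesh, A, b):
    return mesh.nodes @ A.T + b


class TestPatchTest:
    @pytest.mark.parametrize("order", [1, 2])
    def test_linear_field_reproduced_exactly(self, order):
        """Boundary displacements of a linear field force the exact constant
        strain state everywhere (completeness/conformity of the elements)."""
        mesh = box_mesh((1.0, 1.0, 1.0), (2, 2, 2))
        if order == 2:
            mesh = to_quadratic(mesh)
        op = assemble(mesh, unit_materials(nu=0.3, E=70.0))
        A = np.array([[1e-3, 4e-4, -2e-4], [0.0, -5e-4, 3e-4], [2e-4, 1e-4, 8e-4]])
        b = np.array([1e-3, -2e-3, 0.0])
        interior = np.all(np.abs(mesh.nodes[:, :] - 0.5) < 0.5 - 1e-9, axis=1)
        boundary = np.flatnonzero(~interior)
        res = solve_dirichlet(op, boundary, _apply_linear_field(mesh, A, b)[boundary])
        exact = _apply_linear_field(mesh, A, b)
        assert np.abs(res.displacements - exact).max() < 1e-12
        strain = 0.5 * (A + A.T)
        eps = np.array([strain[0, 0], strain[1, 1], strain[2, 2],
                        2 * strain[0, 1], 2 * strain[1, 2], 2 * strain[0, 2]])
        D = unit_materials(nu=0.3, E=70.0).elasticity_matrix("tooth")
        sigma = D @ eps
        assert np.abs(res.stress - sigma).max() < 1e-12


class TestUniaxialBar:
    def test_stress_equals_force_over_area(self):
        """1 N over 1 mm^2 cross-section -> uniform 1.0 MPa axial stress."""
        mesh = box_mesh((1.0, 1.0, 10.0), (2, 2, 8))
        op = assemble(mesh, unit_materials(nu=0.0, E=1000.0))
        bottom = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-9)
        top_faces = boundary_faces(mesh)
        on_top = np.all(np.abs(mesh.nodes[top_faces][:, :, 2] - 10.0) < 1e-9, axis=1)
        f = face_traction_loads(mesh, top_faces[on_top], np.array([0, 0, 1.0]))
        res = solve_dirichlet(op, bottom, np.zeros((len(bottom), 3)), loads=f)
        szz = res.stress[:, 2]
        assert np.abs(szz - 1.0).max() < 0.01
        assert np.abs(res.von_mises - 1.0).max() < 0.01  # uniaxial: VM = |sigma|

    def test_zero_load_zero_displacement(self):
        mesh = box_mesh((1.0, 1.0, 4.0), (1, 1, 3))
        op = assemble(mesh, unit_materials(nu=0.2, E=10.0))
        bottom = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-9)
        res = solve_dirichlet(op, bottom, np.zeros((len(bottom), 3)))
        assert np.abs(res.displacements).max() == 0.0


class TestCantilever:
    def test_tip_deflection_euler_bernoulli(self):
        """Quadratic elements reproduce P L^3 / 3EI within 5%."""
        E, L = 1000.0, 10.0
        mesh = to_quadratic(box_mesh((1.0, 1.0, L), (2, 2, 20)))
        op = assemble(mesh, unit_materials(nu=0.0, E=E))
        fixed = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-9)
        tip_faces = boundary_faces(VolumeMesh(mesh.nodes, mesh.elements[:, :4], mesh.region))
        on_tip = np.all(np.abs(mesh.nodes[tip_faces][:, :, 2] - L) < 1e-9, axis=1)
        P = 1.0
        f = face_traction_loads(mesh, tip_faces[on_tip], np.array([P, 0, 0.0]))
        res = solve_dirichlet(op, fixed, np.zeros((len(fixed), 3)), loads=f)
        tip_nodes = np.flatnonzero(np.abs(mesh.nodes[:, 2] - L) < 1e-9)
        tip_defl = res.displacements[tip_nodes, 0].mean()
        I = 1.0 / 12.0
        euler = P * L**3 / (3 * E * I)
        assert abs(tip_defl - euler) / euler < 0.05


class TestRetractionLoadCase:
    def test_equilibrium(self, solved_default):
        _, _, result, _ = solved_default
        imbalance = result.reactions.sum(axis=0) + result.applied_force
        assert np.abs(imbalance).max() < 1e-8
        assert result.residual < 1e-8

    def test_linearity_in_force(self, default_model, coarse_mesh):
        op = assemble(coarse_mesh)
        s1 = fem.load_spec_from_model(coarse_mesh, default_model, force_magnitude=1.0)
        s2 = fem.load_spec_from_model(coarse_mesh, default_model, force_magnitude=2.0)
        r1, r2 = solve(op, s1), solve(op, s2)
        assert np.allclose(r2.displacements, 2 * r1.displacements, rtol=1e-9, atol=1e-15)
        assert np.allclose(r2.stress, 2 * r1.stress, rtol=1e-9, atol=1e-12)

    def test_frame_invariance(self, default_model, coarse_mesh):
        """Rotating mesh, load and landmarks together leaves von Mises samples
        unchanged."""
        ang = 0.35
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]]
        )
        op = assemble(coarse_mesh)
        spec = fem.load_spec_from_model(coarse_mesh, default_model)
        base = solve(op, spec)
        samples = von_mises_at(base, coarse_mesh, default_model.landmark_set)

        rot_mesh = VolumeMesh(
            nodes=coarse_mesh.nodes @ R.T,
            elements=coarse_mesh.elements.copy(),
            region=coarse_mesh.region.copy(),
            node_sets=coarse_mesh.node_sets,
            target_edge=coarse_mesh.target_edge,
        )
        op_r = assemble(rot_mesh)
        spec_r = LoadBoundarySpec(
            force_magnitude=spec.force_magnitude,
            force_direction=R @ spec.force_direction,
            bracket_nodes=spec.bracket_nodes,
            fixed_nodes=spec.fixed_nodes,
        )
        res_r = solve(op_r, spec_r)
        lm = default_model.landmark_set
        lm_r = LandmarkSet(C1D=R @ lm.C1D, C2D=R @ lm.C2D, C1M=R @ lm.C1M)
        samples_r = von_mises_at(res_r, rot_mesh, lm_r)
        for s, sr in zip(samples, samples_r):
            assert abs(s.von_mises - sr.von_mises) < 1e-8

    def test_mesh_convergence_of_landmark_stress(self, default_model):
        """Landmark von Mises changes < 10% under 2x refinement.

        The sampling radius is held fixed so the comparison isolates the
        discretisation, not the size of the sampled neighbourhood."""
        vals = {}
        for edge in (1.4, 0.7):
            mesh = tetrahedralize(default_model, target_edge=edge)
            op = assemble(mesh)
            spec = fem.load_spec_from_model(mesh, default_model)
            res = solve(op, spec)
            for s in von_mises_at(res, mesh, default_model.landmark_set, radius=1.8):
                vals.setdefault(s.landmark, []).append(s.von_mises)
        for name, (coarse, fine) in vals.items():
            assert abs(fine - coarse) / fine < 0.10, name

    def test_wire_constraint_suppresses_perpendicular_motion(self, default_model, coarse_mesh):
        op = assemble(coarse_mesh)
        spec = fem.load_spec_from_model(coarse_mesh, default_model, use_wire=True)
        res = solve(op, spec)
        u_bracket = res.displacements[spec.bracket_nodes]
        w = spec.wire_axis
        perp = u_bracket - np.outer(u_bracket @ w, w)
        assert np.abs(perp).max() < 1e-12
        assert res.residual < 1e-8


class TestStressInvariants:
    def test_uniaxial_von_mises(self):
        assert von_mises_of(np.array([[1.0, 0, 0, 0, 0, 0]]))[0] == pytest.approx(1.0)

    def test_hydrostatic_von_mises_zero(self):
        assert von_mises_of(np.array([[-3.0, -3.0, -3.0, 0, 0, 0]]))[0] == pytest.approx(0.0)

    def test_pure_shear(self):
        assert von_mises_of(np.array([[0, 0, 0, 1.0, 0, 0]]))[0] == pytest.approx(np.sqrt(3.0))


class TestSampling:
    def test_samples_positive_and_complete(self, solved_default):
        _, _, _, samples = solved_default
        assert {s.landmark for s in samples} == {"C1D", "C2D", "C1M"}
        assert all(s.von_mises > 0 for s in samples)

    def test_empty_sample_suggests_larger_radius(self, solved_default, default_mesh):
        _, _, result, _ = solved_default
        far = {"C1D": np.array([0.0, 0.0, 100.0])}
        with pytest.raises(SamplingError, match="radius"):
            von_mises_at(result, default_mesh, far)

    def test_max_principal_option(self, solved_default, default_mesh, default_model):
        _, _, result, _ = solved_default
        samples = von_mises_at(
            result, default_mesh, default_model.landmark_set, stress_measure="max_principal"
        )
        assert all(s.von_mises >= 0 for s in samples)


class TestSingularSystems:
    def test_empty_fixed_set_rejected(self, coarse_mesh, default_model):
        with pytest.raises(ValueError, match="non-empty"):
            LoadBoundarySpec(
                force_magnitude=1.0,
                force_direction=np.array([1.0, 0, 0]),
                bracket_nodes=coarse_mesh.node_sets["bracket_nodes"],
                fixed_nodes=np.array([], dtype=int),
            )

    def test_underconstrained_names_rigid_mode(self):
        """Fixing a single node leaves rotations free; the error says so."""
        mesh = box_mesh((1.0, 1.0, 1.0), (1, 1, 1))
        op = assemble(mesh, unit_materials(nu=0.2, E=10.0))
        f = np.zeros(3 * mesh.n_nodes)
        f[3] = 1.0  # pull one free node
        with pytest.raises(SingularSystemError, match="rotation|singular"):
            solve_dirichlet(op, np.array([0]), np.zeros((1, 3)), loads=f)
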