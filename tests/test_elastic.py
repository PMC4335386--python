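"""Plane-strain CST solver: symbolic element oracle, patch tests, closed forms."""

import numpy as np
import pytest

from spinefem.elastic import (
    BoundaryCondition,
    DisplacementField,
    Eigenstrain,
    Material,
    assemble_system,
    cst_stiffness,
    element_strain,
    solve,
    update_mesh,
)
from spinefem.errors import (
    BoundaryConditionError,
    ConfigurationError,
    ParameterError,
    StepSizeError,
)
from spinefem.meshing import FEMesh, disc_mesh, rect_mesh


def cst_stiffness_symbolic(coords, E, nu):
    """Independent CST stiffness via symbolic shape functions (sympy).

    Linear shape functions are obtained by solving N_i(x_j) = delta_ij; the
    strain-displacement operator comes from their exact derivatives and the
    (constant) integrand is multiplied by the exact triangle area.
    """
    import sympy as sp

    x, y = sp.symbols("x y")
    pts = [sp.Matrix(p) for p in coords]
    shape = []
    for i in range(3):
        a, b, c = sp.symbols(f"a{i} b{i} c{i}")
        N = a + b * x + c * y
        eqs = [
            sp.Eq(N.subs({x: pts[j][0], y: pts[j][1]}), 1 if i == j else 0)
            for j in range(3)
        ]
        sol = sp.solve(eqs, (a, b, c))
        shape.append(N.subs(sol))
    B = sp.zeros(3, 6)
    for i, N in enumerate(shape):
        B[0, 2 * i] = sp.diff(N, x)
        B[1, 2 * i + 1] = sp.diff(N, y)
        B[2, 2 * i] = sp.diff(N, y)
        B[2, 2 * i + 1] = sp.diff(N, x)
    Es, nus = sp.Rational(E) if E == int(E) else sp.Float(E), sp.Rational(nu)
    cfac = Es / ((1 + nus) * (1 - 2 * nus))
    D = cfac * sp.Matrix(
        [[1 - nus, nus, 0], [nus, 1 - nus, 0], [0, 0, (1 - 2 * nus) / 2]]
    )
    v1 = pts[1] - pts[0]
    v2 = pts[2] - pts[0]
    area = sp.Rational(1, 2) * (v1[0] * v2[1] - v1[1] * v2[0])
    return np.array((area * B.T * D * B).evalf(30), dtype=float)


class TestElementLevel:
    @pytest.mark.parametrize(
        "coords,E,nu",
        [
            ([(0, 0), (1, 0), (0, 1)], 1.0, 0.0),
            ([(0, 0), (2, 0), (0, 1)], 5.0, 0.3),
            ([(1, 1), (3, 2), (0, 4)], 2.0, 0.25),
        ],
    )
    def test_cst_stiffness_matches_symbolic_oracle(self, coords, E, nu):
        Ke = cst_stiffness(coords, Material(E, nu))
        Ke_ref = cst_stiffness_symbolic(coords, E, nu)
        assert np.abs(Ke - Ke_ref).max() < 1e-12 * max(1.0, np.abs(Ke_ref).max())

    def test_zero_eigenstrain_gives_zero_load(self):
        mesh = rect_mesh(1, 1, 3, 3)
        system = assemble_system(mesh, {"domain": Material(2.0, 0.3)})
        assert np.all(system.f == 0)

    def test_missing_material_is_configuration_error(self):
        mesh = rect_mesh(1, 1, 2, 2)
        with pytest.raises(ConfigurationError, match="domain"):
            assemble_system(mesh, {"other": Material(1.0)})

    def test_material_bounds(self):
        with pytest.raises(ParameterError):
            Material(E=-1.0)
        with pytest.raises(ParameterError):
            Material(E=1.0, nu=0.5)

    def test_eigenstrain_increment_bound(self):
        with pytest.raises(ParameterError, match="increment"):
            Eigenstrain(exx=1.5)


class TestSolvedFields:
    def test_patch_uniform_eigenstrain_reproduced_exactly(self):
        """Uniform eigenstrain on a homogeneous pinned body: strain == eps*."""
        mesh = rect_mesh(2.0, 1.0, 6, 3)
        eps = Eigenstrain(exx=0.01, eyy=-0.004, exy=0.003)
        system = assemble_system(
            mesh,
            {"domain": Material(5.0, 0.3)},
            {"domain": eps},
            BoundaryCondition.pin_rigid_modes(mesh),
        )
        u = solve(system)
        strain = element_strain(mesh, u)
        assert np.abs(strain - eps.voigt()).max() < 1e-8

    def test_free_expansion_disc(self):
        """Isotropic eigenstrain alpha on a free disc gives u = alpha * x."""
        mesh = disc_mesh(1.0, 0.15)
        alpha = 0.02
        system = assemble_system(
            mesh,
            {"domain": Material(1.0, 0.3)},
            {"domain": Eigenstrain.isotropic(alpha)},
            BoundaryCondition.pin_rigid_modes(mesh),
        )
        u = solve(system)
        err = np.linalg.norm(u.u - alpha * mesh.nodes, axis=1).max()
        assert err < 0.01 * alpha * 1.0  # within 1% of the peak displacement

    def test_fixed_boundary_zero_load_zero_displacement(self):
        mesh = disc_mesh(1.0, 0.2)
        system = assemble_system(mesh, {"domain": Material(1.0, 0.3)})
        assert np.all(solve(system).u == 0.0)

    def test_clamped_strip_plane_strain_closed_form(self):
        """Axially clamped strip with eigenstrain exx*: eyy = nu/(1-nu)*exx*."""
        L, H, alpha, nu = 2.0, 0.5, 0.01, 0.3
        mesh = rect_mesh(L, H, 40, 10)
        nodes = mesh.nodes
        fixed = np.concatenate(
            [
                2 * np.flatnonzero(np.isclose(nodes[:, 0], 0.0)),
                2 * np.flatnonzero(np.isclose(nodes[:, 0], L)),
                2 * np.flatnonzero(np.isclose(nodes[:, 1], 0.0)) + 1,
            ]
        )
        system = assemble_system(
            mesh,
            {"domain": Material(2.0, nu)},
            {"domain": Eigenstrain(exx=alpha)},
            BoundaryCondition(fixed),
        )
        u = solve(system)
        top = np.isclose(nodes[:, 1], H)
        eyy = u.u[top, 1].mean() / H
        assert eyy == pytest.approx(nu / (1 - nu) * alpha, rel=0.02)

    def test_linearity(self):
        mesh = disc_mesh(1.0, 0.2)
        bc = BoundaryCondition.fixed_outer(mesh)
        mats = {"domain": Material(1.0, 0.3)}
        u1 = solve(assemble_system(mesh, mats, {"domain": Eigenstrain.isotropic(0.01)}, bc))
        u2 = solve(assemble_system(mesh, mats, {"domain": Eigenstrain.isotropic(0.02)}, bc))
        assert np.abs(u2.u - 2.0 * u1.u).max() < 1e-10

    def test_permutation_invariance(self):
        """Relabelling mesh nodes permutes but does not change the solution."""
        mesh = disc_mesh(1.0, 0.25)
        rng = np.random.default_rng(0)
        perm = rng.permutation(mesh.n_nodes)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(mesh.n_nodes)
        permuted = FEMesh(
            nodes=mesh.nodes[inv],
            elements=perm[mesh.elements],
            element_label=mesh.element_label.copy(),
            boundary_nodes=perm[mesh.boundary_nodes],
        )
        mats = {"domain": Material(1.0, 0.3)}
        eps = {"domain": Eigenstrain(exx=0.01, eyy=0.004, exy=-0.002)}
        u = solve(assemble_system(mesh, mats, eps, BoundaryCondition.fixed_outer(mesh)))
        up = solve(
            assemble_system(permuted, mats, eps, BoundaryCondition.fixed_outer(permuted))
        )
        assert np.abs(up.u[perm] - u.u).max() < 1e-10

    def test_frame_objectivity(self):
        """Rotating mesh and eigenstrain together rotates the solution."""
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        mesh = disc_mesh(1.0, 0.25)
        rotated = mesh.copy()
        rotated.nodes = mesh.nodes @ R.T
        eps_t = np.array([[0.01, -0.002], [-0.002, 0.004]])
        eps_r = R @ eps_t @ R.T
        mats = {"domain": Material(1.0, 0.3)}
        u = solve(
            assemble_system(
                mesh,
                mats,
                {"domain": Eigenstrain(eps_t[0, 0], eps_t[1, 1], eps_t[0, 1])},
                BoundaryCondition.fixed_outer(mesh),
            )
        )
        ur = solve(
            assemble_system(
                rotated,
                mats,
                {"domain": Eigenstrain(eps_r[0, 0], eps_r[1, 1], eps_r[0, 1])},
                BoundaryCondition.fixed_outer(rotated),
            )
        )
        assert np.abs(ur.u - u.u @ R.T).max() < 1e-10

    def test_convergence_under_refinement(self):
        """Circular-inclusion closed form: error decreases under refinement.

        A core of radius a = R/2 carries an isotropic eigenstrain eps0 inside
        a disc with fixed outer boundary (same material).  Axisymmetric plane
        strain gives u_r = A r in the core and u_r = B (r - R^2/r) outside,
        with B = -(lam+mu) eps0 a^2 / ((lam+2 mu) R^2)... derived from
        displacement/traction continuity at r = a and u(R) = 0.
        """
        E, nu, eps0, R, a = 2.0, 0.3, 0.01, 1.0, 0.5
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        k = lam + mu
        B = -k * eps0 * a**2 / ((k + mu) * R**2)
        A = B * (1 - R**2 / a**2)

        def u_exact(r):
            rs = np.maximum(r, 1e-9)
            return np.where(r <= a, A * r, B * (rs - R**2 / rs))

        errors = []
        for h in (0.2, 0.1, 0.05):
            mesh = disc_mesh(R, h)
            cent = mesh.element_centroids()
            eps = np.zeros((mesh.n_elements, 3))
            core = np.hypot(cent[:, 0], cent[:, 1]) < a
            eps[core, 0] = eps[core, 1] = eps0
            u = solve(
                assemble_system(
                    mesh,
                    {"domain": Material(E, nu)},
                    eps,
                    BoundaryCondition.fixed_outer(mesh),
                )
            )
            r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
            ur = np.einsum("ij,ij->i", u.u, mesh.nodes) / np.maximum(r, 1e-12)
            errors.append(np.abs(ur - u_exact(r)).max() / (abs(A) * a))
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < 0.02

    def test_underconstrained_bc_rejected(self):
        with pytest.raises(BoundaryConditionError):
            BoundaryCondition(np.array([0, 1]))


class TestMeshUpdate:
    def test_zero_displacement_identity(self):
        mesh = rect_mesh(1, 1, 2, 2)
        out = update_mesh(mesh, DisplacementField(np.zeros_like(mesh.nodes)))
        assert np.array_equal(out.nodes, mesh.nodes)

    def test_rigid_translation_preserves_areas(self):
        mesh = disc_mesh(1.0, 0.3)
        out = update_mesh(mesh, DisplacementField(np.full_like(mesh.nodes, 3.7)))
        assert np.abs(out.element_areas() - mesh.element_areas()).max() < 1e-12

    def test_uniform_expansion_scales_areas(self):
        mesh = disc_mesh(1.0, 0.3)
        alpha = 0.25
        out = update_mesh(mesh, DisplacementField(alpha * mesh.nodes))
        ratio = out.element_areas() / mesh.element_areas()
        assert np.abs(ratio - (1 + alpha) ** 2).max() < 1e-9

    def test_inverting_step_rejected(self):
        mesh = rect_mesh(1, 1, 2, 2)
        u = np.zeros_like(mesh.nodes)
        u[:, 0] = -2.0 * mesh.nodes[:, 0]  # mirror: inverts every element
        with pytest.raises(StepSizeError, match="increment"):
            update_mesh(mesh, DisplacementField(u))
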