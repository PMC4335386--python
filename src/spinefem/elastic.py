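"""Plane-strain linear elasticity on labelled triangular meshes.

Constant-strain triangles (CST), with growth and keratinization entering as
*eigenstrains* via the thermal-expansion analogy: an imposed stress-free
strain :math:`\\varepsilon^*` contributes the element load
:math:`f_e = A_e B^T D \\varepsilon^*`, so a homogeneous unconstrained body
subjected to a uniform eigenstrain deforms exactly by it (patch test).

Voigt convention: strain vectors are ``[exx, eyy, gamma_xy]`` with the
engineering shear ``gamma_xy = 2 exy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import (
    BoundaryConditionError,
    ConfigurationError,
    ParameterError,
    SolverError,
    StepSizeError,
)
from .meshing import FEMesh


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: Young's modulus (kPa), Poisson ratio."""

    E: float
    nu: float = 0.3

    def __post_init__(self):
        if not self.E > 0:
            raise ParameterError(f"Young's modulus must be > 0, got {self.E}")
        if not 0.0 <= self.nu < 0.5:
            raise ParameterError(f"Poisson's ratio must be in [0, 0.5), got {self.nu}")

    def plane_strain_D(self) -> np.ndarray:
        E, nu = self.E, self.nu
        c = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
        return c * np.array(
            [
                [1.0 - nu, nu, 0.0],
                [nu, 1.0 - nu, 0.0],
                [0.0, 0.0, 0.5 * (1.0 - 2.0 * nu)],
            ]
        )


@dataclass(frozen=True)
class Eigenstrain:
    """Imposed in-plane strain (tensor components, dimensionless)."""

    exx: float = 0.0
    eyy: float = 0.0
    exy: float = 0.0

    def __post_init__(self):
        comps = (self.exx, self.eyy, self.exy)
        if not all(np.isfinite(comps)):
            raise ParameterError("eigenstrain components must be finite")
        if max(abs(c) for c in comps) > 1.0:
            raise ParameterError(
                "eigenstrain increments must satisfy |component| <= 1; "
                "split large process strains into more increments"
            )

    @classmethod
    def isotropic(cls, eps: float) -> "Eigenstrain":
        return cls(exx=eps, eyy=eps, exy=0.0)

    def voigt(self) -> np.ndarray:
        return np.array([self.exx, self.eyy, 2.0 * self.exy])


@dataclass
class DisplacementField:
    """Per-node displacement vectors (um)."""

    u: np.ndarray  # (n_nodes, 2)

    def flat(self) -> np.ndarray:
        return self.u.ravel()


@dataclass
class BoundaryCondition:
    """Homogeneous Dirichlet constraints given as global dof indices."""

    fixed_dofs: np.ndarray

    @classmethod
    def fixed_outer(cls, mesh: FEMesh) -> "BoundaryCondition":
        """Fix both displacement components of every outer-boundary node."""
        dofs = np.concatenate([2 * mesh.boundary_nodes, 2 * mesh.boundary_nodes + 1])
        return cls(np.unique(dofs))

    @classmethod
    def pin_rigid_modes(cls, mesh: FEMesh) -> "BoundaryCondition":
        """Pin three dofs to remove rigid translations and rotation.

        The node nearest the centroid is fully fixed; the y-displacement of
        the node farthest along +x from it is also fixed (blocks rotation).
        """
        centroid = mesh.nodes.mean(axis=0)
        i0 = int(np.argmin(np.linalg.norm(mesh.nodes - centroid, axis=1)))
        # second pin on the same y-line as i0, as far along x as possible, so
        # any uniform-strain state remains representable without rotation
        dy = np.abs(mesh.nodes[:, 1] - mesh.nodes[i0, 1])
        near = dy <= dy.min() + 1e-12
        candidates = np.flatnonzero(near)
        i1 = int(candidates[np.argmax(np.abs(mesh.nodes[candidates, 0] - mesh.nodes[i0, 0]))])
        if i1 == i0:
            i1 = int(np.argmax(np.abs(mesh.nodes[:, 0] - mesh.nodes[i0, 0])))
        return cls(np.array([2 * i0, 2 * i0 + 1, 2 * i1 + 1]))

    def __post_init__(self):
        self.fixed_dofs = np.unique(np.asarray(self.fixed_dofs, dtype=np.int64))
        if len(self.fixed_dofs) < 3:
            raise BoundaryConditionError(
                "at least 3 displacement components must be constrained "
                "(rigid-body modes)"
            )


@dataclass
class LinearSystem:
    """Assembled stiffness operator and eigenstrain load, with constraints."""

    K: sp.csr_matrix  # full (2n x 2n), symmetric
    f: np.ndarray  # full load vector
    free: np.ndarray  # boolean mask over dofs
    n_nodes: int


def _element_geometry(nodes: np.ndarray, elements: np.ndarray):
    """CST shape-function gradients: b_i, c_i coefficients and areas."""
    p = nodes[elements]  # (m, 3, 2)
    x, y = p[..., 0], p[..., 1]
    # b_i = y_j - y_k ; c_i = x_k - x_j (cyclic)
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    # equivalently the standard signed area; positive for CCW triangles
    area = 0.5 * (
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    return b, c, area


def element_B(nodes: np.ndarray, elements: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices B (m, 3, 6) and element areas (m,)."""
    b, c, area = _element_geometry(nodes, elements)
    m = len(elements)
    B = np.zeros((m, 3, 6))
    inv2A = 1.0 / (2.0 * area)
    for i in range(3):
        B[:, 0, 2 * i] = b[:, i] * inv2A
        B[:, 1, 2 * i + 1] = c[:, i] * inv2A
        B[:, 2, 2 * i] = c[:, i] * inv2A
        B[:, 2, 2 * i + 1] = b[:, i] * inv2A
    return B, area


def cst_stiffness(coords: np.ndarray, material: Material) -> np.ndarray:
    """6x6 stiffness of a single constant-strain triangle (reference path)."""
    B, area = element_B(np.asarray(coords, dtype=float), np.array([[0, 1, 2]]))
    D = material.plane_strain_D()
    return area[0] * B[0].T @ D @ B[0]


def _material_arrays(mesh: FEMesh, materials: dict) -> tuple[np.ndarray, np.ndarray]:
    labels = mesh.element_label
    missing = set(map(str, np.unique(labels))) - set(materials)
    if missing:
        raise ConfigurationError(f"no material for compartments: {sorted(missing)}")
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    for lab in np.unique(labels):
        mat = materials[str(lab)]
        sel = labels == lab
        E[sel] = mat.E
        nu[sel] = mat.nu
    return E, nu


def _eigenstrain_array(mesh: FEMesh, eigenstrain) -> np.ndarray:
    """Per-element eigenstrain in Voigt form (m, 3)."""
    if eigenstrain is None:
        return np.zeros((mesh.n_elements, 3))
    if isinstance(eigenstrain, np.ndarray):
        if eigenstrain.shape != (mesh.n_elements, 3):
            raise ConfigurationError(
                "per-element eigenstrain must have shape (n_elements, 3) in "
                "Voigt form [exx, eyy, gamma_xy]"
            )
        return eigenstrain
    out = np.zeros((mesh.n_elements, 3))
    for lab, eps in eigenstrain.items():
        out[mesh.element_label == lab] = eps.voigt()
    return out


def assemble_system(
    mesh: FEMesh,
    materials: dict[str, Material],
    eigenstrain=None,
    bc: BoundaryCondition | None = None,
) -> LinearSystem:
    """Assemble stiffness K and eigenstrain-equivalent load f.

    ``eigenstrain`` may be a per-compartment mapping of
    :class:`Eigenstrain` or a per-element ``(n_elements, 3)`` Voigt array
    (used for spatially weighted growth zones).
    """
    if bc is None:
        bc = BoundaryCondition.fixed_outer(mesh)
    E, nu = _material_arrays(mesh, materials)
    B, area = element_B(mesh.nodes, mesh.elements)
    if np.any(area <= 0):
        raise StepSizeError("mesh contains inverted elements; cannot assemble")

    # plane-strain D per element
    c1 = E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    D = np.zeros((mesh.n_elements, 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = c1 * (1.0 - nu)
    D[:, 0, 1] = D[:, 1, 0] = c1 * nu
    D[:, 2, 2] = c1 * 0.5 * (1.0 - 2.0 * nu)

    DB = np.einsum("mij,mjk->mik", D, B)
    Ke = np.einsum("mji,mjk,m->mik", B, DB, area)

    eps0 = _eigenstrain_array(mesh, eigenstrain)
    fe = np.einsum("mji,mjk,mk,m->mi", B, D, eps0, area)

    dof = np.empty((mesh.n_elements, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.elements
    dof[:, 1::2] = 2 * mesh.elements + 1

    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows, cols)), shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes)
    ).tocsr()

    f = np.zeros(2 * mesh.n_nodes)
    np.add.at(f, dof.ravel(), fe.ravel())

    free = np.ones(2 * mesh.n_nodes, dtype=bool)
    if np.any(bc.fixed_dofs >= 2 * mesh.n_nodes):
        raise BoundaryConditionError("fixed dof index out of range")
    free[bc.fixed_dofs] = False
    return LinearSystem(K=K, f=f, free=free, n_nodes=mesh.n_nodes)


def solve(system: LinearSystem, rtol: float = 1e-8) -> DisplacementField:
    """Direct sparse solve of the constrained system (homogeneous Dirichlet)."""
    free = system.free
    Kff = system.K[free][:, free]
    ff = system.f[free]
    u = np.zeros(2 * system.n_nodes)
    fnorm = np.linalg.norm(ff)
    if fnorm > 0:
        try:
            uf = spla.spsolve(Kff.tocsc(), ff)
        except Exception as exc:  # pragma: no cover - singularities
            raise SolverError(f"sparse factorization failed: {exc}") from exc
        if not np.isfinite(uf).all():
            raise SolverError("solver returned non-finite displacements")
        resid = np.linalg.norm(Kff @ uf - ff) / fnorm
        if resid > rtol:
            raise SolverError(f"relative residual {resid:.2e} exceeds {rtol:.0e}")
        u[free] = uf
    return DisplacementField(u=u.reshape(-1, 2))


def update_mesh(mesh: FEMesh, field: DisplacementField) -> FEMesh:
    """Advance node coordinates by the displacement field (quasi-static step)."""
    u = np.asarray(field.u, dtype=float)
    if not np.isfinite(u).all():
        raise SolverError("displacement field contains non-finite values")
    out = mesh.copy()
    out.nodes = out.nodes + u
    areas = out.element_areas()
    if np.any(areas <= 0):
        raise StepSizeError(
            f"{int((areas <= 0).sum())} elements inverted by this increment; "
            "re-run with more, smaller increments"
        )
    return out


def element_strain(mesh: FEMesh, field: DisplacementField) -> np.ndarray:
    """Per-element Voigt strain [exx, eyy, gamma_xy] of a displacement field."""
    B, _ = element_B(mesh.nodes, mesh.elements)
    dof = np.empty((mesh.n_elements, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * mesh.elements
    dof[:, 1::2] = 2 * mesh.elements + 1
    return np.einsum("mij,mj->mi", B, field.flat()[dof])
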