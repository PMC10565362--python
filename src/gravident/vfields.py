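"""Generation of parameter-targeted virtual fields.

Each field is the difference between a fixed-boundary, small-body-load solve
with one material parameter perturbed and the corresponding base solve,
normalized to unit maximum nodal magnitude.  The mu- and K-fields come from a
small-strain isotropic solver driven by (mu, K); the alpha-field uses the
nonlinear forward solver at the same small load, because alpha leaves no
footprint in a linear model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import DisplacementField, TetMesh
from .ogden import OgdenParams
from .power import VirtualField

__all__ = ["LinearSolveSpec", "solve_fixed_boundary", "generate_sensitivity_fields",
           "solve_linear_elasticity"]

#: relative field norm below which a sensitivity field is considered degenerate
_DEGENERATE_RTOL = 1e-9


@dataclass
class LinearSolveSpec:
    """Specification of the fixed-boundary small-load solves used to build
    virtual fields."""

    mesh: TetMesh
    base_params: OgdenParams
    body_load: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -0.001]))
    fixed_nodes: np.ndarray | None = None  # defaults to all boundary nodes
    mu_factor: float = 2.0
    K_factor: float = 2.0
    alpha_shift: float = -10.0

    def __post_init__(self):
        self.body_load = np.asarray(self.body_load, dtype=float)
        if self.fixed_nodes is None:
            self.fixed_nodes = self.mesh.boundary_nodes
        else:
            self.fixed_nodes = np.union1d(
                np.asarray(self.fixed_nodes, dtype=np.int64), self.mesh.boundary_nodes
            )
        if np.linalg.norm(self.body_load) >= 9.81:
            raise ValueError("virtual-field body load must be small (<< 9.81 m s^-2)")


def _strain_displacement_matrices(mesh: TetMesh) -> np.ndarray:
    """(m, 6, 12) engineering strain-displacement matrices for tet4 elements.

    Strain ordering (xx, yy, zz, xy, yz, zx) with engineering shear strains;
    element dof ordering (node0 x,y,z, node1 x,y,z, ...).
    """
    g = mesh.shape_gradients  # (m, 4, 3)
    m = mesh.n_elements
    B = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx
    return B


def _element_dofs(mesh: TetMesh) -> np.ndarray:
    """(m, 12) global dof indices per element."""
    return (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(mesh.n_elements, 12)


def assemble_stiffness(mesh: TetMesh, mu: float, K: float) -> sp.csr_array:
    """Sparse global stiffness for linear isotropic elasticity with moduli
    derived from (mu, K): lambda = K - 2 mu / 3."""
    lam = K - 2.0 * mu / 3.0
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2.0 * mu
    C[3:, 3:] = mu * np.eye(3)
    B = _strain_displacement_matrices(mesh)
    Ke = np.einsum("e,eki,kl,elj->eij", mesh.volumes, B, C, B, optimize=True)
    dofs = _element_dofs(mesh)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_array((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def body_load_vector(mesh: TetMesh, b: np.ndarray) -> np.ndarray:
    """Consistent nodal load for a constant body force: rho V0 b / 4 per vertex."""
    f = np.zeros((mesh.n_nodes, 3))
    fe = mesh.density * np.einsum("e,j->ej", mesh.volumes / 4.0, np.asarray(b, float))
    for a in range(4):
        np.add.at(f, mesh.elements[:, a], fe)
    return f.ravel()


def solve_linear_elasticity(
    mesh: TetMesh,
    mu: float,
    K: float,
    body_force: np.ndarray,
    fixed_nodes: np.ndarray,
    prescribed: np.ndarray | None = None,
) -> DisplacementField:
    """Direct sparse solve of the small-strain problem with Dirichlet data.

    ``prescribed`` optionally gives (n, 3) displacement values imposed on the
    fixed nodes (zero by default).
    """
    fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64)
    if fixed_nodes.size == 0:
        raise ValueError("no fixed nodes: the system is singular (rigid modes)")
    Kmat = assemble_stiffness(mesh, mu, K)
    f = body_load_vector(mesh, body_force)
    n = 3 * mesh.n_nodes
    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    u = np.zeros(n)
    if prescribed is not None:
        u[fixed_dofs] = np.asarray(prescribed, float).ravel()[fixed_dofs]
    rhs = f[free] - Kmat[free][:, fixed_dofs] @ u[fixed_dofs]
    sol = spla.spsolve(Kmat[free][:, free].tocsc(), rhs)
    if not np.all(np.isfinite(sol)):
        raise ArithmeticError("sparse solve failed (non-finite solution)")
    u[free] = sol
    return DisplacementField(values=u.reshape(-1, 3))


def solve_fixed_boundary(spec: LinearSolveSpec, params: OgdenParams
                         ) -> DisplacementField:
    """Small-strain solve with the spec's load and fully fixed boundary set."""
    return solve_linear_elasticity(
        spec.mesh, params.mu, params.K, spec.body_load, spec.fixed_nodes
    )


def _normalized_field(mesh: TetMesh, diff: np.ndarray, label: str,
                      ref_scale: float) -> VirtualField:
    mag = np.linalg.norm(diff, axis=1).max() if len(diff) else 0.0
    degenerate = mag <= _DEGENERATE_RTOL * ref_scale or mag == 0.0
    values = diff if degenerate else diff / mag
    return VirtualField.from_nodal(mesh, values, label=label, degenerate=degenerate)


def generate_sensitivity_fields(
    spec: LinearSolveSpec, newton_tol: float = 1e-8
) -> tuple[VirtualField, VirtualField, VirtualField]:
    """Three parameter-targeted virtual fields (mu, alpha, K order).

    Each is a perturbed-minus-base solve, zero on all boundary nodes,
    normalized to unit maximum nodal magnitude.  A perturbation that produces
    no field change is flagged degenerate.
    """
    mesh = spec.mesh
    base = solve_fixed_boundary(spec, spec.base_params)
    scale = np.linalg.norm(base.values, axis=1).max()
    if scale == 0.0:
        raise ValueError("base solve returned a zero field (zero body load?)")

    u_mu = solve_fixed_boundary(spec, spec.base_params.replace(
        mu=spec.base_params.mu * spec.mu_factor))
    f_mu = _normalized_field(mesh, u_mu.values - base.values, "mu", scale)

    u_K = solve_fixed_boundary(spec, spec.base_params.replace(
        K=spec.base_params.K * spec.K_factor))
    f_K = _normalized_field(mesh, u_K.values - base.values, "K", scale)

    # alpha only appears at finite strain: difference two weakly nonlinear solves
    from .synthetic import forward_solve

    nl_base = forward_solve(mesh, spec.base_params, spec.body_load,
                            spec.fixed_nodes, tol=newton_tol)
    nl_pert = forward_solve(
        mesh,
        spec.base_params.replace(alpha=spec.base_params.alpha + spec.alpha_shift),
        spec.body_load, spec.fixed_nodes, tol=newton_tol,
    )
    f_alpha = _normalized_field(
        mesh, nl_pert.displacement.values - nl_base.displacement.values, "alpha", scale
    )
    return f_mu, f_alpha, f_K
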