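"""Ground-truth synthetic data: a total-Lagrangian nonlinear forward solver for
the compressible Ogden law under body force with fixed boundary, canned
cube/ellipsoid fixtures, homogeneous-deformation fixtures and noise injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import DisplacementField, TetMesh
from .ogden import OgdenParams, cauchy_stress_batch

__all__ = [
    "ForwardSolveResult",
    "NoiseSpec",
    "ForwardSolveError",
    "forward_solve",
    "cube_mesh",
    "ellipsoid_shell_mesh",
    "homogeneous_fixture",
    "add_noise",
    "make_recovery_bundle",
]


class ForwardSolveError(RuntimeError):
    pass


@dataclass
class ForwardSolveResult:
    mesh: TetMesh
    displacement: DisplacementField
    converged: bool
    residual_norm: float
    newton_iterations: int
    J_range: tuple[float, float]
    params: OgdenParams
    body_force: np.ndarray
    fixed_nodes: np.ndarray


@dataclass
class NoiseSpec:
    """Displacement-noise description: RMS amplitude per component (metres),
    kind 'iid_gaussian' or 'smooth_field' (Gaussian-correlated with the given
    correlation length), and a seed fixing the realization."""

    rms: float
    kind: str = "iid_gaussian"
    correlation_length: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.rms < 0:
            raise ValueError("rms must be >= 0")
        if self.kind not in ("iid_gaussian", "smooth_field"):
            raise ValueError(f"unknown noise kind {self.kind!r}")


# ---------------------------------------------------------------------------
# fixture meshes
# ---------------------------------------------------------------------------

# Kuhn subdivision: six tets per grid cell, all sharing the main diagonal.
_CELL_TETS = (
    (0, 1, 3, 7), (0, 1, 5, 7), (0, 2, 3, 7),
    (0, 2, 6, 7), (0, 4, 5, 7), (0, 4, 6, 7),
)


def cube_mesh(n: int = 6, edge: float = 0.1, density: float = 1040.0) -> TetMesh:
    """Structured cube [0, edge]^3 with n divisions per side (6 n^3 tets)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    axis = np.linspace(0.0, edge, n + 1)
    X, Y, Z = np.meshgrid(axis, axis, axis, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (n + 1) + j) * (n + 1) + k

    elements = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                corners = [nid(i + (b & 1), j + ((b >> 1) & 1), k + ((b >> 2) & 1))
                           for b in range(8)]
                for tet in _CELL_TETS:
                    elements.append([corners[v] for v in tet])
    return TetMesh(nodes=nodes, elements=np.asarray(elements), density=density)


def ellipsoid_shell_mesh(
    n: int = 8,
    semiaxes: tuple[float, float, float] = (0.08, 0.06, 0.05),
    cavity_ratio: float = 0.4,
    density: float = 1040.0,
) -> TetMesh:
    """Thick-walled ellipsoid: a spherified cube grid with the central region
    removed, leaving a jagged inner cavity.  Outer surface plays the role of
    the rigid skull constraint."""
    base = cube_mesh(n, edge=2.0, density=density)
    p = base.nodes - 1.0  # [-1, 1]^3
    linf = np.abs(p).max(axis=1)
    l2 = np.linalg.norm(p, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = np.where(l2 > 0, linf / np.where(l2 > 0, l2, 1.0), 0.0)
    mapped = p * factor[:, None] * np.asarray(semiaxes)
    # drop elements fully inside the cavity
    radial = linf[base.elements]
    keep = ~(radial < cavity_ratio).all(axis=1)
    elements = base.elements[keep]
    used = np.unique(elements)
    remap = -np.ones(len(mapped), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TetMesh(nodes=mapped[used], elements=remap[elements], density=density)


def homogeneous_fixture(F_target: np.ndarray, n: int = 2, edge: float = 0.1,
                        density: float = 1040.0) -> tuple[TetMesh, DisplacementField]:
    """Cube mesh with the affine field u = (F - I) X; every element's computed
    deformation gradient equals F_target exactly (linear tets are affine-exact)."""
    F_target = np.asarray(F_target, dtype=float)
    if np.linalg.det(F_target) <= 0:
        raise ValueError("det F_target must be positive")
    mesh = cube_mesh(n, edge=edge, density=density)
    u = mesh.nodes @ (F_target - np.eye(3)).T
    return mesh, DisplacementField(values=u)


# ---------------------------------------------------------------------------
# total-Lagrangian Newton solver
# ---------------------------------------------------------------------------


def _element_internal_forces(u_e, g, V0, params):
    """Internal nodal forces per element, (m, 4, 3), from element displacements.

    F is built as I + grad u (not from current positions) to avoid the
    catastrophic cancellation X + u - X at small strains.  Returns (forces, J).
    """
    F = np.eye(3) + np.einsum("eai,eaj->eij", u_e, g)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        return None, J
    sigma = cauchy_stress_batch(F, params)
    # first Piola P = J sigma F^-T ; nodal force f_a = V0 P gradN_a
    P = J[:, None, None] * sigma @ np.linalg.inv(np.swapaxes(F, 1, 2))
    return V0[:, None, None] * np.einsum("eij,eaj->eai", P, g), J


def _assemble_internal(mesh, u, params):
    g = mesh.shape_gradients
    u_e = u[mesh.elements]
    fe, J = _element_internal_forces(u_e, g, mesh.volumes, params)
    if fe is None:
        return None, J
    f = np.zeros((mesh.n_nodes, 3))
    np.add.at(f, mesh.elements, fe)
    return f, J


def _tangent_matrix(mesh, u, params, h):
    """Global tangent stiffness by central differencing of the element internal
    forces with respect to each of the 12 element dofs (vectorized over elements)."""
    g = mesh.shape_gradients
    u_e = u[mesh.elements]
    m = mesh.n_elements
    Ke = np.empty((m, 12, 12))
    for a in range(4):
        for i in range(3):
            xp = u_e.copy()
            xp[:, a, i] += h
            fp, Jp = _element_internal_forces(xp, g, mesh.volumes, params)
            xm = u_e.copy()
            xm[:, a, i] -= h
            fm, Jm = _element_internal_forces(xm, g, mesh.volumes, params)
            if fp is None or fm is None:
                raise ForwardSolveError("element inversion during tangent assembly")
            Ke[:, :, 3 * a + i] = ((fp - fm) / (2.0 * h)).reshape(m, 12)
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(m, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_array((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def forward_solve(
    mesh: TetMesh,
    params: OgdenParams,
    b,
    fixed_set=None,
    tol: float = 1e-9,
    max_newton: int = 25,
    max_load_halvings: int = 8,
    prescribed: np.ndarray | None = None,
) -> ForwardSolveResult:
    """Newton-Raphson solve of the reference-configuration equilibrium under a
    constant body force ``b`` with zero (or ``prescribed``) displacement on
    ``fixed_set`` (defaults to all boundary nodes).

    Convergence: ||R_free|| <= tol * max(||f_ext_free||, f_floor).  Load is
    stepped with halving when a full step fails to converge or inverts an
    element.
    """
    b = np.asarray(b, dtype=float)
    if fixed_set is None:
        fixed_set = mesh.boundary_nodes
    fixed_set = np.asarray(fixed_set, dtype=np.int64)
    if fixed_set.size == 0:
        raise ValueError("fixed_set must be non-empty (rigid modes)")
    n = 3 * mesh.n_nodes
    fixed_dofs = (3 * fixed_set[:, None] + np.arange(3)).ravel()
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    from .vfields import body_load_vector

    f_ext_full = body_load_vector(mesh, b).reshape(-1, 3)
    span = mesh.nodes.max(axis=0) - mesh.nodes.min(axis=0)
    h = 1e-6 * max(np.linalg.norm(span), 1.0)

    u = np.zeros((mesh.n_nodes, 3))
    if prescribed is not None:
        u.reshape(-1)[fixed_dofs] = np.asarray(prescribed, float).ravel()[fixed_dofs]
    total_iters = 0
    load_done = 0.0
    step = 1.0
    halvings = 0
    res_norm = 0.0
    J = np.ones(mesh.n_elements)

    def newton(u0, factor):
        nonlocal total_iters, res_norm
        u_cur = u0.copy()
        f_ext = factor * f_ext_full
        ref = np.linalg.norm(f_ext.reshape(-1)[free])
        for it in range(max_newton):
            f_int, J_cur = _assemble_internal(mesh, u_cur, params)
            if f_int is None:
                return None, J_cur
            R = (f_int - f_ext).reshape(-1)
            res_norm = np.linalg.norm(R[free])
            if it == 0:
                # Dirichlet-driven problems have f_ext = 0; fall back to the
                # initial residual as the convergence reference
                ref = max(ref, res_norm, 1e-300)
            total_iters += 1
            if res_norm <= tol * ref:
                return u_cur, J_cur
            Kt = _tangent_matrix(mesh, u_cur, params, h)
            du = spla.spsolve(Kt[free][:, free].tocsc(), -R[free])
            if not np.all(np.isfinite(du)):
                return None, J_cur
            u_cur.reshape(-1)[free] += du
        return None, J_cur

    if np.linalg.norm(f_ext_full.reshape(-1)[free]) == 0.0:
        f_int, J = _assemble_internal(mesh, u, params)
        res = np.linalg.norm((f_int).reshape(-1)[free]) if f_int is not None else np.inf
        if prescribed is not None and res > 0:
            # pure Dirichlet problem still needs Newton
            pass
        else:
            return ForwardSolveResult(mesh, DisplacementField(u.copy()), True, res, 0,
                                      (float(J.min()), float(J.max())), params, b,
                                      fixed_set)

    while load_done < 1.0 - 1e-12:
        factor = min(1.0, load_done + step)
        u_try, J_try = newton(u, factor)
        if u_try is None:
            halvings += 1
            step *= 0.5
            if halvings > max_load_halvings:
                raise ForwardSolveError(
                    f"no convergence after {max_load_halvings} load halvings "
                    f"(reached load factor {load_done:.3g})"
                )
            continue
        u, J = u_try, J_try
        load_done = factor
        step = min(step * 2.0, 1.0 - load_done) if load_done < 1.0 else step

    return ForwardSolveResult(
        mesh=mesh,
        displacement=DisplacementField(values=u),
        converged=True,
        residual_norm=float(res_norm),
        newton_iterations=total_iters,
        J_range=(float(J.min()), float(J.max())),
        params=params,
        body_force=b,
        fixed_nodes=fixed_set,
    )


# ---------------------------------------------------------------------------
# noise injection
# ---------------------------------------------------------------------------


def add_noise(disp: DisplacementField, spec: NoiseSpec,
              coords: np.ndarray | None = None) -> DisplacementField:
    """Return a noisy copy of the field.

    iid_gaussian adds N(0, rms^2) independently to every component.
    smooth_field draws iid values, applies a Gaussian kernel smoother of the
    given correlation length over the node coordinates (required), and rescales
    to the requested component RMS - a registration-like error field.
    """
    if spec.rms == 0.0:
        return DisplacementField(values=disp.values.copy())
    rng = np.random.default_rng(spec.seed)
    raw = rng.normal(0.0, 1.0, size=disp.values.shape)
    if spec.kind == "iid_gaussian":
        noise = spec.rms * raw
    else:
        if coords is None:
            raise ValueError("smooth_field noise needs node coordinates")
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        W = np.exp(-0.5 * d2 / spec.correlation_length**2)
        W /= W.sum(axis=1, keepdims=True)
        smooth = W @ raw
        rms_now = np.sqrt((smooth**2).mean())
        noise = spec.rms * smooth / rms_now
    return DisplacementField(values=disp.values + noise)


# ---------------------------------------------------------------------------
# canned recovery bundles
# ---------------------------------------------------------------------------


def make_recovery_bundle(
    fixture_name: str,
    params_true: OgdenParams,
    noise: NoiseSpec | None = None,
    n: int = 6,
    body_force=(0.0, 0.0, -9.81),
    density: float = 1040.0,
    vf_load_magnitude: float = 0.001,
    newton_tol: float = 1e-9,
):
    """Forward-solve a fixture at ``params_true``, generate the three virtual
    fields on the same mesh, optionally add noise, and return
    (DataBundle, params_true, ForwardSolveResult)."""
    from .identify import DataBundle
    from .vfields import LinearSolveSpec, generate_sensitivity_fields

    if fixture_name == "cube":
        mesh = cube_mesh(n=n, density=density)
    elif fixture_name == "thick_shell_ellipsoid":
        mesh = ellipsoid_shell_mesh(n=n, density=density)
    else:
        raise ValueError(f"unknown fixture {fixture_name!r}")
    b = np.asarray(body_force, dtype=float)
    fwd = forward_solve(mesh, params_true, b, tol=newton_tol)
    disp = fwd.displacement
    if noise is not None:
        disp = add_noise(disp, noise, coords=mesh.nodes)
    bhat = b / np.linalg.norm(b) if np.linalg.norm(b) else np.array([0.0, 0.0, -1.0])
    spec = LinearSolveSpec(mesh=mesh, base_params=params_true,
                           body_load=vf_load_magnitude * bhat)
    vfs = generate_sensitivity_fields(spec)
    bundle = DataBundle.build(mesh, disp, vfs, b)
    return bundle, params_true, fwd
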