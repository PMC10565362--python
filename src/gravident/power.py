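"""Virtual-power equilibrium gap.

Internal power is the one-point-quadrature sum over constant-strain tets of
``(sigma : D*) J V0`` with the Cauchy stress evaluated at the measured
deformation gradient of each element; external power is
``sum b . v*(centroid) rho V0`` (the J factors cancel exactly because rho/J is
the current density).  The spatial virtual-velocity gradient is taken with
respect to the measured current configuration, ``grad v* = G* F^-1``; when the
virtual field equals the measured displacement this reduces to (F - I) F^-1.

The acceleration term and the surface-traction integral are compiled out:
virtual fields vanish on the boundary and loading is quasi-static.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import DisplacementField, TetMesh
from .ogden import OgdenParams, cauchy_stress_batch

__all__ = [
    "VirtualField",
    "PowerResult",
    "virtual_velocity_gradient",
    "rate_of_deformation",
    "internal_power",
    "external_power",
    "field_error",
    "total_error",
    "self_consistency_check",
]


@dataclass
class VirtualField:
    """A test function: per-node virtual velocities plus cached per-element
    reference gradients G* = dv*/dX (consistent with linear tet interpolation)."""

    values: np.ndarray  # (n, 3) nodal virtual velocities
    label: str = ""
    ref_gradients: np.ndarray | None = None  # (m, 3, 3)
    degenerate: bool = False

    @classmethod
    def from_nodal(cls, mesh: TetMesh, values: np.ndarray, label: str = "",
                   degenerate: bool = False) -> "VirtualField":
        values = np.ascontiguousarray(values, dtype=np.float64)
        g = np.einsum("eai,eaj->eij", values[mesh.elements], mesh.shape_gradients)
        return cls(values=values, label=label, ref_gradients=g, degenerate=degenerate)

    def gradients(self, mesh: TetMesh) -> np.ndarray:
        if self.ref_gradients is None:
            self.ref_gradients = np.einsum(
                "eai,eaj->eij", self.values[mesh.elements], mesh.shape_gradients
            )
        return self.ref_gradients

    def check_admissible(self, mesh: TetMesh, atol: float = 0.0):
        """Verify v* = 0 on every boundary node of ``mesh``."""
        worst = np.abs(self.values[mesh.boundary_nodes]).max(initial=0.0)
        if worst > atol:
            raise ValueError(
                f"virtual field {self.label!r} is nonzero on the boundary "
                f"(max |v*| = {worst:.3e})"
            )


@dataclass
class PowerResult:
    P_int: float
    P_ext: float
    P_err: float
    element_contributions: np.ndarray | None = None


def virtual_velocity_gradient(G_star: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Spatial gradient grad v* = G* F^-1 (chain rule to the current frame).

    Works on single 3x3 tensors or stacked (m, 3, 3) arrays.
    """
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("singular or inverted F in virtual_velocity_gradient")
    return np.asarray(G_star) @ np.linalg.inv(F)


def rate_of_deformation(grad_v_star: np.ndarray) -> np.ndarray:
    """Symmetric part D* = (grad v* + grad v*^T) / 2."""
    g = np.asarray(grad_v_star)
    return 0.5 * (g + np.swapaxes(g, -1, -2))


def internal_power(
    mesh: TetMesh,
    disp: DisplacementField,
    vfield: VirtualField,
    params: OgdenParams,
    return_contributions: bool = False,
):
    """One-point-quadrature internal virtual power  sum_e (sigma : D*) J V0."""
    F = mesh.deformation_gradients(disp.values)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        bad = np.flatnonzero(J <= 0)
        raise ValueError(f"J <= 0 on elements {bad[:10].tolist()}")
    sigma = cauchy_stress_batch(F, params)
    D = rate_of_deformation(vfield.gradients(mesh) @ np.linalg.inv(F))
    contrib = np.einsum("eij,eij->e", sigma, D) * J * mesh.volumes
    if return_contributions:
        return float(contrib.sum()), contrib
    return float(contrib.sum())


def external_power(mesh: TetMesh, vfield: VirtualField, body_force_b: np.ndarray
                   ) -> float:
    """External virtual power  sum_e b . v*(centroid) rho V0.

    Independent of the measured displacement (reference density, J cancels).
    """
    b = np.asarray(body_force_b, dtype=float)
    v_cent = vfield.values[mesh.elements].mean(axis=1)  # (m, 3)
    return float(mesh.density * ((v_cent @ b) * mesh.volumes).sum())


def field_error(P_int: float, P_ext: float) -> float:
    """Normalized equilibrium gap (P_int - P_ext) / P_ext."""
    if P_ext == 0.0:
        raise ZeroDivisionError("external virtual power is zero; cannot normalize")
    return (P_int - P_ext) / P_ext


def total_error(errors) -> float:
    """Pythagorean sum of the per-field errors."""
    errors = np.asarray(errors, dtype=float)
    if errors.shape != (3,):
        raise ValueError("expected exactly three per-field errors")
    return float(np.linalg.norm(errors))


def self_consistency_check(forward_solution, params: OgdenParams, b) -> float:
    """Discretization-error probe: use a forward solve's own displacement as
    both measured field and virtual field and return |P_int - P_ext| / |P_ext|.

    The zero-load case (P_int = P_ext = 0) returns 0 by convention.
    """
    if not forward_solution.converged:
        raise ValueError("forward solution did not converge")
    mesh = forward_solution.mesh
    disp = forward_solution.displacement
    vf = VirtualField.from_nodal(mesh, disp.values, label="self")
    p_int = internal_power(mesh, disp, vf, params)
    p_ext = external_power(mesh, vf, b)
    if p_ext == 0.0:
        if p_int == 0.0:
            return 0.0
        raise ZeroDivisionError("P_ext = 0 with nonzero P_int")
    return abs(p_int - p_ext) / abs(p_ext)
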