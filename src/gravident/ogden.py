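"""One-term compressible Ogden hyperelasticity.

The strain energy density is

    psi(F) = (2 mu / alpha^2) * (lt1^alpha + lt2^alpha + lt3^alpha - 3) + (K/2) (ln J)^2

with deviatoric principal stretches ``lt_i = J^(-1/3) lambda_i`` (lambda_i the
singular values of F) and J = det F.  The volumetric potential is chosen so
that the volumetric Cauchy stress is exactly ``K ln(J)/J I``.

The Cauchy stress is diagonal in the principal frame of b = F F^T:

    sigma_dev_i = (2 mu / (alpha J)) * (lt_i^alpha - (1/3) sum_k lt_k^alpha)
    sigma_vol   = K ln(J) / J

The alpha -> 0 limit (deviatoric energy mu * sum ln^2 lt_i, stress
2 mu ln(lt_i) / J) is taken analytically for |alpha| < 1e-6 so optimizers may
cross zero.  Repeated principal stretches need no special casing: equal
stretches give equal principal stresses, so any orthonormal eigenbasis of b
yields the same tensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["OgdenParams", "StressState", "strain_energy", "cauchy_stress",
           "small_strain_moduli", "principal_stretches"]

_ALPHA_EPS = 1e-6


@dataclass(frozen=True)
class OgdenParams:
    """Material parameters (mu, alpha, K) of the one-term compressible Ogden model.

    mu is the small-strain shear modulus (Pa), alpha the dimensionless
    strain-stiffening exponent, K the bulk modulus (Pa).  ``bounds`` stores
    per-parameter identification bounds (used by the optimizers).
    """

    mu: float
    alpha: float
    K: float
    bounds: dict = field(
        default_factory=lambda: {
            "mu": (100.0, 1e4),
            "alpha": (-100.0, 100.0),
            "K": (1e4, 1e6),
        }
    )

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")

    def replace(self, **kw) -> "OgdenParams":
        d = {"mu": self.mu, "alpha": self.alpha, "K": self.K, "bounds": self.bounds}
        d.update(kw)
        return OgdenParams(**d)

    def as_array(self) -> np.ndarray:
        return np.array([self.mu, self.alpha, self.K])


@dataclass
class StressState:
    sigma: np.ndarray  # symmetric 3x3 Cauchy stress, Pa
    psi: float  # strain energy density, J m^-3
    dev_stretches: np.ndarray  # deviatoric principal stretches, descending


def principal_stretches(F: np.ndarray) -> np.ndarray:
    """Singular values of F (principal stretches), descending."""
    return np.linalg.svd(np.asarray(F, dtype=float), compute_uv=False)


def _check_J(J):
    if np.any(J <= 0):
        raise ValueError(f"det F = {np.min(J):.3e} <= 0: inadmissible deformation")


def dev_energy_from_stretches(lt: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    """Deviatoric energy from deviatoric stretches ``lt`` (..., 3)."""
    lt = np.asarray(lt)
    if abs(alpha) < _ALPHA_EPS:
        return mu * (np.log(lt) ** 2).sum(axis=-1)
    return (2.0 * mu / alpha**2) * (lt**alpha).sum(axis=-1) - 6.0 * mu / alpha**2


def dev_principal_stress(lt: np.ndarray, J: np.ndarray, mu: float, alpha: float
                         ) -> np.ndarray:
    """Deviatoric principal Cauchy stresses, shape (..., 3); trace-free."""
    lt = np.asarray(lt)
    J = np.asarray(J)
    if abs(alpha) < _ALPHA_EPS:
        lnl = np.log(lt)
        dev = lnl - lnl.mean(axis=-1, keepdims=True)
        return 2.0 * mu * dev / J[..., None]
    p = lt**alpha
    dev = p - p.mean(axis=-1, keepdims=True)
    return (2.0 * mu / alpha) * dev / J[..., None]


def vol_stress(J, K: float):
    """Volumetric Cauchy stress magnitude K ln(J)/J (an isotropic pressure term)."""
    J = np.asarray(J)
    return K * np.log(J) / J


def strain_energy(F: np.ndarray, params: OgdenParams) -> float:
    """Strain energy density psi(F), J m^-3; zero at F = I."""
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))  # det, not prod of singular values: sign matters
    _check_J(J)
    lam = principal_stretches(F)
    lt = lam * J ** (-1.0 / 3.0)
    psi_dev = float(dev_energy_from_stretches(lt, params.mu, params.alpha))
    psi_vol = 0.5 * params.K * np.log(J) ** 2
    return psi_dev + psi_vol


def cauchy_stress(F: np.ndarray, params: OgdenParams) -> StressState:
    """Cauchy stress, energy and deviatoric stretches at deformation gradient F."""
    F = np.asarray(F, dtype=float)
    b = F @ F.T
    w, V = np.linalg.eigh(b)  # ascending eigenvalues of b = F F^T
    w = w[::-1]
    V = V[:, ::-1]
    lam = np.sqrt(np.maximum(w, 0.0))
    J = float(np.linalg.det(F))
    _check_J(J)
    lt = lam * J ** (-1.0 / 3.0)
    s_dev = dev_principal_stress(lt, np.asarray(J), params.mu, params.alpha)
    sigma = (V * s_dev) @ V.T
    sigma += vol_stress(J, params.K) * np.eye(3)
    sigma = 0.5 * (sigma + sigma.T)  # exact symmetrization
    psi = float(dev_energy_from_stretches(lt, params.mu, params.alpha)
                + 0.5 * params.K * np.log(J) ** 2)
    return StressState(sigma=sigma, psi=psi, dev_stretches=lt)


def cauchy_stress_batch(F: np.ndarray, params: OgdenParams) -> np.ndarray:
    """Vectorized Cauchy stress for stacked deformation gradients (m, 3, 3)."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    _check_J(J)
    b = F @ np.swapaxes(F, -1, -2)
    w, V = np.linalg.eigh(b)
    lam = np.sqrt(np.maximum(w, 0.0))
    lt = lam * J[..., None] ** (-1.0 / 3.0)
    s_dev = dev_principal_stress(lt, J, params.mu, params.alpha)
    sigma = np.einsum("...ik,...k,...jk->...ij", V, s_dev, V)
    sigma += vol_stress(J, params.K)[..., None, None] * np.eye(3)
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def small_strain_moduli(params: OgdenParams) -> tuple[float, float]:
    """Young's modulus and Poisson's ratio from (mu, K) by the standard
    isotropic conversions E = 9 K mu / (3 K + mu), nu = (3K - 2mu) / (6K + 2mu)."""
    mu, K = params.mu, params.K
    E = 9.0 * K * mu / (3.0 * K + mu)
    nu = (3.0 * K - 2.0 * mu) / (6.0 * K + 2.0 * mu)
    return E, nu
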