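"""Identification of (mu, alpha, K) by minimizing the total virtual-power error.

The DataBundle precomputes everything that does not depend on the candidate
parameters: per-element Jacobians and principal frames of the measured
deformation, the projections of each virtual field's rate of deformation onto
that frame, and the per-field external powers.  A parameter evaluation is then
a handful of vectorized array operations, so sweeps of thousands of parameter
sets are cheap.

Optimization is carried out in (log mu, alpha, log K); bounds are enforced
natively by the least-squares solver and via a logistic transform for the
Nelder-Mead simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .mesh import DisplacementField, TetMesh
from .ogden import OgdenParams, dev_principal_stress, vol_stress
from .power import VirtualField, external_power, total_error

__all__ = [
    "DataBundle",
    "IdentificationResult",
    "LandscapeSample",
    "identify_leastsq",
    "identify_simplex",
    "multistart",
    "random_sweep",
    "classify_errors",
    "stress_statistics",
    "FIG4_THRESHOLDS",
    "FIG5_THRESHOLDS",
]

#: absolute-error class boundaries used for optimizer landscapes
FIG4_THRESHOLDS = (1e-8, 1e-6, 1e-4, 1e-2)
#: relative(%)-error class boundaries used for random sweeps
FIG5_THRESHOLDS = (0.01, 0.02, 0.05)

_DEFAULT_BOUNDS = {"mu": (100.0, 1e4), "alpha": (-100.0, 100.0), "K": (1e4, 1e6)}


@dataclass
class DataBundle:
    """Measured data plus parameter-independent caches for fast evaluation."""

    mesh: TetMesh
    displacement: DisplacementField
    vfields: tuple
    body_force: np.ndarray
    # caches
    J: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)  # J * V0
    lam: np.ndarray = field(repr=False, default=None)  # principal stretches (m, 3)
    d_proj: np.ndarray = field(repr=False, default=None)  # (3 fields, m, 3)
    trD: np.ndarray = field(repr=False, default=None)  # (3, m)
    P_ext: np.ndarray = field(repr=False, default=None)  # (3,)

    @classmethod
    def build(cls, mesh: TetMesh, disp: DisplacementField, vfields, body_force
              ) -> "DataBundle":
        vfields = tuple(vfields)
        if len(vfields) != 3:
            raise ValueError("exactly three virtual fields are required")
        b = np.asarray(body_force, dtype=float)
        F = mesh.deformation_gradients(disp.values)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            bad = np.flatnonzero(J <= 0)
            raise ValueError(
                f"measured field inverts {bad.size} elements "
                f"(first: {bad[:10].tolist()})"
            )
        Finv = np.linalg.inv(F)
        bmat = F @ np.swapaxes(F, 1, 2)
        w, V = np.linalg.eigh(bmat)
        lam = np.sqrt(np.maximum(w, 0.0))
        d_proj = np.empty((3, mesh.n_elements, 3))
        P_ext = np.empty(3)
        for j, vf in enumerate(vfields):
            A = vf.gradients(mesh) @ Finv
            D = 0.5 * (A + np.swapaxes(A, 1, 2))
            d_proj[j] = np.einsum("eki,ekl,eli->ei", V, D, V)
            P_ext[j] = external_power(mesh, vf, b)
        if np.any(P_ext == 0.0):
            raise ValueError("a virtual field has zero external power under b")
        return cls(mesh=mesh, displacement=disp, vfields=vfields, body_force=b,
                   J=J, weights=J * mesh.volumes, lam=lam, d_proj=d_proj,
                   trD=d_proj.sum(axis=2), P_ext=P_ext)

    def evaluate(self, params: OgdenParams) -> tuple[np.ndarray, float]:
        """Per-field equilibrium-gap errors and their Pythagorean sum.

        Pure function of ``params``; concurrent calls do not interact.
        """
        lt = self.lam * self.J[:, None] ** (-1.0 / 3.0)
        s_dev = dev_principal_stress(lt, self.J, params.mu, params.alpha)  # (m, 3)
        s_vol = vol_stress(self.J, params.K)  # (m,)
        sD = np.einsum("ei,jei->je", s_dev, self.d_proj) + s_vol * self.trD
        P_int = sD @ self.weights
        errors = (P_int - self.P_ext) / self.P_ext
        return errors, total_error(errors)

    def principal_stresses(self, params: OgdenParams) -> np.ndarray:
        """(m, 3) per-element principal Cauchy stresses, descending."""
        lt = self.lam * self.J[:, None] ** (-1.0 / 3.0)
        s = dev_principal_stress(lt, self.J, params.mu, params.alpha) \
            + vol_stress(self.J, params.K)[:, None]
        return np.sort(s, axis=1)[:, ::-1]


@dataclass
class IdentificationResult:
    params: OgdenParams
    total_err: float
    field_errors: np.ndarray
    start: OgdenParams
    converged: bool
    optimizer: str
    n_evaluations: int
    trace: list = field(default_factory=list)
    message: str = ""


@dataclass
class LandscapeSample:
    params: OgdenParams
    total_err: float
    label: str | None = None


def _resolve_bounds(bounds) -> dict:
    out = dict(_DEFAULT_BOUNDS)
    if bounds:
        out.update(bounds)
    for name, (lo, hi) in out.items():
        if not lo < hi:
            raise ValueError(f"empty bound for {name}: {(lo, hi)}")
    if out["mu"][0] <= 0 or out["K"][0] <= 0:
        raise ValueError("mu and K bounds must be positive")
    return out


def _to_x(p: OgdenParams) -> np.ndarray:
    return np.array([np.log(p.mu), p.alpha, np.log(p.K)])


def _from_x(x) -> OgdenParams:
    return OgdenParams(mu=float(np.exp(x[0])), alpha=float(x[1]),
                       K=float(np.exp(x[2])))


def identify_leastsq(start: OgdenParams, bundle: DataBundle, bounds=None,
                     ftol: float = 1e-15, xtol: float = 1e-15) -> IdentificationResult:
    """Bounded least-squares fit of the three per-field errors
    (trust-region Levenberg-Marquardt step model) in (log mu, alpha, log K)."""
    bnds = _resolve_bounds(bounds)
    lo = np.array([np.log(bnds["mu"][0]), bnds["alpha"][0], np.log(bnds["K"][0])])
    hi = np.array([np.log(bnds["mu"][1]), bnds["alpha"][1], np.log(bnds["K"][1])])
    x0 = np.clip(_to_x(start), lo, hi)
    trace = []

    def residuals(x):
        p = _from_x(x)
        errors, tot = bundle.evaluate(p)
        trace.append((p.as_array(), tot))
        return errors

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        ftol=ftol, xtol=xtol, gtol=1e-15,
                        diff_step=1e-6, max_nfev=2000)
    p_best = _from_x(res.x)
    errors, tot = bundle.evaluate(p_best)
    return IdentificationResult(
        params=p_best, total_err=tot, field_errors=errors, start=start,
        converged=bool(res.success), optimizer="leastsq",
        n_evaluations=int(res.nfev), trace=trace, message=res.message,
    )


def _logistic(z, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp(-z))


def _logit(t, lo, hi):
    frac = np.clip((t - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(frac / (1.0 - frac))


def identify_simplex(start: OgdenParams, bundle: DataBundle, bounds=None,
                     fatol: float = 1e-16, maxiter: int = 4000
                     ) -> IdentificationResult:
    """Nelder-Mead minimization of the scalar total error; bounds enforced by a
    logistic transform of (log mu, alpha, log K)."""
    bnds = _resolve_bounds(bounds)
    lo = np.array([np.log(bnds["mu"][0]), bnds["alpha"][0], np.log(bnds["K"][0])])
    hi = np.array([np.log(bnds["mu"][1]), bnds["alpha"][1], np.log(bnds["K"][1])])
    z0 = _logit(np.clip(_to_x(start), lo, hi), lo, hi)
    trace = []

    def objective(z):
        p = _from_x(_logistic(z, lo, hi))
        _, tot = bundle.evaluate(p)
        trace.append((p.as_array(), tot))
        return tot

    opts = {"fatol": fatol, "xatol": 1e-10, "maxiter": maxiter,
            "maxfev": 2 * maxiter}
    res = minimize(objective, z0, method="Nelder-Mead", options=opts)
    # restart from the incumbent pulled back into the interior: the logistic
    # transform flattens gradients near the bounds, which can trap a collapsed
    # simplex in a spurious corner attractor
    margin = 0.02 * (hi - lo)
    z_restart = _logit(np.clip(_logistic(res.x, lo, hi), lo + margin, hi - margin),
                       lo, hi)
    res2 = minimize(objective, z_restart, method="Nelder-Mead", options=opts)
    if res2.fun < res.fun:
        res = res2
    p_best = _from_x(_logistic(res.x, lo, hi))
    errors, tot = bundle.evaluate(p_best)
    return IdentificationResult(
        params=p_best, total_err=tot, field_errors=errors, start=start,
        converged=bool(res.success), optimizer="simplex",
        n_evaluations=int(res.nfev), trace=trace, message=res.message,
    )


def _sample_params(unit: np.ndarray, bnds: dict) -> list[OgdenParams]:
    """Map unit-cube samples to parameters: log-uniform mu, K; uniform alpha."""
    lmu = np.log(bnds["mu"])
    lK = np.log(bnds["K"])
    a = bnds["alpha"]
    return [
        OgdenParams(
            mu=float(np.exp(lmu[0] + u[0] * (lmu[1] - lmu[0]))),
            alpha=float(a[0] + u[1] * (a[1] - a[0])),
            K=float(np.exp(lK[0] + u[2] * (lK[1] - lK[0]))),
        )
        for u in np.atleast_2d(unit)
    ]


def multistart(bundle: DataBundle, n_starts: int, bounds=None, seed: int = 0,
               optimizer: str = "leastsq") -> list[IdentificationResult]:
    """Run an optimizer from Latin-hypercube start points; deterministic in seed."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bnds = _resolve_bounds(bounds)
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = _sample_params(sampler.random(n_starts), bnds)
    runner = {"leastsq": identify_leastsq, "simplex": identify_simplex}[optimizer]
    return [runner(s, bundle, bounds=bnds) for s in starts]


def random_sweep(bundle: DataBundle, n: int, bounds=None, seed: int = 0
                 ) -> list[LandscapeSample]:
    """Evaluate n independent random parameter sets (log-uniform mu, K; uniform
    alpha); reproducible by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    bnds = _resolve_bounds(bounds)
    rng = np.random.default_rng(seed)
    params = _sample_params(rng.random((n, 3)), bnds)
    return [LandscapeSample(params=p, total_err=bundle.evaluate(p)[1])
            for p in params]


def classify_errors(samples, threshold_set=FIG4_THRESHOLDS) -> list[LandscapeSample]:
    """Label samples into half-open error bins [0, t1), [t1, t2), ..., [t_last, inf)."""
    t = np.asarray(threshold_set, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
        raise ValueError("thresholds must be positive and strictly increasing")
    labels = [f"< {t[0]:g}"]
    labels += [f"{a:g} <= err < {b:g}" for a, b in zip(t[:-1], t[1:])]
    labels += [f">= {t[-1]:g}"]
    out = []
    for s in samples:
        k = int(np.searchsorted(t, s.total_err, side="right"))
        out.append(LandscapeSample(params=s.params, total_err=s.total_err,
                                   label=labels[k]))
    return out


def stress_statistics(params: OgdenParams, bundle: DataBundle,
                      percentile_spec: dict | None = None) -> dict:
    """Per-element stress summary at ``params``.

    Reports the maximum-shear measure tau_max = (sigma1 - sigma3)/2 and the
    mean (triaxial) stress tr(sigma)/3, with configurable percentiles
    (defaults: 95th of tau_max; 2.5th/97.5th of mean stress) and maxima.
    Conventions are configurable because several are in common use.
    """
    spec = {"shear_percentile": 95.0, "mean_percentiles": (2.5, 97.5)}
    if percentile_spec:
        spec.update(percentile_spec)
    s = bundle.principal_stresses(params)
    tau = 0.5 * (s[:, 0] - s[:, 2])
    mean = s.mean(axis=1)
    lo_p, hi_p = spec["mean_percentiles"]
    return {
        "shear_percentile": float(np.percentile(tau, spec["shear_percentile"])),
        "shear_max": float(tau.max()),
        "mean_low": float(np.percentile(mean, lo_p)),
        "mean_high": float(np.percentile(mean, hi_p)),
        "mean_abs_max": float(np.abs(mean).max()),
        "n_elements": int(len(tau)),
        "conventions": {
            "shear": "tau_max = (sigma1 - sigma3)/2",
            "triaxial": "tr(sigma)/3",
            **spec,
        },
    }
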