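"""Material-point relations of the fibril-reinforced viscoelastic model.

The total cartilage stress decomposes into nonfibrillar matrix stress,
fibrillar matrix stress and fluid pressure,

    sigma_tot = sigma_nf + sigma_f + p I .

Collagen fibrils carry tension only.  A single fibril obeys the
first-order viscoelastic rate law

    sigma_f + [eta / (2 sqrt((sigma_f - E_0 eps_f) E_eps))] dsigma_f/dt
        = E_0 eps_f
        + [eta + eta E_0 / (2 sqrt((sigma_f - E_0 eps_f) E_eps))] deps_f/dt,
    sigma_f = 0                                  if eps_f <= 0,

with damping coefficient eta and initial / strain-dependent network moduli
E_0 and E_eps.  Setting the rates to zero recovers the static limit
sigma_f = E_0 eps_f; the law stiffens under fast loading.  The per-element
fibril stress tensor sums the per-fibril contributions over all primary
and secondary fibril directions, each modulated by the current collagen
degeneration level D:

    sigma_f_tensor = sum_j sigma_fj  e_j (x) e_j,
    sigma_fj = rho * D * C * sigma_f   (primary fibrils)
    sigma_fj = rho * D * sigma_f       (secondary fibrils).

Time integration is implicit backward Euler with a damped Newton solve and
a bracketed-root fallback; the square-root argument is clamped from below
(``REG_FLOOR``) because it vanishes as sigma_f approaches E_0 eps_f, where
the ODE becomes stiff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .materials import MaterialParams
from .mesh import Element

# floor for the square-root argument (MPa^2); keeps the damping term finite
REG_FLOOR = 1e-9
MAX_NEWTON = 50
_SYM_TOL = 1e-9


class FibrilStressError(RuntimeError):
    """Implicit fibril-stress step failed to converge."""


@dataclass
class FibrilState:
    """State of one fibril: current stress (MPa), strain, and time (s)."""

    sigma_f: float = 0.0
    eps_f: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_f <= 0.0 and self.sigma_f != 0.0:
            raise ValueError("tension-only fibril: sigma_f must be 0 when eps_f <= 0")


def _damping(sigma: float, eps: float, params: MaterialParams) -> float:
    """eta / (2 sqrt((sigma - E_0 eps) E_eps)), regularized near the root."""
    arg = (sigma - params.E_0 * eps) * params.E_eps
    return params.eta / (2.0 * np.sqrt(max(arg, REG_FLOOR)))


def fibril_stress_step(
    state: FibrilState,
    eps_f_next: float,
    dt: float,
    params: MaterialParams,
) -> FibrilState:
    """Advance the fibril stress one implicit time step to strain ``eps_f_next``.

    Returns a new :class:`FibrilState` at ``state.time + dt``.  For
    non-positive target strain the fibril is slack and carries zero stress.
    Strain rate is the backward difference over the step.
    """
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    t_next = state.time + dt
    if eps_f_next <= 0.0:
        return FibrilState(sigma_f=0.0, eps_f=eps_f_next, time=t_next)

    eps_dot = (eps_f_next - state.eps_f) / dt
    sig_n = state.sigma_f
    E0e = params.E_0 * eps_f_next

    def residual(sig: float) -> float:
        a = _damping(sig, eps_f_next, params)
        return (
            sig
            + a * (sig - sig_n) / dt
            - E0e
            - (params.eta + params.E_0 * a) * eps_dot
        )

    # unloading can push the unconstrained root below zero; the fibril then
    # goes slack and carries no stress
    if residual(0.0) >= 0.0:
        return FibrilState(sigma_f=0.0, eps_f=eps_f_next, time=t_next)

    # damped Newton with numerical Jacobian, starting from the larger of the
    # previous stress and the static limit
    sig = max(sig_n, E0e)
    converged = False
    for _ in range(MAX_NEWTON):
        r = residual(sig)
        if abs(r) < 1e-12 * max(1.0, abs(sig)):
            converged = True
            break
        h = 1e-7 * max(abs(sig), 1e-3)
        drds = (residual(sig + h) - residual(sig - h)) / (2.0 * h)
        if drds == 0.0:
            break
        step = r / drds
        lam = 1.0
        while lam > 1e-4:
            cand = sig - lam * step
            if cand >= 0.0 and abs(residual(cand)) < abs(r):
                sig = cand
                break
            lam *= 0.5
        else:
            break

    if not converged:
        # bracketed fallback: expand upper bound until the residual changes sign
        lo, hi = 0.0, max(2.0 * max(sig_n, E0e), 1.0)
        r_lo = residual(lo)
        for _ in range(80):
            if r_lo * residual(hi) <= 0.0:
                break
            hi *= 2.0
        else:
            raise FibrilStressError(
                f"fibril stress step did not converge; last residual {residual(sig):.3e}"
            )
        sig = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16)

    return FibrilState(sigma_f=max(sig, 0.0), eps_f=eps_f_next, time=t_next)


def _check_symmetric(t: np.ndarray, name: str) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if t.shape != (3, 3):
        raise ValueError(f"{name} must be a 3x3 tensor")
    if np.max(np.abs(t - t.T)) > _SYM_TOL:
        raise ValueError(f"{name} is not symmetric within {_SYM_TOL}")
    return t


def fibril_tensor(fibrils, fibril_stresses, D: float) -> np.ndarray:
    """Assemble the fibrillar stress tensor from per-fibril scalar stresses.

    Each fibril contributes ``sigma_fj * e (x) e`` with
    ``sigma_fj = rho * D * C * sigma_f`` for primary and
    ``rho * D * sigma_f`` for secondary fibrils.
    """
    if len(fibrils) != len(fibril_stresses):
        raise ValueError("fibrils and fibril_stresses must have equal length")
    if not (0.0 <= D <= 1.0):
        raise ValueError("degeneration level D must lie in [0, 1]")
    out = np.zeros((3, 3))
    for spec, sig in zip(fibrils, fibril_stresses):
        w = spec.density_rho * D
        if spec.is_primary:
            w *= spec.primary_fraction_C
        out += (w * sig) * np.outer(spec.direction, spec.direction)
    return out


@dataclass
class TotalStress:
    """Total stress decomposition: nonfibrillar + fibrillar + fluid pressure."""

    sigma_nf: np.ndarray
    sigma_f_tensor: np.ndarray
    fluid_pressure_p: float
    sigma_tot: np.ndarray


def total_stress(sigma_nf: np.ndarray, sigma_f_tensor: np.ndarray, p: float) -> TotalStress:
    """Total stress ``sigma_tot = sigma_nf + sigma_f + p I``."""
    nf = _check_symmetric(sigma_nf, "sigma_nf")
    ft = _check_symmetric(sigma_f_tensor, "sigma_f_tensor")
    tot = nf + ft + p * np.eye(3)
    return TotalStress(sigma_nf=nf, sigma_f_tensor=ft, fluid_pressure_p=p, sigma_tot=tot)


def nonfibrillar_stress(strain: np.ndarray, params: MaterialParams) -> np.ndarray:
    """Linear isotropic elastic stress of the nonfibrillar matrix from
    (E_m, nu_m).  Provided for completeness of the total-stress split; the
    degeneration algorithm consumes fibril tensile stress only."""
    eps = _check_symmetric(strain, "strain")
    lam = params.E_m * params.nu_m / ((1 + params.nu_m) * (1 - 2 * params.nu_m))
    mu = params.E_m / (2 * (1 + params.nu_m))
    return lam * np.trace(eps) * np.eye(3) + 2 * mu * eps


def max_tensile_fibril_stress(
    element: Element,
    D: float,
    strain_histories: np.ndarray,
    durations: np.ndarray,
    params: MaterialParams,
) -> np.ndarray:
    """Per-increment maximum over the element's fibrils of the
    degeneration-modulated tensile fibril stress rho * D * (C|1) * sigma_f.

    ``strain_histories`` has shape (n_fibrils, n_increments) on the shared
    stance grid with increment ``durations`` (s).  Returns an array of
    length n_increments (MPa).
    """
    strains = np.atleast_2d(np.asarray(strain_histories, dtype=float))
    durations = np.asarray(durations, dtype=float)
    if strains.shape[0] != len(element.fibrils):
        raise ValueError("one strain series required per fibril")
    if strains.shape[1] != durations.shape[0]:
        raise ValueError("strain series must share the increment grid")
    n_inc = durations.shape[0]
    out = np.zeros(n_inc)
    for spec, series in zip(element.fibrils, strains):
        w = spec.density_rho * D * (spec.primary_fraction_C if spec.is_primary else 1.0)
        st = FibrilState()
        for t in range(n_inc):
            st = fibril_stress_step(st, float(series[t]), float(durations[t]), params)
            mod = w * st.sigma_f
            if mod > out[t]:
                out[t] = mod
    return out
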