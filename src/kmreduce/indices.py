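"""Epidemic summary indices: R0, growth rate, generation time, final size, HIT.

For a kernel b(tau) = U e^{tau Sigma} V and nonlinearity Psi:

* R0 = (-U Sigma^{-1} V) * Psi'(0).  For the homogeneous model Psi'(0) = N
  and this is the classical N * integral(b); with heterogeneity it is the
  unique definition under which the Euler-Lotka root crosses zero exactly
  at R0 = 1.
* The intrinsic growth rate r is the real root of the Euler-Lotka equation
  Psi'(0) * U (lambda I - Sigma)^{-1} V = 1, which is strictly decreasing
  in lambda above the spectral abscissa of Sigma.
* The generation time T = integral(tau b)/integral(b) = -(U Sigma^{-2} V)/(U Sigma^{-1} V).
* The final cumulative force w_inf is the positive fixed point of
  w = (-U Sigma^{-1} V) Psi(w); the attack rate follows by averaging the
  escape probability e^{-a(xi) w_inf} over the trait distribution.
* The herd-immunity threshold is reached when depletion of susceptibles
  brings the effective reproduction number to one, i.e. at the w* with
  (-U Sigma^{-1} V) Psi'(w*) = 1.

All root-finding is bracketing-first (bisection/Brent) on monotone scalar
problems, with residuals reported, so results are deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import CompartmentKernel, ModelSpec
from .psi import PsiFunction

logger = logging.getLogger("kmreduce")

__all__ = [
    "EpidemicIndices",
    "r0",
    "growth_rate",
    "generation_time",
    "final_size",
    "herd_immunity_threshold",
    "compute_indices",
]


@dataclass(frozen=True)
class EpidemicIndices:
    R0: float
    r: float
    T: float
    w_inf: float
    attack_rate: float
    hit: float


def _total_infectivity(kernel: CompartmentKernel) -> float:
    """-U Sigma^{-1} V by linear solve (no explicit inverse)."""
    return -float(kernel.U @ np.linalg.solve(kernel.Sigma, kernel.V))


def r0(model: ModelSpec, psi: PsiFunction) -> float:
    """Basic reproduction number (-U Sigma^{-1} V) * Psi'(0)."""
    return _total_infectivity(model.kernel) * float(psi.prime(0.0))


def growth_rate(model: ModelSpec, psi: PsiFunction, *, tol: float = 1e-12) -> float:
    """Real root r of the Euler-Lotka equation Psi'(0) U (rI - Sigma)^{-1} V = 1.

    The left-hand side is strictly decreasing for lambda above the spectral
    abscissa of Sigma, so the root is unique; it is positive iff R0 > 1.
    """
    kernel = model.kernel
    R0 = r0(model, psi)
    if R0 <= 0:
        raise ValueError("growth rate undefined: R0 <= 0")
    psi0 = float(psi.prime(0.0))
    n = kernel.n
    eye = np.eye(n)

    def euler_lotka(lam: float) -> float:
        return psi0 * float(
            kernel.U @ np.linalg.solve(lam * eye - kernel.Sigma, kernel.V)
        ) - 1.0

    abscissa = kernel.spectral_abscissa()
    # bracket: just above the abscissa the resolvent blows up (+), and for
    # large lambda it decays to -1
    scale = max(1.0, abs(abscissa))
    lo = abscissa + 1e-8 * scale
    while euler_lotka(lo) <= 0:
        lo = abscissa + 0.1 * (lo - abscissa)
        if lo - abscissa < 1e-300:
            raise RuntimeError("failed to bracket the Euler-Lotka root from below")
    hi = abscissa + scale
    for _ in range(10):
        if euler_lotka(hi) < 0:
            break
        hi = abscissa + 2.0 * (hi - abscissa)
    else:
        raise RuntimeError("failed to bracket the Euler-Lotka root from above")
    root = brentq(euler_lotka, lo, hi, xtol=1e-15, rtol=8.9e-16)
    residual = euler_lotka(root)
    if abs(residual) > tol:
        logger.warning("Euler-Lotka residual %.3g above tolerance %.3g", residual, tol)
    return float(root)


def generation_time(kernel: CompartmentKernel) -> float:
    """Mean time since infection weighted by the kernel:
    T = -(U Sigma^{-2} V)/(U Sigma^{-1} V), via two linear solves."""
    x = np.linalg.solve(kernel.Sigma, kernel.V)     # Sigma^{-1} V
    y = np.linalg.solve(kernel.Sigma, x)            # Sigma^{-2} V
    return -float(kernel.U @ y) / float(kernel.U @ x)


def final_size(model: ModelSpec, psi: PsiFunction) -> tuple[float, float]:
    """Final cumulative force of infection w_inf and overall attack rate.

    w_inf is the unique positive root of w = (-U Sigma^{-1} V) Psi(w); the
    attack rate is 1 - integral e^{-a(xi) w_inf} Phi(dxi).  Subcritical
    models (R0 <= 1) return (0, 0).
    """
    B = _total_infectivity(model.kernel)
    if B * float(psi.prime(0.0)) <= 1.0:
        return 0.0, 0.0

    def g(w: float) -> float:
        return B * float(psi(w)) - w

    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - Psi bounded, so g must go negative
            raise RuntimeError("failed to bracket the final-size root")
    w_inf = brentq(g, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
    attack = 1.0 - model.susceptible_fraction(w_inf)
    return float(w_inf), float(attack)


def herd_immunity_threshold(model: ModelSpec, psi: PsiFunction) -> float:
    """Fraction of the population no longer susceptible when the effective
    reproduction number first equals one.

    Solves (-U Sigma^{-1} V) Psi'(w*) = 1 (Psi' is strictly decreasing, so
    the root is unique) and returns 1 - s_tot(w*).  Returns 0 with a
    warning for subcritical models.
    """
    B = _total_infectivity(model.kernel)
    if B * float(psi.prime(0.0)) <= 1.0:
        logger.warning("R0 <= 1: herd-immunity threshold is 0")
        return 0.0

    def g(w: float) -> float:
        return B * float(psi.prime(w)) - 1.0

    hi = 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the HIT root")
    w_star = brentq(g, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    return float(1.0 - model.susceptible_fraction(w_star))


def compute_indices(model: ModelSpec, psi: PsiFunction) -> EpidemicIndices:
    """All indices in one report."""
    R0 = r0(model, psi)
    T = generation_time(model.kernel)
    if R0 > 1.0:
        r = growth_rate(model, psi)
        w_inf, attack = final_size(model, psi)
        hit = herd_immunity_threshold(model, psi)
    else:
        r = growth_rate(model, psi) if R0 > 0 else -math.inf
        w_inf, attack, hit = 0.0, 0.0, 0.0
    return EpidemicIndices(R0=R0, r=r, T=T, w_inf=w_inf, attack_rate=attack, hit=hit)
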