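"""Direct numerical solution of the scalar renewal equation.

The cumulative force of infection at the reference trait satisfies

    w(t) = integral_0^inf b(tau) Psi(w(t - tau)) dtau,

and the multitype generalisation couples one such equation per type
through the arc kernels.  This module discretises the convolution with the
trapezoidal rule on a uniform grid and marches forward in time, resolving
the implicit dependence on Psi(w(t)) by fixed-point iteration.  It is the
independent oracle for the ODE reductions in :mod:`kmreduce.dynamics` and
deliberately never imports from that module.

The kernel is truncated at tau_max where its exact tail integral
(available in closed form as -U e^{tau Sigma} Sigma^{-1} V) drops below
``tail_tol``, and tabulated once per run by propagating e^{h Sigma}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

from .model_core import CompartmentKernel
from .psi import PsiFunction

logger = logging.getLogger("kmreduce")

__all__ = ["REGrid", "truncate_kernel", "tabulate_kernel", "solve_re", "solve_re_system", "eigen_history"]

#: relative tolerance of the per-step fixed-point iteration
_FP_TOL = 1e-12
#: maximum automatic step halvings when the implicit step is not contractive
_MAX_HALVINGS = 5


@dataclass(frozen=True)
class REGrid:
    """Uniform discretisation of the renewal equation.

    ``history`` maps (arrays of) t <= 0 to w(t); in eigen seeding this is
    the exponential ansatz w0 e^{r t}.  ``tau_max`` defaults to the point
    where the kernel's exact tail integral falls below ``tail_tol``.
    """

    h: float
    t_end: float
    history: Callable[[np.ndarray], np.ndarray]
    tau_max: float | None = None
    tail_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.h <= 0 or self.t_end <= 0:
            raise ValueError("h and t_end must be positive")


def truncate_kernel(kernel: CompartmentKernel, tail_tol: float = 1e-10,
                    h: float | None = None) -> float:
    """Smallest (grid-aligned) tau_max with integral_{tau_max}^inf b < tail_tol.

    The tail integral is exact: -U e^{tau Sigma} Sigma^{-1} V.
    """
    if kernel.spectral_abscissa() >= 0:
        raise ValueError("kernel is not integrable: spectral abscissa >= 0")
    x = np.linalg.solve(kernel.Sigma, kernel.V)  # Sigma^{-1} V

    def tail(tau: float) -> float:
        return -float(kernel.U @ expm(tau * kernel.Sigma) @ x)

    # aim below half the tolerance so the contract holds with margin
    tail_tol = 0.5 * tail_tol
    hi = 1.0
    for _ in range(60):
        if tail(hi) < tail_tol:
            break
        hi *= 2.0
    else:  # pragma: no cover
        raise RuntimeError("failed to locate kernel truncation point")
    lo = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if tail(mid) < tail_tol:
            hi = mid
        else:
            lo = mid
    tau_max = hi
    if h is not None:
        tau_max = float(np.ceil(tau_max / h) * h)
    return tau_max


def tabulate_kernel(kernel: CompartmentKernel, h: float, J: int) -> np.ndarray:
    """b(j h) for j = 0..J by repeated application of e^{h Sigma}."""
    E = expm(h * kernel.Sigma)
    out = np.empty(J + 1)
    v = kernel.V.copy()
    for j in range(J + 1):
        out[j] = kernel.U @ v
        v = E @ v
    return out


def _resolve_b(b, h: float, grid: REGrid) -> tuple[np.ndarray, int]:
    """Accept a kernel, a callable, or a tabulated array; return (b_j, J)."""
    if isinstance(b, CompartmentKernel):
        tau_max = grid.tau_max or truncate_kernel(b, grid.tail_tol, h)
        J = max(1, int(round(tau_max / h)))
        return tabulate_kernel(b, h, J), J
    if callable(b):
        if grid.tau_max is None:
            raise ValueError("tau_max must be given for a tabulated/callable kernel")
        J = max(1, int(round(grid.tau_max / h)))
        return np.asarray(b(np.arange(J + 1) * h), dtype=float), J
    arr = np.asarray(b, dtype=float)
    return arr, arr.size - 1


def solve_re(b, psi: PsiFunction, grid: REGrid) -> tuple[np.ndarray, np.ndarray]:
    """March the trapezoidal discretisation of the renewal equation.

    ``b`` may be a :class:`CompartmentKernel`, a callable b(tau), or an
    array tabulated on the tau-grid.  Returns ``(times, w)`` on
    t = 0, h, ..., t_end.  The implicit weight (h/2) b(0) Psi' must make the
    per-step map a contraction; if not, the step is halved automatically
    (up to 5 times) before giving up.
    """
    h = grid.h
    for _ in range(_MAX_HALVINGS + 1):
        b_j, J = _resolve_b(b, h, grid)
        kappa = 0.5 * h * b_j[0] * float(psi.prime(0.0))
        if kappa < 0.9:
            break
        logger.info("implicit RE step not contractive (kappa=%.3g); halving h", kappa)
        h *= 0.5
    else:
        raise RuntimeError("renewal step size could not be made contractive")

    K = int(round(grid.t_end / h))
    coeff = np.full(J + 1, h)
    coeff[0] = coeff[J] = 0.5 * h
    coeff *= b_j
    coeff_rev = coeff[:0:-1]  # coeff[J], ..., coeff[1]
    c0 = coeff[0]

    # P[idx] = Psi(w_k) with idx = k + J, for k = -J .. K
    P = np.empty(J + K + 1)
    t_hist = -h * np.arange(J, 0, -1)
    P[:J] = np.asarray(psi(grid.history(t_hist)), dtype=float)
    w = np.empty(K + 1)
    w[0] = float(grid.history(0.0))
    P[J] = float(psi(w[0]))
    for k in range(1, K + 1):
        idx = k + J
        base = float(coeff_rev @ P[idx - J : idx])
        wk = w[k - 1]
        for _ in range(100):
            new = base + c0 * float(psi(wk))
            if abs(new - wk) <= _FP_TOL * max(1.0, abs(new)):
                wk = new
                break
            wk = new
        else:  # pragma: no cover
            raise RuntimeError(f"fixed-point iteration failed at t = {k * h:.4g}")
        w[k] = wk
        P[idx] = float(psi(wk))
    return h * np.arange(K + 1), w


def solve_re_system(
    arcs: Sequence[Sequence],
    psis: Sequence[PsiFunction],
    grid: REGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Componentwise trapezoidal marching for a system of renewal equations.

    ``arcs[i][j]`` is the kernel carrying transmission from type j to type
    i (None for an absent arc): w_i(t) = sum_j integral b_ij(tau)
    Psi_j(w_j(t - tau)) dtau.  ``grid.history`` must return shape (m,)
    (or (m, len(t))) arrays.  Returns ``(times, w)`` with w of shape
    (m, K + 1).
    """
    m = len(psis)
    h = grid.h
    # tabulate every arc on a common tau-grid
    tau_max = grid.tau_max
    if tau_max is None:
        tau_max = 0.0
        for row in arcs:
            for arc in row:
                if isinstance(arc, CompartmentKernel):
                    tau_max = max(tau_max, truncate_kernel(arc, grid.tail_tol, h))
        if tau_max == 0.0:
            tau_max = h
    J = max(1, int(round(tau_max / h)))
    B = np.zeros((m, m, J + 1))
    for i in range(m):
        for j in range(m):
            arc = arcs[i][j]
            if arc is None:
                continue
            if isinstance(arc, CompartmentKernel):
                B[i, j] = tabulate_kernel(arc, h, J)
            elif callable(arc):
                B[i, j] = arc(np.arange(J + 1) * h)
            else:
                B[i, j] = np.asarray(arc, dtype=float)

    psi0 = np.array([float(p.prime(0.0)) for p in psis])
    kappa = 0.5 * h * float(np.max(B[:, :, 0] @ psi0))
    if kappa >= 0.9:
        raise RuntimeError(
            f"implicit RE-system step not contractive (kappa = {kappa:.3g}); use smaller h"
        )

    K = int(round(grid.t_end / h))
    wt = np.full(J + 1, h)
    wt[0] = wt[J] = 0.5 * h
    coeff = B * wt  # (m, m, J+1)
    coeff_rev = coeff[:, :, :0:-1]  # j = J..1
    C0 = coeff[:, :, 0]  # (m, m)

    P = np.empty((m, J + K + 1))
    t_hist = -h * np.arange(J, 0, -1)
    hist = np.asarray(grid.history(t_hist), dtype=float).reshape(m, J)
    for j in range(m):
        P[j, :J] = psis[j](hist[j])
    w = np.empty((m, K + 1))
    w[:, 0] = np.asarray(grid.history(0.0), dtype=float).reshape(m)
    for j in range(m):
        P[j, J] = float(psis[j](w[j, 0]))
    for k in range(1, K + 1):
        idx = k + J
        base = np.einsum("ijl,jl->i", coeff_rev, P[:, idx - J : idx])
        wk = w[:, k - 1].copy()
        for _ in range(100):
            pk = np.array([float(psis[j](wk[j])) for j in range(m)])
            new = base + C0 @ pk
            if np.max(np.abs(new - wk)) <= _FP_TOL * max(1.0, float(np.max(np.abs(new)))):
                wk = new
                break
            wk = new
        else:  # pragma: no cover
            raise RuntimeError(f"fixed-point iteration failed at t = {k * h:.4g}")
        w[:, k] = wk
        for j in range(m):
            P[j, idx] = float(psis[j](wk[j]))
    return h * np.arange(K + 1), w


def eigen_history(model, psi: PsiFunction, w0: float = 1e-6) -> Callable:
    """History w(t) = w0 e^{r t} on t <= 0 from the Euler-Lotka root r."""
    from .indices import growth_rate

    r = growth_rate(model, psi)
    return lambda t: w0 * np.exp(r * np.asarray(t, dtype=float))
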