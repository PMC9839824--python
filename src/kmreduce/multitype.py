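"""Multitype transmission: two-sex and host-vector cyclic structures.

Each type i has its own population size N_i, a kernel triple
(V_i, Sigma_i, U_i) describing *infected individuals of type i*, and a
nonlinearity Psi_i (homogeneous or built from a per-type trait model).
The arc structure says who infects whom: ``arcs[i][j]`` present means the
force of infection on type i receives the output U_j of type-j infecteds.
For the heterosexual / host-vector case the arc matrix is antidiagonal
(zero diagonal), giving the coupled renewal system

    w_i(t) = sum_j integral b_j(tau) Psi_j(w_j(t - tau)) dtau   over arcs (i, j),

the integrated form dQ_i/dt = Sigma_i Q_i + Psi_i(w_i) V_i with
w_i = sum_j U_j Q_j, and the standard form in (S_i, Y_i).

The next-generation matrix has entries K_ij = Psi_i'(0) (-U_j Sigma_j^{-1}
V_j) on present arcs; its spectral radius is R0, reducing to
sqrt(K_12 K_21) for the two-type zero-diagonal case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import SeedSpec, SolverConfig, Trajectory
from .model_core import (
    CompartmentKernel,
    ModelSpec,
    StructuralError,
    TraitModel,
    validate_kernel,
)
from .psi import PsiFunction, psi_for_model

logger = logging.getLogger("kmreduce")

__all__ = [
    "MultitypeModel",
    "multitype_r0",
    "multitype_growth_rate",
    "multitype_seed_state",
    "simulate_multitype_integrated",
    "simulate_multitype_standard",
]


@dataclass(frozen=True)
class MultitypeModel:
    """Cyclic multitype model: per-type kernels, populations and traits.

    ``arcs[i][j]`` (boolean) enables transmission from type j to type i
    using type j's kernel.  ``traits[i]`` is None for a homogeneous type.
    """

    Ns: tuple[float, ...]
    kernels: tuple[CompartmentKernel, ...]
    arcs: np.ndarray
    traits: tuple[TraitModel | None, ...] | None = None

    def __post_init__(self) -> None:
        m = len(self.Ns)
        arcs = np.asarray(self.arcs, dtype=bool)
        if arcs.shape != (m, m):
            raise StructuralError(f"arcs must be {m}x{m}, got {arcs.shape}")
        if len(self.kernels) != m:
            raise StructuralError("one kernel per type is required")
        object.__setattr__(self, "arcs", arcs)
        if self.traits is None:
            object.__setattr__(self, "traits", tuple(None for _ in range(m)))
        for i, k in enumerate(self.kernels):
            rep = validate_kernel(k)
            if not rep.passed:
                raise ValueError(f"kernel of type {i} invalid: {rep.violations}")

    @property
    def m(self) -> int:
        return len(self.Ns)

    def psis(self) -> tuple[PsiFunction, ...]:
        return tuple(
            psi_for_model(ModelSpec(N=self.Ns[i], kernel=self.kernels[i], trait=self.traits[i]))
            for i in range(self.m)
        )

    def type_model(self, i: int) -> ModelSpec:
        return ModelSpec(N=self.Ns[i], kernel=self.kernels[i], trait=self.traits[i])

    def is_irreducible(self) -> bool:
        m = self.m
        reach = self.arcs | np.eye(m, dtype=bool)
        power = reach.copy()
        for _ in range(m):
            power = power @ reach
        return bool(np.all(power))


def multitype_r0(model: MultitypeModel) -> float:
    """Spectral radius of the next-generation matrix."""
    m = model.m
    psis = model.psis()
    expected = np.array(
        [-float(k.U @ np.linalg.solve(k.Sigma, k.V)) for k in model.kernels]
    )
    psi0 = np.array([float(p.prime(0.0)) for p in psis])
    K = np.where(model.arcs, np.outer(psi0, expected), 0.0)
    return float(np.max(np.abs(np.linalg.eigvals(K))))


def _linearization(model: MultitypeModel):
    """Block matrix of the linearised integrated system, plus block offsets."""
    psis = model.psis()
    sizes = [k.n for k in model.kernels]
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    dim = offsets[-1]
    M = np.zeros((dim, dim))
    for i, ki in enumerate(model.kernels):
        sl_i = slice(offsets[i], offsets[i + 1])
        M[sl_i, sl_i] += ki.Sigma
        for j, kj in enumerate(model.kernels):
            if model.arcs[i, j]:
                sl_j = slice(offsets[j], offsets[j + 1])
                M[sl_i, sl_j] += float(psis[i].prime(0.0)) * np.outer(ki.V, kj.U)
    return M, offsets, psis


def multitype_growth_rate(model: MultitypeModel) -> float:
    """Leading eigenvalue (largest real part) of the linearised system."""
    M, _, _ = _linearization(model)
    return float(np.max(np.linalg.eigvals(M).real))


def multitype_seed_state(model: MultitypeModel, seed: SeedSpec):
    """Eigen seeding along the leading eigenvector of the linearisation.

    Scales the mode so the cumulative force on type 1 starts at w0, sets
    Y_i(0) = r Q_i(0), and returns (Q0 blocks, Y0 blocks, w_i(0), r).
    """
    if not model.is_irreducible():
        raise ValueError("eigen seeding requires an irreducible arc structure")
    M, offsets, psis = _linearization(model)
    vals, vecs = np.linalg.eig(M)
    lead = int(np.argmax(vals.real))
    r = float(vals[lead].real)
    if abs(vals[lead].imag) > 1e-9 * max(1.0, abs(r)):
        raise RuntimeError("leading eigenvalue is not real; cannot eigen-seed")
    if r <= 0:
        raise ValueError("eigen seeding requires a supercritical model (r > 0)")
    v = vecs[:, lead].real
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9 * np.max(np.abs(v))):
        raise RuntimeError("leading eigenvector is not nonnegative")
    v = np.clip(v, 0.0, None)
    Q_blocks = [v[offsets[i]: offsets[i + 1]] for i in range(model.m)]
    w = np.array([
        sum(
            float(model.kernels[j].U @ Q_blocks[j])
            for j in range(model.m) if model.arcs[i, j]
        )
        for i in range(model.m)
    ])
    scale = seed.w0 / w[0]
    Q0 = [q * scale for q in Q_blocks]
    return Q0, [r * q for q in Q0], w * scale, r


def _force(model: MultitypeModel, blocks: list[np.ndarray]) -> np.ndarray:
    """w_i (or F_i) = sum over present arcs (i, j) of U_j . block_j."""
    out = np.zeros(model.m)
    for i in range(model.m):
        for j in range(model.m):
            if model.arcs[i, j]:
                out[i] += float(model.kernels[j].U @ blocks[j])
    return out


def _per_type_trajectories(model, times, w, wdot, Q=None, Y=None, form="integrated"):
    trajs = []
    for i in range(model.m):
        spec = model.type_model(i)
        traj = Trajectory(
            times=times, w=w[i],
            Q=None if Q is None else Q[i],
            Y=None if Y is None else Y[i],
            form=form,
        )
        traj.s_bar = np.exp(-w[i])
        traj.s_tot = np.asarray(spec.susceptible_fraction(w[i]), dtype=float)
        traj.S = spec.N * traj.s_tot
        traj.incidence = spec.N * np.asarray(spec.depletion_weight(w[i])) * wdot[i]
        trajs.append(traj)
    return trajs


def simulate_multitype_integrated(
    model: MultitypeModel,
    seed: SeedSpec | None = None,
    t_end: float = 100.0,
    config: SolverConfig | None = None,
) -> list[Trajectory]:
    """Integrate dQ_i/dt = Sigma_i Q_i + Psi_i(w_i) V_i, w_i = sum_j U_j Q_j."""
    seed = seed or SeedSpec()
    config = config or SolverConfig()
    psis = model.psis()
    sizes = [k.n for k in model.kernels]
    offsets = np.concatenate(([0], np.cumsum(sizes)))

    def split(z):
        return [z[offsets[i]: offsets[i + 1]] for i in range(model.m)]

    def rhs(_t, z):
        Q = split(z)
        w = _force(model, Q)
        return np.concatenate([
            model.kernels[i].Sigma @ Q[i] + float(psis[i](w[i])) * model.kernels[i].V
            for i in range(model.m)
        ])

    if seed.mode == "eigen":
        Q0, _, _, _ = multitype_seed_state(model, seed)
        z0 = np.concatenate(Q0)
    else:
        z0 = np.asarray(seed.Q0, dtype=float)
        if z0.shape != (offsets[-1],):
            raise StructuralError("explicit multitype seed must concatenate all Q_i")
    times = np.linspace(0.0, t_end, config.n_points)
    sol = solve_ivp(rhs, (0.0, t_end), z0, method=config.method, t_eval=times,
                    rtol=config.rtol, atol=config.atol_scale * max(model.Ns))
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    Q_t = [sol.y[offsets[i]: offsets[i + 1]].T for i in range(model.m)]
    w = np.stack([
        sum(Q_t[j] @ model.kernels[j].U for j in range(model.m) if model.arcs[i, j])
        for i in range(model.m)
    ])
    dz = np.stack([rhs(0.0, zc) for zc in sol.y.T])
    dQ_t = [dz[:, offsets[i]: offsets[i + 1]] for i in range(model.m)]
    wdot = np.stack([
        sum(dQ_t[j] @ model.kernels[j].U for j in range(model.m) if model.arcs[i, j])
        for i in range(model.m)
    ])
    return _per_type_trajectories(model, times, w, wdot, Q=Q_t, form="integrated")


def simulate_multitype_standard(
    model: MultitypeModel,
    seed: SeedSpec | None = None,
    t_end: float = 100.0,
    config: SolverConfig | None = None,
) -> list[Trajectory]:
    """Integrate the multitype standard form in (w_i, Y_i).

    dw_i/dt = F_i = sum_j U_j Y_j over present arcs, and
    dY_i/dt = Sigma_i Y_i + F_i Psi_i'(w_i) V_i; for homogeneous types
    Psi_i'(w_i) = N_i e^{-w_i} = S_i, the textbook system.
    """
    seed = seed or SeedSpec()
    config = config or SolverConfig()
    psis = model.psis()
    m = model.m
    sizes = [k.n for k in model.kernels]
    offsets = np.concatenate(([0], np.cumsum(sizes)))

    def rhs(_t, z):
        w = z[:m]
        Y = [z[m + offsets[i]: m + offsets[i + 1]] for i in range(m)]
        F = _force(model, Y)
        dY = [
            model.kernels[i].Sigma @ Y[i]
            + F[i] * float(psis[i].prime(w[i])) * model.kernels[i].V
            for i in range(m)
        ]
        return np.concatenate([F, *dY])

    if seed.mode == "eigen":
        Q0, Y0, w0, _ = multitype_seed_state(model, seed)
        z0 = np.concatenate([w0, *Y0])
    else:
        if seed.Q0 is None or seed.Y0 is None:
            raise StructuralError("explicit multitype standard seed needs Q0-style w and Y0")
        z0 = np.concatenate([np.asarray(seed.Q0, dtype=float), np.asarray(seed.Y0, dtype=float)])
    times = np.linspace(0.0, t_end, config.n_points)
    sol = solve_ivp(rhs, (0.0, t_end), z0, method=config.method, t_eval=times,
                    rtol=config.rtol, atol=config.atol_scale * max(model.Ns))
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    w = sol.y[:m]
    Y_t = [sol.y[m + offsets[i]: m + offsets[i + 1]].T for i in range(m)]
    wdot = np.stack([
        sum(Y_t[j] @ model.kernels[j].U for j in range(m) if model.arcs[i, j])
        for i in range(m)
    ])
    return _per_type_trajectories(model, times, w, wdot, Y=Y_t, form="standard")
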