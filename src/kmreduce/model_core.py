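"""Core model objects: the compartmental kernel triple and trait models.

A compartmental outbreak model with one state-at-infection is coded by a
triple ``(V, Sigma, U)``: ``V`` is the (sub)probability distribution of the
state at the moment of infection, ``Sigma`` the transition-rate matrix among
the ``n`` infected compartments, and ``U`` the per-compartment contribution
rates to the force of infection.  The time-since-infection kernel is then

    b(tau) = U expm(tau * Sigma) V,

the expected contribution to the force of infection of an individual
infected ``tau`` time units ago.

Separable static heterogeneity is described by a :class:`TraitModel`: a
trait distribution Phi on a domain Omega together with relative
susceptibility ``a`` and relative infectiousness ``c`` maps, normalised to 1
at a reference trait ``x_bar``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

logger = logging.getLogger("kmreduce")

#: eigenvalues of Sigma must have real part below this threshold
EIG_REAL_PART_TOL = -1e-12
#: tolerance for trait weights summing / integrating to one
TRAIT_MASS_TOL = 1e-10
#: tolerance for a(x_bar) = c(x_bar) = 1
TRAIT_NORM_TOL = 1e-12


class StructuralError(ValueError):
    """Shapes or types of a model specification are inconsistent."""


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


@dataclass(frozen=True)
class CompartmentKernel:
    """The (V, Sigma, U) triple defining b(tau) = U e^{tau Sigma} V.

    Parameters
    ----------
    U : array_like, shape (n,)
        Nonnegative contribution rates to the force of infection,
        units 1/(time * individual).
    Sigma : array_like, shape (n, n)
        Transition-rate matrix (subgenerator: nonnegative off-diagonal,
        eigenvalues with strictly negative real part), units 1/time.
    V : array_like, shape (n,)
        Nonnegative state-at-infection distribution; sums to a value in
        (0, 1].  A sum below one is interpreted as a fraction of
        infections that never contribute to transmission.
    """

    U: np.ndarray
    Sigma: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        U = np.atleast_1d(np.asarray(self.U, dtype=float)).ravel()
        V = np.atleast_1d(np.asarray(self.V, dtype=float)).ravel()
        Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if Sigma.ndim != 2 or Sigma.shape[0] != Sigma.shape[1]:
            raise StructuralError(f"Sigma must be square, got shape {Sigma.shape}")
        n = Sigma.shape[0]
        if U.shape != (n,) or V.shape != (n,):
            raise StructuralError(
                f"dimension mismatch: Sigma is {n}x{n}, U has length {U.shape[0]}, "
                f"V has length {V.shape[0]}"
            )
        if not (np.all(np.isfinite(U)) and np.all(np.isfinite(V)) and np.all(np.isfinite(Sigma))):
            raise StructuralError("kernel entries must be finite")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "Sigma", Sigma)
        object.__setattr__(self, "V", V)
        if 0.0 < V.sum() < 1.0 - 1e-12:
            logger.warning(
                "V sums to %.6g < 1; the deficit is treated as infections that "
                "never transmit", V.sum(),
            )

    @property
    def n(self) -> int:
        return self.Sigma.shape[0]

    def spectral_abscissa(self) -> float:
        return float(np.max(np.linalg.eigvals(self.Sigma).real))

    def b(self, tau):
        """Evaluate the kernel b(tau) = U e^{tau Sigma} V (vectorised)."""
        return kernel_eval(self, tau)

    def total_infectivity(self) -> float:
        """integral of b over [0, inf) = -U Sigma^{-1} V, by linear solve."""
        return -float(self.U @ np.linalg.solve(self.Sigma, self.V))


def validate_kernel(kernel: CompartmentKernel) -> ValidationReport:
    """Check the subgenerator/sign invariants of a kernel triple.

    Structural problems (non-square Sigma, length mismatches) raise
    :class:`StructuralError` at construction time; this function reports
    violations of the mathematical invariants.
    """
    violations: list[str] = []
    S, U, V = kernel.Sigma, kernel.U, kernel.V
    off = S - np.diag(np.diag(S))
    if np.any(off < 0):
        violations.append("Sigma has a negative off-diagonal entry")
    if np.any(np.diag(S) > 0):
        violations.append("Sigma has a positive diagonal entry")
    if np.max(np.linalg.eigvals(S).real) > EIG_REAL_PART_TOL:
        violations.append("eigenvalue real part not negative")
    if np.any(V < 0):
        violations.append("V has a negative entry")
    vsum = V.sum()
    if not (0.0 < vsum <= 1.0 + 1e-12):
        violations.append(f"V entries sum to {vsum:.6g}, outside (0, 1]")
    if np.any(U < 0):
        violations.append("U has a negative entry")
    if not np.any(U > 0):
        violations.append("U has no positive entry")
    return ValidationReport(passed=not violations, violations=tuple(violations))


def kernel_eval(kernel: CompartmentKernel, tau):
    """b(tau) = U e^{tau Sigma} V for scalar or array tau >= 0.

    Uses a dense scaling-and-squaring matrix exponential; accurate to near
    machine precision for the small n typical of compartmental models.
    """
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be nonnegative")
    flat = np.atleast_1d(tau_arr).ravel()
    out = np.empty(flat.shape)
    for i, t in enumerate(flat):
        out[i] = kernel.U @ expm(t * kernel.Sigma) @ kernel.V
    if tau_arr.ndim == 0:
        return float(out[0])
    return out.reshape(tau_arr.shape)


def random_kernel_fixture(n: int, seed: int) -> CompartmentKernel:
    """Deterministic-in-seed generator of valid kernel triples.

    Off-diagonal Sigma entries are uniform nonnegative; diagonals make each
    column sum strictly negative (so the subgenerator and eigenvalue
    conditions hold); U is nonnegative with at least one positive entry and
    V is a probability vector.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    off = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(off, 0.0)
    # column j: outflow exceeds the transfer into other compartments
    leave = off.sum(axis=0) + rng.uniform(0.1, 1.0, size=n)
    Sigma = off - np.diag(leave)
    U = rng.uniform(0.05, 1.0, size=n)
    V = rng.dirichlet(np.ones(n))
    return CompartmentKernel(U=U, Sigma=Sigma, V=V)


# ---------------------------------------------------------------------------
# Trait models
# ---------------------------------------------------------------------------

def _as_map(m, atoms=None) -> Callable[[float], float]:
    """Accept a callable, a constant, or (for discrete domains) a sequence
    of per-atom values, and return a callable on the trait domain."""
    if callable(m):
        return m
    if np.isscalar(m):
        val = float(m)
        return lambda x, _v=val: _v
    if atoms is None:
        raise StructuralError("tabulated trait map requires a discrete domain")
    values = {float(x): float(v) for (x, _w), v in zip(atoms, m)}
    return lambda x, _tab=values: _tab[float(x)]


@dataclass(frozen=True)
class TraitModel:
    """Trait distribution Phi with susceptibility map a and infectiousness map c.

    Either a finite list of ``atoms`` (value, probability-weight pairs) or a
    continuous ``density`` on ``support`` (right endpoint may be inf).  The
    maps satisfy a(x_bar) = c(x_bar) = 1 so that w(t) is the cumulative
    force of infection experienced by reference-trait individuals.
    """

    a: Callable[[float], float]
    c: Callable[[float], float]
    x_bar: float
    atoms: tuple[tuple[float, float], ...] | None = None
    density: Callable[[np.ndarray], np.ndarray] | None = None
    support: tuple[float, float] = (0.0, math.inf)
    #: set by the gamma_trait constructor; lets dynamics/psi pick closed forms
    gamma_p: float | None = None
    gamma_c_mode: str | None = None

    def __post_init__(self) -> None:
        if (self.atoms is None) == (self.density is None):
            raise StructuralError("provide exactly one of atoms or density")
        if self.atoms is not None:
            atoms = tuple((float(x), float(w)) for x, w in self.atoms)
            object.__setattr__(self, "atoms", atoms)

    @property
    def is_discrete(self) -> bool:
        return self.atoms is not None

    def validate(self) -> ValidationReport:
        violations: list[str] = []
        if self.is_discrete:
            mass = sum(w for _x, w in self.atoms)
            if abs(mass - 1.0) > TRAIT_MASS_TOL:
                violations.append(f"atom weights sum to {mass!r}, not 1")
            if any(w < 0 for _x, w in self.atoms):
                violations.append("negative atom weight")
        else:
            from .psi import _quad_nodes  # deferred: avoids import cycle at module load

            nodes, wts = _quad_nodes(self)
            mass = float(np.sum(wts))
            if abs(mass - 1.0) > 1e-8:
                violations.append(f"density integrates to {mass!r}, not 1")
        if abs(self.a(self.x_bar) - 1.0) > TRAIT_NORM_TOL:
            violations.append("a(x_bar) != 1")
        if abs(self.c(self.x_bar) - 1.0) > TRAIT_NORM_TOL:
            violations.append("c(x_bar) != 1")
        return ValidationReport(passed=not violations, violations=tuple(violations))


def discrete_trait(atoms: Sequence[tuple[float, float]], a, c, x_bar: float) -> TraitModel:
    """Trait model on a finite set.  ``atoms`` are (value, weight) pairs; the
    maps may be callables, constants, or sequences aligned with ``atoms``."""
    atoms = tuple((float(x), float(w)) for x, w in atoms)
    return TraitModel(a=_as_map(a, atoms), c=_as_map(c, atoms), x_bar=float(x_bar), atoms=atoms)


def gamma_trait(p: float, c_mode: str = "constant_one") -> TraitModel:
    """Gamma-distributed relative susceptibility.

    The trait x on (0, inf) follows a Gamma distribution with mean 1 and
    variance 1/p; a(x) = x, and c is either identically 1 (``constant_one``)
    or c(x) = x (``proportional_to_trait``).  The mean trait 1 is the
    reference, so a(x_bar) = 1 exactly.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    if c_mode not in ("constant_one", "proportional_to_trait"):
        raise ValueError(f"unknown c_mode {c_mode!r}")
    lognorm = p * math.log(p) - math.lgamma(p)

    def density(x):
        x = np.asarray(x, dtype=float)
        return np.exp(lognorm + (p - 1.0) * np.log(x) - p * x)

    c = (lambda x: 1.0) if c_mode == "constant_one" else (lambda x: x)
    return TraitModel(
        a=lambda x: x, c=c, x_bar=1.0, density=density, support=(0.0, math.inf),
        gamma_p=float(p), gamma_c_mode=c_mode,
    )


@dataclass(frozen=True)
class ModelSpec:
    """Population size N, kernel triple, and optional trait model.

    An absent trait means the homogeneous model (a = c = 1 identically).
    """

    N: float
    kernel: CompartmentKernel
    trait: TraitModel | None = None

    def __post_init__(self) -> None:
        if not (self.N > 0 and math.isfinite(self.N)):
            raise ValueError("N must be a positive finite real")

    def validate(self) -> ValidationReport:
        rep = validate_kernel(self.kernel)
        violations = list(rep.violations)
        if self.trait is not None:
            violations.extend(self.trait.validate().violations)
        return ValidationReport(passed=not violations, violations=tuple(violations))

    def susceptible_fraction(self, w):
        """s_tot(w) = integral of sbar^{a(xi)} Phi(dxi) with sbar = e^{-w}."""
        w = np.asarray(w, dtype=float)
        if self.trait is None:
            out = np.exp(-w)
        elif self.trait.is_discrete:
            out = sum(
                wt * np.exp(-self.trait.a(x) * w) for x, wt in self.trait.atoms
            )
        elif self.trait.gamma_p is not None:
            from .psi import gamma_laplace

            out = gamma_laplace(self.trait.gamma_p, w)
        else:
            from .psi import _quad_nodes

            nodes, wts = _quad_nodes(self.trait)
            a_vals = np.asarray([self.trait.a(x) for x in nodes])
            out = np.exp(-np.multiply.outer(w, a_vals)) @ wts
        return out if np.ndim(w) else float(out)

    def depletion_weight(self, w):
        """integral of a(xi) sbar^{a(xi)} Phi(dxi); incidence = N * this * dw/dt."""
        w = np.asarray(w, dtype=float)
        if self.trait is None:
            out = np.exp(-w)
        elif self.trait.is_discrete:
            out = sum(
                wt * self.trait.a(x) * np.exp(-self.trait.a(x) * w)
                for x, wt in self.trait.atoms
            )
        elif self.trait.gamma_p is not None:
            p = self.trait.gamma_p
            out = np.power(w / p + 1.0, -p - 1.0)
        else:
            from .psi import _quad_nodes

            nodes, wts = _quad_nodes(self.trait)
            a_vals = np.asarray([self.trait.a(x) for x in nodes])
            out = np.exp(-np.multiply.outer(w, a_vals)) @ (wts * a_vals)
        return out if np.ndim(w) else float(out)
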