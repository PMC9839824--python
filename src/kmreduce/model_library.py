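"""Named model constructors: SIR, SEIR, quarantine-SEIR, two-sex systems.

Each constructor returns the kernel triple (V, Sigma, U) coding the model,
wrapped in a :class:`~kmreduce.model_core.ModelSpec` (or
:class:`~kmreduce.multitype.MultitypeModel` for the two-sex case).
"""

from __future__ import annotations

import numpy as np

from .model_core import CompartmentKernel, ModelSpec, TraitModel, discrete_trait
from .multitype import MultitypeModel

__all__ = [
    "sir_model",
    "seir_model",
    "quarantine_seir_model",
    "two_group_immunity_variant",
    "two_sex_model",
]


def _require_positive(**params: float) -> None:
    for name, val in params.items():
        if not val > 0:
            raise ValueError(f"{name} must be positive, got {val!r}")


def sir_model(beta: float, alpha: float, N: float,
              trait: TraitModel | None = None) -> ModelSpec:
    """SIR: n = 1, U = [beta], Sigma = [-alpha], V = [1].

    beta is the transmission rate per infectious individual per susceptible,
    alpha the recovery rate; the kernel is b(tau) = beta e^{-alpha tau}.
    """
    _require_positive(beta=beta, alpha=alpha, N=N)
    kernel = CompartmentKernel(U=[beta], Sigma=[[-alpha]], V=[1.0])
    return ModelSpec(N=N, kernel=kernel, trait=trait)


def seir_model(beta: float, gamma: float, alpha: float, N: float,
               trait: TraitModel | None = None) -> ModelSpec:
    """SEIR: exposed (rate gamma to infectious) then infectious (recovery
    rate alpha); n = 2 with V seeding E and U reading I."""
    _require_positive(beta=beta, gamma=gamma, alpha=alpha, N=N)
    kernel = CompartmentKernel(
        U=[0.0, beta],
        Sigma=[[-gamma, 0.0], [gamma, -alpha]],
        V=[1.0, 0.0],
    )
    return ModelSpec(N=N, kernel=kernel, trait=trait)


def quarantine_seir_model(
    p: float, gamma1: float, gamma2: float, alpha1: float, alpha2: float,
    theta: float, beta1: float, beta2: float, N: float,
    trait: TraitModel | None = None,
) -> ModelSpec:
    """SEIR with asymptomatic infection and quarantine.

    A fraction p of infections is asymptomatic (index 1), the rest
    symptomatic (index 2); symptomatic infectious individuals are removed
    into quarantine at rate theta on top of recovery at rate alpha2.
    Compartment ordering is (E1, E2, I1, I2); the recovered and
    quarantined pools are bookkeeping only and not part of the state.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    _require_positive(gamma1=gamma1, gamma2=gamma2, alpha1=alpha1,
                      alpha2=alpha2, theta=theta, beta1=beta1, beta2=beta2, N=N)
    Sigma = np.array([
        [-gamma1, 0.0, 0.0, 0.0],
        [0.0, -gamma2, 0.0, 0.0],
        [gamma1, 0.0, -alpha1, 0.0],
        [0.0, gamma2, 0.0, -(alpha2 + theta)],
    ])
    kernel = CompartmentKernel(
        U=[0.0, 0.0, beta1, beta2],
        Sigma=Sigma,
        V=[p, 1.0 - p, 0.0, 0.0],
    )
    return ModelSpec(N=N, kernel=kernel, trait=trait)


def two_group_immunity_variant(base: ModelSpec, N1: float, N2: float,
                               eps1: float, eps2: float) -> ModelSpec:
    """Attach two-group partial immunity to an existing model.

    Group 1 (size N1) is the fully susceptible reference; group 2 (size
    N2) has relative susceptibility eps1 and relative infectiousness eps2,
    whether from prior infection or vaccination.  With eps1 = eps2 = eps
    the same trait model reads as a fraction N2/N complying with a contact
    reduction by factor eps.  The resulting nonlinearity is

        Psi(w) = N1 (1 - e^{-w}) + N2 eps2 (1 - e^{-eps1 w}).
    """
    if abs(N1 + N2 - base.N) > 1e-9 * base.N:
        raise ValueError("N1 + N2 must equal the base population size")
    if eps1 < 0 or eps2 < 0:
        raise ValueError("eps1 and eps2 must be nonnegative")
    N = base.N
    trait = discrete_trait(
        atoms=[(1.0, N1 / N), (2.0, N2 / N)],
        a=[1.0, eps1], c=[1.0, eps2], x_bar=1.0,
    )
    return ModelSpec(N=N, kernel=base.kernel, trait=trait)


def two_sex_model(
    N1: float, N2: float,
    kernel1: CompartmentKernel | None = None,
    kernel2: CompartmentKernel | None = None,
    beta: tuple[float, float] = (0.0005, 0.0005),
    alpha: tuple[float, float] = (0.25, 0.25),
    traits: tuple[TraitModel | None, TraitModel | None] = (None, None),
) -> MultitypeModel:
    """Heterosexual (or host-vector) two-type model with zero-diagonal arcs.

    Each sex has its own kernel triple; by default SIR-like kernels
    (U_i = [beta_i], Sigma_i = [-alpha_i], V_i = [1]).  Infections of
    type 1 are driven by type-2 infecteds and vice versa.  Per-type trait
    models (e.g. a Gamma-distributed promiscuity trait) may be attached;
    the contact-symmetry constraint between the sexes is deliberately not
    enforced.
    """
    _require_positive(N1=N1, N2=N2)
    if kernel1 is None:
        kernel1 = CompartmentKernel(U=[beta[0]], Sigma=[[-alpha[0]]], V=[1.0])
    if kernel2 is None:
        kernel2 = CompartmentKernel(U=[beta[1]], Sigma=[[-alpha[1]]], V=[1.0])
    arcs = np.array([[False, True], [True, False]])
    return MultitypeModel(Ns=(N1, N2), kernels=(kernel1, kernel2),
                          arcs=arcs, traits=tuple(traits))
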