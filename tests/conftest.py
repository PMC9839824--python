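import numpy as np
import pytest

import kmreduce as km


def make_fixture_model(seed: int, heterogeneity: str | None = None,
                       R0_target: float | None = None) -> km.ModelSpec:
    """Random supercritical model, deterministic in seed.

    The kernel is a random valid triple; N is chosen so R0 hits the target
    (default cycles through 1.5 .. 2.5).  ``heterogeneity`` is None,
    "gamma" or "discrete".
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 5))
    kernel = km.random_kernel_fixture(n, seed)
    if R0_target is None:
        R0_target = 1.5 + 0.25 * (seed % 5)
    if heterogeneity == "gamma":
        trait = km.gamma_trait(p=float(rng.choice([0.5, 1.0, 2.0])))
    elif heterogeneity == "discrete":
        eps1, eps2 = rng.uniform(0.3, 1.8, size=2)
        trait = km.discrete_trait(
            atoms=[(1.0, 0.5), (2.0, 0.5)], a=[1.0, eps1], c=[1.0, eps2], x_bar=1.0,
        )
    else:
        trait = None
    B = kernel.total_infectivity()
    # Psi'(0) = N * E[c a]; rescale N so (-U Sigma^-1 V) Psi'(0) = R0_target
    probe = km.psi_for_model(km.ModelSpec(N=1.0, kernel=kernel, trait=trait))
    N = R0_target / (B * float(probe.prime(0.0)))
    return km.ModelSpec(N=N, kernel=kernel, trait=trait)


@pytest.fixture
def sir():
    model = km.sir_model(beta=0.0005, alpha=0.25, N=1000.0)
    return model, km.psi_for_model(model)


@pytest.fixture
def seir():
    model = km.seir_model(beta=0.0005, gamma=0.25, alpha=0.25, N=1000.0)
    return model, km.psi_for_model(model)


@pytest.fixture
def gamma_sir():
    model = km.sir_model(beta=0.0005, alpha=0.25, N=1000.0,
                         trait=km.gamma_trait(p=1.0))
    return model, km.psi_for_model(model)
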