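import numpy as np
import pytest

from mihmm import (
    GeneratorProfile,
    HMMConfig,
    SessionSet,
    SyntheticSpec,
    default_high_profile,
    default_low_profile,
    generate_dataset,
)


@pytest.fixture(scope="session")
def relaxed_config() -> HMMConfig:
    """EM settings for quick fits in tests."""
    return HMMConfig(max_iter=60, tol=1e-4)


@pytest.fixture(scope="session")
def study_sessions() -> SessionSet:
    """Default 30 high + 10 low study design from the default profiles."""
    return generate_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def short_profile() -> GeneratorProfile:
    """High-quality dynamics with shorter sessions (fast fits)."""
    p = default_high_profile()
    return GeneratorProfile(name="short-high", pi=p.pi, A=p.A, length_range=(30, 60))


def random_hmm_model(rng: np.random.Generator, n_states: int = 3, discretization: str = "none"):
    """A random valid Gaussian HMM for oracle tests.

    Plain-density emissions by default so enumeration oracles can use the
    continuous Gaussian pdf directly.
    """
    from mihmm.hmm import HMMModel

    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    mu = rng.uniform(-4.0, 4.0, n_states)
    sd = rng.uniform(0.3, 2.0, n_states)
    return HMMModel(
        pi, A, mu, sd, None, [0.0], True,
        HMMConfig(n_states=n_states, discretization=discretization),
    )
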