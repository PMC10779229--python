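import numpy as np
import pytest

from hvgating import kinetic


@pytest.fixture(scope="session")
def two_state_scheme():
    return kinetic.KineticScheme(
        state_names=("R", "A"),
        transitions=(kinetic.TransitionParams(alpha0=0.5, beta0=0.5, x=0.5, z_delta=1.0),),
        n_channels=1e9,
    )


@pytest.fixture(scope="session")
def trapping_scheme():
    return kinetic.example_scheme(trapping=True)


@pytest.fixture(scope="session")
def conservative_scheme():
    return kinetic.example_scheme(trapping=False)


def random_scheme(rng: np.random.Generator, n_states: int = 5) -> kinetic.KineticScheme:
    """Random linear-chain scheme with moderate rates and charges."""
    transitions = tuple(
        kinetic.TransitionParams(
            alpha0=float(rng.uniform(0.05, 2.0)),
            beta0=float(rng.uniform(0.05, 2.0)),
            x=float(rng.uniform(0.0, 1.0)),
            z_delta=float(rng.uniform(0.1, 1.0)),
        )
        for _ in range(n_states - 1)
    )
    return kinetic.KineticScheme(
        state_names=tuple(f"S{i}" for i in range(n_states)),
        transitions=transitions,
        n_channels=1e8,
    )
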