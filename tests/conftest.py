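import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import multitrophic as mt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_params():
    """The well-mixed reference condition used throughout: pools (50, 56, 62)."""
    return mt.ModelParams3()


@pytest.fixture(scope="session")
def reference_cavity(reference_params):
    """Cavity solution at the reference condition (shared; solving is cheap but not free)."""
    return mt.solve(reference_params, seed=1)


@pytest.fixture(scope="session")
def random_cavity_states():
    """A handful of solved cavity states across the parameter space."""
    rng = np.random.default_rng(42)
    states = []
    for _ in range(4):
        p = mt.ModelParams3(
            k=float(rng.uniform(2, 6)),
            u=float(rng.uniform(0.6, 2.0)),
            sigma_c=float(rng.uniform(0.3, 0.7)),
            sigma_d=float(rng.uniform(0.3, 0.7)),
            eta_N=float(rng.uniform(0.5, 1.0)),
            eta_X=float(rng.uniform(0.5, 1.0)),
        ).with_ratios(float(rng.uniform(0.5, 1.1)), float(rng.uniform(0.5, 1.1)))
        states.append(mt.solve(p, seed=int(rng.integers(2**31))))
    return states
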