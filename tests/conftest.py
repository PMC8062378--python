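import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cogscale import lba, rl, synthetic_data

settings.register_profile(
    "cogscale",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cogscale")


@pytest.fixture(scope="session")
def reference_lba_params() -> lba.LBAParams:
    """Well-identified LBA regime used across tests: ~0.47 s mean RT,
    ~15% errors, both-negative-drift probability < 1e-4."""
    return lba.LBAParams(A=0.5, B=1.0, v1=3.0, v2=1.5, s1=1.0, s2=1.0, t0=0.2)


@pytest.fixture(scope="session")
def lba_trials_1000(reference_lba_params) -> lba.LBATrialSet:
    return lba.simulate_lba(reference_lba_params, 1000, seed=20240901)


@pytest.fixture(scope="session")
def rl_reference_data() -> rl.RLData:
    """One agent at the recovery reference point (alpha=0.3, beta=3, gamma=1)."""
    return rl.simulate_agent(rl.BanditTask(), rl.RLParams(0.3, 3.0, 1.0), seed=77)


@pytest.fixture(scope="session")
def sdt_population() -> synthetic_data.Population:
    return synthetic_data.generate_sdt_population(synthetic_data.SDTPopulationSpec(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
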