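import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    import nas
    return nas.simulate_genome(20_000, seed=1)


@pytest.fixture(scope="session")
def small_pairs(small_genome):
    import nas
    return nas.simulate_read_pairs(small_genome, 50, seed=3)


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), n))
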