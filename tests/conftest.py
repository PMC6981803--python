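import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_genome():
    from soyqtl.genome import GenomeSpec

    return GenomeSpec(
        (("Gm01", 30_000_000), ("Gm02", 30_000_000), ("Gm03", 30_000_000),
         ("Gm04", 30_000_000)),
        {"Gm01": "D1a", "Gm02": "D1b", "Gm03": "N", "Gm04": "C1"})


@pytest.fixture(scope="session")
def small_population(small_genome):
    from soyqtl.simulate import simulate_population

    return simulate_population(small_genome, 60,
                               segment_length=(2_000_000, 8_000_000),
                               seed=11)


@pytest.fixture(scope="session")
def default_population():
    from soyqtl.genome import default_genome
    from soyqtl.simulate import simulate_population

    return simulate_population(default_genome(), 208, seed=7)
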