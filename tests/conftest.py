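import random

import pytest

from paredeg.synthetic_data import (SyntheticConfig, generate_references,
                                    simulate_degradome)

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(rng.choice(BASES) for _ in range(n))


@pytest.fixture
def rng():
    return random.Random(20170224)


@pytest.fixture
def zero_noise_config():
    """Clean simulation: every read is planted signal."""
    return SyntheticConfig(seed=11, noise_rate=0.0, contaminant_fractions={})


@pytest.fixture
def noisy_config():
    """Realistic simulation with background and every contaminant class."""
    return SyntheticConfig(
        seed=13, noise_rate=0.02,
        contaminant_fractions={"rRNA": 0.05, "tRNA": 0.01, "snRNA": 0.01,
                               "snoRNA": 0.01, "polyN": 0.01,
                               "N_read": 0.005, "low_quality": 0.005})


@pytest.fixture
def zero_noise_library(zero_noise_config):
    refs = generate_references(zero_noise_config)
    reads, truth = simulate_degradome(zero_noise_config, refs)
    return zero_noise_config, refs, reads, truth
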