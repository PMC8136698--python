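import random

import pytest
from hypothesis import HealthCheck, settings

from dbgcycles import (
    build_closure_graph,
    build_dbg,
    example_readset,
    spectrum,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def example():
    """The two-read worked example (R = {TATTA, TAATA}, k = 3)."""
    return example_readset()


@pytest.fixture(scope="session")
def example_spectrum(example):
    reads, k = example
    return spectrum(reads, k)


@pytest.fixture(scope="session")
def g1(example_spectrum):
    return build_dbg(example_spectrum)


@pytest.fixture(scope="session")
def g2(example_spectrum):
    return build_closure_graph(example_spectrum)


def random_circular_genome(length: int, seed: int, alphabet: str = "ACGT") -> str:
    """Independent genome draw used by oracle tests (not the simulator)."""
    rng = random.Random(seed)
    return "".join(rng.choice(alphabet) for _ in range(length))
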