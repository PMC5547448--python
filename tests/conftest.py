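import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from privseq import (  # noqa: E402
    NucleotideSequence,
    SequenceDataset,
    generate_dataset,
    synthetic_frequency_table,
)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture(scope="session")
def small_corpus():
    """40 records of length 300 plus 2 query sequences, fixed seed."""
    freqs = synthetic_frequency_table(300, seed=11)
    return generate_dataset(freqs, 40, 2, seed=12)


@pytest.fixture
def toy_dataset():
    return SequenceDataset(
        [
            NucleotideSequence("r1", "ATGCATGC"),
            NucleotideSequence("r2", "ATGGATGC"),
            NucleotideSequence("r3", "TTTTTTTT"),
        ]
    )
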