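import random

import pytest

from capcure.seqio_core import LocusAlignment, SequenceRecord


@pytest.fixture
def rng():
    return random.Random(42)


@pytest.fixture
def small_alignment():
    return LocusAlignment(
        "locus1",
        {
            "alpha": "ACGTACGT",
            "beta": "ACGTACGA",
            "gamma": "ACGAACGA",
            "delta": "TCGAACGA",
        },
    )


def random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def random_records(rng):
    return [SequenceRecord(f"s{i}", random_seq(rng, 200)) for i in range(5)]
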