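import random

import pytest

from psykit.motifs import psy_strict_pattern, relaxed_five_residue_pattern

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def strict_pattern():
    return psy_strict_pattern()


@pytest.fixture
def relaxed_pattern():
    return relaxed_five_residue_pattern()


@pytest.fixture
def py_rng():
    return random.Random(20260929)


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))
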