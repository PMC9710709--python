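import random

import pytest


def make_dna(rnd: random.Random, n: int) -> str:
    return "".join(rnd.choice("ACGT") for _ in range(n))


@pytest.fixture
def rnd() -> random.Random:
    return random.Random(20240917)


def random_instance(rnd: random.Random, max_t: int = 80, max_refs: int = 6,
                    max_ref_len: int = 60):
    """A small random (target, references) pair for oracle comparisons."""
    t = make_dna(rnd, rnd.randint(1, max_t))
    refs = [make_dna(rnd, rnd.randint(1, max_ref_len))
            for _ in range(rnd.randint(1, max_refs))]
    return t, refs
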