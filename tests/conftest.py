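import itertools

import numpy as np
import pytest

from mitorder.gene_order import GeneOrder


@pytest.fixture
def rng():
    return np.random.default_rng(20240201)


@pytest.fixture
def abcde():
    return GeneOrder("abcde", tuple((s, 1) for s in "ABCDE"))


def random_signed_circular(n, rng, genome_id="r"):
    """Uniformly random signed circular order of genes g1..gn."""
    perm = rng.permutation(n)
    signs = rng.choice([1, -1], size=n)
    return GeneOrder(
        genome_id,
        tuple((f"g{i + 1}", int(s)) for i, s in zip(perm, signs)),
        circular=True,
    )


def all_signed_circular_orders(symbols):
    """Every signed circular order with the first gene fixed at +.

    Fixing one gene's position and sign removes the rotation degeneracy
    (reflection is kept, so reflected pairs both appear).
    """
    first, rest = symbols[0], symbols[1:]
    for perm in itertools.permutations(rest):
        for signs in itertools.product((1, -1), repeat=len(rest)):
            yield GeneOrder(
                "enum",
                ((first, 1),) + tuple(zip(perm, signs)),
                circular=True,
            )
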