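import math
from math import comb

import pytest

import editotype as et


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Independent two-sided Fisher oracle by hypergeometric enumeration.

    Conditions on the margins of the 2x2 table [[a, b], [c, d]] and sums
    the probabilities of all tables no more likely than the observed one
    (classical two-sided rule, with the customary 1e-7 relative slack on
    the tie comparison).  Exact binomial coefficients throughout.
    """
    r1, r2 = a + b, c + d
    col1 = a + c
    n = r1 + r2
    denom = comb(n, col1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, col1 - r2), min(r1, col1) + 1):
        p = comb(r1, x) * comb(r2, col1 - x) / denom
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


@pytest.fixture(scope="session")
def code_table():
    return et.default_code_table()


@pytest.fixture(scope="session")
def small_fixture():
    """20-site fixture: 2 planted knockdowns, 1 linked pair, 3 planted PPRs."""
    cfg = et.SimulationConfig(
        genome_length=5_000,
        n_sites=20,
        coverage_mean=500,
        n_replicates=3,
        knockdown_effects={0: 0.1, 1: 0.1},
        linked_pairs=[et.LinkedPair(upstream=2, downstream=3, offset=-15)],
        seed=7,
    )
    return cfg, et.generate_fixture(cfg, n_planted_ppr=3)
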