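"""Shared fixtures and independent brute-force oracles.

The enumeration oracle below is deliberately naive: it lists every way one
allele from each parent can combine into the child and derives consistency
and het-parent transmission counts from that list. The library never uses
it; tests compare the library's closed-form rules against it.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import triotdt as tdt

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def enumerate_transmissions(f: int, m: int, c: int):
    """All (paternal allele, maternal allele) pairs compatible with the child."""
    return [
        (af, am)
        for af, am in itertools.product(_ALLELES[f], _ALLELES[m])
        if af + am == c
    ]


def oracle_consistent(f: int, m: int, c: int) -> bool:
    return bool(enumerate_transmissions(f, m, c))


def oracle_counts(f: int, m: int, c: int):
    """(t, u) from het parents, by enumerating equally likely compatible
    transmissions. For every consistent triple the contribution is the same
    under each compatible transmission, so the result is exact, not an
    average."""
    contributions = set()
    for af, am in enumerate_transmissions(f, m, c):
        t = (af if f == 1 else 0) + (am if m == 1 else 0)
        u = ((1 - af) if f == 1 else 0) + ((1 - am) if m == 1 else 0)
        contributions.add((t, u))
    assert len(contributions) == 1, "ambiguous contribution — oracle misuse"
    return contributions.pop()


ALL_TRIPLES = list(itertools.product(range(3), repeat=3))
CONSISTENT_TRIPLES = [tr for tr in ALL_TRIPLES if oracle_consistent(*tr)]


def cohort_from_triples(triples):
    """One-variant-per-triple cohort with the given (father, mother, child)
    dosages in a single trio — handy for pinning exact tallies."""
    triples = np.asarray(triples, dtype=np.int8)
    n_var = len(triples)
    table = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n_var)],
            "gene_id": ["g1"] * n_var,
            "position": np.arange(1, n_var + 1) * 100,
            "rare_allele_freq": 0.01,
            "is_causal": False,
        }
    )
    panel = tdt.VariantPanel(table, maf_cap=0.05)
    geno = triples.T.reshape(1, 3, n_var)
    return tdt.TrioCohort(panel, geno, geno.copy())


@pytest.fixture(scope="session")
def small_panel():
    return tdt.sample_panel(10, 20, maf_cap=0.05, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    return tdt.simulate_trios(small_panel, 80, seed=12)
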