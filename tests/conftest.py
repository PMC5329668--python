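"""Shared fixture worlds and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from epimatch.fixtures import WorldParams, generate_world
from epimatch.nomenclature import Genotype


@pytest.fixture(scope="session")
def small_world():
    """Default small world: 4 alleles/locus, degeneracy 2, 40 haplotypes."""
    return generate_world(11)


@pytest.fixture(scope="session")
def sparse_world():
    """Denser serology (4 splits/locus) over a sparse table: split typings
    resolve to small candidate sets, so cross-product scoring stays cheap."""
    return generate_world(
        17,
        WorldParams(
            alleles_per_locus=8,
            alleles_per_split=2,
            splits_per_broad=2,
            n_haplotypes=80,
            protein_length=50,
            eplets_per_allele=6,
            eplet_pool=60,
        ),
    )


@pytest.fixture(scope="session")
def injective_world():
    """One allele per split antigen: split typing determines alleles."""
    return generate_world(
        13,
        WorldParams(alleles_per_locus=4, alleles_per_split=1, splits_per_broad=2,
                    n_haplotypes=40),
    )


def random_genotype(world, rng: np.random.Generator) -> Genotype:
    """A genotype of two (frequency-weighted) haplotypes from the table."""
    freqs = np.array([h.frequency for h in world.table.entries])
    i, j = rng.choice(len(freqs), size=2, p=freqs / freqs.sum())
    return Genotype.from_haplotypes(world.table.entries[int(i)], world.table.entries[int(j)])
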