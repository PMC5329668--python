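"""Virtual donor populations and allocation-rule couple formation.

Individuals are generated by assigning two haplotypes drawn from a
frequency table.  Donor-recipient couples are formed under a deceased-kidney
allocation rule evaluated on serological *broad* antigens: at most three
mismatches at HLA-A plus HLA-B combined, and at most one mismatch at HLA-DR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from os import PathLike
from typing import IO, Sequence, Union

import numpy as np

from .errors import PoolExhaustedError, RetryLimitError
from .nomenclature import (
    LOCI,
    AlleleCode,
    Genotype,
    HaplotypeFrequencyTable,
    SerologyMap,
    serologize,
)

#: Allocation rule thresholds (broad-level mismatches).
MAX_AB_MISMATCHES = 3
MAX_DR_MISMATCHES = 1
DEFAULT_RETRY_CAP = 100_000


@dataclass(frozen=True)
class VirtualIndividual:
    id: str
    genotype: Genotype


@dataclass(frozen=True)
class Couple:
    donor: VirtualIndividual
    recipient: VirtualIndividual
    mm_a: int
    mm_b: int
    mm_dr: int

    def satisfies_rule(self) -> bool:
        return self.mm_a + self.mm_b <= MAX_AB_MISMATCHES and self.mm_dr <= MAX_DR_MISMATCHES


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_population(
    table: HaplotypeFrequencyTable,
    n: int,
    seed=None,
    policy: str = "iid",
    pool_size: int | None = None,
    id_prefix: str = "ind",
) -> list[VirtualIndividual]:
    """Sample ``n`` individuals, two haplotypes each, from the table.

    ``iid`` (default): every haplotype draw is independent with probability
    proportional to its table frequency.  ``finite_pool``: a discretized pool
    of ``pool_size`` haplotype copies apportioned proportionally to frequency
    is shuffled and consumed without replacement, modelling draws from a
    finite registry; the pool must hold at least ``2 n`` copies.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = _as_rng(seed)
    freqs = np.array([h.frequency for h in table.entries], dtype=float)
    if policy == "iid":
        p = freqs / freqs.sum()
        idx = rng.choice(len(freqs), size=2 * n, p=p)
    elif policy == "finite_pool":
        if pool_size is None:
            pool_size = 20 * n
        # Largest-remainder apportionment of pool_size copies by frequency.
        shares = freqs / freqs.sum() * pool_size
        counts = np.floor(shares).astype(int)
        remainder = pool_size - counts.sum()
        if remainder > 0:
            order = np.argsort(-(shares - counts))
            counts[order[:remainder]] += 1
        if counts.sum() < 2 * n:
            raise PoolExhaustedError(
                f"pool of {counts.sum()} haplotype copies cannot supply {2 * n} draws"
            )
        pool = np.repeat(np.arange(len(freqs)), counts)
        idx = rng.permutation(pool)[: 2 * n]
    else:
        raise ValueError(f"unknown sampling policy {policy!r}")
    out = []
    for i in range(n):
        h1 = table.entries[int(idx[2 * i])]
        h2 = table.entries[int(idx[2 * i + 1])]
        out.append(
            VirtualIndividual(id=f"{id_prefix}{i:06d}", genotype=Genotype.from_haplotypes(h1, h2))
        )
    return out


def count_broad_mismatches(
    donor: Genotype, recipient: Genotype, smap: SerologyMap, locus: str
) -> int:
    """Donor broad antigens at a locus absent from the recipient's set.

    Antigens are compared as sets, so a homozygous donor contributes a
    single antigen (the standard serological mismatch convention).
    """
    donor_set = {serologize(a, smap, "broad") for a in donor.alleles_at(locus)}
    recipient_set = {serologize(a, smap, "broad") for a in recipient.alleles_at(locus)}
    return len(donor_set - recipient_set)


def couple_mismatches(
    donor: Genotype, recipient: Genotype, smap: SerologyMap
) -> tuple[int, int, int]:
    return (
        count_broad_mismatches(donor, recipient, smap, "A"),
        count_broad_mismatches(donor, recipient, smap, "B"),
        count_broad_mismatches(donor, recipient, smap, "DRB1"),
    )


def form_couples(
    donors: Sequence[VirtualIndividual],
    recipients: Sequence[VirtualIndividual],
    smap: SerologyMap,
    seed=None,
    retry_cap: int = DEFAULT_RETRY_CAP,
) -> list[Couple]:
    """Assign exactly one donor to each recipient under the allocation rule.

    For each recipient, donors are drawn at random from the remaining pool;
    a pairing is accepted iff mmA+mmB <= 3 and mmDR <= 1, otherwise another
    donor is drawn.  Accepted donors leave the pool, so every couple has a
    distinct donor.  A retry cap guards against pools with no compatible
    donor for some recipient.
    """
    if not donors or not recipients:
        raise ValueError("donor and recipient populations must be nonempty")
    rng = _as_rng(seed)
    available = list(range(len(donors)))
    couples: list[Couple] = []
    for recipient in recipients:
        if not available:
            raise RetryLimitError(
                f"donor pool exhausted before recipient {recipient.id}"
            )
        accepted = None
        for _ in range(retry_cap):
            pos = int(rng.integers(len(available)))
            donor = donors[available[pos]]
            mm_a, mm_b, mm_dr = couple_mismatches(
                donor.genotype, recipient.genotype, smap
            )
            if mm_a + mm_b <= MAX_AB_MISMATCHES and mm_dr <= MAX_DR_MISMATCHES:
                accepted = (pos, donor, mm_a, mm_b, mm_dr)
                break
        if accepted is None:
            raise RetryLimitError(
                f"no compatible donor found for recipient {recipient.id} "
                f"within {retry_cap} draws"
            )
        pos, donor, mm_a, mm_b, mm_dr = accepted
        available.pop(pos)
        couples.append(
            Couple(donor=donor, recipient=recipient, mm_a=mm_a, mm_b=mm_b, mm_dr=mm_dr)
        )
    return couples


# --- JSON round-trips -------------------------------------------------------

Dest = Union[str, PathLike, IO]


def _individual_doc(ind: VirtualIndividual) -> dict:
    return {
        "id": ind.id,
        "haplotypes": [[a.name for a in vec] for vec in ind.genotype.haplotypes],
    }


def _individual_from_doc(doc: dict) -> VirtualIndividual:
    vecs = tuple(
        tuple(AlleleCode.parse(name, locus=l) for name, l in zip(vec, LOCI))
        for vec in doc["haplotypes"]
    )
    return VirtualIndividual(id=doc["id"], genotype=Genotype(haplotypes=vecs))


def write_population(population: Sequence[VirtualIndividual], dest: Dest) -> None:
    docs = [_individual_doc(ind) for ind in population]
    if isinstance(dest, (str, PathLike)):
        with open(dest, "w") as fh:
            json.dump(docs, fh, indent=1)
    else:
        json.dump(docs, dest, indent=1)


def read_population(source: Dest) -> list[VirtualIndividual]:
    if isinstance(source, (str, PathLike)):
        with open(source) as fh:
            docs = json.load(fh)
    else:
        docs = json.load(source)
    return [_individual_from_doc(d) for d in docs]


def write_couples(couples: Sequence[Couple], dest: Dest) -> None:
    docs = [
        {
            "donor": _individual_doc(c.donor),
            "recipient": _individual_doc(c.recipient),
            "mismatches": {"A": c.mm_a, "B": c.mm_b, "DR": c.mm_dr},
        }
        for c in couples
    ]
    if isinstance(dest, (str, PathLike)):
        with open(dest, "w") as fh:
            json.dump(docs, fh, indent=1)
    else:
        json.dump(docs, dest, indent=1)


def read_couples(source: Dest) -> list[Couple]:
    if isinstance(source, (str, PathLike)):
        with open(source) as fh:
            docs = json.load(fh)
    else:
        docs = json.load(source)
    return [
        Couple(
            donor=_individual_from_doc(d["donor"]),
            recipient=_individual_from_doc(d["recipient"]),
            mm_a=d["mismatches"]["A"],
            mm_b=d["mismatches"]["B"],
            mm_dr=d["mismatches"]["DR"],
        )
        for d in docs
    ]
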