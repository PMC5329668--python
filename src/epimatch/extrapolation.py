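"""Genotype imputation from low-resolution typings via haplotype frequencies.

Given a phenotype (serological split or two-field values, possibly with loci
absent), enumerate every high-resolution 5-locus genotype consistent with it
and weight each candidate by its population frequency.  Candidates are built
from the haplotype-frequency table under a *linkage scheme*: first using full
5-locus haplotypes, then — if no candidate exists — breaking the linkage
between loci step-wise until, in the last scheme, every locus is treated
independently (equivalent to per-locus allele frequencies).  Weights are the
candidates' absolute frequencies normalized to sum to one, so downstream
scores are frequency-weighted expectations (multiple imputation rather than
a single best-guess genotype).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

from .errors import CandidateExplosionError, UnimputableError
from .nomenclature import (
    LOCI,
    AlleleCode,
    Genotype,
    HaplotypeFrequencyTable,
    Phenotype,
    SerologyMap,
    project_allele,
)

#: Hard cap on enumerated candidate pairs; full linkage breakdown on rich
#: tables is combinatorial, so an explicit guard beats an apparent hang.
DEFAULT_MAX_CANDIDATES = 1_000_000


@dataclass(frozen=True)
class LinkageScheme:
    """An ordered partition of the five loci into linked blocks."""

    blocks: tuple[tuple[str, ...], ...]
    mode_index: int  # 1..5, position in the fallback ladder

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return " | ".join("-".join(b) for b in self.blocks)


#: The fallback ladder, in the order schemes are tried.
SCHEMES: tuple[LinkageScheme, ...] = (
    LinkageScheme(blocks=(("A", "B", "C", "DRB1", "DQB1"),), mode_index=1),
    LinkageScheme(blocks=(("A", "B", "C"), ("DRB1", "DQB1")), mode_index=2),
    LinkageScheme(blocks=(("A",), ("B", "C"), ("DRB1", "DQB1")), mode_index=3),
    LinkageScheme(blocks=(("A",), ("B", "C"), ("DRB1",), ("DQB1",)), mode_index=4),
    LinkageScheme(blocks=(("A",), ("B",), ("C",), ("DRB1",), ("DQB1",)), mode_index=5),
)


@dataclass(frozen=True)
class PartialHaplotype:
    """Alleles over one block of loci with their marginal frequency."""

    loci: tuple[str, ...]
    alleles: tuple[AlleleCode, ...]
    marginal_frequency: float


@dataclass(frozen=True)
class CandidateGenotype:
    """A candidate full genotype with its absolute (unnormalized) frequency."""

    genotype: Genotype
    absolute_frequency: float
    scheme_used: LinkageScheme


@dataclass(frozen=True)
class WeightedGenotype:
    """A candidate genotype with its normalized weight within the set."""

    genotype: Genotype
    weight: float
    absolute_frequency: float
    scheme_used: LinkageScheme


@dataclass(frozen=True)
class ExtrapolationResult:
    genotypes: tuple[WeightedGenotype, ...]
    scheme_used: LinkageScheme


def matches(
    alleles: Mapping[str, AlleleCode],
    phenotype: Phenotype,
    smap: SerologyMap,
) -> bool:
    """Single-haplotype (or block) compatibility with a phenotype.

    True iff at every phenotype locus the vector covers, its allele projects
    (serologically, or identically for two-field values) to one of the
    phenotype's values.  Loci absent from the phenotype are unconstrained.
    Note this is a necessary condition only: the *pair* of haplotypes must
    jointly reproduce the phenotype (see :func:`enumerate_candidates`).
    """
    for locus, allele in alleles.items():
        if locus not in phenotype.loci:
            continue
        kind = phenotype.kind_at(locus)
        if project_allele(allele, kind, smap) not in phenotype.values_at(locus):
            return False
    return True


def _pair_covers(
    proj1: tuple,
    proj2: tuple,
    wanted: tuple[frozenset, ...],
    single_as_unknown: bool,
) -> bool:
    """Exact-cover check per covered locus for one unordered vector pair."""
    for p1, p2, want in zip(proj1, proj2, wanted):
        got = {p1, p2}
        if single_as_unknown and len(want) == 1:
            if not want <= got:
                return False
        elif got != want:
            return False
    return True


def enumerate_candidates(
    phenotype: Phenotype,
    table: HaplotypeFrequencyTable,
    smap: SerologyMap,
    scheme: LinkageScheme,
    hw_factor: bool = False,
    single_as_unknown: bool = False,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> list[CandidateGenotype]:
    """All candidate genotypes consistent with a phenotype under one scheme.

    Full candidate chromosomes are assembled from block marginals (under
    scheme 1 these are whole table haplotypes); every unordered pair is kept
    whose projection reproduces the phenotype exactly at each covered locus
    — every phenotype value is hit and no extra value appears.  A single
    phenotype value at a locus is read as a true homozygote unless
    ``single_as_unknown`` is set.

    The pair frequency is the product of the two chromosome frequencies,
    each chromosome's frequency being the product of its blocks' marginal
    frequencies.  ``hw_factor`` applies the Hardy-Weinberg factor 2 to
    heterozygous pairs (off by default: the plain product keeps the weights
    on the literal frequency-product scale).  All cross-block phase
    assignments are enumerated; duplicate unordered genotypes are merged by
    summing frequency.
    """
    covered = phenotype.covered_loci()
    if not covered:
        raise ValueError("phenotype covers no locus")
    kinds = {l: phenotype.kind_at(l) for l in covered}
    wanted = tuple(frozenset(phenotype.values_at(l)) for l in covered)

    # Compatible partial haplotypes per block (necessary per-locus filter).
    block_partials: list[list[tuple[tuple[AlleleCode, ...], float]]] = []
    for block in scheme.blocks:
        compat = []
        for alleles, freq in table.marginal(block).items():
            ok = True
            for locus, allele in zip(block, alleles):
                if locus in kinds:
                    if project_allele(allele, kinds[locus], smap) not in phenotype.values_at(locus):
                        ok = False
                        break
            if ok:
                compat.append((alleles, freq))
        if not compat:
            return []
        block_partials.append(compat)

    # Assemble full chromosomes as cross products of block partials.
    n_vectors = 1
    for compat in block_partials:
        n_vectors *= len(compat)
    if n_vectors * (n_vectors + 1) // 2 > max_candidates:
        raise CandidateExplosionError(
            f"{n_vectors} candidate chromosomes imply more than "
            f"{max_candidates} candidate pairs under scheme {scheme}"
        )
    order = [LOCI.index(l) for block in scheme.blocks for l in block]
    inverse = sorted(range(len(order)), key=order.__getitem__)
    vectors: list[tuple[tuple[AlleleCode, ...], float]] = []
    for combo in product(*block_partials):
        flat = tuple(a for alleles, _ in combo for a in alleles)
        vec = tuple(flat[i] for i in inverse)  # reorder to canonical LOCI order
        freq = 1.0
        for _, f in combo:
            freq *= f
        vectors.append((vec, freq))

    cov_idx = [LOCI.index(l) for l in covered]

    # The cover check depends only on each vector's projection signature, so
    # vectors are grouped by signature and the check runs once per signature
    # pair instead of once per vector pair.
    groups: dict[tuple, list[tuple[tuple[AlleleCode, ...], float]]] = {}
    for vec, freq in vectors:
        sig = tuple(
            project_allele(vec[i], kinds[l], smap) for i, l in zip(cov_idx, covered)
        )
        groups.setdefault(sig, []).append((vec, freq))
    signatures = list(groups)

    merged: dict[tuple, float] = {}
    for si in range(len(signatures)):
        for sj in range(si, len(signatures)):
            if not _pair_covers(signatures[si], signatures[sj], wanted, single_as_unknown):
                continue
            g1, g2 = groups[signatures[si]], groups[signatures[sj]]
            same_group = si == sj
            for i, (v1, f1) in enumerate(g1):
                start = i if same_group else 0
                for v2, f2 in g2[start:]:
                    freq = f1 * f2
                    if hw_factor and v1 != v2:
                        freq *= 2.0
                    key = (v1, v2) if v1 <= v2 else (v2, v1)
                    merged[key] = merged.get(key, 0.0) + freq

    return [
        CandidateGenotype(
            genotype=Genotype(haplotypes=pair),
            absolute_frequency=freq,
            scheme_used=scheme,
        )
        for pair, freq in merged.items()
    ]


def extrapolate(
    phenotype: Phenotype,
    table: HaplotypeFrequencyTable,
    smap: SerologyMap,
    hw_factor: bool = False,
    single_as_unknown: bool = False,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> ExtrapolationResult:
    """Impute weighted high-resolution genotypes for a phenotype.

    Schemes are tried in ladder order; the first scheme yielding at least one
    candidate wins (global fallback: one scheme per call, never mixed between
    the two chromosomes).  Candidate frequencies are normalized to weights
    summing to one.  If even the fully unlinked scheme yields nothing — some
    input value has no mapped allele anywhere in the table — the phenotype is
    unimputable and a typed error is raised.
    """
    for scheme in SCHEMES:
        candidates = enumerate_candidates(
            phenotype,
            table,
            smap,
            scheme,
            hw_factor=hw_factor,
            single_as_unknown=single_as_unknown,
            max_candidates=max_candidates,
        )
        if candidates:
            total = sum(c.absolute_frequency for c in candidates)
            weighted = tuple(
                WeightedGenotype(
                    genotype=c.genotype,
                    weight=c.absolute_frequency / total,
                    absolute_frequency=c.absolute_frequency,
                    scheme_used=scheme,
                )
                for c in candidates
            )
            return ExtrapolationResult(genotypes=weighted, scheme_used=scheme)
    raise UnimputableError(
        "no candidate genotype under any linkage scheme", phenotype=phenotype
    )
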