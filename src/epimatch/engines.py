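"""Epitope-mismatch engines: eplet counting and PIRCHE-II counting.

Both engines consume *resolved* two-field genotypes.

**Eplets** are small patches of polymorphic surface residues treated as
B-cell epitope units.  A mismatched eplet is present on at least one donor
HLA molecule and absent from every recipient HLA molecule; comparisons are
interlocus, i.e. an eplet carried by any recipient allele at any of the five
loci neutralizes it.

**PIRCHE-II** are T-helper epitopes: nonameric binding cores of peptides
derived from mismatched donor HLA proteins that are predicted to bind
recipient HLA-DRB1 (IC50 below a threshold) and whose nine residues do not
occur anywhere in the recipient's own HLA protein sequences.  Binding
prediction is delegated to a pluggable predictor callable; a deterministic
hash-based mock is provided so the full pipeline runs without an external
neural-network predictor.
"""

from __future__ import annotations

import functools
import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

from .errors import MissingLocusError, MissingProteinError, RegistryError
from .nomenclature import AlleleCode, Genotype, CLASS_I

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default binder cutoff: predictions with IC50 strictly below this (nM)
#: count as relevant HLA-DRB1 binders.
DEFAULT_IC50_THRESHOLD = 1000.0

#: Default peptide length scanned from mismatched donor proteins (class-II
#: binding grooves are open-ended; 15-mers are the scanning convention).
DEFAULT_PEPTIDE_WINDOW = 15

CORE_LENGTH = 9


@dataclass(frozen=True)
class ProteinDB:
    """Mapping of allele → amino-acid sequence (single-letter codes)."""

    sequences: Mapping[AlleleCode, str]

    def __post_init__(self):
        for allele, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty protein sequence for {allele.name}")
            bad = set(seq) - set(AMINO_ACIDS)
            if bad:
                raise ValueError(
                    f"non-standard residues {sorted(bad)} in sequence of {allele.name}"
                )

    def __getitem__(self, allele: AlleleCode) -> str:
        try:
            return self.sequences[allele]
        except KeyError:
            raise MissingProteinError(
                f"no protein sequence for allele {allele.name}"
            ) from None

    def __contains__(self, allele: AlleleCode) -> bool:
        return allele in self.sequences


@dataclass(frozen=True)
class EpletRegistry:
    """Per-allele eplet annotations (allele → set of eplet names)."""

    annotations: Mapping[AlleleCode, frozenset[str]]

    def __post_init__(self):
        for allele, eplets in self.annotations.items():
            if any(not e for e in eplets):
                raise ValueError(f"empty eplet name annotated on {allele.name}")

    def eplets_of(self, allele: AlleleCode) -> frozenset[str]:
        try:
            return self.annotations[allele]
        except KeyError:
            raise RegistryError(
                f"allele {allele.name} is not annotated in the eplet registry"
            ) from None


@dataclass(frozen=True)
class BindingPrediction:
    """One peptide/DRB1 binding prediction: the 9-mer core and its IC50."""

    peptide: str
    core: str
    ic50: float

    def __post_init__(self):
        if len(self.core) != CORE_LENGTH:
            raise ValueError(f"binding core must be {CORE_LENGTH} residues")
        if self.core not in self.peptide:
            raise ValueError("binding core must occur within its peptide")
        if not self.ic50 > 0:
            raise ValueError("IC50 must be positive")


@dataclass(frozen=True)
class EpitopeScore:
    """An integer epitope-mismatch count with the identity set behind it."""

    count: int
    items: frozenset

    def __post_init__(self):
        if self.count != len(self.items):
            raise ValueError("count must equal the number of items")


def count_eplet_mismatches(
    donor: Genotype,
    recipient: Genotype,
    registry: EpletRegistry,
    per_class: bool = False,
) -> EpitopeScore:
    """Count eplets present on donor HLA and absent from all recipient HLA.

    By default eplets are pooled across all five loci on both sides
    (interlocus comparison).  With ``per_class`` the pooling is restricted to
    within class I and class II separately, a variant some eplet-analysis
    workflows use.
    """
    if not per_class:
        donor_pool = frozenset().union(
            *(registry.eplets_of(a) for a in donor.unique_alleles())
        )
        recip_pool = frozenset().union(
            *(registry.eplets_of(a) for a in recipient.unique_alleles())
        )
        items = frozenset(donor_pool - recip_pool)
        return EpitopeScore(count=len(items), items=items)

    items = frozenset()
    for cls in (True, False):  # class I, then class II
        d = [a for a in donor.unique_alleles() if (a.locus in CLASS_I) is cls]
        r = [a for a in recipient.unique_alleles() if (a.locus in CLASS_I) is cls]
        dp = frozenset().union(*(registry.eplets_of(a) for a in d)) if d else frozenset()
        rp = frozenset().union(*(registry.eplets_of(a) for a in r)) if r else frozenset()
        items |= dp - rp
    return EpitopeScore(count=len(items), items=items)


def generate_peptides(sequence: str, window: int = DEFAULT_PEPTIDE_WINDOW, step: int = 1) -> list[str]:
    """All contiguous windows of ``window`` residues, in sequence order.

    A sequence shorter than the window yields the whole sequence once, so
    short proteins still enter the scanning pipeline.
    """
    if window < CORE_LENGTH:
        raise ValueError(f"peptide window must be >= {CORE_LENGTH}, got {window}")
    if step < 1:
        raise ValueError("step must be >= 1")
    if len(sequence) <= window:
        return [sequence]
    return [sequence[i : i + window] for i in range(0, len(sequence) - window + 1, step)]


def _window_hash(window: str, allele: AlleleCode) -> int:
    digest = hashlib.md5(f"{window}|{allele.name}".encode()).digest()
    return int.from_bytes(digest, "big")


@functools.lru_cache(maxsize=1 << 18)
def mock_predictor(peptide: str, drb1_allele: AlleleCode) -> BindingPrediction:
    """Deterministic, seed-free stand-in for a class-II binding predictor.

    The binding core is the 9-mer window of the peptide minimizing a fixed
    hash of (window, allele); the IC50 is a monotone transform of that hash
    into (1, 50000) nM.  The hash spreads uniformly, so fixture worlds
    reproducibly contain both binders and non-binders at the 1000 nM cutoff.
    """
    if len(peptide) < CORE_LENGTH:
        raise ValueError(f"peptide must be at least {CORE_LENGTH} residues")
    best_core = None
    best_hash = None
    for i in range(len(peptide) - CORE_LENGTH + 1):
        core = peptide[i : i + CORE_LENGTH]
        h = _window_hash(core, drb1_allele)
        if best_hash is None or h < best_hash:  # leftmost wins ties
            best_core, best_hash = core, h
    ic50 = 1.0 + 49998.0 * (best_hash / 2.0**128)
    return BindingPrediction(peptide=peptide, core=best_core, ic50=ic50)


#: Signature expected of any binding predictor (the mock above, or an
#: adapter around an external tool): (peptide, DRB1 allele) -> prediction.
Predictor = Callable[[str, AlleleCode], BindingPrediction]


def count_pirche2(
    donor: Genotype,
    recipient: Genotype,
    proteins: ProteinDB,
    predictor: Predictor = mock_predictor,
    ic50_threshold: float = DEFAULT_IC50_THRESHOLD,
    peptide_window: int = DEFAULT_PEPTIDE_WINDOW,
    per_drb1: bool = False,
) -> EpitopeScore:
    """Count PIRCHE-II for a donor-recipient genotype pair.

    Pipeline: (1) donor alleles absent from the recipient at two-field level
    are the mismatched alleles; (2) their proteins are scanned into peptides;
    (3) each peptide is scored against each recipient DRB1 allele; (4) only
    predictions with IC50 strictly below the threshold are kept; (5) any
    prediction whose 9-mer core occurs within any recipient HLA protein (all
    five loci) is discarded as self; (6) surviving cores are deduplicated.

    By default one unique core counts once regardless of which DRB1 molecule
    presents it; with ``per_drb1`` cores are counted per presenting DRB1
    allele (items become (DRB1, core) pairs).
    """
    recipient_alleles = set(recipient.alleles)
    drb1 = sorted(set(recipient.alleles_at("DRB1")))
    if not drb1:  # unreachable for well-formed genotypes; guards raw input
        raise MissingLocusError("recipient genotype lacks DRB1 alleles")
    self_sequences = [proteins[a] for a in recipient.unique_alleles()]
    mismatched = [a for a in donor.unique_alleles() if a not in recipient_alleles]

    items: set = set()
    for allele in mismatched:
        for peptide in generate_peptides(proteins[allele], window=peptide_window):
            for presenter in drb1:
                pred = predictor(peptide, presenter)
                if not pred.ic50 < ic50_threshold:
                    continue
                if any(pred.core in seq for seq in self_sequences):
                    continue
                items.add((presenter.name, pred.core) if per_drb1 else pred.core)
    frozen = frozenset(items)
    return EpitopeScore(count=len(frozen), items=frozen)
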