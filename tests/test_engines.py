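"""Eplet and PIRCHE-II engines: examples, invariants, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_eplets, brute_force_pirche2
from conftest import random_genotype

from epimatch.engines import (
    AMINO_ACIDS,
    BindingPrediction,
    EpletRegistry,
    ProteinDB,
    count_eplet_mismatches,
    count_pirche2,
    generate_peptides,
    mock_predictor,
)
from epimatch.errors import MissingProteinError, RegistryError
from epimatch.nomenclature import LOCI, AlleleCode, Genotype


def _genotype(allele_names):
    """Build a genotype from 10 allele names ordered h1[5] + h2[5]."""
    alleles = [AlleleCode.parse(n) for n in allele_names]
    return Genotype(haplotypes=(tuple(alleles[:5]), tuple(alleles[5:])))


VEC1 = ["A*01:01", "B*01:01", "C*01:01", "DRB1*01:01", "DQB1*01:01"]
VEC2 = ["A*02:01", "B*02:01", "C*02:01", "DRB1*02:01", "DQB1*02:01"]


def test_eplet_self_match_is_zero(small_world):
    g = Genotype.from_haplotypes(*small_world.table.entries[:2])
    assert count_eplet_mismatches(g, g, small_world.eplets).count == 0


def test_eplet_interlocus_neutralization():
    """An eplet carried by a recipient allele at a *different* locus still
    neutralizes the donor eplet."""
    registry = EpletRegistry(
        annotations={
            **{AlleleCode.parse(n): frozenset() for n in VEC1 + VEC2},
            AlleleCode.parse("A*01:01"): frozenset({"e1", "e2"}),
            AlleleCode.parse("DQB1*02:01"): frozenset({"e2"}),
        }
    )
    donor = _genotype(VEC1 + VEC1)
    recipient = _genotype(VEC2 + VEC2)
    score = count_eplet_mismatches(donor, recipient, registry)
    assert score.items == frozenset({"e1"})
    assert score.count == 1


def test_eplet_unannotated_allele_raises(small_world):
    registry = EpletRegistry(annotations={})
    g = Genotype.from_haplotypes(*small_world.table.entries[:2])
    with pytest.raises(RegistryError, match=g.unique_alleles()[0].name):
        count_eplet_mismatches(g, g, registry)


def test_eplet_matches_set_algebra_oracle(small_world):
    rng = np.random.default_rng(2)
    for _ in range(200):
        donor = random_genotype(small_world, rng)
        recipient = random_genotype(small_world, rng)
        for per_class in (False, True):
            score = count_eplet_mismatches(
                donor, recipient, small_world.eplets, per_class=per_class
            )
            assert set(score.items) == brute_force_eplets(
                donor, recipient, small_world.eplets, per_class=per_class
            )


def test_eplet_neutralization_is_monotone(small_world):
    """Adding an allele's eplets to the recipient can only lower the count."""
    rng = np.random.default_rng(8)
    registry = small_world.eplets
    for _ in range(30):
        donor = random_genotype(small_world, rng)
        recipient = random_genotype(small_world, rng)
        base = count_eplet_mismatches(donor, recipient, registry).count
        extra = random_genotype(small_world, rng)
        widened = EpletRegistry(
            annotations={
                a: (
                    eplets | registry.eplets_of(extra.alleles[0])
                    if a in recipient.alleles
                    else eplets
                )
                for a, eplets in registry.annotations.items()
            }
        )
        assert count_eplet_mismatches(donor, recipient, widened).count <= base


@pytest.mark.parametrize(
    "length,window,expected",
    [(17, 15, 3), (9, 15, 1), (15, 15, 1), (20, 9, 12)],
)
def test_peptide_window_counts(length, window, expected):
    seq = "".join(AMINO_ACIDS[i % 20] for i in range(length))
    assert len(generate_peptides(seq, window=window)) == expected


def test_peptide_window_below_core_rejected():
    with pytest.raises(ValueError):
        generate_peptides("A" * 20, window=8)


@given(st.integers(9, 40), st.integers(9, 20))
@settings(max_examples=40, derandomize=True, deadline=None)
def test_peptides_relocate_in_source(length, window):
    rng = np.random.default_rng(length * 100 + window)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    peptides = generate_peptides(seq, window=window)
    pos = 0
    for p in peptides:
        found = seq.find(p, pos)
        assert found >= 0
        pos = found  # order preserved
    assert peptides[0] == seq[: min(window, length)]


def test_mock_predictor_is_deterministic_and_bounded():
    allele = AlleleCode.parse("DRB1*01:01")
    p1 = mock_predictor("ACDEFGHIKLMNPQR", allele)
    p2 = mock_predictor("ACDEFGHIKLMNPQR", allele)
    assert p1 == p2
    assert len(p1.core) == 9 and p1.core in p1.peptide
    assert 1.0 < p1.ic50 < 50000.0
    with pytest.raises(ValueError):
        mock_predictor("SHORT", allele)


def test_mock_predictor_yields_binders_and_nonbinders():
    rng = np.random.default_rng(123)
    allele = AlleleCode.parse("DRB1*03:01")
    ic50s = []
    for _ in range(2000):
        pep = "".join(rng.choice(list(AMINO_ACIDS), size=15))
        ic50s.append(mock_predictor(pep, allele).ic50)
    below = sum(1 for x in ic50s if x < 1000.0)
    assert 0 < below < len(ic50s)


def test_pirche_self_match_is_zero(small_world):
    g = Genotype.from_haplotypes(*small_world.table.entries[:2])
    assert count_pirche2(g, g, small_world.proteins).count == 0


def test_pirche_self_core_filter():
    """A high-affinity core present in a recipient protein is discarded."""
    core = "AAAAAAAAA"

    def stub_predictor(peptide, allele):
        return BindingPrediction(peptide=peptide, core=peptide[:9], ic50=500.0)

    donor = _genotype(VEC1 + VEC1)
    recipient = _genotype(VEC2 + VEC2)
    donor_seq = core + "CDEF"
    sequences = {a: "MNPQRSTVWY" for a in recipient.unique_alleles()}
    sequences[AlleleCode.parse("C*02:01")] = "W" + core  # self carries the core
    for a in donor.unique_alleles():
        sequences[a] = donor_seq
    proteins = ProteinDB(sequences=sequences)
    score = count_pirche2(donor, recipient, proteins, predictor=stub_predictor)
    assert core not in score.items
    # removing the self copy reinstates the core
    sequences[AlleleCode.parse("C*02:01")] = "MNPQRSTVWY"
    score2 = count_pirche2(donor, recipient, ProteinDB(sequences=sequences),
                           predictor=stub_predictor)
    assert core in score2.items


def test_pirche_matches_straight_line_oracle(small_world):
    rng = np.random.default_rng(31)
    for _ in range(100):
        donor = random_genotype(small_world, rng)
        recipient = random_genotype(small_world, rng)
        score = count_pirche2(donor, recipient, small_world.proteins)
        oracle = brute_force_pirche2(
            donor, recipient, small_world.proteins, mock_predictor
        )
        assert set(score.items) == oracle
        assert score.count == len(oracle)


def test_pirche_threshold_monotonicity(small_world):
    rng = np.random.default_rng(37)
    for _ in range(20):
        donor = random_genotype(small_world, rng)
        recipient = random_genotype(small_world, rng)
        counts = [
            count_pirche2(
                donor, recipient, small_world.proteins, ic50_threshold=t
            ).count
            for t in (200.0, 1000.0, 5000.0, 50000.0)
        ]
        assert counts == sorted(counts)


def test_pirche_missing_protein_raises(small_world):
    donor = _genotype(VEC1 + VEC1)
    recipient = _genotype(VEC2 + VEC2)
    with pytest.raises(MissingProteinError):
        count_pirche2(donor, recipient, ProteinDB(sequences={}))


def test_pirche_per_drb1_counts_at_least_global(small_world):
    rng = np.random.default_rng(43)
    for _ in range(20):
        donor = random_genotype(small_world, rng)
        recipient = random_genotype(small_world, rng)
        global_count = count_pirche2(donor, recipient, small_world.proteins).count
        per_drb1 = count_pirche2(
            donor, recipient, small_world.proteins, per_drb1=True
        ).count
        assert per_drb1 >= global_count
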