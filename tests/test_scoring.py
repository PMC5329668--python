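"""Frequency-weighted couple scoring: expectation algebra and scenarios."""

import numpy as np
import pytest

from conftest import random_genotype

from epimatch.engines import EpletRegistry
from epimatch.errors import UnimputableError
from epimatch.extrapolation import SCHEMES, enumerate_candidates, extrapolate
from epimatch.fixtures import degrade
from epimatch.nomenclature import (
    LOCI,
    AlleleCode,
    Genotype,
    Haplotype,
    HaplotypeFrequencyTable,
    Phenotype,
    SerologyMap,
    SerotypeCode,
    phenotype_of,
)
from epimatch.population import Couple, VirtualIndividual
from epimatch.scoring import (
    ScoringResources,
    evaluate_couples,
    genotype_score,
    imputed_epitope_value,
    scenario_score,
)


def _couple(donor_g, recipient_g):
    return Couple(
        donor=VirtualIndividual(id="d", genotype=donor_g),
        recipient=VirtualIndividual(id="r", genotype=recipient_g),
        mm_a=0, mm_b=0, mm_dr=0,
    )


def test_two_equal_weight_candidates_average_their_scores():
    """Recipient ambiguous between a 0-eplet and a 4-eplet candidate, both
    equally frequent, vs a single donor candidate -> expectation 2.0."""
    def vec(tag):
        return tuple(AlleleCode.parse(f"{locus}*{tag:02d}:01") for locus in LOCI)

    v1, v_d = vec(1), vec(3)
    a_good = AlleleCode.parse("A*02:01")   # neutralizes the donor eplets
    a_bad = AlleleCode.parse("A*02:02")    # same split antigen, no eplets
    v_good = (a_good,) + v1[1:]
    v_bad = (a_bad,) + v1[1:]

    allele_to_split: dict = {}
    split_to_broad: dict = {}
    prefix = {"A": "A", "B": "B", "C": "Cw", "DRB1": "DR", "DQB1": "DQ"}
    for tag, vv in (("1", v1), ("3", v_d)):
        for locus, a in zip(LOCI, vv):
            s = SerotypeCode(locus=locus, antigen=f"{prefix[locus]}1{tag}", level="split")
            split_to_broad[s] = SerotypeCode(locus=locus, antigen=f"{prefix[locus]}1",
                                             level="broad")
            allele_to_split[a] = s
    s_a2 = SerotypeCode(locus="A", antigen="A12", level="split")
    split_to_broad[s_a2] = SerotypeCode(locus="A", antigen="A1", level="broad")
    allele_to_split[a_good] = s_a2
    allele_to_split[a_bad] = s_a2
    smap = SerologyMap(allele_to_split=allele_to_split, split_to_broad=split_to_broad)

    table = HaplotypeFrequencyTable(
        entries=(
            Haplotype(alleles=v1, frequency=0.2),
            Haplotype(alleles=v_good, frequency=0.3),
            Haplotype(alleles=v_bad, frequency=0.3),
            Haplotype(alleles=v_d, frequency=0.2),
        )
    )
    registry = EpletRegistry(
        annotations={
            **{a: frozenset() for a in v1 + v_d + (a_good, a_bad)},
            v_d[0]: frozenset({"e1", "e2", "e3", "e4"}),  # donor's A carries 4
            a_good: frozenset({"e1", "e2", "e3", "e4"}),  # recipient may carry them
        }
    )
    resources = ScoringResources(registry=registry)
    donor = Genotype(haplotypes=(v_d, v_d))
    donor_ph = degrade(donor, smap, "two_field")
    # recipient typed heterozygous A11/A12: candidates (v1, v_good) scoring 0
    # and (v1, v_bad) scoring 4, frequencies .06 each -> weights .5/.5
    recipient_ph = phenotype_of(Genotype(haplotypes=(v1, v_good)), smap, "split")
    result = imputed_epitope_value(
        donor_ph, recipient_ph, table, smap, "eplet", resources
    )
    assert result.n_donor_candidates == 1
    assert result.n_recipient_candidates == 2
    assert result.expected_value == pytest.approx(2.0, abs=1e-12)


def test_reference_agreement_for_in_table_two_field_inputs(small_world):
    rng = np.random.default_rng(19)
    resources = small_world.resources()
    for _ in range(5):
        donor = random_genotype(small_world, rng)
        recipient = random_genotype(small_world, rng)
        for engine in ("pirche2", "eplet"):
            reference = genotype_score(donor, recipient, engine, resources)
            observed = imputed_epitope_value(
                degrade(donor, small_world.serology, "two_field"),
                degrade(recipient, small_world.serology, "two_field"),
                small_world.table,
                small_world.serology,
                engine,
                resources,
            )
            assert observed.expected_value == float(reference)
            assert observed.n_donor_candidates == 1
            assert observed.n_recipient_candidates == 1


def test_expectation_bounds_and_weight_conservation(small_world):
    rng = np.random.default_rng(23)
    resources = small_world.resources()
    cache: dict = {}
    for _ in range(5):
        donor = random_genotype(small_world, rng)
        recipient = random_genotype(small_world, rng)
        d_res = extrapolate(degrade(donor, small_world.serology, "split"),
                            small_world.table, small_world.serology)
        r_res = extrapolate(degrade(recipient, small_world.serology, "split"),
                            small_world.table, small_world.serology)
        total_weight = sum(d.weight * r.weight for d in d_res.genotypes
                           for r in r_res.genotypes)
        assert total_weight == pytest.approx(1.0, abs=1e-9)
        for engine in ("pirche2", "eplet"):
            scores = [
                genotype_score(d.genotype, r.genotype, engine, resources, cache)
                for d in d_res.genotypes
                for r in r_res.genotypes
            ]
            result = imputed_epitope_value(
                degrade(donor, small_world.serology, "split"),
                degrade(recipient, small_world.serology, "split"),
                small_world.table, small_world.serology, engine, resources,
                cache=cache,
            )
            assert min(scores) - 1e-9 <= result.expected_value <= max(scores) + 1e-9


def test_scenario_reference_equals_plain_engine_score(small_world):
    rng = np.random.default_rng(29)
    resources = small_world.resources()
    donor = random_genotype(small_world, rng)
    recipient = random_genotype(small_world, rng)
    couple = _couple(donor, recipient)
    for engine in ("pirche2", "eplet"):
        ref = scenario_score(
            couple, small_world.table, small_world.serology, engine, "reference",
            resources,
        )
        assert ref.expected_value == float(
            genotype_score(donor, recipient, engine, resources)
        )
        assert ref.scheme_donor is None


def test_dropping_a_locus_preserves_candidates(small_world):
    """Candidates of the full split phenotype remain candidates after the C
    locus is dropped (removing a constraint cannot remove a candidate)."""
    rng = np.random.default_rng(31)
    smap = small_world.serology
    for _ in range(10):
        g = random_genotype(small_world, rng)
        full = {
            c.genotype
            for c in enumerate_candidates(
                degrade(g, smap, "split"), small_world.table, smap, SCHEMES[0]
            )
        }
        dropped = {
            c.genotype
            for c in enumerate_candidates(
                degrade(g, smap, "split_drop_C"), small_world.table, smap, SCHEMES[0]
            )
        }
        assert full <= dropped


def test_twofield_recipient_collapses_recipient_side(small_world):
    rng = np.random.default_rng(37)
    resources = small_world.resources()
    couple = _couple(random_genotype(small_world, rng), random_genotype(small_world, rng))
    result = scenario_score(
        couple, small_world.table, small_world.serology, "eplet",
        "twofield_recipient_split_donor", resources,
    )
    assert result.n_recipient_candidates == 1


def test_unimputable_side_is_tagged(small_world):
    ghost = SerotypeCode(locus="A", antigen="A99", level="split")
    ph = Phenotype(loci={"A": (ghost,)})
    ok_ph = degrade(
        Genotype.from_haplotypes(*small_world.table.entries[:2]),
        small_world.serology, "split",
    )
    with pytest.raises(UnimputableError) as exc:
        imputed_epitope_value(
            ph, ok_ph, small_world.table, small_world.serology, "eplet",
            small_world.resources(),
        )
    assert exc.value.side == "donor"


def test_cache_reuse_gives_identical_scores(small_world):
    rng = np.random.default_rng(41)
    resources = small_world.resources()
    donor = random_genotype(small_world, rng)
    recipient = random_genotype(small_world, rng)
    cache: dict = {}
    first = genotype_score(donor, recipient, "eplet", resources, cache)
    assert cache  # populated
    assert genotype_score(donor, recipient, "eplet", resources, cache) == first


def test_evaluate_couples_counts_unimputable(small_world):
    rng = np.random.default_rng(47)
    couples = [
        _couple(random_genotype(small_world, rng), random_genotype(small_world, rng))
        for _ in range(5)
    ]
    evaluation = evaluate_couples(
        couples, small_world.table, small_world.serology, "eplet", "split_both",
        small_world.resources(),
    )
    assert evaluation.n_unimputable == 0
    assert len(evaluation.observed) == 5
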