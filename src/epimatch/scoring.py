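"""Frequency-weighted epitope scores for donor-recipient couples.

Combines genotype imputation with the epitope engines: both sides of a
couple are extrapolated independently, the engine is evaluated on every
(donor candidate x recipient candidate) genotype pair, and the weighted sum

    E[score] = sum_d sum_r  w_d * w_r * score(d, r)

is returned.  For two-field in-table inputs each side collapses to a single
candidate of weight one and the expectation equals the plain integer score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .engines import (
    DEFAULT_IC50_THRESHOLD,
    DEFAULT_PEPTIDE_WINDOW,
    EpletRegistry,
    Predictor,
    ProteinDB,
    count_eplet_mismatches,
    count_pirche2,
    mock_predictor,
)
from .errors import UnimputableError
from .extrapolation import DEFAULT_MAX_CANDIDATES, LinkageScheme, extrapolate
from .nomenclature import Genotype, HaplotypeFrequencyTable, Phenotype, SerologyMap

ENGINES = ("pirche2", "eplet")

#: Input scenarios for couple scoring, mirroring the validation settings:
#: split serology on both sides, split with HLA-C or HLA-DQ omitted,
#: two-field recipient with split donor, and the two-field reference.
SCENARIOS = (
    "split_both",
    "split_drop_C",
    "split_drop_DQ",
    "twofield_recipient_split_donor",
    "reference",
)


@dataclass
class ScoringResources:
    """Engine inputs bundled for couple scoring."""

    registry: Optional[EpletRegistry] = None
    proteins: Optional[ProteinDB] = None
    predictor: Predictor = mock_predictor
    ic50_threshold: float = DEFAULT_IC50_THRESHOLD
    peptide_window: int = DEFAULT_PEPTIDE_WINDOW
    per_class: bool = False
    per_drb1: bool = False


@dataclass(frozen=True)
class ImputedScore:
    """The frequency-weighted epitope value for one couple."""

    expected_value: float
    engine: str
    n_donor_candidates: int
    n_recipient_candidates: int
    scheme_donor: Optional[int]  # linkage-scheme mode index, None = bypassed
    scheme_recipient: Optional[int]


def genotype_score(
    donor: Genotype,
    recipient: Genotype,
    engine: str,
    resources: ScoringResources,
    cache: Optional[dict] = None,
) -> int:
    """Integer engine score for one resolved genotype pair, memoized.

    Candidate cross-products repeat genotype pairs heavily, so callers pass
    a shared ``cache`` dict; identical inputs always give identical outputs.
    """
    if cache is not None:
        key = (engine, donor, recipient)
        hit = cache.get(key)
        if hit is not None:
            return hit
    if engine == "eplet":
        if resources.registry is None:
            raise ValueError("eplet engine requires an eplet registry")
        score = count_eplet_mismatches(
            donor, recipient, resources.registry, per_class=resources.per_class
        ).count
    elif engine == "pirche2":
        if resources.proteins is None:
            raise ValueError("pirche2 engine requires a protein database")
        score = count_pirche2(
            donor,
            recipient,
            resources.proteins,
            predictor=resources.predictor,
            ic50_threshold=resources.ic50_threshold,
            peptide_window=resources.peptide_window,
            per_drb1=resources.per_drb1,
        ).count
    else:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    if cache is not None:
        cache[key] = score
    return score


def imputed_epitope_value(
    donor_phenotype: Phenotype,
    recipient_phenotype: Phenotype,
    table: HaplotypeFrequencyTable,
    smap: SerologyMap,
    engine: str,
    resources: ScoringResources,
    cache: Optional[dict] = None,
    hw_factor: bool = False,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> ImputedScore:
    """Frequency-weighted epitope value for a couple at any input resolution.

    Both phenotypes are extrapolated independently over the full five loci
    (loci omitted from the input are filled in by imputation); the engine
    runs on every candidate pair and the double-weighted sum is returned.
    An unimputable side raises :class:`UnimputableError` tagged with the
    side that failed.
    """
    try:
        donor_result = extrapolate(
            donor_phenotype, table, smap, hw_factor=hw_factor, max_candidates=max_candidates
        )
    except UnimputableError as exc:
        raise UnimputableError(str(exc), phenotype=exc.phenotype, side="donor") from None
    try:
        recipient_result = extrapolate(
            recipient_phenotype, table, smap, hw_factor=hw_factor, max_candidates=max_candidates
        )
    except UnimputableError as exc:
        raise UnimputableError(str(exc), phenotype=exc.phenotype, side="recipient") from None

    expected = 0.0
    for d in donor_result.genotypes:
        for r in recipient_result.genotypes:
            score = genotype_score(d.genotype, r.genotype, engine, resources, cache)
            expected += d.weight * r.weight * score
    return ImputedScore(
        expected_value=expected,
        engine=engine,
        n_donor_candidates=len(donor_result.genotypes),
        n_recipient_candidates=len(recipient_result.genotypes),
        scheme_donor=donor_result.scheme_used.mode_index,
        scheme_recipient=recipient_result.scheme_used.mode_index,
    )


def scenario_score(
    couple,
    table: HaplotypeFrequencyTable,
    smap: SerologyMap,
    engine: str,
    scenario: str,
    resources: ScoringResources,
    cache: Optional[dict] = None,
    hw_factor: bool = False,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> ImputedScore:
    """Score a couple under one input scenario.

    ``couple`` must carry true two-field genotypes (``couple.donor.genotype``
    and ``couple.recipient.genotype``) from which each scenario's input
    phenotypes are derived; ``reference`` bypasses imputation entirely and
    returns the plain engine score.
    """
    from .fixtures import degrade  # deferred: fixtures also imports engines

    donor_g = couple.donor.genotype
    recipient_g = couple.recipient.genotype
    if scenario == "reference":
        score = genotype_score(donor_g, recipient_g, engine, resources, cache)
        return ImputedScore(
            expected_value=float(score),
            engine=engine,
            n_donor_candidates=1,
            n_recipient_candidates=1,
            scheme_donor=None,
            scheme_recipient=None,
        )
    if scenario == "split_both":
        donor_ph = degrade(donor_g, smap, "split")
        recipient_ph = degrade(recipient_g, smap, "split")
    elif scenario == "split_drop_C":
        donor_ph = degrade(donor_g, smap, "split_drop_C")
        recipient_ph = degrade(recipient_g, smap, "split_drop_C")
    elif scenario == "split_drop_DQ":
        donor_ph = degrade(donor_g, smap, "split_drop_DQ")
        recipient_ph = degrade(recipient_g, smap, "split_drop_DQ")
    elif scenario == "twofield_recipient_split_donor":
        donor_ph = degrade(donor_g, smap, "split")
        recipient_ph = degrade(recipient_g, smap, "two_field")
    else:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    return imputed_epitope_value(
        donor_ph,
        recipient_ph,
        table,
        smap,
        engine,
        resources,
        cache=cache,
        hw_factor=hw_factor,
        max_candidates=max_candidates,
    )


@dataclass
class CoupleEvaluation:
    """Observed vs reference scores for a list of couples, one scenario."""

    engine: str
    scenario: str
    observed: list  # (couple_index, observed expected value, reference score)
    n_unimputable: int


def evaluate_couples(
    couples,
    table: HaplotypeFrequencyTable,
    smap: SerologyMap,
    engine: str,
    scenario: str,
    resources: ScoringResources,
    cache: Optional[dict] = None,
    hw_factor: bool = False,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
) -> CoupleEvaluation:
    """Observed and reference scores for every couple; unimputable couples
    are counted and excluded rather than aborting the run."""
    if cache is None:
        cache = {}
    observed = []
    n_unimputable = 0
    for i, couple in enumerate(couples):
        reference = genotype_score(
            couple.donor.genotype, couple.recipient.genotype, engine, resources, cache
        )
        try:
            score = scenario_score(
                couple,
                table,
                smap,
                engine,
                scenario,
                resources,
                cache=cache,
                hw_factor=hw_factor,
                max_candidates=max_candidates,
            )
        except UnimputableError:
            n_unimputable += 1
            continue
        observed.append((i, score.expected_value, reference))
    return CoupleEvaluation(
        engine=engine, scenario=scenario, observed=observed, n_unimputable=n_unimputable
    )
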