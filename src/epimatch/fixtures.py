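"""Deterministic synthetic HLA "worlds" for testing and simulation studies.

A world bundles everything the pipeline consumes: per-locus allele lists, a
serology map with configurable degeneracy (``alleles_per_split`` alleles per
split antigen, ``splits_per_broad`` splits per broad antigen), random
protein sequences, a random eplet registry with controlled sharing, and a
truncated Dirichlet-sampled haplotype-frequency table.  Worlds are sized so
exhaustive brute-force oracles stay feasible; they emulate the *structure*
of published frequency tables and registries, not their biology — protein
sequences are random strings, because only the pipeline's combinatorics
matter for validation.

Everything is regenerable bit-exactly from (seed, parameters).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from .engines import AMINO_ACIDS, EpletRegistry, ProteinDB
from .io import (
    write_eplets,
    write_frequency_table,
    write_proteins,
    write_serology_map,
)
from .nomenclature import (
    LOCI,
    SEROLOGY_PREFIX,
    AlleleCode,
    Genotype,
    Haplotype,
    HaplotypeFrequencyTable,
    Phenotype,
    SerologyMap,
    SerotypeCode,
    phenotype_of,
)

#: Scenario names accepted by :func:`degrade`.
DEGRADE_SCENARIOS = ("split", "split_drop_C", "split_drop_DQ", "two_field")


@dataclass(frozen=True)
class WorldParams:
    """Size and degeneracy knobs of a synthetic world.

    The defaults give a small world (4 alleles per locus, 40 haplotypes)
    on which exhaustive pair enumeration is cheap; serological degeneracy 2
    (two alleles behind every split antigen) makes split-level typings
    genuinely ambiguous.
    """

    alleles_per_locus: int = 4
    alleles_per_split: int = 2
    splits_per_broad: int = 2
    n_haplotypes: int = 40
    protein_length: int = 50
    eplets_per_allele: int = 6
    eplet_pool: int = 40
    #: Dirichlet concentration; < 1 gives the skewed few-common/many-rare
    #: frequency profile real truncated tables show, exercising fallback.
    dirichlet_alpha: float = 0.35

    def __post_init__(self):
        for name in (
            "alleles_per_locus",
            "alleles_per_split",
            "splits_per_broad",
            "n_haplotypes",
            "protein_length",
            "eplets_per_allele",
            "eplet_pool",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_haplotypes > self.alleles_per_locus ** len(LOCI):
            raise ValueError(
                "n_haplotypes exceeds the number of possible 5-locus combinations"
            )


@dataclass(frozen=True)
class FixtureWorld:
    seed: int
    params: WorldParams
    alleles: dict  # locus -> tuple[AlleleCode] actually covered by the table
    serology: SerologyMap
    proteins: ProteinDB
    eplets: EpletRegistry
    table: HaplotypeFrequencyTable
    dropped_alleles: tuple  # alleles generated but absent from every haplotype

    def resources(self):
        from .scoring import ScoringResources

        return ScoringResources(registry=self.eplets, proteins=self.proteins)


def _allele_names(locus: str, params: WorldParams) -> list[tuple[AlleleCode, int]]:
    """Alleles for one locus with their split index (1-based).

    Allele ``L*ss:jj`` belongs to split ``ss``, so serological degeneracy is
    built into the naming.
    """
    out = []
    s, j = 1, 1
    for _ in range(params.alleles_per_locus):
        out.append((AlleleCode.parse(f"{locus}*{s:02d}:{j:02d}"), s))
        j += 1
        if j > params.alleles_per_split:
            s, j = s + 1, 1
    return out


def generate_world(seed: int, params: WorldParams | None = None) -> FixtureWorld:
    """Generate a deterministic synthetic world from a seed and parameters."""
    params = params or WorldParams()
    rng = np.random.default_rng(seed)

    # Alleles and serology.
    allele_split: dict[AlleleCode, SerotypeCode] = {}
    split_broad: dict[SerotypeCode, SerotypeCode] = {}
    per_locus: dict[str, list[AlleleCode]] = {}
    for locus in LOCI:
        named = _allele_names(locus, params)
        per_locus[locus] = [a for a, _ in named]
        n_splits = max(s for _, s in named)
        n_broads = -(-n_splits // params.splits_per_broad)  # ceil
        prefix = SEROLOGY_PREFIX[locus]
        # Broad antigens take numbers 1..n_broads, splits continue after, so
        # split and broad names never collide.
        for s in range(1, n_splits + 1):
            split = SerotypeCode(locus=locus, antigen=f"{prefix}{n_broads + s}", level="split")
            b = (s - 1) // params.splits_per_broad + 1
            split_broad[split] = SerotypeCode(locus=locus, antigen=f"{prefix}{b}", level="broad")
        for allele, s in named:
            allele_split[allele] = SerotypeCode(
                locus=locus, antigen=f"{prefix}{n_broads + s}", level="split"
            )
    serology = SerologyMap(allele_to_split=allele_split, split_to_broad=split_broad)

    # Protein sequences (iteration order fixed: loci order, then allele order).
    aa = np.array(list(AMINO_ACIDS))
    sequences = {
        allele: "".join(rng.choice(aa, size=params.protein_length))
        for locus in LOCI
        for allele in per_locus[locus]
    }
    proteins = ProteinDB(sequences=sequences)

    # Eplet registry: draws from a shared pool give controlled sharing.
    pool = np.array([f"EP{i:03d}" for i in range(params.eplet_pool)])
    k = min(params.eplets_per_allele, params.eplet_pool)
    registry = EpletRegistry(
        annotations={
            allele: frozenset(rng.choice(pool, size=k, replace=False))
            for locus in LOCI
            for allele in per_locus[locus]
        }
    )

    # Frequency table: a random subset of all 5-locus combinations with
    # skewed Dirichlet frequencies, sorted most-common-first like a
    # truncated published table.
    n_combos = params.alleles_per_locus ** len(LOCI)
    combo_idx = rng.choice(n_combos, size=params.n_haplotypes, replace=False)
    freqs = rng.dirichlet(np.full(params.n_haplotypes, params.dirichlet_alpha))
    entries = []
    for ci, f in zip(combo_idx, freqs):
        digits = []
        rem = int(ci)
        for _ in LOCI:
            digits.append(rem % params.alleles_per_locus)
            rem //= params.alleles_per_locus
        alleles = tuple(per_locus[locus][d] for locus, d in zip(LOCI, digits))
        entries.append(Haplotype(alleles=alleles, frequency=float(f)))
    entries.sort(key=lambda h: (-h.frequency, tuple(a.name for a in h.alleles)))
    table = HaplotypeFrequencyTable(
        entries=tuple(entries), metadata={"source": f"synthetic world seed={seed}"}
    )

    # Alleles never drawn into a haplotype cannot be imputed; drop them from
    # the world's allele lists and report them.
    covered = table.alleles()
    dropped = tuple(
        a for locus in LOCI for a in per_locus[locus] if a not in covered
    )
    alleles = {
        locus: tuple(a for a in per_locus[locus] if a in covered) for locus in LOCI
    }
    return FixtureWorld(
        seed=seed,
        params=params,
        alleles=alleles,
        serology=serology,
        proteins=proteins,
        eplets=registry,
        table=table,
        dropped_alleles=dropped,
    )


def degrade(genotype: Genotype, smap: SerologyMap, scenario: str) -> Phenotype:
    """Project a true two-field genotype to one scenario's input phenotype."""
    if scenario == "split":
        return phenotype_of(genotype, smap, "split", loci=LOCI)
    if scenario == "split_drop_C":
        return phenotype_of(
            genotype, smap, "split", loci=tuple(l for l in LOCI if l != "C")
        )
    if scenario == "split_drop_DQ":
        return phenotype_of(
            genotype, smap, "split", loci=tuple(l for l in LOCI if l != "DQB1")
        )
    if scenario == "two_field":
        return phenotype_of(genotype, smap, "two-field", loci=LOCI)
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {DEGRADE_SCENARIOS}")


def write_world(world: FixtureWorld, outdir: str | Path) -> dict[str, Path]:
    """Write all external-interface files of a world plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "frequency_table": outdir / "frequencies.csv",
        "serology_map": outdir / "serology.csv",
        "proteins": outdir / "proteins.fasta",
        "eplets": outdir / "eplets.csv",
        "manifest": outdir / "manifest.json",
    }
    write_frequency_table(world.table, paths["frequency_table"])
    write_serology_map(world.serology, paths["serology_map"])
    write_proteins(world.proteins, str(paths["proteins"]))
    write_eplets(world.eplets, paths["eplets"])
    manifest = {
        "seed": world.seed,
        "params": asdict(world.params),
        "dropped_alleles": [a.name for a in world.dropped_alleles],
        "files": {k: p.name for k, p in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
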