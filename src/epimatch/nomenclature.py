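"""HLA naming, serological mapping, haplotypes, genotypes and phenotypes.

The matching pipeline works on five loci (HLA-A, -B, -C, -DRB1, -DQB1) at
two resolution levels:

* **two-field alleles** (``A*01:01``) — the resolution at which protein
  sequences, eplet annotations and peptide scoring are defined;
* **serological antigens** at *split* (``A24``) or *broad* (``A9``) level —
  the resolution of routine pre-transplant typing.  One serotype covers many
  alleles, so a serological typing is ambiguous at the allele level.

An explicit :class:`SerologyMap` (allele → split antigen → broad antigen)
carries the dictionary between the two worlds; it is always an input, never
hard-coded, because published frequency tables and serology releases differ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .errors import MappingError, ParseError

#: The five loci handled by the pipeline, in canonical order.
LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQB1")
CLASS_I: tuple[str, ...] = ("A", "B", "C")
CLASS_II: tuple[str, ...] = ("DRB1", "DQB1")

#: Conventional serological antigen prefix per locus (Cw4, DR15, DQ6 ...).
SEROLOGY_PREFIX: dict[str, str] = {
    "A": "A",
    "B": "B",
    "C": "Cw",
    "DRB1": "DR",
    "DQB1": "DQ",
}
_PREFIX_TO_LOCUS = {"A": "A", "B": "B", "CW": "C", "DR": "DRB1", "DQ": "DQB1"}

_ALLELE_RE = re.compile(
    r"^(?:(?P<locus>[A-Za-z0-9]+)\*)?(?P<f1>\d+):(?P<f2>\d+)(?P<suffix>[A-Z]?)$"
)
_SEROTYPE_RE = re.compile(r"^(?P<prefix>A|B|Cw|CW|DR|DQ)(?P<num>\d+)$")


def _check_locus(locus: str) -> str:
    locus = locus.upper()
    if locus not in LOCI:
        raise ParseError(
            f"unsupported locus {locus!r}: this pipeline is restricted to "
            f"the five loci {', '.join(LOCI)}"
        )
    return locus


@dataclass(frozen=True, order=True)
class AlleleCode:
    """A two-field HLA allele, normalized to ``LOCUS*NN:NN`` form."""

    locus: str
    name: str

    @classmethod
    def parse(cls, text: str, locus: str | None = None) -> "AlleleCode":
        """Parse an allele name, with or without a locus prefix.

        Accepts missing leading zeros (``A*1:1``) and lower-case loci.
        Normalization is idempotent: ``parse(str(a)) == a``.
        """
        m = _ALLELE_RE.match(text.strip())
        if m is None:
            raise ParseError(f"malformed allele name {text!r}")
        embedded = m.group("locus")
        if embedded is not None:
            embedded = _check_locus(embedded)
            if locus is not None and _check_locus(locus) != embedded:
                raise ParseError(
                    f"allele {text!r} does not belong to locus {locus!r}"
                )
            locus = embedded
        elif locus is None:
            raise ParseError(f"allele {text!r} has no locus prefix and none was given")
        locus = _check_locus(locus)
        f1 = m.group("f1").zfill(2)
        f2 = m.group("f2").zfill(2)
        name = f"{locus}*{f1}:{f2}{m.group('suffix')}"
        return cls(locus=locus, name=name)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


@dataclass(frozen=True, order=True)
class SerotypeCode:
    """A serological antigen at split or broad level (e.g. ``A24`` split)."""

    locus: str
    antigen: str
    level: str  # "split" | "broad"

    def __post_init__(self):
        if self.level not in ("split", "broad"):
            raise ParseError(f"serotype level must be split/broad, got {self.level!r}")

    @classmethod
    def parse(cls, text: str, level: str, locus: str | None = None) -> "SerotypeCode":
        m = _SEROTYPE_RE.match(text.strip())
        if m is None:
            raise ParseError(f"malformed serotype name {text!r}")
        inferred = _PREFIX_TO_LOCUS[m.group("prefix").upper()]
        if locus is not None and _check_locus(locus) != inferred:
            raise ParseError(f"serotype {text!r} does not belong to locus {locus!r}")
        prefix = SEROLOGY_PREFIX[inferred]
        return cls(locus=inferred, antigen=f"{prefix}{int(m.group('num'))}", level=level)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.antigen


#: A typing value: either an allele or a serotype.
TypingValue = Union[AlleleCode, SerotypeCode]


@dataclass(frozen=True)
class SerologyMap:
    """Dictionary between alleles and serological antigens.

    ``allele_to_split`` maps every known allele to its split antigen;
    ``split_to_broad`` collapses split antigens into broad antigens.  Every
    split antigen appearing in ``allele_to_split`` must have a broad parent.
    """

    allele_to_split: Mapping[AlleleCode, SerotypeCode]
    split_to_broad: Mapping[SerotypeCode, SerotypeCode]

    def __post_init__(self):
        missing = {
            s for s in set(self.allele_to_split.values()) if s not in self.split_to_broad
        }
        if missing:
            names = ", ".join(sorted(s.antigen for s in missing))
            raise MappingError(f"split antigens without a broad parent: {names}")

    def require_covers(self, alleles: Iterable[AlleleCode]) -> None:
        """Raise :class:`MappingError` if any allele lacks a split mapping."""
        missing = sorted(a.name for a in alleles if a not in self.allele_to_split)
        if missing:
            raise MappingError(
                f"alleles without a serological mapping: {', '.join(missing)}",
                value=missing,
            )


def serologize(value: TypingValue, smap: SerologyMap, level: str) -> SerotypeCode:
    """Project a typing value to the requested serological level.

    Alleles are mapped through the serology map; a split serotype passes
    through unchanged at split level and is collapsed at broad level; a broad
    serotype is only valid at broad level (it cannot be refined to a split).
    """
    if level not in ("split", "broad"):
        raise ValueError(f"level must be split/broad, got {level!r}")
    if isinstance(value, AlleleCode):
        split = smap.allele_to_split.get(value)
        if split is None:
            raise MappingError(f"allele {value.name} has no serological mapping", value=value)
        return split if level == "split" else smap.split_to_broad[split]
    if value.level == "split":
        if level == "split":
            return value
        broad = smap.split_to_broad.get(value)
        if broad is None:
            raise MappingError(f"split antigen {value.antigen} has no broad parent", value=value)
        return broad
    # broad input
    if level == "broad":
        return value
    raise MappingError(
        f"broad antigen {value.antigen} cannot be refined to split level", value=value
    )


@dataclass(frozen=True)
class Haplotype:
    """One 5-locus haplotype with its population frequency."""

    alleles: tuple[AlleleCode, ...]  # ordered as LOCI
    frequency: float

    def __post_init__(self):
        if len(self.alleles) != len(LOCI):
            raise ParseError(f"haplotype must carry all {len(LOCI)} loci")
        for locus, allele in zip(LOCI, self.alleles):
            if allele.locus != locus:
                raise ParseError(
                    f"haplotype allele {allele.name} is not at locus {locus}"
                )
        if not self.frequency > 0:
            raise ValueError(f"haplotype frequency must be > 0, got {self.frequency}")

    @property
    def key(self) -> tuple[AlleleCode, ...]:
        return self.alleles


#: Tolerance on the frequency-sum invariant; published tables are truncated
#: (sum < 1) but rounding may also push the sum marginally above 1.
FREQUENCY_SUM_TOLERANCE = 1e-3


@dataclass(frozen=True)
class HaplotypeFrequencyTable:
    """A list of 5-locus haplotypes with frequencies — the imputation prior."""

    entries: tuple[Haplotype, ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[tuple, int] = {}
        for i, h in enumerate(self.entries):
            if h.key in seen:
                from .errors import DuplicateHaplotypeError

                names = "~".join(a.name for a in h.alleles)
                raise DuplicateHaplotypeError(
                    f"duplicate haplotype {names} at rows {seen[h.key]} and {i}"
                )
            seen[h.key] = i
        total = sum(h.frequency for h in self.entries)
        if total > 1 + FREQUENCY_SUM_TOLERANCE:
            raise ValueError(f"haplotype frequencies sum to {total} > 1")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def alleles(self) -> set[AlleleCode]:
        return {a for h in self.entries for a in h.alleles}

    def marginal(self, loci: Sequence[str]) -> dict[tuple[AlleleCode, ...], float]:
        """Marginal frequencies of partial haplotypes over a block of loci.

        The marginal frequency of a block is the sum of table frequencies
        over all full haplotypes agreeing with it at the block's loci.
        """
        idx = [LOCI.index(l) for l in loci]
        out: dict[tuple[AlleleCode, ...], float] = {}
        for h in self.entries:
            key = tuple(h.alleles[i] for i in idx)
            out[key] = out.get(key, 0.0) + h.frequency
        return out


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of full 5-locus allele vectors.

    The two vectors are stored in canonical (sorted) order so that equal
    genotypes hash and compare equal regardless of input chromosome order.
    """

    haplotypes: tuple[tuple[AlleleCode, ...], tuple[AlleleCode, ...]]

    def __post_init__(self):
        h1, h2 = self.haplotypes
        for vec in (h1, h2):
            if len(vec) != len(LOCI):
                raise ParseError("genotype vectors must cover all five loci")
            for locus, allele in zip(LOCI, vec):
                if allele.locus != locus:
                    raise ParseError(
                        f"allele {allele.name} out of place at locus {locus}"
                    )
        if h2 < h1:
            object.__setattr__(self, "haplotypes", (h2, h1))

    @classmethod
    def from_haplotypes(cls, h1: Haplotype, h2: Haplotype) -> "Genotype":
        return cls(haplotypes=(h1.alleles, h2.alleles))

    @property
    def alleles(self) -> tuple[AlleleCode, ...]:
        """All ten allele slots (duplicates kept for homozygous loci)."""
        return self.haplotypes[0] + self.haplotypes[1]

    def alleles_at(self, locus: str) -> tuple[AlleleCode, AlleleCode]:
        i = LOCI.index(locus)
        return (self.haplotypes[0][i], self.haplotypes[1][i])

    def unique_alleles(self) -> tuple[AlleleCode, ...]:
        return tuple(sorted(set(self.alleles)))


@dataclass(frozen=True)
class Phenotype:
    """Per-locus unordered sets of 1–2 typing values; loci may be absent.

    A single value at a locus means the individual is (presumed) homozygous
    at the typed resolution.  Values at one locus must share a resolution;
    different loci may mix resolutions (e.g. two-field class I, split
    class II).
    """

    loci: Mapping[str, tuple[TypingValue, ...]]

    def __post_init__(self):
        norm: dict[str, tuple[TypingValue, ...]] = {}
        for locus in LOCI:
            if locus not in self.loci:
                continue
            values = tuple(
                sorted(set(self.loci[locus]), key=lambda v: (type(v).__name__, str(v)))
            )
            if not 1 <= len(values) <= 2:
                raise ParseError(
                    f"phenotype locus {locus} must carry 1-2 distinct values, "
                    f"got {len(values)}"
                )
            kinds = {self._kind(v) for v in values}
            if len(kinds) > 1:
                raise ParseError(
                    f"phenotype locus {locus} mixes resolutions {sorted(kinds)}"
                )
            for v in values:
                if v.locus != locus:
                    raise ParseError(f"value {v} filed under wrong locus {locus}")
            norm[locus] = values
        unknown = set(self.loci) - set(LOCI)
        if unknown:
            raise ParseError(f"unsupported loci in phenotype: {sorted(unknown)}")
        object.__setattr__(self, "loci", norm)

    @staticmethod
    def _kind(value: TypingValue) -> str:
        return "two-field" if isinstance(value, AlleleCode) else value.level

    def covered_loci(self) -> tuple[str, ...]:
        return tuple(l for l in LOCI if l in self.loci)

    def kind_at(self, locus: str) -> str:
        """Resolution of the values at a locus: two-field, split or broad."""
        return self._kind(self.loci[locus][0])

    def values_at(self, locus: str) -> tuple[TypingValue, ...]:
        return self.loci[locus]


def project_allele(allele: AlleleCode, kind: str, smap: SerologyMap) -> TypingValue:
    """Project an allele to a target resolution ('two-field'/'split'/'broad')."""
    if kind == "two-field":
        return allele
    return serologize(allele, smap, kind)


def phenotype_of(
    genotype: Genotype,
    smap: SerologyMap,
    level: str,
    loci: Sequence[str] = LOCI,
) -> Phenotype:
    """Project a resolved genotype to a phenotype at the requested level.

    Equal projected values collapse to a single entry (homozygosity at the
    typed resolution); loci outside ``loci`` are absent from the output.
    """
    out: dict[str, tuple[TypingValue, ...]] = {}
    for locus in loci:
        a1, a2 = genotype.alleles_at(locus)
        values = {project_allele(a1, level, smap), project_allele(a2, level, smap)}
        out[locus] = tuple(sorted(values))
    return Phenotype(loci=out)
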