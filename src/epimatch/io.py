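"""Readers and writers for the file formats the tool touches.

Formats:

* frequency table — CSV with columns ``A,B,C,DRB1,DQB1,freq`` (``fixtures``
  dialect) or a single ``haplotype`` column of ``~``-joined allele names plus
  ``frequency`` (``nmdp`` dialect, matching the layout of published
  haplotype-frequency releases);
* serology map — CSV ``allele,split,broad``;
* protein database — FASTA with normalized allele names as headers;
* eplet registry — long-format CSV ``allele,eplet``;
* typings — JSON ``{"id", "loci": {"A": [...], ...}, "resolution"}``.
"""

from __future__ import annotations

import json
from os import PathLike
from typing import IO, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .engines import EpletRegistry, ProteinDB
from .errors import ParseError
from .nomenclature import (
    LOCI,
    AlleleCode,
    Haplotype,
    HaplotypeFrequencyTable,
    Phenotype,
    SerologyMap,
    SerotypeCode,
)

Source = Union[str, PathLike, IO]

_FIXTURES_COLUMNS = list(LOCI) + ["freq"]


def parse_frequency_table(source: Source, dialect: str = "fixtures") -> HaplotypeFrequencyTable:
    """Parse a haplotype-frequency CSV; row order is preserved in `entries`."""
    df = pd.read_csv(source, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    entries: list[Haplotype] = []
    if dialect == "fixtures":
        missing = [c for c in _FIXTURES_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"frequency table is missing columns {missing}")
        for i, row in df.iterrows():
            try:
                alleles = tuple(AlleleCode.parse(row[l], locus=l) for l in LOCI)
                freq = float(row["freq"])
            except ParseError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
            if not freq > 0:
                raise ValueError(f"row {i}: nonpositive frequency {freq}")
            entries.append(Haplotype(alleles=alleles, frequency=freq))
    elif dialect == "nmdp":
        if "haplotype" not in df.columns or "frequency" not in df.columns:
            raise ParseError("nmdp dialect requires 'haplotype' and 'frequency' columns")
        for i, row in df.iterrows():
            parts = str(row["haplotype"]).split("~")
            if len(parts) != len(LOCI):
                raise ParseError(f"row {i}: haplotype must list {len(LOCI)} alleles")
            try:
                alleles = tuple(AlleleCode.parse(p, locus=l) for p, l in zip(parts, LOCI))
                freq = float(row["frequency"])
            except ParseError as exc:
                raise ParseError(f"row {i}: {exc}") from exc
            if not freq > 0:
                raise ValueError(f"row {i}: nonpositive frequency {freq}")
            entries.append(Haplotype(alleles=alleles, frequency=freq))
    else:
        raise ParseError(f"unknown frequency-table dialect {dialect!r}")
    name = source if isinstance(source, (str, PathLike)) else getattr(source, "name", "<stream>")
    return HaplotypeFrequencyTable(
        entries=tuple(entries), metadata={"dialect": dialect, "source": str(name)}
    )


def write_frequency_table(table: HaplotypeFrequencyTable, dest: Source) -> None:
    rows = [
        {**{l: a.name for l, a in zip(LOCI, h.alleles)}, "freq": repr(h.frequency)}
        for h in table.entries
    ]
    pd.DataFrame(rows, columns=_FIXTURES_COLUMNS).to_csv(dest, index=False)


def parse_serology_map(source: Source) -> SerologyMap:
    """Parse a CSV ``allele,split,broad`` into a serology map.

    Conflicting rows (one allele under two splits, or one split under two
    broads) are rejected.
    """
    df = pd.read_csv(source, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in ("allele", "split", "broad"):
        if col not in df.columns:
            raise ParseError(f"serology map is missing column {col!r}")
    allele_to_split: dict[AlleleCode, SerotypeCode] = {}
    split_to_broad: dict[SerotypeCode, SerotypeCode] = {}
    for i, row in df.iterrows():
        try:
            allele = AlleleCode.parse(row["allele"])
            split = SerotypeCode.parse(row["split"], level="split", locus=allele.locus)
            broad = SerotypeCode.parse(row["broad"], level="broad", locus=allele.locus)
        except ParseError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        if allele_to_split.get(allele, split) != split:
            raise ParseError(f"row {i}: allele {allele.name} mapped to two splits")
        if split_to_broad.get(split, broad) != broad:
            raise ParseError(f"row {i}: split {split.antigen} mapped to two broads")
        allele_to_split[allele] = split
        split_to_broad[split] = broad
    return SerologyMap(allele_to_split=allele_to_split, split_to_broad=split_to_broad)


def write_serology_map(smap: SerologyMap, dest: Source) -> None:
    rows = [
        {
            "allele": a.name,
            "split": s.antigen,
            "broad": smap.split_to_broad[s].antigen,
        }
        for a, s in sorted(smap.allele_to_split.items())
    ]
    pd.DataFrame(rows, columns=["allele", "split", "broad"]).to_csv(dest, index=False)


def parse_proteins(source: Source) -> ProteinDB:
    """Parse a FASTA of allele protein sequences (headers = allele names)."""
    sequences: dict[AlleleCode, str] = {}
    for record in SeqIO.parse(source, "fasta"):
        allele = AlleleCode.parse(record.id)
        sequences[allele] = str(record.seq)
    return ProteinDB(sequences=sequences)


def write_proteins(proteins: ProteinDB, dest: Source) -> None:
    records = [
        SeqRecord(Seq(seq), id=allele.name, description="")
        for allele, seq in sorted(proteins.sequences.items())
    ]
    SeqIO.write(records, dest, "fasta")


def parse_eplets(source: Source) -> EpletRegistry:
    """Parse a long-format CSV ``allele,eplet`` into an eplet registry."""
    df = pd.read_csv(source, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in ("allele", "eplet"):
        if col not in df.columns:
            raise ParseError(f"eplet registry is missing column {col!r}")
    annotations: dict[AlleleCode, set[str]] = {}
    for i, row in df.iterrows():
        try:
            allele = AlleleCode.parse(row["allele"])
        except ParseError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        annotations.setdefault(allele, set()).add(str(row["eplet"]))
    return EpletRegistry(
        annotations={a: frozenset(e) for a, e in annotations.items()}
    )


def write_eplets(registry: EpletRegistry, dest: Source) -> None:
    rows = [
        {"allele": allele.name, "eplet": eplet}
        for allele, eplets in sorted(registry.annotations.items())
        for eplet in sorted(eplets)
    ]
    pd.DataFrame(rows, columns=["allele", "eplet"]).to_csv(dest, index=False)


def _parse_typing_value(text: str, locus: str) -> "AlleleCode | SerotypeCode":
    if "*" in text or ":" in text:
        return AlleleCode.parse(text, locus=locus)
    return SerotypeCode.parse(text, level="split", locus=locus)


def parse_typing(source: Source) -> tuple[str, Phenotype]:
    """Parse a typing JSON into (id, phenotype).

    Values containing ``*`` or ``:`` are read as two-field alleles, others as
    split-level serotypes; broad-level values are accepted when the document
    declares ``"resolution": "broad"``.
    """
    if isinstance(source, (str, PathLike)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = json.load(source)
    level = doc.get("resolution", "split")
    loci: dict[str, tuple] = {}
    for locus, values in doc["loci"].items():
        parsed = []
        for v in values:
            if level == "broad" and "*" not in v and ":" not in v:
                parsed.append(SerotypeCode.parse(v, level="broad", locus=locus))
            else:
                parsed.append(_parse_typing_value(v, locus))
        loci[locus] = tuple(parsed)
    return str(doc.get("id", "")), Phenotype(loci=loci)


def write_typing(identifier: str, phenotype: Phenotype, dest: Source) -> None:
    kinds = {phenotype.kind_at(l) for l in phenotype.covered_loci()}
    resolution = kinds.pop() if len(kinds) == 1 else "mixed"
    doc = {
        "id": identifier,
        "loci": {
            l: [str(v) for v in phenotype.values_at(l)] for l in phenotype.covered_loci()
        },
        "resolution": resolution,
    }
    if isinstance(dest, (str, PathLike)):
        with open(dest, "w") as fh:
            json.dump(doc, fh, indent=2)
    else:
        json.dump(doc, dest, indent=2)
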