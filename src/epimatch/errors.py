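"""Typed errors raised across the package."""


class EpimatchError(Exception):
    """Base class for all package errors."""


class ParseError(EpimatchError):
    """Malformed input file or name; message names the offending row/value."""


class DuplicateHaplotypeError(ParseError):
    """Frequency table contains the same 5-locus allele combination twice."""


class MappingError(EpimatchError):
    """An allele or serotype has no entry in the loaded serology map."""

    def __init__(self, message: str, value=None):
        super().__init__(message)
        self.value = value


class RegistryError(EpimatchError):
    """An allele is not annotated in the eplet registry."""


class MissingProteinError(EpimatchError):
    """An allele has no protein sequence in the protein database."""


class MissingLocusError(EpimatchError):
    """A genotype lacks a locus required by the operation (e.g. DRB1)."""


class UnimputableError(EpimatchError):
    """No candidate genotype exists even after full linkage breakdown.

    Carries the phenotype that failed and, when raised from couple scoring,
    which side (donor / recipient) it belonged to.
    """

    def __init__(self, message: str, phenotype=None, side: str | None = None):
        super().__init__(message)
        self.phenotype = phenotype
        self.side = side


class CandidateExplosionError(EpimatchError):
    """The candidate-pair enumeration exceeded the configured cap."""


class PoolExhaustedError(EpimatchError):
    """A finite haplotype pool ran out of copies while sampling."""


class RetryLimitError(EpimatchError):
    """Couple formation exceeded the retry cap for one recipient."""
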