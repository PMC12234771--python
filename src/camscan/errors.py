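"""Exception types shared across the package."""


class CamscanError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(CamscanError):
    """Rows of an alignment (or a reference) disagree in length."""


class MetadataError(CamscanError):
    """A sequence header or strain id does not resolve against the strain table."""


class AlphabetError(CamscanError):
    """A sequence contains a character outside {A,C,G,T,N,-}."""


class SelectionError(CamscanError):
    """An empty strain/lineage selection where at least one strain is required."""


class InfeasibilityError(CamscanError):
    """A requested simulation edit cannot be carried out (e.g. single-codon family)."""


class GenerationError(CamscanError):
    """The synthetic-sequence generator could not satisfy its constraints."""


class ConstructionError(CamscanError):
    """Decision-map construction was called with unusable inputs."""
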