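"""Exception types shared across the package."""


class DwarfcallError(Exception):
    """Base class for all package-specific errors."""


class NotFoundError(DwarfcallError, KeyError):
    """A named entity (allele, locus, sample) is not in the collection."""


class NoSiteError(DwarfcallError):
    """A primer has no acceptable binding site on the template."""


class AmbiguousPrimingError(DwarfcallError):
    """More than one valid PCR product is possible for a primer pair."""


class InvalidInputError(DwarfcallError, ValueError):
    """An operation received input that violates its preconditions."""


class InvalidSignatureError(DwarfcallError, ValueError):
    """A mutation signature cannot be applied to the given template."""


class GenotypeParseError(DwarfcallError, ValueError):
    """A genotype string does not follow the documented grammar."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DegenerateInputError(DwarfcallError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class UnsupportedDesignError(DwarfcallError, ValueError):
    """The experimental design is outside what the estimator supports."""
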