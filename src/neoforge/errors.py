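"""Exception hierarchy shared across the package."""


class NeoforgeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeoforgeError):
    """A file violated the expected on-disk format."""


class ValidationError(NeoforgeError):
    """A domain object violated one of its invariants."""


class VariantApplicationError(NeoforgeError):
    """A variant could not be applied to a transcript (ref mismatch,
    CDS-boundary spanning, untranslatable codon)."""


class DegenerateInputError(NeoforgeError):
    """Statistical input admits no meaningful answer (zero variance,
    no events, all-identical split values)."""
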