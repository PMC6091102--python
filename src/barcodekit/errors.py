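"""Exception types shared across the pipeline stages."""


class BarcodekitError(Exception):
    """Base class for all package errors."""


class HeaderParseError(BarcodekitError):
    """A FASTA header does not parse under the configured schema."""


class SequenceAlphabetError(BarcodekitError):
    """A sequence contains a character outside the nucleotide alphabet."""


class RaggedAlignmentError(BarcodekitError):
    """Rows of an alignment differ in gapped length."""


class UndefinedDistanceError(BarcodekitError):
    """A pairwise distance required by an operation is undefined."""


class OutgroupError(BarcodekitError):
    """The requested outgroup cannot root the tree."""


class ThresholdError(BarcodekitError):
    """No intraspecific pairs exist, so no automatic threshold can be set."""
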