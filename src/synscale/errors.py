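"""Exception hierarchy shared by all synscale modules."""


class SynscaleError(Exception):
    """Base class for all errors raised by synscale."""


class FormatError(SynscaleError):
    """A file could not be parsed (message names the offending location)."""


class SchemaError(SynscaleError):
    """A tabular input is missing a required column."""


class DimensionError(SynscaleError):
    """A matrix is not square or is too small for the operation."""


class AlignmentError(SynscaleError):
    """Two labeled objects do not share the same label set/order."""


class DomainError(SynscaleError):
    """A value lies outside the domain the operation requires."""


class MissingDataError(SynscaleError):
    """Required data (e.g. a 16S gene set) is absent."""


class InsufficientOrthologsError(SynscaleError):
    """Fewer than two ortholog pairs; the genome pair is skipped."""


class EmptySketchError(SynscaleError):
    """No k-mer survived sketching (all sequences shorter than k)."""


class ParameterError(SynscaleError):
    """Two objects were built with incompatible parameters."""
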