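"""Exception hierarchy for mitorder."""


class MitorderError(Exception):
    """Base class for all package errors."""


class FormatError(MitorderError):
    """Malformed input file (bad schema, bad ranks, unknown strand...)."""


class DuplicateGeneError(FormatError):
    """A protein-coding gene symbol occurs more than once in one genome."""


class SchemaError(FormatError):
    """A tabular fixture is missing required columns or rows."""


class UndefinedInputError(MitorderError):
    """Inputs are too small or degenerate for the statistic to be defined."""


class ContentMismatchError(MitorderError):
    """Operation requires identical gene content between the two genomes."""


class LookupError_(MitorderError):
    """A requested leaf, taxon or cluster is absent from the input."""


class FitError(MitorderError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateTableError(MitorderError):
    """Contingency table with a zero margin."""


class RateUndefinedError(MitorderError):
    """Rate normalization attempted with a non-positive denominator."""


class IntegrityError(MitorderError):
    """Packaged fixture does not match its recorded checksum."""
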