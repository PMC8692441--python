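"""Exception hierarchy shared by all loyscan modules."""


class LoyscanError(Exception):
    """Base class for all loyscan errors."""


class ValidationError(LoyscanError, ValueError):
    """A parameter or configuration value is outside its valid range.

    The message always names the offending field.
    """


class LayoutError(LoyscanError, ValueError):
    """A genome layout is malformed, or data refers to an unknown chromosome."""


class ParseError(LoyscanError, ValueError):
    """A text input (depth TSV, BED, table) could not be parsed.

    The message carries the 1-based line number where parsing failed.
    """


class ContractError(LoyscanError, RuntimeError):
    """An operation was called on data that violates its preconditions,
    e.g. profiling unnormalized tracks or re-normalizing a track."""


class AlignmentError(LoyscanError, ValueError):
    """Two window tracks do not share a common window grid."""


class EstimationError(LoyscanError, ValueError):
    """A dosage estimate cannot be formed (missing median, zero expectation)."""


class DegenerateInputError(LoyscanError, ValueError):
    """A statistical test received input with no usable information,
    e.g. all-zero values for a signed-rank test or constant x for OLS."""
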