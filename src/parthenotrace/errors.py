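"""Exception hierarchy shared across the package."""


class ParthenotraceError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ParthenotraceError, ValueError):
    """A file header or a genotype panel does not match expectations."""


class ParseError(ParthenotraceError, ValueError):
    """A cell or token could not be parsed; message names row and column."""


class ValidationError(ParthenotraceError, ValueError):
    """Structurally valid input violates a domain invariant."""


class CapacityError(ParthenotraceError, ValueError):
    """A format limit was exceeded (e.g. >999 alleles at one locus)."""


class IncompatibleGroupError(ParthenotraceError, ValueError):
    """A group of offspring cannot share a single dam."""


class UsageError(ParthenotraceError, ValueError):
    """An operation was called with arguments outside its contract."""


class UndefinedMetricError(ParthenotraceError, ArithmeticError):
    """A ratio metric has a zero denominator and is undefined."""
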