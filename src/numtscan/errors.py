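"""Exception hierarchy shared across the package."""


class NumtscanError(Exception):
    """Base class for all package errors."""


class InputError(NumtscanError, ValueError):
    """Malformed or empty input."""


class AlignmentError(NumtscanError, ValueError):
    """Sequences that violate alignment invariants (unequal lengths, no columns left)."""


class DegenerateTableError(NumtscanError, ValueError):
    """A contingency table with a zero margin or too few rows/columns."""


class SaturationError(NumtscanError, ValueError):
    """A distance correction whose logarithm argument is non-positive."""


class UndefinedContentError(NumtscanError, ValueError):
    """A composition statistic requested on a sequence with no unambiguous bases."""


class ComparisonUndefinedError(NumtscanError, ValueError):
    """A profile comparison requested on a zero-divergence pair."""


class ConfigurationError(NumtscanError, ValueError):
    """A screening configuration that fails its own sanity checks."""


class GenerationError(NumtscanError, RuntimeError):
    """The simulator could not satisfy its constraints (e.g. stop-free draw)."""
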