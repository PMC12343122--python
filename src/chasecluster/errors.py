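"""Exception hierarchy shared across the package."""


class ChaseClusterError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChaseClusterError):
    """A delimited-text input violates the documented column contract."""


class EmptyInputError(ChaseClusterError):
    """An input (file or matrix) is empty where content is required."""


class ReferentialIntegrityError(ChaseClusterError):
    """Occurrence records reference site ids absent from the site table."""


class DomainError(ChaseClusterError):
    """A value is outside the mathematical domain of an operation."""


class SizeError(ChaseClusterError):
    """A problem size precondition (e.g. k vs number of sites) is violated."""


class DegenerateInputError(ChaseClusterError):
    """An input is degenerate for the requested operation (e.g. all-zero
    dissimilarity matrix that cannot be max-normalized)."""


class ConfigError(ChaseClusterError):
    """A configuration object violates its invariants."""
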