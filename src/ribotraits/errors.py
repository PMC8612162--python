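"""Exception hierarchy shared across the package."""


class RibotraitsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RibotraitsError, ValueError):
    """Raised when a value violates an operation's preconditions."""


class InsufficientDataError(RibotraitsError, ValueError):
    """Raised when fewer data points are supplied than a fit requires."""


class ContractError(RibotraitsError, ValueError):
    """Raised when an object is used outside its declared state contract."""


class UndefinedRateError(RibotraitsError, ValueError):
    """Raised when a growth rate cannot be defined (e.g. all-zero counts)."""


class SchemaError(RibotraitsError, ValueError):
    """Raised when a tabular input is missing mandatory columns."""
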