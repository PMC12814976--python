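"""Exception hierarchy shared across the package."""


class FdcError(Exception):
    """Base class for all package errors."""


class FormatError(FdcError):
    """A file could not be parsed in its declared format."""


class EmptyInputError(FdcError):
    """An input collection that must be nonempty was empty."""


class CatalogError(FdcError):
    """An unknown fixture template was requested."""


class ParameterError(FdcError):
    """An argument violated an operation's preconditions."""


class ValidityError(FdcError):
    """A molecule failed sanitization where a valid one is required."""


class ContextError(FdcError):
    """A conditioning context was missing or inconsistent."""


class ModelError(FdcError):
    """A model was untrained, empty, or otherwise unusable."""


class NumericError(FdcError):
    """A non-finite value appeared during network evaluation."""
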