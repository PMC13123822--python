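"""Exception hierarchy shared across the package."""


class CarmapError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CarmapError, ValueError):
    """A parameter violates its documented range or precondition."""


class MissingReferenceError(CarmapError, KeyError):
    """A coordinate, chromosome or index refers to something that does not exist."""


class MalformedRecordError(CarmapError, ValueError):
    """An input record cannot be parsed or violates the format contract."""


class EmptyInputError(CarmapError, ValueError):
    """An operation received no usable input (zero windows, too few anchors...)."""


class DegenerateInputError(CarmapError, ValueError):
    """Input is syntactically valid but makes the statistic undefined."""
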