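"""Exception hierarchy shared across the package."""


class PainmeshError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PainmeshError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateGeometryError(PainmeshError, ValueError):
    """A landmark frame has no usable geometry (e.g. all points coincide)."""


class CapabilityError(PainmeshError, RuntimeError):
    """An optional capability (external extractor, mirror map) is missing."""


class FormatError(PainmeshError, ValueError):
    """A dataset container is unreadable or malformed."""


class ContractViolationError(PainmeshError, RuntimeError):
    """An operation was invoked in a way that breaks a pipeline contract,
    e.g. augmenting a test split."""
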