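"""Exception hierarchy shared across the package."""


class RnaMotifsError(Exception):
    """Base class for all package errors."""


class FormatError(RnaMotifsError):
    """A file or text blob could not be parsed in the declared format."""


class CapacityError(RnaMotifsError):
    """An input exceeds a documented structural limit (chains, pages, query size)."""


class ReferenceError_(RnaMotifsError):
    """A residue key or member does not resolve in the target structure."""


class IntegrityError_(RnaMotifsError):
    """Duplicate keys or other relational-integrity violations."""


class ContractError(RnaMotifsError):
    """A precondition of an operation was violated by the caller."""


class ModelError(RnaMotifsError):
    """A mathematical model is ill-posed for the given parameters."""
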