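"""Exception hierarchy.

CLI exit-code mapping: :class:`FormatError` -> 2, :class:`DomainError` -> 3.
Argument-validation failures raise plain :class:`ValueError`.
"""


class BreathgateError(Exception):
    """Base class for breathgate-specific failures."""


class FormatError(BreathgateError):
    """Malformed input file (bad header, non-monotone time, negative flow...)."""


class DomainError(BreathgateError):
    """A physically meaningful failure of the method itself."""


class InsufficientExhalationError(DomainError):
    """The exhaled volume is too small for the requested dead-space removal."""


class ContainerUnreachableError(DomainError):
    """Exhalation ends before the dead-space front clears the gas container."""


class NoTriggerError(DomainError):
    """Flow never exceeded the collection threshold, so the valve never armed."""
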