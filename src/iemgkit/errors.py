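"""Exception hierarchy for iemgkit."""


class IemgError(Exception):
    """Base class for all iemgkit errors."""


class FormatError(IemgError):
    """A file does not follow the published container layout.

    ``element`` names the missing or malformed element when known.
    """

    def __init__(self, message: str, element: str | None = None):
        super().__init__(message)
        self.element = element


class IntegrityError(IemgError):
    """An in-memory container violates one of its invariants."""


class UnknownCodeError(IemgError, LookupError):
    """A movement code does not match any protocol stage."""


class DesignError(IemgError):
    """A filter design request is infeasible (e.g. center above Nyquist)."""


class AlignmentError(IemgError):
    """Dual-stream sync verification failed (pulse-count mismatch)."""

    def __init__(self, message: str, count_a: int, count_b: int):
        super().__init__(message)
        self.count_a = count_a
        self.count_b = count_b


class LengthError(IemgError, ValueError):
    """An input signal is too short for the requested operation."""


class ConfigError(IemgError, ValueError):
    """A synthetic-session or protocol configuration is inconsistent."""
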