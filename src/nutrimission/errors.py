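"""Exception hierarchy shared across the engine."""

from __future__ import annotations


class NutrimissionError(Exception):
    """Base class for all engine errors."""


class ConfigurationError(NutrimissionError):
    """A configuration document is malformed or internally inconsistent."""


class ValidationError(NutrimissionError):
    """Input data violates a documented precondition.

    ``details`` carries machine-readable findings (e.g. the offending
    item_ids) so callers can surface them without parsing the message.
    """

    def __init__(self, message: str, details: list | None = None):
        super().__init__(message)
        self.details = details if details is not None else []


class StateError(NutrimissionError):
    """An operation was attempted in a state that does not allow it."""


class EngineError(NutrimissionError):
    """The inference engine failed (e.g. the cycle guard tripped)."""
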