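"""Exception hierarchy shared across the pipeline."""


class NlrevoError(Exception):
    """Base class for all package errors."""


class ParseError(NlrevoError, ValueError):
    """A file could not be parsed in its declared dialect."""


class ValidationError(NlrevoError, ValueError):
    """Parsed content violates an invariant (coordinates, uniqueness, ...)."""


class UsageError(NlrevoError, ValueError):
    """A function was called with an unsupported option."""
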