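"""Exception hierarchy shared by all lbdtrace modules."""


class LbdtraceError(Exception):
    """Base class for all package errors."""


class ParseError(LbdtraceError, ValueError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(LbdtraceError, ValueError):
    """Parsed data violated a structural invariant."""


class ConfigError(LbdtraceError, ValueError):
    """An inconsistent configuration was supplied."""
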