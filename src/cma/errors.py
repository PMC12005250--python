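"""Exception hierarchy for the cma package."""


class CMAError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CMAError, ValueError):
    """A configuration value is out of its admissible range or inconsistent."""


class ParseError(CMAError, ValueError):
    """A file could not be parsed in the requested dialect."""


class ValidationError(CMAError, ValueError):
    """An in-memory object violates one of its invariants."""
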