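"""Exception hierarchy for dtekit."""


class DTEError(Exception):
    """Base class for all dtekit errors."""


class FormatError(DTEError):
    """A trajectory table or config file does not conform to its dialect."""


class ValidationError(DTEError):
    """Data violates a declared invariant (non-monotone time, duplicate ids, ...)."""


class UnitError(DTEError):
    """Unknown or inconsistent stress unit."""
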