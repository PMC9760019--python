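"""Exception hierarchy shared across the package."""


class IsospecError(Exception):
    """Base class for all package errors."""


class SchemaError(IsospecError):
    """A required column is missing or the column mapping is invalid."""


class ParseError(IsospecError):
    """A cell could not be parsed; the message names the offending row."""


class IntegrityError(IsospecError):
    """Structural invariant violated (e.g. duplicate individual/tissue pair)."""


class DomainError(IsospecError):
    """A value lies outside its scientific domain."""


class DegenerateNicheError(IsospecError):
    """Total niche width is zero; the WIC/TNW ratio is undefined."""


class ConfigurationError(IsospecError):
    """A required configuration entry is absent or inconsistent."""


class ConvergenceError(IsospecError):
    """An iterative fit failed to converge and no override was given."""
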