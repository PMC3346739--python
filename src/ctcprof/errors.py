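"""Exception hierarchy for the ctcprof pipeline.

``ConfigError`` maps to CLI exit code 2, every other :class:`CtcProfError`
to exit code 3.
"""


class CtcProfError(Exception):
    """Base class for all ctcprof errors."""


class FormatError(CtcProfError):
    """A file does not conform to the declared dialect/schema."""


class IntegrityError(CtcProfError):
    """Internal inconsistency in a dataset (duplicates, broken invariants)."""


class RangeError(CtcProfError):
    """A value lies outside its documented range."""


class ConfigError(CtcProfError):
    """Invalid configuration or parameters."""


class DataError(CtcProfError):
    """A computation cannot proceed on the given data."""
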