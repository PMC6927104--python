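"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`CdemapError`, so callers (and the CLI) can distinguish bad input
from genuine bugs.
"""


class CdemapError(Exception):
    """Base class for all errors raised by cdemap."""


class SchemaError(CdemapError):
    """An input file does not match the canonical corpus schema."""


class DuplicateIdError(SchemaError):
    """Two records in one corpus share a public_id."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(f"duplicate public_id values: {', '.join(self.offenders)}")


class ValidationError(CdemapError):
    """A record or corpus violates an operation's precondition."""


class ConfigurationError(CdemapError):
    """A configuration object holds an out-of-range or inconsistent value."""


class DegenerateInputError(CdemapError):
    """The input is too small for the statistic to be defined.

    Raised e.g. for a within-class average over a single-member class, a
    between-class average with no outside records, or a concept-overlap
    statistic over a concept-free test corpus.
    """
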